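"""Design of barcoded proximity-ligation H-probe panels.

A PLISH detection site is a ~40-nt window on a target transcript split at a
central 5'-AG-3' or 5'-TA-3' dinucleotide. The left (HL) and right (HR) H
probes carry ~20-nt binding arms complementary to the two halves of the site,
plus template-specific overhangs that hybridize to a circle and a common
31-base bridge oligonucleotide. Ligation closes the circle, rolling-circle
amplification copies it into a tandem amplicon, and a fluorescent imager
oligonucleotide reads out the barcode embedded in the circle.

This module enumerates candidate sites, screens them against a background
transcriptome for shared >=k-mers, adjusts arm lengths into a melting
temperature window, and assembles complete ready-to-order oligo panels.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .seqs import (
    DNA_ALPHABET,
    Transcript,
    gc_fraction,
    kmers,
    max_homopolymer,
    revcomp,
)

TM_RANGE_DEFAULT = (45.0, 65.0)
ARM_LENGTH_RANGE = (12, 30)
ARM_NOMINAL = 20
SCREEN_K_DEFAULT = 10
SELF_COMP_MAX_DEFAULT = 6
BRIDGE_LENGTH = 31
CIRCLE_ARM_LENGTH = 11
BARCODE_LENGTH = 16
MAX_H_CONC_NM = 1000.0
STANDARD_H_CONC_NM = 100.0
MAX_CHANNELS_PER_CYCLE = 5
N_TEMPLATES = 8

ImagerMode = Literal["standard", "erasable_dU", "rapid_short"]


# ---------------------------------------------------------------------------
# detection sites


@dataclass(frozen=True)
class DetectionSite:
    """An interval on a target transcript where the two H probes abut.

    Coordinates are 1-based inclusive; ``junction_pos`` is the coordinate of
    the first base of the AG/TA junction dinucleotide, which terminates the
    site's 5' half.
    """

    transcript_id: str
    start: int
    end: int
    junction_pos: int
    dinucleotide: str

    def __post_init__(self) -> None:
        if self.dinucleotide not in ("AG", "TA"):
            raise ValueError(f"junction dinucleotide must be AG or TA, got {self.dinucleotide!r}")
        if not (self.start <= self.junction_pos < self.end):
            raise ValueError("junction must lie strictly inside the site")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def halves(self, transcript: Transcript) -> tuple[str, str]:
        """(5' half, 3' half) of the site sequence, split after the first
        junction base."""
        left = transcript.subseq(self.start, self.junction_pos)
        right = transcript.subseq(self.junction_pos + 1, self.end)
        return left, right

    def sequence(self, transcript: Transcript) -> str:
        return transcript.subseq(self.start, self.end)


def _junction_split(site_length: int) -> int:
    """Offset of the first junction base from the site start.

    The 5' half ends with the first base of the AG/TA dinucleotide
    (... A | G ... and ... T | A ...), so for a 40-nt site the junction base is
    the 20th site position. Both split conventions satisfy published site
    coordinates; this one is fixed here and used everywhere.
    """
    return site_length // 2 - 1


def find_detection_sites(
    transcript: Transcript,
    site_length: int = 40,
    max_sites: int = 10,
) -> list[DetectionSite]:
    """Enumerate non-overlapping detection sites with a central AG/TA junction.

    All windows of ``site_length`` whose central dinucleotide is AG or TA are
    enumerated, tiled greedily left-to-right without overlap, and, if more
    than ``max_sites`` survive, subsampled at evenly spaced indices so the
    selection spreads along the transcript. Deterministic.
    """
    if not 1 <= max_sites <= 10:
        raise ValueError(f"max_sites must be in [1, 10], got {max_sites}")
    if site_length < 8 or site_length % 2:
        raise ValueError(f"site_length must be even and >= 8, got {site_length}")
    if len(transcript) < site_length:
        raise ValueError(
            f"transcript {transcript.id!r} ({len(transcript)} nt) is shorter "
            f"than the site length {site_length}"
        )
    seq = transcript.sequence
    off = _junction_split(site_length)
    candidates: list[DetectionSite] = []
    for start0 in range(len(seq) - site_length + 1):
        j0 = start0 + off  # 0-based first junction base
        if seq[j0 : j0 + 2] in ("AG", "TA"):
            candidates.append(
                DetectionSite(
                    transcript_id=transcript.id,
                    start=start0 + 1,
                    end=start0 + site_length,
                    junction_pos=j0 + 1,
                    dinucleotide=seq[j0 : j0 + 2],
                )
            )
    # greedy left-to-right non-overlapping tiling
    tiled: list[DetectionSite] = []
    last_end = 0
    for c in candidates:
        if c.start > last_end:
            tiled.append(c)
            last_end = c.end
    if len(tiled) <= max_sites:
        return tiled
    if max_sites == 1:
        return [tiled[(len(tiled) - 1) // 2]]
    idx = [round(i * (len(tiled) - 1) / (max_sites - 1)) for i in range(max_sites)]
    return [tiled[i] for i in sorted(set(idx))]


# ---------------------------------------------------------------------------
# thermodynamics


def melting_temperature(seq: str, oligo_conc_uM: float = 0.25, salt_mM: float = 50.0) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Two-state DNA/DNA nearest-neighbor model (unified parameter table) with a
    monovalent-salt correction, evaluated at a total strand concentration of
    ``oligo_conc_uM`` split equally between the two strands. These defaults
    (0.25 uM oligo, 50 mM Na+) match common oligo-analyzer settings.
    """
    s = seq.upper()
    if len(s) < 8:
        raise ValueError(f"sequence too short for a duplex Tm estimate ({len(s)} < 8 nt)")
    for i, ch in enumerate(s):
        if ch not in DNA_ALPHABET:
            raise ValueError(f"ambiguous or invalid base {ch!r} at position {i + 1}")
    half_nM = oligo_conc_uM * 1000.0 / 2.0
    return float(_mt.Tm_NN(s, Na=salt_mM, dnac1=half_nM, dnac2=half_nM))


# ---------------------------------------------------------------------------
# arm-length adjustment


@dataclass(frozen=True)
class ArmAdjustment:
    """Result of fitting both binding arms into the Tm window.

    If ``ok``, ``site`` carries the (possibly resized) coordinates, the two
    target-side arm sequences concatenate to the adjusted site, and both Tm
    values fall in the requested window. Otherwise ``reason`` explains why the
    site is unusable.
    """

    ok: bool
    site: DetectionSite | None
    left_arm_target: str = ""
    right_arm_target: str = ""
    hl_tm: float = float("nan")
    hr_tm: float = float("nan")
    reason: str = ""


def _fit_one_arm(
    seq: str,
    junction0: int,
    side: Literal["left", "right"],
    tm_range: tuple[float, float],
    nominal: int,
    length_range: tuple[int, int],
) -> tuple[int, float] | str:
    """Grow/shrink one arm at its distal end until its duplex Tm is in range.

    Returns (length, tm) or a failure reason. ``junction0`` is the 0-based
    index of the first junction base; the left arm ends at it (inclusive), the
    right arm starts just after it.
    """
    lo, hi = tm_range
    min_len, max_len = length_range
    avail = junction0 + 1 if side == "left" else len(seq) - junction0 - 1

    def arm(n: int) -> str:
        if side == "left":
            return seq[junction0 - n + 1 : junction0 + 1]
        return seq[junction0 + 1 : junction0 + 1 + n]

    n = min(nominal, max_len, avail)
    if n < min_len:
        return f"{side} arm truncated by transcript end ({avail} nt available)"
    seen: set[int] = set()
    while n not in seen:
        seen.add(n)
        tm = melting_temperature(revcomp(arm(n)))
        if lo <= tm <= hi:
            return n, tm
        if tm < lo:
            if n >= max_len or n >= avail:
                return f"{side} arm Tm {tm:.1f}C below window at maximal length {n}"
            n += 1
        else:
            if n <= min_len:
                return f"{side} arm Tm {tm:.1f}C above window at minimal length {n}"
            n -= 1
    return f"{side} arm oscillates without entering the Tm window"


def adjust_arm_lengths(
    site: DetectionSite,
    transcript: Transcript,
    tm_range: tuple[float, float] = TM_RANGE_DEFAULT,
    nominal: int = ARM_NOMINAL,
    length_range: tuple[int, int] = ARM_LENGTH_RANGE,
) -> ArmAdjustment:
    """Resize both binding arms one base at a time until each Tm is in range.

    Arms start at ``nominal`` bases from the junction outward and are extended
    or trimmed at their distal ends within ``length_range``. Failure flags the
    site rather than raising.
    """
    seq = transcript.sequence
    j0 = site.junction_pos - 1
    left = _fit_one_arm(seq, j0, "left", tm_range, nominal, length_range)
    if isinstance(left, str):
        return ArmAdjustment(ok=False, site=None, reason=left)
    right = _fit_one_arm(seq, j0, "right", tm_range, nominal, length_range)
    if isinstance(right, str):
        return ArmAdjustment(ok=False, site=None, reason=right)
    (ln, ltm), (rn, rtm) = left, right
    new_site = DetectionSite(
        transcript_id=site.transcript_id,
        start=site.junction_pos - ln + 1,
        end=site.junction_pos + rn,
        junction_pos=site.junction_pos,
        dinucleotide=site.dinucleotide,
    )
    l_seq, r_seq = new_site.halves(transcript)
    return ArmAdjustment(
        ok=True, site=new_site, left_arm_target=l_seq, right_arm_target=r_seq,
        hl_tm=ltm, hr_tm=rtm,
    )


# ---------------------------------------------------------------------------
# specificity screen


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reason: str = ""


class BackgroundIndex:
    """Exact k-mer index over background transcripts for off-target screening.

    By default only the sense strand is indexed (H probes hybridize to RNA);
    ``both_strands=True`` adds the antisense strand for BLAST-style parity.
    """

    def __init__(self, transcripts: Iterable[Transcript], k: int = SCREEN_K_DEFAULT,
                 both_strands: bool = False):
        if k < 4:
            raise ValueError(f"screen k-mer length must be >= 4, got {k}")
        self.k = k
        self.both_strands = both_strands
        self._index: dict[str, set[str]] = {}
        for t in transcripts:
            strands = [t.sequence]
            if both_strands:
                strands.append(revcomp(t.sequence))
            for s in strands:
                for i in range(len(s) - k + 1):
                    self._index.setdefault(s[i : i + k], set()).add(t.id)

    def hits(self, seq: str, exempt_ids: frozenset[str] = frozenset()) -> list[tuple[str, str]]:
        """(k-mer, transcript id) pairs shared between ``seq`` and the index."""
        out = []
        for i in range(len(seq) - self.k + 1):
            km = seq[i : i + self.k]
            for tid in sorted(self._index.get(km, ())):
                if tid not in exempt_ids:
                    out.append((km, tid))
        return out


def specificity_screen(
    site: DetectionSite,
    background: Sequence[Transcript] | BackgroundIndex,
    transcript: Transcript,
    k: int = SCREEN_K_DEFAULT,
    exempt_ids: Iterable[str] = (),
) -> ScreenResult:
    """Fail a site that shares >= k contiguous nucleotides with a non-target RNA.

    Equivalent to exact substring search: the site fails iff any length-k
    substring of its sequence occurs verbatim in a background transcript whose
    id is not exempt (the target's own isoforms are exempt by precondition).
    """
    exempt = frozenset(exempt_ids) | {site.transcript_id}
    index = (
        background
        if isinstance(background, BackgroundIndex)
        else BackgroundIndex(background, k=k)
    )
    hits = index.hits(site.sequence(transcript), exempt_ids=exempt)
    if hits:
        km, tid = hits[0]
        return ScreenResult(False, f"shares {index.k}-mer {km} with {tid}")
    return ScreenResult(True)


def self_complementarity(seq: str) -> int:
    """Length of the longest exact complementary self-match.

    Computed as the longest common substring between the sequence and its own
    reverse complement; a perfect palindrome scores its full length.
    """
    s = seq.upper()
    if not s:
        return 0
    t = revcomp(s)
    n = len(s)
    prev = [0] * (n + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        si = s[i - 1]
        for j in range(1, n + 1):
            if si == t[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


# ---------------------------------------------------------------------------
# design templates, barcodes and oligo assembly


@dataclass(frozen=True)
class DesignTemplate:
    """One of the eight modular overhang templates routing a site to a barcode."""

    template_id: int
    l_overhang: str  # 5' overhang on HL
    r_overhang: str  # 3' overhang on HR


def _orthogonal(seq: str, pool: list[str], k: int = 8) -> bool:
    """No shared >=k-mer and no cross-complementary >=k-mer against the pool."""
    km = kmers(seq, k) | kmers(revcomp(seq), k)
    return all(not (km & kmers(other, k)) for other in pool)


def _random_oligo(rng: np.random.Generator, length: int, pool: list[str],
                  max_self_comp: int = SELF_COMP_MAX_DEFAULT, max_tries: int = 10000) -> str:
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        s = "".join(rng.choice(bases, size=length))
        if not 0.4 <= gc_fraction(s) <= 0.6:
            continue
        if max_homopolymer(s) > 3:
            continue
        if self_complementarity(s) > max_self_comp:
            continue
        if _orthogonal(s, pool):
            return s
    raise RuntimeError(f"could not draw an orthogonal {length}-mer after {max_tries} tries")


_TEMPLATE_SEED = 20180409  # fixed: templates must be stable across runs
_templates_cache: list[DesignTemplate] | None = None
_bridge_cache: str | None = None


def design_templates() -> list[DesignTemplate]:
    """The eight built-in overhang templates (deterministic).

    Overhangs are 11 nt (the circle's terminal complementarity arms), drawn
    once from a fixed-seed generator under GC 40-60%, homopolymer <= 3 and
    pairwise-orthogonality constraints. Users with their own template table can
    load it with :func:`load_templates`.
    """
    global _templates_cache
    if _templates_cache is None:
        rng = np.random.default_rng(_TEMPLATE_SEED)
        pool: list[str] = []
        out = []
        for tid in range(1, N_TEMPLATES + 1):
            l_oh = _random_oligo(rng, CIRCLE_ARM_LENGTH, pool)
            pool.append(l_oh)
            r_oh = _random_oligo(rng, CIRCLE_ARM_LENGTH, pool)
            pool.append(r_oh)
            out.append(DesignTemplate(tid, l_oh, r_oh))
        _templates_cache = out
    return _templates_cache


def load_templates(path: str | Path) -> list[DesignTemplate]:
    """Load overhang templates from a TSV with columns template_id, l_overhang, r_overhang."""
    df = pd.read_csv(path, sep="\t")
    return [
        DesignTemplate(int(r.template_id), str(r.l_overhang), str(r.r_overhang))
        for r in df.itertuples()
    ]


def get_template(template_id: int, templates: Sequence[DesignTemplate] | None = None) -> DesignTemplate:
    templates = templates if templates is not None else design_templates()
    for t in templates:
        if t.template_id == template_id:
            return t
    raise KeyError(f"unknown design template id {template_id}")


def common_bridge() -> str:
    """The common 31-base bridge oligonucleotide shared by all templates."""
    global _bridge_cache
    if _bridge_cache is None:
        rng = np.random.default_rng(_TEMPLATE_SEED + 1)
        _bridge_cache = _random_oligo(rng, BRIDGE_LENGTH, [])
    return _bridge_cache


@dataclass(frozen=True)
class Imager:
    """A fluorophore-conjugated readout oligo hybridizing to amplicon barcode repeats."""

    sequence: str  # may contain U in erasable_dU mode
    mode: ImagerMode
    fluor: str


def make_imager(barcode_seq: str, mode: ImagerMode, fluor: str) -> Imager:
    """Derive an imager oligo for one readout mode.

    standard: a 15-20 nt stretch of the barcode; erasable_dU: the same with
    every dT replaced by dU (USER-enzyme erasable); rapid_short: a 10-11 nt
    stretch whose duplex is unstable enough to wash off.
    """
    n = len(barcode_seq)
    if mode in ("standard", "erasable_dU"):
        if n < 15:
            raise ValueError(f"barcode of {n} nt cannot host a 15-20 nt imager")
        seq = barcode_seq[: min(n, 20)]
        if mode == "erasable_dU":
            seq = seq.replace("T", "U")
        return Imager(seq, mode, fluor)
    if mode == "rapid_short":
        if n < 10:
            raise ValueError(f"barcode of {n} nt cannot host a 10-11 nt imager")
        return Imager(barcode_seq[: min(n, 11)], mode, fluor)
    raise ValueError(f"unknown imager mode {mode!r}")


@dataclass(frozen=True)
class BarcodeSet:
    """The circle/bridge/imager oligo set carrying one barcode channel."""

    barcode_id: str
    barcode_seq: str
    circle_seq: str
    bridge_seq: str
    template_id: int
    imagers: dict[ImagerMode, Imager]

    def simulated_amplicon(self, n_repeats: int = 3) -> str:
        """Tandem reverse complement of the circle, as RCA would produce."""
        return revcomp(self.circle_seq) * n_repeats


class BarcodeRegistry:
    """Issues barcodes and enforces pairwise orthogonality across a panel.

    Orthogonality: no two issued barcodes share a >=8-mer, nor is any >=8-mer
    of one complementary to the other (configurable via ``ortho_k``).
    """

    def __init__(self, rng: np.random.Generator | None = None, ortho_k: int = 8):
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.ortho_k = ortho_k
        self.issued: dict[str, str] = {}

    def new_barcode(self, barcode_id: str, length: int = BARCODE_LENGTH) -> str:
        pool = list(self.issued.values())
        seq = _random_oligo(self.rng, length, pool)
        self.register(barcode_id, seq)
        return seq

    def register(self, barcode_id: str, seq: str) -> None:
        for other_id, other in self.issued.items():
            if not _orthogonal(seq, [other], k=self.ortho_k):
                raise ValueError(
                    f"barcode {barcode_id!r} clashes with previously issued "
                    f"{other_id!r} (shared or complementary >={self.ortho_k}-mer)"
                )
        self.issued[barcode_id] = seq


def assemble_barcode_set(
    barcode_id: str,
    template_id: int,
    modes: Sequence[ImagerMode] = ("standard",),
    fluor: str = "Cy3",
    registry: BarcodeRegistry | None = None,
    barcode_seq: str | None = None,
    templates: Sequence[DesignTemplate] | None = None,
) -> BarcodeSet:
    """Build the circle, bridge and imager oligos for one barcode channel.

    The circle is 60 nt: an 11-nt arm complementary to the HL overhang, a
    38-nt core embedding the barcode, and an 11-nt arm complementary to the HR
    overhang. Imagers are substrings of the circle (the barcode), so their
    reverse complements occur in the tandem RCA amplicon.
    """
    tpl = get_template(template_id, templates)
    registry = registry if registry is not None else BarcodeRegistry()
    if barcode_seq is None:
        barcode_seq = registry.new_barcode(barcode_id)
    else:
        registry.register(barcode_id, barcode_seq)
    core_len = 60 - 2 * CIRCLE_ARM_LENGTH
    filler = _random_oligo(registry.rng, core_len - len(barcode_seq),
                           list(registry.issued.values()))
    circle = revcomp(tpl.l_overhang) + barcode_seq + filler + revcomp(tpl.r_overhang)
    imagers = {m: make_imager(barcode_seq, m, fluor) for m in modes}
    return BarcodeSet(
        barcode_id=barcode_id,
        barcode_seq=barcode_seq,
        circle_seq=circle,
        bridge_seq=common_bridge(),
        template_id=template_id,
        imagers=imagers,
    )


@dataclass(frozen=True)
class HProbePair:
    """The HL/HR probe pair for one detection site.

    ``hl_binding``/``hr_binding`` are the reverse complements of the site's 5'
    and 3' halves; the full HL is overhang + binding (5' overhang) and the full
    HR is binding + overhang (3' overhang primes replication).
    """

    site: DetectionSite
    hl_binding: str
    hr_binding: str
    hl_overhang: str
    hr_overhang: str
    hl_tm: float
    hr_tm: float
    template_id: int

    @property
    def hl_full(self) -> str:
        return self.hl_overhang + self.hl_binding

    @property
    def hr_full(self) -> str:
        return self.hr_binding + self.hr_overhang


def assemble_h_pair(
    site: DetectionSite,
    transcript: Transcript,
    template_id: int,
    arms: ArmAdjustment | None = None,
    templates: Sequence[DesignTemplate] | None = None,
) -> HProbePair:
    """Assemble the HL/HR pair for an (arm-adjusted) detection site."""
    tpl = get_template(template_id, templates)
    if arms is None:
        arms = adjust_arm_lengths(site, transcript)
    if not arms.ok or arms.site is None:
        raise ValueError(f"site is unusable: {arms.reason}")
    return HProbePair(
        site=arms.site,
        hl_binding=revcomp(arms.left_arm_target),
        hr_binding=revcomp(arms.right_arm_target),
        hl_overhang=tpl.l_overhang,
        hr_overhang=tpl.r_overhang,
        hl_tm=arms.hl_tm,
        hr_tm=arms.hr_tm,
        template_id=template_id,
    )


# ---------------------------------------------------------------------------
# panel assembly


def h_probe_concentration_nM(n_pairs: int) -> float:
    """Per-H-probe working concentration under the 1000 nM pro-rating rule.

    Each pair contributes two H oligos. Up to five pairs, every H probe is at
    100 nM; beyond that, concentrations are pro-rated so the per-target sum is
    exactly 1000 nM (e.g. 10 pairs -> 20 probes at 50 nM each).
    """
    if n_pairs < 1:
        raise ValueError("a target needs at least one probe pair")
    if n_pairs <= 5:
        return STANDARD_H_CONC_NM
    return MAX_H_CONC_NM / (2 * n_pairs)


@dataclass
class TargetPanel:
    target_id: str
    pairs: list[HProbePair]
    barcode: BarcodeSet
    fluor: str
    cycle: int
    h_conc_nM: float


@dataclass
class ProbePanel:
    """A complete multiplexed probe panel with cycle/channel routing."""

    targets: list[TargetPanel]
    failures: dict[str, str]
    seed: int
    params: dict[str, object]

    def order_sheet(self) -> pd.DataFrame:
        rows = []
        for tp in self.targets:
            for p in tp.pairs:
                loc = f"{p.site.start}_{p.site.end}"
                common = dict(target_id=tp.target_id, site_start=p.site.start,
                              site_end=p.site.end, template_id=p.template_id,
                              fluor=tp.fluor, cycle=tp.cycle)
                rows.append(dict(oligo_name=f"{tp.target_id}_s{loc}_HL",
                                 sequence=p.hl_full, type="HL",
                                 concentration_nM=tp.h_conc_nM,
                                 tm_C=round(p.hl_tm, 2), **common))
                rows.append(dict(oligo_name=f"{tp.target_id}_s{loc}_HR",
                                 sequence=p.hr_full, type="HR",
                                 concentration_nM=tp.h_conc_nM,
                                 tm_C=round(p.hr_tm, 2), **common))
            shared = dict(target_id=tp.target_id, site_start=0, site_end=0,
                          template_id=tp.barcode.template_id, fluor=tp.fluor,
                          cycle=tp.cycle, tm_C=float("nan"))
            rows.append(dict(oligo_name=f"{tp.target_id}_bridge",
                             sequence=tp.barcode.bridge_seq, type="bridge",
                             concentration_nM=6000.0, **shared))
            rows.append(dict(oligo_name=f"{tp.target_id}_circle",
                             sequence=tp.barcode.circle_seq, type="circle",
                             concentration_nM=6000.0, **shared))
            for mode, im in tp.barcode.imagers.items():
                rows.append(dict(oligo_name=f"{tp.target_id}_imager_{mode}",
                                 sequence=im.sequence, type="imager",
                                 concentration_nM=100.0, **shared))
        cols = ["oligo_name", "sequence", "type", "target_id", "site_start",
                "site_end", "template_id", "fluor", "cycle",
                "concentration_nM", "tm_C"]
        return pd.DataFrame(rows, columns=cols)

    def manifest(self) -> str:
        lines = [f"{k}\t{v}" for k, v in sorted(self.params.items())]
        lines.append(f"seed\t{self.seed}")
        lines.append(f"n_targets\t{len(self.targets)}")
        lines.append(f"n_failures\t{len(self.failures)}")
        for tid, reason in sorted(self.failures.items()):
            lines.append(f"failure:{tid}\t{reason}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.order_sheet().to_csv(outdir / "order_sheet.tsv", sep="\t", index=False)
        (outdir / "panel_manifest.txt").write_text(self.manifest())


def _base_id(tid: str) -> str:
    return tid.split(".")[0].split("|")[0]


def design_panel(
    targets: Sequence[Transcript],
    background: Sequence[Transcript],
    sites_per_target: int = 4,
    fluor_palette: Sequence[str] = ("AF488", "Cy3", "Cy5", "AF750"),
    n_cycles: int = 1,
    seed: int = 0,
    site_length: int = 40,
    screen_k: int = SCREEN_K_DEFAULT,
    modes: Sequence[ImagerMode] = ("standard", "erasable_dU"),
    tm_range: tuple[float, float] = TM_RANGE_DEFAULT,
) -> ProbePanel:
    """Run the full per-target design pipeline and route targets to
    (cycle, channel) slots.

    Pipeline per target: site enumeration -> off-target k-mer screen -> arm Tm
    adjustment -> H-pair assembly -> barcode/circle/imager assembly. Targets
    with zero surviving sites are reported under ``failures`` and the panel is
    still emitted for the rest. Deterministic for fixed inputs and seed.
    """
    if len(fluor_palette) > MAX_CHANNELS_PER_CYCLE:
        raise ValueError(f"at most {MAX_CHANNELS_PER_CYCLE} fluorophores per cycle")
    if len(targets) > n_cycles * len(fluor_palette):
        raise ValueError(
            f"{len(targets)} targets exceed {n_cycles} cycles x "
            f"{len(fluor_palette)} channels"
        )
    index = BackgroundIndex(background, k=screen_k)
    registry = BarcodeRegistry(rng=np.random.default_rng(seed))
    panels: list[TargetPanel] = []
    failures: dict[str, str] = {}
    for i, t in enumerate(targets):
        template_id = i % N_TEMPLATES + 1
        fluor = fluor_palette[i % len(fluor_palette)]
        cycle = i // len(fluor_palette) + 1
        exempt = {b.id for b in background if _base_id(b.id) == _base_id(t.id)}
        reasons: list[str] = []
        try:
            sites = find_detection_sites(t, site_length=site_length, max_sites=sites_per_target)
        except ValueError as e:
            failures[t.id] = str(e)
            continue
        pairs: list[HProbePair] = []
        for s in sites:
            verdict = specificity_screen(s, index, t, exempt_ids=exempt)
            if not verdict.passed:
                reasons.append(f"site {s.start}-{s.end}: {verdict.reason}")
                continue
            arms = adjust_arm_lengths(s, t, tm_range=tm_range)
            if not arms.ok:
                reasons.append(f"site {s.start}-{s.end}: {arms.reason}")
                continue
            pairs.append(assemble_h_pair(s, t, template_id, arms=arms))
        if not pairs:
            failures[t.id] = "; ".join(reasons) if reasons else "no AG/TA junction site found"
            continue
        barcode = assemble_barcode_set(
            barcode_id=f"bc_{t.id}", template_id=template_id, modes=modes,
            fluor=fluor, registry=registry,
        )
        panels.append(TargetPanel(
            target_id=t.id, pairs=pairs, barcode=barcode, fluor=fluor,
            cycle=cycle, h_conc_nM=h_probe_concentration_nM(len(pairs)),
        ))
    params = dict(sites_per_target=sites_per_target, site_length=site_length,
                  screen_k=screen_k, n_cycles=n_cycles,
                  palette=",".join(fluor_palette),
                  tm_range=f"{tm_range[0]}-{tm_range[1]}")
    return ProbePanel(targets=panels, failures=failures, seed=seed, params=params)
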