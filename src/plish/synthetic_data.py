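"""Synthetic inputs for every stage of the toolkit.

Three generators make the package testable end to end without any downloads:

* :func:`gen_transcriptome` — random target/background transcript sets with
  controllable off-target k-mer sharing (planted 10-mer collisions, listed in
  a manifest so the specificity screen's verdicts have ground truth);
* :func:`gen_calibration_curve` — binomial cells-positive counts drawn from
  the Poisson detection model, for calibration-fit recovery tests;
* :func:`gen_tissue_images` — multi-cycle, multi-channel fields with planted
  nuclei, cell classes, Poisson puncta counts, negative-binomial puncta
  amplitudes, autofluorescent background and per-cycle translation offsets,
  together with full ground-truth tables.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detection_model import CalibrationModel, detection_fraction, nb_dispersion_for_cv
from .image_quant import FieldImage, _translate
from .probe_design import find_detection_sites
from .seqs import Transcript, kmers

DEFAULT_GENES = ("Sftpc", "Scgb1a1", "Hopx", "Foxj1", "Cd68", "Pecam1", "Col1a1", "Ager")


# ---------------------------------------------------------------------------
# transcriptomes with planted off-target collisions


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _scrub_background(seq: str, target_kmers: set[str], rng: np.random.Generator,
                      k: int, protected: set[int] = frozenset()) -> str:
    """Mutate bases until the sequence shares no k-mer with the target set.

    Positions in ``protected`` (0-based) are never touched, so planted
    collisions survive scrubbing.
    """
    s = list(seq)
    bases = "ACGT"
    for _ in range(200):
        dirty = False
        for i in range(len(s) - k + 1):
            if "".join(s[i : i + k]) in target_kmers:
                if all(j in protected for j in range(i, i + k)):
                    continue
                free = [j for j in range(i, i + k) if j not in protected]
                j = free[len(free) // 2]
                s[j] = bases[(bases.index(s[j]) + 1 + rng.integers(0, 3)) % 4]
                dirty = True
        if not dirty:
            return "".join(s)
    raise RuntimeError("could not scrub accidental k-mer collisions")


def gen_transcriptome(
    n_targets: int = 4,
    n_background: int = 20,
    length_range: tuple[int, int] = (1000, 2500),
    planted_collisions: int = 0,
    seed: int = 0,
    k: int = 10,
    sites_per_target: int = 4,
) -> tuple[list[Transcript], list[Transcript], pd.DataFrame]:
    """Random transcriptome with exactly the requested off-target structure.

    Background transcripts are scrubbed of accidental >=k-mer sharing with any
    target, then each planted collision copies the central k-mer of one
    detection site into a named background transcript, so precisely the
    manifest's sites fail the specificity screen. The manifest has columns
    target_id, site_start, site_end, background_id, kmer, bg_position (1-based).
    """
    lo, hi = length_range
    if lo < 200:
        raise ValueError("transcript lengths must be >= 200")
    rng = np.random.default_rng(seed)
    targets = [
        Transcript(id=f"target_{i + 1}", sequence=_random_seq(rng, int(rng.integers(lo, hi + 1))),
                   role="target")
        for i in range(n_targets)
    ]
    target_kmers: set[str] = set()
    for t in targets:
        target_kmers |= kmers(t.sequence, k)
    bg_seqs = [
        _scrub_background(_random_seq(rng, int(rng.integers(lo, hi + 1))),
                          target_kmers, rng, k)
        for _ in range(n_background)
    ]
    # collect plantable sites round-robin over targets
    all_sites = []
    for t in targets:
        for s in find_detection_sites(t, max_sites=sites_per_target):
            all_sites.append((t, s))
    if planted_collisions > len(all_sites):
        raise ValueError(
            f"cannot plant {planted_collisions} collisions: only {len(all_sites)} sites"
        )
    order = sorted(range(len(all_sites)),
                   key=lambda i: (i % n_targets, i // n_targets))
    rows = []
    protected: dict[int, set[int]] = {}
    for j in range(planted_collisions):
        t, site = all_sites[order[j]]
        mid = site.start + site.length // 2 - k // 2  # 1-based
        km = t.subseq(mid, mid + k - 1)
        bi = j % n_background
        pos0 = int(rng.integers(50, len(bg_seqs[bi]) - 50 - k))
        s = list(bg_seqs[bi])
        s[pos0 : pos0 + k] = km
        bg_seqs[bi] = "".join(s)
        protected.setdefault(bi, set()).update(range(pos0, pos0 + k))
        rows.append(dict(target_id=t.id, site_start=site.start, site_end=site.end,
                         background_id=f"bg_{bi + 1}", kmer=km, bg_position=pos0 + 1))
    # planting can create fresh junction k-mers; scrub again around them
    planted_kmers = {r["kmer"] for r in rows}
    for bi in range(n_background):
        bg_seqs[bi] = _scrub_background(
            bg_seqs[bi], target_kmers - planted_kmers, rng, k,
            protected=protected.get(bi, set()),
        )
    backgrounds = [
        Transcript(id=f"bg_{i + 1}", sequence=s, role="background")
        for i, s in enumerate(bg_seqs)
    ]
    manifest = pd.DataFrame(
        rows, columns=["target_id", "site_start", "site_end", "background_id",
                       "kmer", "bg_position"],
    )
    return targets, backgrounds, manifest


# ---------------------------------------------------------------------------
# calibration curves


def gen_calibration_curve(
    c: float = 2.5,
    fpkm_grid: Sequence[float] | None = None,
    n_cells: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated (fpkm, n_cells, n_positive) qPCR-style calibration table.

    Positives are Binomial(n_cells, 1 - exp(-c * fpkm)) per grid point. The
    default grid is 36 log-spaced FPKM values spanning 0.05-5, emulating a
    36-gene single-cell qPCR panel across the sensitive part of the curve.
    """
    if c <= 0:
        raise ValueError("copies-per-FPKM constant must be positive")
    if fpkm_grid is None:
        fpkm_grid = np.geomspace(0.05, 5.0, 36)
    rng = np.random.default_rng(seed)
    model = CalibrationModel(copies_per_fpkm=c)
    rows = [
        dict(fpkm=f, n_cells=n_cells,
             n_positive=int(rng.binomial(n_cells, detection_fraction(f, model))))
        for f in fpkm_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tissue images


def default_class_rates(n_classes: int = 10, genes: Sequence[str] = DEFAULT_GENES,
                        high: float = 25.0, low: float = 0.5) -> pd.DataFrame:
    """Planted per-class expected puncta counts with marker-like structure.

    Each of the first ``len(genes)`` classes is high in exactly one gene;
    remaining classes are dual-positive in consecutive gene pairs (a
    BASC-like pattern for the Sftpc/Scgb1a1 pair). Fixture parameters, not
    biological claims.
    """
    genes = list(genes)
    rates = np.full((n_classes, len(genes)), low)
    for cls in range(n_classes):
        if cls < len(genes):
            rates[cls, cls] = high
        else:
            a = (2 * (cls - len(genes))) % len(genes)
            rates[cls, a] = high
            rates[cls, (a + 1) % len(genes)] = high
    return pd.DataFrame(rates, index=[f"class_{c + 1}" for c in range(n_classes)],
                        columns=genes)


@dataclass
class TissueSpec:
    """Parameters of one synthetic multi-cycle tissue field.

    Defaults emulate an 8-gene, 10-class, ~300-cell field imaged in two
    label-image-erase cycles of four gene channels plus a nuclear stain, with
    a planted (3, -2) px stage offset on the second cycle. Puncta amplitudes
    are NB with cv 1.5 (mid-range of the 1-2 regime typical of rolling-circle
    amplicons) and the autofluorescent background sits far below the puncta
    mean, mirroring the >30-fold signal-to-background regime.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_cells: int = 300
    min_separation_um: float = 8.0
    nucleus_radius_um: float = 2.5
    genes: tuple[str, ...] = DEFAULT_GENES
    channels_per_cycle: int = 4
    class_proportions: tuple[float, ...] = tuple([0.1] * 10)
    class_rates: pd.DataFrame | None = None  # defaults to default_class_rates()
    puncta_mean: float = 150.0
    puncta_cv: float = 1.5
    puncta_sigma_px: float = 1.5
    puncta_placement_radius_um: float = 2.5
    background_level: float = 1.5
    background_noise_sd: float = 0.3
    nuclear_amplitude: float = 200.0
    cycle_offsets: tuple[tuple[int, int], ...] = ((0, 0), (3, -2))
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.class_rates is None:
            self.class_rates = default_class_rates(
                n_classes=len(self.class_proportions), genes=self.genes
            )
        if (self.class_rates.to_numpy() < 0).any():
            raise ValueError("puncta rates must be non-negative")
        n_cycles = -(-len(self.genes) // self.channels_per_cycle)
        if len(self.cycle_offsets) < n_cycles:
            raise ValueError(f"need offsets for {n_cycles} cycles")

    @property
    def n_cycles(self) -> int:
        return -(-len(self.genes) // self.channels_per_cycle)

    def gene_slots(self) -> dict[str, int]:
        """Gene -> cycle index (genes fill cycles in channel-sized blocks)."""
        return {g: i // self.channels_per_cycle for i, g in enumerate(self.genes)}


@dataclass
class SyntheticTissue:
    cycles: list[FieldImage]
    ground_truth: pd.DataFrame  # cell, class, centroid, per-gene planted rates
    puncta: pd.DataFrame  # per-punctum gene, position, amplitude
    nucleus_centers: np.ndarray
    offsets: tuple[tuple[int, int], ...]
    spec: TissueSpec


def _poisson_disk(rng: np.random.Generator, shape: tuple[int, int], n: int,
                  min_dist: float, margin: float) -> np.ndarray:
    """Dart-throwing placement of n points with a minimum pairwise distance."""
    pts: list[tuple[float, float]] = []
    grid = min_dist  # coarse neighbor grid
    cells: dict[tuple[int, int], list[int]] = {}
    for _ in range(n * 400):
        if len(pts) == n:
            break
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        gi, gj = int(r // grid), int(c // grid)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in cells.get((gi + di, gj + dj), ()):
                    pr, pc = pts[idx]
                    if (pr - r) ** 2 + (pc - c) ** 2 < min_dist**2:
                        ok = False
                        break
        if ok:
            cells.setdefault((gi, gj), []).append(len(pts))
            pts.append((r, c))
    if len(pts) < n:
        raise ValueError(
            f"could only place {len(pts)}/{n} nuclei at {min_dist:.1f} px "
            f"separation; reduce the cell count or separation"
        )
    return np.array(pts)


def _add_spot(img: np.ndarray, r: float, c: float, amp: float, sigma: float) -> None:
    rad = int(np.ceil(4 * sigma))
    r0, c0 = int(round(r)), int(round(c))
    ys = slice(max(0, r0 - rad), min(img.shape[0], r0 + rad + 1))
    xs = slice(max(0, c0 - rad), min(img.shape[1], c0 + rad + 1))
    yy, xx = np.mgrid[ys, xs]
    img[ys, xs] += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))


def gen_tissue_images(spec: TissueSpec) -> SyntheticTissue:
    """Render a multi-cycle synthetic tissue field with full ground truth.

    Nuclei are smooth Gaussian blobs on the nuclear channel; per cell and
    gene, a Poisson number of puncta (rate set by the cell's class) is placed
    near the nucleus, each a small Gaussian spot with an NB-distributed peak
    amplitude. Constant-plus-noise background is added to every channel and
    each cycle's channels are translated by that cycle's planted offset.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    min_dist = spec.min_separation_um / px
    nuc_sigma = spec.nucleus_radius_um / px / 1.5
    margin = spec.nucleus_radius_um / px + 8
    if spec.n_cells > 0:
        centers = _poisson_disk(rng, spec.shape, spec.n_cells, min_dist, margin)
    else:
        centers = np.empty((0, 2))
    classes = rng.choice(len(spec.class_proportions), size=spec.n_cells,
                         p=np.asarray(spec.class_proportions))
    rates = spec.class_rates.to_numpy()
    r_disp = nb_dispersion_for_cv(spec.puncta_mean, spec.puncta_cv)
    nb_p = r_disp / (r_disp + spec.puncta_mean)
    place_rad = spec.puncta_placement_radius_um / px

    dapi = np.zeros(spec.shape)
    gene_imgs = {g: np.zeros(spec.shape) for g in spec.genes}
    puncta_rows = []
    for i, (cr, cc) in enumerate(centers):
        _add_spot(dapi, cr, cc, spec.nuclear_amplitude, nuc_sigma)
        for gi, g in enumerate(spec.genes):
            n_puncta = rng.poisson(rates[classes[i], gi])
            for _ in range(n_puncta):
                ang = rng.uniform(0, 2 * np.pi)
                rad = place_rad * np.sqrt(rng.uniform())
                pr, pc = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
                amp = float(rng.negative_binomial(r_disp, nb_p))
                _add_spot(gene_imgs[g], pr, pc, amp, spec.puncta_sigma_px)
                puncta_rows.append(dict(cell=i + 1, gene=g, row=pr, col=pc,
                                        amplitude=amp))

    def with_background(img: np.ndarray) -> np.ndarray:
        noise = rng.normal(spec.background_level, spec.background_noise_sd, spec.shape)
        return img + np.clip(noise, 0, None)

    slots = spec.gene_slots()
    cycles = []
    for ci in range(spec.n_cycles):
        dy, dx = spec.cycle_offsets[ci]
        channels = {"DAPI": _translate(with_background(dapi), dy, dx)}
        for g in spec.genes:
            if slots[g] == ci:
                channels[g] = _translate(with_background(gene_imgs[g]), dy, dx)
        cycles.append(FieldImage(channels=channels, cycle=ci + 1, pixel_size_um=px))

    gt = pd.DataFrame(dict(
        cell=np.arange(1, spec.n_cells + 1),
        cls=[f"class_{c + 1}" for c in classes],
        class_index=classes + 1,
        centroid_row=centers[:, 0] if spec.n_cells else [],
        centroid_col=centers[:, 1] if spec.n_cells else [],
    ))
    for gi, g in enumerate(spec.genes):
        gt[f"rate_{g}"] = rates[classes, gi] if spec.n_cells else []
    puncta = pd.DataFrame(puncta_rows,
                          columns=["cell", "gene", "row", "col", "amplitude"])
    return SyntheticTissue(
        cycles=cycles, ground_truth=gt, puncta=puncta, nucleus_centers=centers,
        offsets=tuple(spec.cycle_offsets[: spec.n_cycles]), spec=spec,
    )
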