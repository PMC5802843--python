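"""Probe design: sites, thermodynamics, specificity, oligo assembly, panels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plish import probe_design as pdn
from plish import synthetic_data as sd
from plish.seqs import Transcript, revcomp

dna = st.text(alphabet="ACGT", min_size=8, max_size=60)


def random_transcript(rng, length, tid="t", role="target"):
    return Transcript(
        id=tid, sequence="".join(np.array(list("ACGT"))[rng.integers(0, 4, length)]),
        role=role,
    )


# ---------------------------------------------------------------------------
# detection sites


def oracle_sites(seq, site_length, max_sites):
    """Independent enumeration: every window with a central AG/TA dinucleotide,
    greedy left-to-right tiling, even-index subsampling."""
    half = site_length // 2
    wins = []
    for start in range(1, len(seq) - site_length + 2):  # 1-based
        j = start + half - 1
        if seq[j - 1 : j + 1] in ("AG", "TA"):
            wins.append((start, start + site_length - 1, j))
    tiled, last = [], 0
    for w in wins:
        if w[0] > last:
            tiled.append(w)
            last = w[1]
    if len(tiled) <= max_sites:
        return tiled
    if max_sites == 1:
        return [tiled[(len(tiled) - 1) // 2]]
    picks = sorted({round(i * (len(tiled) - 1) / (max_sites - 1)) for i in range(max_sites)})
    return [tiled[i] for i in picks]


def test_homopolymer_has_no_sites():
    t = Transcript(id="polyA", sequence="A" * 100)
    assert pdn.find_detection_sites(t) == []


def test_sites_match_bruteforce_oracle(rng):
    t = random_transcript(rng, 2000)
    for max_sites in (1, 3, 10):
        got = pdn.find_detection_sites(t, max_sites=max_sites)
        exp = oracle_sites(t.sequence, 40, max_sites)
        assert [(s.start, s.end, s.junction_pos) for s in got] == exp


def test_site_conventions_and_invariants(rng):
    """1-based inclusive spans (end - start + 1 = 40), AG/TA at the junction,
    mutually non-overlapping."""
    t = random_transcript(rng, 3000)
    sites = pdn.find_detection_sites(t, max_sites=10)
    assert sites, "random 3 kb transcript should contain junctions"
    prev_end = 0
    for s in sites:
        assert s.end - s.start + 1 == 40
        assert t.subseq(s.junction_pos, s.junction_pos + 1) == s.dinucleotide
        assert s.dinucleotide in ("AG", "TA")
        assert s.start > prev_end
        prev_end = s.end
    # the published blocking-oligo span convention: 219-278 is 60 nt
    assert 278 - 219 + 1 == 60
    site = pdn.DetectionSite("x", 347, 386, 366, "AG")
    assert site.length == 40


def test_short_transcript_rejected():
    t = Transcript(id="tiny", sequence="ACGTAGCT" * 4)  # 32 nt
    with pytest.raises(ValueError, match="shorter"):
        pdn.find_detection_sites(t, site_length=40)


# ---------------------------------------------------------------------------
# melting temperature

# Unified DNA/DNA nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K),
# written out literally so this oracle is independent of the implementation.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)


def oracle_tm(seq, oligo_conc_uM=0.25, salt_mM=50.0):
    """Hand evaluation of the two-state NN formula with salt-corrected entropy."""
    dh = ds = 0.0
    for b in (seq[0], seq[-1]):
        inc = _INIT_AT if b in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM * 1e-3)
    k = oligo_conc_uM * 1e-6 / 4.0  # duplex of two strands at conc/2 each
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


def test_tm_matches_hand_computed_nn_sum(rng):
    assert pdn.melting_temperature("ACGTACGTACGTACGTACGT") == pytest.approx(
        oracle_tm("ACGTACGTACGTACGTACGT"), abs=1e-6
    )
    for _ in range(20):
        s = random_transcript(rng, int(rng.integers(12, 35))).sequence
        assert pdn.melting_temperature(s) == pytest.approx(oracle_tm(s), abs=1e-6)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(dna.filter(lambda s: len(s) >= 8))
def test_tm_gc_append_monotone_and_revcomp_symmetric(seq):
    tm = pdn.melting_temperature(seq)
    assert pdn.melting_temperature(seq + "GC") >= tm
    assert pdn.melting_temperature(revcomp(seq)) == pytest.approx(tm, abs=1e-9)


def test_tm_rejects_ambiguous_base_naming_position():
    with pytest.raises(ValueError, match="position 5"):
        pdn.melting_temperature("ACGTNACGTACG")
    with pytest.raises(ValueError, match="too short"):
        pdn.melting_temperature("ACGTACG")


# ---------------------------------------------------------------------------
# arm-length adjustment


def test_arms_in_range_returned_unchanged(rng):
    # search for a site whose nominal 20-nt arms are already within the window
    for seed in range(40):
        t = random_transcript(np.random.default_rng(seed), 500)
        for s in pdn.find_detection_sites(t, max_sites=10):
            halves = s.halves(t)
            if all(45 <= pdn.melting_temperature(revcomp(h)) <= 65 for h in halves):
                adj = pdn.adjust_arm_lengths(s, t)
                assert adj.ok
                assert (adj.site.start, adj.site.end) == (s.start, s.end)
                return
    pytest.fail("no nominally in-range site found in 40 random transcripts")


def test_at_rich_flank_extended_into_range():
    """A poly-A left flank is too weak at 20 nt; the arm must be extended
    base-by-base until its Tm enters the window, consistent with an exhaustive
    length scan under the Tm oracle."""
    seq = "A" * 60 + "G" + "CATGCCGATCGGATCCGTAGCATGCGTACG"
    t = Transcript(id="atrich", sequence=seq)
    site = pdn.DetectionSite("atrich", 41, 80, 60, "AG")
    adj = pdn.adjust_arm_lengths(site, t)
    assert adj.ok
    assert 45 <= adj.hl_tm <= 65 and 45 <= adj.hr_tm <= 65
    n = len(adj.left_arm_target)
    assert n > 20
    # exhaustive scan: every shorter left arm is below the window
    for length in range(12, n):
        arm = t.subseq(site.junction_pos - length + 1, site.junction_pos)
        assert pdn.melting_temperature(revcomp(arm)) < 45


def test_unreachable_window_flags_site():
    """An arm boxed in by the transcript end that never reaches 45 C is
    flagged unusable rather than emitted."""
    seq = "A" * 13 + "G" + "CATGCCGATCGGATCCGTAGCATGCGTACG"
    t = Transcript(id="boxed", sequence=seq)
    site = pdn.DetectionSite("boxed", 2, 33, 13, "AG")
    adj = pdn.adjust_arm_lengths(site, t)
    assert not adj.ok
    assert "left arm" in adj.reason


def test_gc_rich_arm_trimmed_into_range():
    seq = "GCGGCGCCGCGGCCGCGGCGGCGCCGGCA" + "G" + "TATCATGAATTAGCATACTTATAAGCTT"
    t = Transcript(id="gcrich", sequence=seq)
    site = pdn.DetectionSite("gcrich", 10, 49, 29, "AG")
    assert pdn.melting_temperature(revcomp(site.halves(t)[0])) > 65
    adj = pdn.adjust_arm_lengths(site, t)
    assert adj.ok
    assert len(adj.left_arm_target) < 20
    assert 45 <= adj.hl_tm <= 65


# ---------------------------------------------------------------------------
# specificity screen


def naive_screen(site_seq, background, k=10, exempt=()):
    """Brute-force oracle: exact substring search for any shared >=k-mer."""
    for b in background:
        if b.id in exempt:
            continue
        for i in range(len(site_seq) - k + 1):
            if site_seq[i : i + k] in b.sequence:
                return False
    return True


def test_empty_background_passes(rng):
    t = random_transcript(rng, 200)
    s = pdn.find_detection_sites(t, max_sites=1)[0]
    assert pdn.specificity_screen(s, [], t).passed


def test_planted_tenmer_fails(rng):
    t = random_transcript(rng, 300)
    s = pdn.find_detection_sites(t, max_sites=1)[0]
    stolen = s.sequence(t)[15:25]
    bg = Transcript(id="decoy", sequence="T" * 100 + stolen + "G" * 100, role="background")
    verdict = pdn.specificity_screen(s, [bg], t)
    assert not verdict.passed
    assert "decoy" in verdict.reason


def test_screen_agrees_with_naive_search(collision_transcriptome):
    """Verdicts of the k-mer index equal brute-force substring search for 50
    sites against a 20-transcript background, planted collisions included."""
    targets, background, manifest = collision_transcriptome
    index = pdn.BackgroundIndex(background, k=10)
    planted = {(r.target_id, r.site_start) for r in manifest.itertuples()}
    n_checked = n_failed = 0
    for t in targets:
        for s in pdn.find_detection_sites(t, max_sites=10):
            got = pdn.specificity_screen(s, index, t).passed
            exp = naive_screen(s.sequence(t), background, k=10)
            assert got == exp, f"{t.id} {s.start}-{s.end}"
            n_checked += 1
            n_failed += not got
            if (t.id, s.start) in planted:
                assert not got
    assert n_checked >= 50
    assert n_failed >= len(manifest)


def test_screen_k_validation(rng):
    with pytest.raises(ValueError, match=">= 4"):
        pdn.BackgroundIndex([], k=3)


# ---------------------------------------------------------------------------
# self-complementarity


def oracle_self_comp(seq):
    """Longest substring whose reverse complement also occurs in the sequence."""
    best = 0
    for i in range(len(seq)):
        for j in range(i + best + 1, len(seq) + 1):
            if revcomp(seq[i:j]) in seq:
                best = j - i
    return best


@pytest.mark.parametrize("seq,score", [("AAAAAA", 0), ("GAATTC", 6)])
def test_self_complementarity_known_values(seq, score):
    assert pdn.self_complementarity(seq) == score


def test_self_complementarity_matches_lcs_oracle(rng):
    for _ in range(20):
        s = random_transcript(rng, 60).sequence
        assert pdn.self_complementarity(s) == oracle_self_comp(s)


# ---------------------------------------------------------------------------
# oligo assembly


def test_h_pair_reconstructs_site(rng):
    t = random_transcript(rng, 400)
    s = pdn.find_detection_sites(t, max_sites=1)[0]
    pair = pdn.assemble_h_pair(s, t, template_id=3)
    rebuilt = revcomp(pair.hl_binding) + revcomp(pair.hr_binding)
    assert rebuilt == pair.site.sequence(t)
    assert revcomp(revcomp(pair.hl_binding)) == pair.hl_binding
    tpl = pdn.get_template(3)
    assert pair.hl_full == tpl.l_overhang + pair.hl_binding
    assert pair.hr_full == pair.hr_binding + tpl.r_overhang


def test_tiled_pairs_share_overhangs(rng):
    """Pairs tiled on one target carry identical overhangs so they route to
    the same barcode."""
    t = random_transcript(rng, 2000)
    sites = pdn.find_detection_sites(t, max_sites=5)
    pairs = [pdn.assemble_h_pair(s, t, template_id=2) for s in sites]
    assert len({p.hl_overhang for p in pairs}) == 1
    assert len({p.hr_overhang for p in pairs}) == 1


def test_unknown_template_rejected(rng):
    t = random_transcript(rng, 400)
    s = pdn.find_detection_sites(t, max_sites=1)[0]
    with pytest.raises(KeyError, match="template"):
        pdn.assemble_h_pair(s, t, template_id=99)


def test_barcode_set_construction_identities():
    reg = pdn.BarcodeRegistry(rng=np.random.default_rng(5))
    bs = pdn.assemble_barcode_set(
        "bc1", template_id=1, modes=("standard", "erasable_dU", "rapid_short"),
        registry=reg,
    )
    tpl = pdn.get_template(1)
    assert len(bs.circle_seq) == 60
    assert revcomp(bs.circle_seq[:11]) == tpl.l_overhang
    assert revcomp(bs.circle_seq[-11:]) == tpl.r_overhang
    assert len(bs.bridge_seq) == 31
    assert bs.barcode_seq in bs.circle_seq
    amplicon = bs.simulated_amplicon(3)
    for im in bs.imagers.values():
        assert revcomp(im.sequence.replace("U", "T")) in amplicon


def test_bridge_common_across_templates():
    reg = pdn.BarcodeRegistry(rng=np.random.default_rng(6))
    sets = [pdn.assemble_barcode_set(f"b{t}", template_id=t, registry=reg)
            for t in range(1, 9)]
    assert len({s.bridge_seq for s in sets}) == 1
    assert all(len(s.bridge_seq) == 31 for s in sets)


def test_barcode_orthogonality_clash_is_named():
    reg = pdn.BarcodeRegistry(rng=np.random.default_rng(7))
    seq = reg.new_barcode("first")
    with pytest.raises(ValueError, match="first"):
        reg.register("second", seq)


def test_imager_modes():
    no_t = "GAGCAGCAGGCAGCAG"
    assert pdn.make_imager(no_t, "erasable_dU", "Cy3").sequence == \
        pdn.make_imager(no_t, "standard", "Cy3").sequence
    bc = "GATCAGTCGATTGCAT"
    std = pdn.make_imager(bc, "standard", "Cy3")
    du = pdn.make_imager(bc, "erasable_dU", "Cy3")
    assert 15 <= len(du.sequence) <= 20
    assert du.sequence.count("U") == std.sequence.count("T")
    assert "T" not in du.sequence
    assert len(pdn.make_imager(bc, "rapid_short", "Cy5").sequence) in (10, 11)
    with pytest.raises(ValueError, match="15-20"):
        pdn.make_imager("ACGTACGTAC", "standard", "Cy3")


# ---------------------------------------------------------------------------
# panels


def test_pro_rating_rule():
    assert pdn.h_probe_concentration_nM(1) == 100.0
    assert pdn.h_probe_concentration_nM(5) == 100.0
    assert pdn.h_probe_concentration_nM(10) == 50.0
    for n in range(1, 11):
        total = 2 * n * pdn.h_probe_concentration_nM(n)
        assert total <= 1000.0 + 1e-9
        if n > 5:
            assert total == pytest.approx(1000.0)


def test_panel_slots_and_failures(rng):
    targets = [random_transcript(np.random.default_rng(100 + i), 1500, tid=f"g{i}")
               for i in range(8)]
    targets.append(Transcript(id="polyA", sequence="A" * 500))
    with pytest.raises(ValueError, match="exceed"):
        pdn.design_panel(targets, [], n_cycles=2, fluor_palette=("a", "b", "c", "d"))
    panel = pdn.design_panel(targets, [], n_cycles=3,
                             fluor_palette=("a", "b", "c", "d"), seed=0)
    assert "polyA" in panel.failures
    slots = [(tp.cycle, tp.fluor) for tp in panel.targets]
    assert len(set(slots)) == len(slots) == 8
    assert {tp.cycle for tp in panel.targets} == {1, 2}


def test_minimal_panel_contents(rng):
    t = random_transcript(rng, 600, tid="solo")
    panel = pdn.design_panel([t], [], sites_per_target=1, seed=1)
    df = panel.order_sheet()
    counts = df.type.value_counts()
    assert counts["HL"] == 1 and counts["HR"] == 1
    assert counts["bridge"] == 1 and counts["circle"] == 1
    assert counts["imager"] >= 1


def test_panel_order_sheet_deterministic(tmp_path, collision_transcriptome):
    targets, background, _ = collision_transcriptome
    kw = dict(sites_per_target=4, n_cycles=2, seed=9)
    a = pdn.design_panel(targets, background, **kw)
    b = pdn.design_panel(targets, background, **kw)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.order_sheet().to_csv(pa, sep="\t", index=False)
    b.order_sheet().to_csv(pb, sep="\t", index=False)
    assert pa.read_bytes() == pb.read_bytes()


def test_panel_emitted_arms_obey_tm_window(collision_transcriptome):
    targets, background, _ = collision_transcriptome
    panel = pdn.design_panel(targets, background, sites_per_target=4, n_cycles=2)
    for tp in panel.targets:
        for p in tp.pairs:
            assert 45 <= p.hl_tm <= 65
            assert 45 <= p.hr_tm <= 65
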