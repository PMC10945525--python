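"""Generators: planted genomes, rearrangements, contact maps, ChIP tracks."""

import numpy as np
import pytest

from terscope.chip_cov import call_peaks, normalize_tracks
from terscope.contact_map import scn_normalize
from terscope.mats_genomics import scan_motif
from terscope.range_quant import contact_range, summarize_range
from terscope.synthetic_data import (Rearrangement, SyntheticChipSpec,
                                     SyntheticMapSpec, expected_counts,
                                     gen_chip_experiment, gen_contact_map,
                                     gen_genome, liftover, liftover_inverse,
                                     transpose_segment)


# ---------------------------------------------------------------- genomes
def test_planted_sites_recovered_exactly():
    planted = sorted(np.random.default_rng(0).choice(
        np.arange(600_000, 1_400_000, 50), 28, replace=False).tolist())
    genome, feats = gen_genome(2_000_000, planted, dif=1_500_000, seed=5)
    sites = scan_motif(genome)
    assert [s.position for s in sites] == planted
    assert feats["dif"] == 1_500_000


def test_no_planted_sites_empty_scan():
    genome, _ = gen_genome(20_000, [], seed=1)
    assert scan_motif(genome) == []


def test_same_seed_identical_genome():
    g1, _ = gen_genome(10_000, [3000], seed=9)
    g2, _ = gen_genome(10_000, [3000], seed=9)
    g3, _ = gen_genome(10_000, [3000], seed=10)
    assert g1 == g2
    assert g1 != g3


def test_overlapping_plants_rejected():
    with pytest.raises(ValueError):
        gen_genome(10_000, [100, 105], seed=0)


# ---------------------------------------------------------------- liftover
def test_liftover_roundtrip_identity(rng):
    for _ in range(50):
        n = int(rng.integers(50, 2000))
        a = int(rng.integers(0, n - 2))
        b = int(rng.integers(a + 1, n))
        outside = [c for c in range(n) if not (a <= c < b)]
        c = int(rng.choice(outside))
        r = Rearrangement(a, b, c, bool(rng.integers(2)))
        pos = np.arange(n)
        lifted = np.array([liftover(p, r, n) for p in pos])
        assert sorted(lifted) == list(range(n))  # bijection
        back = np.array([liftover_inverse(p, r, n) for p in lifted])
        assert np.array_equal(back, pos)


def test_marker_word_relocated_by_string_surgery():
    rng = np.random.default_rng(4)
    genome = "".join(rng.choice(list("AT"), 1000))
    marker = "GGCCGGCC"
    genome = genome[:150] + marker + genome[158:]
    r = Rearrangement(100, 200, 500)
    new, lift, _ = transpose_segment(genome, r)
    assert len(new) == len(genome)
    assert sorted(new) == sorted(genome)
    assert new.index(marker) == lift(150)
    assert lift(150) == 450  # [100,200) re-inserted at 500: 150 -> 450


def test_inverted_segment_reverse_complemented():
    genome = "A" * 100 + "ACGTTT" + "A" * 94
    r = Rearrangement(100, 106, 50, inverted=True)
    new, lift, unlift = transpose_segment(genome, r)
    assert new[50:56] == "AAACGT"  # reverse complement of ACGTTT
    assert lift(100) == 55  # first base of segment ends up last
    assert unlift(lift(103)) == 103


def test_insertion_point_inside_segment_rejected():
    with pytest.raises(ValueError):
        Rearrangement(100, 200, 150)


def test_feature_counts_conserved_through_transposition():
    planted = [200_000, 230_000, 260_000, 600_000, 630_000]
    genome, _ = gen_genome(800_000, planted, seed=2)
    # move a motif-free segment between the two clusters
    r = Rearrangement(350_000, 500_000, 700_000)
    new, lift, _ = transpose_segment(genome, r)
    sites = sorted(s.position for s in scan_motif(new))
    assert sites == sorted(lift(p) for p in planted)


# ---------------------------------------------------------------- maps
def test_zero_depth_zero_matrix():
    spec = SyntheticMapSpec(chrom_length=100_000, depth=0,
                            background_fraction=0)
    cm = gen_contact_map(spec, 0)
    assert cm.matrix.sum() == 0


def test_symmetry_and_determinism():
    spec = SyntheticMapSpec(chrom_length=250_000, depth=100)
    a = gen_contact_map(spec, 7)
    b = gen_contact_map(spec, 7)
    c = gen_contact_map(spec, 8)
    assert np.array_equal(a.matrix, a.matrix.T)
    assert np.array_equal(a.matrix, b.matrix)
    assert not np.array_equal(a.matrix, c.matrix)


def test_empirical_decay_matches_closed_form():
    spec = SyntheticMapSpec(chrom_length=500_000, lambda_bp=100_000,
                            depth=20_000, background_fraction=0)
    cm = gen_contact_map(spec, 3)
    n = spec.n_bins
    idx = np.arange(n)
    d = np.minimum(np.abs(idx[:, None] - idx[None, :]),
                   n - np.abs(idx[:, None] - idx[None, :]))
    for s in (2, 5, 10, 20):
        mean = cm.matrix[d == s].mean() / spec.depth
        expect = np.exp(-s * 5000 / 100_000)
        assert mean == pytest.approx(expect, rel=0.05)


def test_marginals_scale_linearly_with_depth():
    lo = gen_contact_map(SyntheticMapSpec(chrom_length=250_000, depth=200), 1)
    hi = gen_contact_map(SyntheticMapSpec(chrom_length=250_000, depth=2000), 1)
    assert hi.matrix.sum() / lo.matrix.sum() == pytest.approx(10, rel=0.05)


def test_insulation_factor_applied_between_boundaries():
    spec = SyntheticMapSpec(chrom_length=200_000, depth=100,
                            cid_boundaries={20: 0.5})
    mu = expected_counts(spec)
    base = expected_counts(SyntheticMapSpec(chrom_length=200_000, depth=100))
    # pair straddling the boundary on the shorter arc is halved
    assert mu[18, 22] == pytest.approx(base[18, 22] * 0.5
                                       + 0.5 * 100 * spec.background_fraction)
    # same-side pair untouched
    assert mu[25, 30] == base[25, 30]


def test_min_lambda_couples_ter_loci_to_everyone():
    spec = SyntheticMapSpec(chrom_length=500_000, lambda_bp=200_000,
                            ter_interval=(40, 60), ter_lambda_factor=4,
                            background_fraction=0)
    mu = expected_counts(spec)
    # Ter bin 50 with far outside bin 80: decays at lambda/4
    d = 30 * 5000
    assert mu[50, 80] == pytest.approx(spec.depth * np.exp(-d / 50_000))


def test_ter_reduction_shrinks_measured_range():
    spec = SyntheticMapSpec(chrom_length=2_000_000, lambda_bp=200_000,
                            ter_interval=(150, 250), depth=1000)
    cm = scn_normalize(gen_contact_map(spec, 12))
    prof = contact_range(cm)
    inside = summarize_range(prof, 155, 245).median
    outside = summarize_range(prof, 270, 130).median
    assert inside < outside


def test_liter_style_short_ter2_measures_larger_range():
    """Transposition splitting Ter in two: a short restricted Ter2 far from
    Ter1 (the four-matS design) measures a larger contact range than a long
    one (the nine-matS design), because the wide flanking bands bleed
    across a short low-lambda interval but a long one breaks the band."""
    def ter2_range(ter2_bins):
        n = 920
        lam = np.full(n, 250_000.0)
        lam[100:240] /= 6                 # Ter1: ~700 kb
        lam[440:440 + ter2_bins] /= 6     # Ter2, ~1 Mb away
        spec = SyntheticMapSpec(chrom_length=4_600_000, lambda_bp=lam,
                                depth=1000)
        cm = scn_normalize(gen_contact_map(spec, 31))
        prof = contact_range(cm)
        return summarize_range(prof, 440, 440 + ter2_bins).median

    short = ter2_range(27)   # ~136 kb Ter2
    long_ = ter2_range(51)   # ~253 kb Ter2
    assert short > long_


# ---------------------------------------------------------------- chip
def test_unit_fold_gives_flat_enrichment():
    spec = SyntheticChipSpec(chrom_length=50_000, depth=200,
                             replicated_interval=(10_000, 30_000),
                             enrichment_fold=1.0)
    ip, inp = gen_chip_experiment(spec, 0)
    enr = normalize_tracks(ip, inp)
    assert np.nanmedian(enr.values) == pytest.approx(1.0, abs=0.05)
    assert abs(np.nanmedian(enr.values[10_000:30_000])
               - np.nanmedian(enr.values[30_000:])) < 0.05


def test_planted_fold_recovered_within_ten_percent():
    spec = SyntheticChipSpec(chrom_length=100_000, depth=100,
                             replicated_interval=(0, 50_000),
                             enrichment_fold=3.0)
    ip, inp = gen_chip_experiment(spec, 7)
    enr = normalize_tracks(ip, inp)
    ratio = np.nanmedian(enr.values[:50_000]) / np.nanmedian(enr.values[50_000:])
    assert ratio == pytest.approx(3.0, rel=0.10)


def test_ter_excluded_interval_stays_baseline():
    spec = SyntheticChipSpec(chrom_length=120_000, depth=100,
                             replicated_interval=(0, 90_000),
                             ter_excluded_interval=(30_000, 60_000),
                             enrichment_fold=3.0)
    ip, inp = gen_chip_experiment(spec, 3)
    enr = normalize_tracks(ip, inp)
    inside_ter = np.nanmedian(enr.values[30_000:60_000])
    replicated = np.nanmedian(enr.values[:30_000])
    baseline = np.nanmedian(enr.values[90_000:])
    assert inside_ter == pytest.approx(baseline, rel=0.10)
    assert replicated == pytest.approx(3 * baseline, rel=0.10)


def test_planted_narrow_peak_called_at_center():
    spec = SyntheticChipSpec(chrom_length=20_000, depth=100,
                             peaks=[(5_000, 50, 15.0)])
    ip, inp = gen_chip_experiment(spec, 11)
    peaks = call_peaks(normalize_tracks(ip, inp))
    assert len(peaks) == 1
    assert abs(peaks[0].center - 5_000) <= 2


def test_yaml_spec_round_trip(tmp_path):
    from terscope.synthetic_data import load_spec
    p = tmp_path / "spec.yaml"
    p.write_text("kind: map\nchrom_length: 500000\nlambda_bp: 80000\n"
                 "ter_interval: [20, 40]\ndepth: 300\n")
    spec = load_spec(p)
    assert isinstance(spec, SyntheticMapSpec)
    assert spec.ter_interval == (20, 40)
    assert gen_contact_map(spec, 1).n_bins == 100
    p2 = tmp_path / "chip.yaml"
    p2.write_text("kind: chip\nchrom_length: 10000\n"
                  "peaks: [[5000, 50, 15.0]]\n")
    spec2 = load_spec(p2)
    assert isinstance(spec2, SyntheticChipSpec)
    assert spec2.peaks == [(5000, 50, 15.0)]


def test_chip_determinism():
    spec = SyntheticChipSpec(chrom_length=10_000)
    a, _ = gen_chip_experiment(spec, 3)
    b, _ = gen_chip_experiment(spec, 3)
    assert np.array_equal(a.values, b.values)
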