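"""Pile-ups, DiffGene ranking, stacking, enrichment statistics, motif scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromarch as ca
from chromarch.difftad_pileups import PileupMatrix, _chunk_means
from chromarch.tad_caller import TADSet

from conftest import make_loopset


def _expr(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "strand", "log2fc", "q"])


# ---------------------------------------------------------------------------
# DiffGene ranking


def brute_force_rank(loops_df, genes, direction, q_max, top_n, min_spacing):
    sign = 1 if direction == "up" else -1
    scored = []
    for _, l in loops_df.iterrows():
        if not l["q"] < q_max:
            continue
        s = 0.0
        for _, g in genes.iterrows():
            if g["chrom"] != l["chrom1"] or np.sign(g["log2fc"]) != sign:
                continue
            for a, b in ((l["start1"], l["end1"]), (l["start2"], l["end2"])):
                if g["start"] < b and g["end"] > a:
                    s += sign * g["log2fc"]
        mid = ((l["start1"] + l["end1"]) // 2 + (l["start2"] + l["end2"]) // 2) // 2
        scored.append((s, l["chrom1"], mid))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    picked = []
    for s, chrom, mid in scored:
        if any(c == chrom and abs(mid - m) < min_spacing for _, c, m in picked):
            continue
        picked.append((s, chrom, mid))
        if len(picked) == top_n:
            break
    return picked


def test_rank_diffgenes_order_and_spacing():
    genes = _expr([("g1", "chr1", 90_000, 110_000, "+", 5.0, 1e-4),
                   ("g2", "chr1", 5_090_000, 5_110_000, "+", 3.2, 1e-4),
                   ("g3", "chr1", 10_090_000, 10_110_000, "+", 4.1, 1e-4)])
    loops = make_loopset([
        ("chr1", 80_000, 120_000, "chr1", 200_000, 240_000, 5.0, 1e-4),
        ("chr1", 5_080_000, 5_120_000, "chr1", 5_200_000, 5_240_000, 5.0, 1e-4),
        ("chr1", 10_080_000, 10_120_000, "chr1", 10_200_000, 10_240_000, 5.0, 1e-4)])
    out = ca.rank_diffgenes(loops, genes, "up", top_n=3)
    assert out["sum_log2fc"].tolist() == [5.0, 4.1, 3.2]

    # two top candidates 1 Mb apart: the second is skipped
    near = make_loopset([
        ("chr1", 80_000, 120_000, "chr1", 200_000, 240_000, 5.0, 1e-4),
        ("chr1", 1_080_000, 1_120_000, "chr1", 1_200_000, 1_240_000, 5.0, 1e-4),
        ("chr1", 10_080_000, 10_120_000, "chr1", 10_200_000, 10_240_000, 5.0, 1e-4)])
    genes2 = _expr([("g1", "chr1", 90_000, 110_000, "+", 5.0, 1e-4),
                    ("g2", "chr1", 1_090_000, 1_110_000, "+", 4.0, 1e-4),
                    ("g3", "chr1", 10_090_000, 10_110_000, "+", 3.0, 1e-4)])
    out2 = ca.rank_diffgenes(near, genes2, "up", top_n=2)
    assert out2["sum_log2fc"].tolist() == [5.0, 3.0]

    with pytest.raises(ValueError):
        ca.rank_diffgenes(near.filter_q(1e-9), genes2, "up")


def test_rank_diffgenes_down_uses_reciprocal_fold():
    genes = _expr([("g1", "chr1", 90_000, 110_000, "+", -4.0, 1e-4),
                   ("g2", "chr1", 90_000, 110_000, "+", 2.0, 1e-4)])
    loops = make_loopset([("chr1", 80_000, 120_000, "chr1", 300_000, 340_000, 5.0, 1e-4)])
    out = ca.rank_diffgenes(loops, genes, "down", top_n=1)
    # only the downregulated gene counts, with flipped (reciprocal) sign
    assert out["sum_log2fc"].iloc[0] == pytest.approx(4.0)


def test_rank_diffgenes_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n_loops = int(rng.integers(3, 30))
        rows, grows = [], []
        for i in range(n_loops):
            m1 = int(rng.integers(0, 20_000_000))
            m2 = m1 + int(rng.integers(100_000, 2_000_000))
            rows.append(("chr1", m1, m1 + 40_000, "chr1", m2, m2 + 40_000,
                         1.0, float(rng.choice([1e-5, 0.5]))))
        for i in range(int(rng.integers(5, 40))):
            s = int(rng.integers(0, 20_000_000))
            grows.append((f"g{i}", "chr1", s, s + 20_000, "+",
                          float(rng.normal(0, 2)), 1e-4))
        loops = make_loopset(rows)
        genes = _expr(grows)
        got = ca.rank_diffgenes(loops, genes, "up", top_n=10)
        exp = brute_force_rank(loops.df, genes, "up", 0.001, 10, 2_500_000)
        assert got["sum_log2fc"].tolist() == pytest.approx([s for s, _, _ in exp])
        assert got["midpoint"].tolist() == [m for _, _, m in exp]


# ---------------------------------------------------------------------------
# Midpoint pile-ups


def test_align_midpoints_basic_shapes():
    track = {"chr1": np.ones(1000)}
    pm = ca.align_midpoints(track, [("chr1", 500_000)], flank=100_000, bin_width=1000)
    assert pm.values.shape == (1, 200)
    assert np.allclose(pm.column_means(), 1.0)
    with pytest.raises(ValueError):
        ca.align_midpoints(track, [], flank=100_000)


def test_align_midpoints_mirror_symmetry_and_spike():
    rng = np.random.default_rng(1)
    half = rng.random(100)
    arr = np.zeros(1000)
    arr[400:500] = half[::-1]
    arr[500:600] = half
    pm = ca.align_midpoints({"chr1": arr}, [("chr1", 500_000)],
                            flank=100_000, bin_width=1000)
    cm = pm.column_means()
    assert np.array_equal(cm[:100][::-1], cm[100:])

    spike = np.zeros(1000)
    spike[510] = 7.0
    pm2 = ca.align_midpoints({"chr1": spike}, [("chr1", 500_000)],
                             flank=100_000, bin_width=1000)
    cm2 = pm2.column_means()
    nz = np.flatnonzero(cm2)
    assert nz.tolist() == [110] and pm2.offsets[110] == 10_000


def test_align_midpoints_edge_masking():
    track = {"chr1": np.ones(50)}
    pm = ca.align_midpoints(track, [("chr1", 10_000)], flank=30_000, bin_width=1000)
    assert pm.mask[0, :20].all() and not pm.mask[0, 20:].any()


def test_anova_condition_compare_detects_shift():
    rng = np.random.default_rng(2)
    base = {"chr1": rng.normal(10, 0.1, 400)}
    shifted = {"chr1": base["chr1"] + np.where(np.arange(400) < 210, 0, 3.0)}
    mids = [("chr1", 200_000)]
    pa = ca.align_midpoints(base, mids, flank=50_000, bin_width=1000)
    pb = ca.align_midpoints(shifted, mids, flank=50_000, bin_width=1000)
    res = ca.anova_condition_compare(pa, pb)
    assert (res[res["offset"] >= 15_000]["p"] < 0.01).all()
    assert (res[res["offset"] < 0]["p"] > 0.05).all()


def test_tad_overlap_profile():
    tads = TADSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000_000]}))
    counts = ca.tad_overlap_profile([("chr1", 5_000_000)], tads,
                                    flank=100_000, bin_width=1000)
    assert (counts == 1).all()
    empty = TADSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    assert (ca.tad_overlap_profile([("chr1", 5_000_000)], empty,
                                   flank=100_000, bin_width=1000) == 0).all()
    one = TADSet(pd.DataFrame({"chrom": ["chr1"], "start": [4_900_000],
                               "end": [5_050_000]}))
    counts = ca.tad_overlap_profile([("chr1", 5_000_000)], one,
                                    flank=100_000, bin_width=1000)
    # covered exactly on [-100 kb, +50 kb)
    assert counts[:150].sum() == 150 and counts[150:].sum() == 0


# ---------------------------------------------------------------------------
# Oriented border alignment


def _difftads():
    return TADSet(pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [1_000_000, 3_000_000, 6_000_000],
        "end": [1_400_000, 3_600_000, 6_200_000]}))


def test_tad_orientation_rules():
    tads = _difftads()
    fwd = _expr([("g1", "chr1", 1_100_000, 1_150_000, "+", 2.0, 1e-3)])
    left, right = ca.align_tad_borders(tads, fwd, "up",
                                       {"chr1": np.zeros(10_000)}, flank=100_000)
    row = left.loci[left.loci["start"] == 1_000_000].iloc[0]
    assert row["orient"] == 1 and not row["orientation_defaulted"]
    # no qualifying genes: forward, flagged
    assert left.loci[left.loci["start"] == 3_000_000].iloc[0]["orientation_defaulted"]

    rev = _expr([("g1", "chr1", 1_100_000, 1_150_000, "-", 2.0, 1e-3)])
    left2, _ = ca.align_tad_borders(tads, rev, "up",
                                    {"chr1": np.zeros(10_000)}, flank=100_000)
    assert left2.loci[left2.loci["start"] == 1_000_000].iloc[0]["orient"] == -1


def test_align_tad_borders_flip_mirrors_marker():
    """A marker just inside the left genomic border shows at the mirrored
    offset once the TAD is flipped by its (- strand) gene directionality."""
    track = np.zeros(10_000)
    track[1_010] = 9.0  # 10 kb inside the genomic left border at 1 Mb
    tads = TADSet(pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000],
                                "end": [1_400_000]}))
    fwd_genes = _expr([("g", "chr1", 1_050_000, 1_100_000, "+", 2.0, 1e-3)])
    rev_genes = _expr([("g", "chr1", 1_050_000, 1_100_000, "-", 2.0, 1e-3)])
    lf, _ = ca.align_tad_borders(tads, fwd_genes, "up", {"chr1": track}, flank=100_000)
    lr, rr = ca.align_tad_borders(tads, rev_genes, "up", {"chr1": track}, flank=100_000)
    f = 100
    assert lf.values[0, f + 10] == 9.0            # forward: +10 kb from left border
    # flipped: the oriented left border is the genomic right border, so the
    # marker (389 mirrored bins inside) leaves the left-block window entirely
    # and shows on the right-aligned block just inside the oriented right
    # border (the genomic start)
    assert np.where(lr.mask[0], 0, lr.values[0]).max() < 9.0
    assert rr.values[0, f - 11] == 9.0
    assert not rr.mask[0, f - 11]


def test_align_tad_borders_midpoint_truncation():
    tads = TADSet(pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000],
                                "end": [1_200_000]}))
    genes = _expr([("g", "chr1", 1_050_000, 1_100_000, "+", 2.0, 1e-3)])
    left, right = ca.align_tad_borders(tads, genes, "up",
                                       {"chr1": np.ones(10_000)}, flank=500_000)
    offs = left.offsets // 1000
    # TAD length 200 kb: interior offsets >= +100 kb masked on the left block
    assert left.mask[0, offs >= 100].all()
    assert not left.mask[0, (offs >= 0) & (offs < 100)].any()
    assert right.mask[0, offs < -100].all()
    with pytest.raises(ValueError):
        ca.align_tad_borders(TADSet(pd.DataFrame(columns=["chrom", "start", "end"])),
                             genes, "up", {"chr1": np.ones(10)})


def test_flip_is_involution_and_masked_cells_never_read():
    rng = np.random.default_rng(8)
    values = rng.random((5, 20))
    mask = rng.random((5, 20)) < 0.3
    pm = PileupMatrix(values.copy(), mask.copy(), np.arange(-10, 10) * 1000, 1000)
    twice = pm.flipped().flipped()
    assert np.array_equal(twice.values, values)
    assert np.array_equal(twice.mask, mask)
    assert np.array_equal(twice.offsets, pm.offsets)

    # sentinel poison in masked cells must not leak into any summary
    poisoned = values.copy()
    poisoned[mask] = 1e30
    pm2 = PileupMatrix(poisoned, mask.copy(), pm.offsets, 1000)
    ref = PileupMatrix(np.where(mask, 0, values), mask.copy(), pm.offsets, 1000)
    assert np.allclose(np.nan_to_num(pm2.column_means()),
                       np.nan_to_num(ref.column_means()))
    assert np.allclose(np.nan_to_num(pm2.row_means()),
                       np.nan_to_num(ref.row_means()))
    assert np.allclose(np.nan_to_num(pm2.binned_column_means()),
                       np.nan_to_num(ref.binned_column_means()))


def test_pileup_summaries_invariant_to_row_order():
    rng = np.random.default_rng(12)
    values = rng.random((7, 10))
    mask = np.zeros_like(values, dtype=bool)
    pm = PileupMatrix(values, mask, np.arange(-5, 5) * 1000, 1000)
    perm = rng.permutation(7)
    pm2 = PileupMatrix(values[perm], mask[perm], pm.offsets, 1000)
    assert np.allclose(pm.column_means(), pm2.column_means())


# ---------------------------------------------------------------------------
# Same-size stacking and split alignment


def _tads_and_tracks(rho, seed, n=200, size=480_000, bw=1000):
    rng = np.random.default_rng(seed)
    starts = np.arange(n) * size
    tads = TADSet(pd.DataFrame({"chrom": "chr1", "start": starts,
                                "end": starts + size}))
    s = rng.normal(0, 1, n)
    attr = rho * s + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
    rep = size // bw
    return tads, {"strength": {"chr1": np.repeat(s, rep)},
                  "attr": {"chr1": np.repeat(attr, rep)}}


def test_stack_same_size_perfect_correlations():
    tads, tracks = _tads_and_tracks(1.0, 0)
    tracks["neg"] = {"chr1": -tracks["strength"]["chr1"]}
    out = ca.stack_same_size(tads, tracks, "strength")
    assert out["pearson"]["strength"]["r"] == pytest.approx(1.0)
    assert out["pearson"]["neg"]["r"] == pytest.approx(-1.0)
    # rows sorted descending by the sort attribute
    rm = out["pileups"]["strength"].row_means()
    assert (np.diff(rm) <= 1e-12).all()
    with pytest.raises(ValueError):
        ca.stack_same_size(tads, tracks, "strength", n=500)


def test_split_align_all_geometry():
    tads = TADSet(pd.DataFrame({"chrom": ["chr1"] * 3,
                                "start": [0, 1_000_000, 5_000_000],
                                "end": [400_000, 1_400_000, 8_000_000]}))
    track = {"chr1": np.ones(10_000)}
    left, right = ca.split_align_all(tads, track)
    # 3 Mb TAD contributes only its outer 1 Mb per side
    assert left.values.shape[1] == 1_000_000 // 1000
    assert (~left.mask[2]).sum() == 1000
    # 400 kb TADs contribute 200 kb halves
    assert (~left.mask[0]).sum() == 200
    assert (~right.mask[0]).sum() == 200
    # rows sorted by length: the 3 Mb TAD is last
    assert left.loci["length"].is_monotonic_increasing


def test_split_align_border_enrichment_visible():
    """Peaks planted at TAD borders raise offset-0 column means above the
    interior, matching a direct group-mean oracle."""
    rng = np.random.default_rng(3)
    n, size = 40, 400_000
    starts = np.arange(n) * size
    tads = TADSet(pd.DataFrame({"chrom": "chr1", "start": starts,
                                "end": starts + size}))
    arr = rng.random(n * size // 1000)
    for s in starts:
        arr[s // 1000] += 5.0
    left, _ = ca.split_align_all(tads, {"chr1": arr})
    cm = left.column_means()
    assert cm[0] > np.nanmean(cm[10:]) + 3.0
    direct = np.mean([arr[s // 1000] for s in starts])
    assert cm[0] == pytest.approx(direct)


# ---------------------------------------------------------------------------
# Enrichment statistics


def test_zscore_profile_cases():
    prof = ca.zscore_profile([0.0, 0, 0, 10])
    assert prof.z[3] == pytest.approx(1.5)
    assert prof.p[3] == pytest.approx(0.1336, abs=2e-4)
    neg = ca.zscore_profile([-0.0, 0, 0, -10])
    assert np.allclose(neg.p, prof.p)
    const = ca.zscore_profile([3.0, 3, 3])
    assert (const.p == 1.0).all() and (const.z == 0).all()
    with pytest.raises(ValueError):
        ca.zscore_profile([1.0, 2.0])
    assert ca.zscore_profile([0.0, 0, 0, 10]).tiers().tolist() == ["", "", "", ""]


def test_go_positional_profile():
    genes = pd.DataFrame({
        "gene": [f"g{i}" for i in range(40)],
        "chrom": "chr1",
        "start": np.linspace(100_000, 900_000, 40).astype(int),
        "end": np.linspace(100_000, 900_000, 40).astype(int) + 1000,
        "strand": "+",
    })
    # category A concentrated within +-100 kb of the center; B uniform
    center = 500_000
    cat = np.where(np.abs(genes["start"] - center) <= 100_000, "A", "B")
    go = pd.DataFrame({"gene": genes["gene"], "category": cat})
    profiles = ca.go_positional_profile(genes, go, [("chr1", center)],
                                        flank=400_000, bin_width=10_000)
    a = profiles["A"]
    assert abs(a.sum()) < 1e-9                      # zero-centered over span
    inner = np.abs(np.arange(-40, 40) * 10_000 + 5_000) <= 100_000
    assert a[inner].mean() > 0 > a[~inner].mean()
    # categories are independent profiles
    assert abs(profiles["B"].sum()) < 1e-9
    with pytest.raises(ValueError):
        ca.go_positional_profile(genes, go.iloc[:0], [("chr1", center)])


def test_border_resampling_enrichment_modes():
    sizes = {"chr1": 300_000}
    b = 150_000
    seq = ca.simulate_sequence(sizes, {"chr1": [b]}, motif="TGACGTCATTGG",
                               border_density=2e-3, background_density=1e-4,
                               border_window=10_000, seed=0)
    pwm = ca.pwm_from_consensus("TGACGTCATTGG")
    kwargs = dict(bin_width=10_000, span=95_000, n_iterations=3,
                  n_repeats=2, n_samples=40, seed=1)
    res = ca.border_resampling_enrichment(seq, [("chr1", b)], mode="pwm_scan",
                                          pwms={"m": pwm}, **kwargs)
    center = res[res["offset"] == -5_000]
    assert center["mean_count"].iloc[0] == res["mean_count"].max()
    # determinism under a fixed sampler seed
    res2 = ca.border_resampling_enrichment(seq, [("chr1", b)], mode="pwm_scan",
                                           pwms={"m": pwm}, **kwargs)
    pd.testing.assert_frame_equal(res, res2)
    # a motif absent from the sequence is dropped by the low-count filter
    absent = ca.border_resampling_enrichment(
        seq, [("chr1", b)], mode="pwm_scan",
        pwms={"none": ca.pwm_from_consensus("TTTTTTTTTTTTTTTT")}, **kwargs)
    assert len(absent) == 0
    with pytest.raises(ValueError):
        ca.border_resampling_enrichment(seq, [("chr1", b)], mode="pwm_scan")

    kres = ca.border_resampling_enrichment(
        seq, [("chr1", b)], mode="kmer", kmers=["TGACGTCATTGGTGACGTCA"],
        bin_width=10_000, span=45_000, n_iterations=2, n_repeats=2,
        n_samples=200, seed=2, min_total=0)
    assert set(kres["motif"]) <= {"TGACGTCATTGGTGACGTCA"}


def test_chunk_means():
    assert np.allclose(_chunk_means(np.arange(10.0), 5), [2.0, 7.0])
    assert _chunk_means(np.arange(3.0), 5).size == 0
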