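"""Diversity statistics against independent oracles; selection scan rules."""

import numpy as np
import pandas as pd
import pytest

from linkld import popgen_selection as pg
from linkld.data_model import GenomicInterval
from conftest import make_matrix


# --- independent oracles -------------------------------------------------


def brute_force_pi(haplotypes: np.ndarray) -> float:
    """Average pairwise Hamming distance over all haplotype pairs."""
    n = haplotypes.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sum(haplotypes[i] != haplotypes[j])
    return total / (n * (n - 1) / 2)


def wc_fst_single_site(counts1, counts2):
    """Independent single-site Weir & Cockerham theta, parameterised by
    genotype counts (n_AA, n_Aa, n_aa) — written from the 1984 paper's
    frequency formulation, distinct from the package's dosage algebra."""
    r = 2
    stats = []
    for nAA, nAa, naa in (counts1, counts2):
        n = nAA + nAa + naa
        p = (2 * nAA + nAa) / (2 * n)
        h = nAa / n
        stats.append((n, p, h))
    nbar = sum(s[0] for s in stats) / r
    nc = (r * nbar - sum(s[0] ** 2 for s in stats) / (r * nbar)) / (r - 1)
    pbar = sum(s[0] * s[1] for s in stats) / (r * nbar)
    s2 = sum(s[0] * (s[1] - pbar) ** 2 for s in stats) / ((r - 1) * nbar)
    hbar = sum(s[0] * s[2] for s in stats) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


# --- Tajima's D ----------------------------------------------------------


def test_tajimas_d_worked_example():
    """4 haplotypes {0000,1000,1100,1110}: S=3, pi_total=10/6 -> +0.168."""
    assert pg.tajimas_d(3, 4, 10 / 6) == pytest.approx(0.168, abs=1e-3)


def test_tajimas_d_zero_and_undefined():
    n = 10
    a1 = pg.tajima_constants(n)["a1"]
    assert pg.tajimas_d(5, n, 5 / a1) == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(pg.tajimas_d(0, n, 0.0))


# --- window diversity ----------------------------------------------------


def test_single_site_pi_formula():
    # one site, alt count c=1 among n=4 haplotypes, window length 250
    g = make_matrix([[1.0], [0.0]], start_pos=101)
    w = [GenomicInterval("Chr01", 0, 250)]
    out = pg.window_diversity(g, w, np.array([0, 1]))
    assert out["pi"].iloc[0] == pytest.approx(2 * 1 * 3 / (4 * 3) / 250)
    assert out["S"].iloc[0] == 1


def test_window_pi_equals_brute_force_hamming():
    rng = np.random.default_rng(12)
    haps = rng.integers(0, 2, size=(12, 30))  # phased toy, 6 diploids
    dosage = haps[0::2] + haps[1::2]
    g = make_matrix(dosage, start_pos=1, spacing=5)
    w = [GenomicInterval("Chr01", 0, 250)]
    out = pg.window_diversity(g, w, np.arange(6))
    assert out["pi"].iloc[0] * 250 == pytest.approx(brute_force_pi(haps))


def test_empty_window_and_monomorphic_window():
    g = make_matrix(np.zeros((6, 4)), start_pos=10)
    w = [GenomicInterval("Chr01", 0, 250), GenomicInterval("Chr01", 250, 500)]
    out = pg.window_diversity(g, w, np.arange(6))
    assert out.loc[0, "pi"] == 0.0 and out.loc[0, "theta_w"] == 0.0
    assert out.loc[0, "S"] == 0 and np.isnan(out.loc[0, "D"])


# --- Weir & Cockerham Fst ------------------------------------------------


def test_fst_identical_subpops_near_zero_flagged():
    dos = np.array([[0, 1, 2, 1, 0, 2]] * 2, dtype=float).T
    sub = np.array(["A"] * 3 + ["B"] * 3)
    dos = np.vstack([dos, dos])  # same genotype counts in both halves
    g = make_matrix(dos[:6], subpop=sub)
    out = pg.weir_cockerham_fst(g, [GenomicInterval("Chr01", 0, 300)], "A", "B")
    assert out["fst"].iloc[0] <= 0.01
    # identical counts give a non-positive estimate, reported raw
    assert bool(out["negative_flag"].iloc[0]) == (out["fst"].iloc[0] < 0)


def test_fst_fixed_difference_is_one():
    dos = np.array([[2.0]] * 10 + [[0.0]] * 10)
    g = make_matrix(dos, subpop=np.array(["A"] * 10 + ["B"] * 10))
    out = pg.weir_cockerham_fst(g, [GenomicInterval("Chr01", 0, 250)], "A", "B")
    assert out["fst"].iloc[0] == pytest.approx(1.0)


def test_fst_matches_independent_single_site_script():
    # printed toy counts: pop1 15 AA / 10 Aa / 5 aa; pop2 5 / 10 / 15
    dos1 = [2.0] * 15 + [1.0] * 10 + [0.0] * 5
    dos2 = [2.0] * 5 + [1.0] * 10 + [0.0] * 15
    dos = np.array(dos1 + dos2)[:, None]
    g = make_matrix(dos, subpop=np.array(["A"] * 30 + ["B"] * 30))
    out = pg.weir_cockerham_fst(g, [GenomicInterval("Chr01", 0, 250)], "A", "B")
    expected = wc_fst_single_site((15, 10, 5), (5, 10, 15))
    assert out["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_statistics_invariant_to_ordering_and_allele_labels():
    rng = np.random.default_rng(5)
    dos = rng.binomial(2, 0.3, size=(40, 20)).astype(float)
    sub = np.array(["A"] * 20 + ["B"] * 20)
    w = [GenomicInterval("Chr01", 0, 2000)]
    g = make_matrix(dos, subpop=sub)
    base_div = pg.window_diversity(g, w, "A")
    base_fst = pg.weir_cockerham_fst(g, w, "A", "B")
    # relabel ref/alt (dosage -> 2 - dosage)
    g_swap = make_matrix(2.0 - dos, subpop=sub)
    pd.testing.assert_frame_equal(
        base_div, pg.window_diversity(g_swap, w, "A")
    )
    pd.testing.assert_frame_equal(
        base_fst, pg.weir_cockerham_fst(g_swap, w, "A", "B")
    )
    # permute individuals within subpops
    perm = np.concatenate([rng.permutation(20), 20 + rng.permutation(20)])
    g_perm = make_matrix(dos[perm], subpop=sub[perm])
    pd.testing.assert_frame_equal(
        base_div, pg.window_diversity(g_perm, w, "A")
    )


# --- ROD -----------------------------------------------------------------


@pytest.mark.parametrize(
    "pi_obj,pi_ref,expected",
    [(0.004, 0.004, 0.0), (0.0, 0.004, 1.0), (0.001, 0.004, 0.75)],
)
def test_rod_arithmetic(pi_obj, pi_ref, expected):
    assert pg.rod_statistic(pi_obj, pi_ref) == pytest.approx(expected)


def test_rod_undefined_when_reference_monomorphic():
    assert np.isnan(pg.rod_statistic(0.001, 0.0))


# --- joint outliers, merging, confirmation -------------------------------


def _stats_frame(fst, lr, pi_obj=None, pi_ref=None):
    n = len(fst)
    return pd.DataFrame(
        {
            "chrom": ["Chr01"] * n,
            "start": np.arange(n) * 250,
            "end": (np.arange(n) + 1) * 250,
            "pi_A": pi_obj if pi_obj is not None else np.full(n, 0.001),
            "pi_B": pi_ref if pi_ref is not None else np.full(n, 0.001),
            "D_A": np.zeros(n),
            "D_B": np.zeros(n),
            "fst_A_B": fst,
            "logratio_A_B": lr,
        }
    )


def test_joint_criterion_requires_both_tails():
    rng = np.random.default_rng(0)
    fst = rng.normal(0.1, 0.01, 300)
    lr = rng.normal(0.0, 0.1, 300)
    fst[0] = 0.9  # extreme Fst but unremarkable log-ratio
    stats = _stats_frame(fst, lr)
    flags = pg.joint_outlier_windows(stats, ("A", "B"), q=0.01)
    assert not flags.iloc[0]
    fst[1] = 0.9
    lr[1] = -2.0  # extreme in both
    stats = _stats_frame(fst, lr)
    flags = pg.joint_outlier_windows(stats, ("A", "B"), q=0.01)
    assert flags.iloc[1]


def test_joint_criterion_q1_flags_all_defined():
    stats = _stats_frame(np.full(120, 0.1), np.zeros(120))
    flags = pg.joint_outlier_windows(stats, ("A", "B"), q=1.0)
    assert flags.all()


def test_merge_regions_rules():
    stats = _stats_frame(np.full(10, 0.1), np.zeros(10))
    # 3 consecutive flagged -> one 750-bp region
    flags = pd.Series([True, True, True] + [False] * 7)
    regions = pg.merge_regions(stats, flags, ("A", "B"), max_gap=1)
    assert len(regions) == 1
    assert len(regions[0].interval) == 750
    # two flagged windows separated by 2 unflagged -> two regions
    flags = pd.Series(
        [True, False, False, True] + [False] * 6
    )
    regions = pg.merge_regions(stats, flags, ("A", "B"), max_gap=1)
    assert len(regions) == 2
    # single flagged window -> one 250-bp region
    flags = pd.Series([False] * 9 + [True])
    regions = pg.merge_regions(stats, flags, ("A", "B"), max_gap=1)
    assert len(regions[0].interval) == 250


def test_tajima_confirmation_rules():
    rng = np.random.default_rng(1)
    stats = _stats_frame(np.full(12, 0.1), np.zeros(12))
    stats["D_A"] = rng.normal(0, 0.1, 12)
    stats["D_B"] = stats["D_A"]  # identical distributions
    flags = pd.Series([True] * 12)
    regions = pg.merge_regions(stats, flags, ("A", "B"))
    regions = pg.confirm_with_tajima(regions, stats, ("A", "B"))
    assert regions[0].tajima_confirmed is False
    # clearly lower objective D -> confirmed
    stats2 = stats.copy()
    stats2["D_A"] = stats2["D_B"] - 2.0
    regions = pg.merge_regions(stats2, flags, ("A", "B"))
    regions = pg.confirm_with_tajima(regions, stats2, ("A", "B"))
    assert regions[0].tajima_confirmed is True
    # undefined objective D -> not evaluable
    stats3 = stats.copy()
    stats3["D_A"] = np.nan
    regions = pg.merge_regions(stats3, flags, ("A", "B"))
    regions = pg.confirm_with_tajima(regions, stats3, ("A", "B"))
    assert regions[0].tajima_confirmed is None


# --- fixation classes ----------------------------------------------------


def make_subpop_matrix(freqs, n_per=40):
    """One SNP with exact per-subpop MAFs via constructed dosages."""
    labels, rows = [], []
    for k, f in enumerate(freqs):
        n_alt = int(round(2 * n_per * f))
        dosages = [1.0] * n_alt + [0.0] * (n_per - n_alt)
        rows.extend(dosages)
        labels.extend([f"P{k}"] * n_per)
    return make_matrix(np.array(rows)[:, None], subpop=np.array(labels))


@pytest.mark.parametrize(
    "freqs,expected",
    [
        ((0.30, 0.02, 0.20), "nearly_fixed"),
        ((0.30, 0.00, 0.20), "completely_fixed"),
        ((0.30, 0.10, 0.20), "segregating"),
    ],
)
def test_fixation_classes(freqs, expected):
    g = make_subpop_matrix(freqs)
    out = pg.classify_fixation(g)
    assert out["fixation_class"].iloc[0] == expected


def test_fixation_excludes_all_missing_subpop():
    g = make_subpop_matrix((0.30, 0.10, 0.20))
    dos = g.dosage.copy()
    dos[g.subpop.values == "P1", 0] = np.nan
    g2 = make_matrix(dos, subpop=g.subpop.values)
    out = pg.classify_fixation(g2)
    assert out["excluded"].iloc[0] == "P1"
    assert out["fixation_class"].iloc[0] == "segregating"
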