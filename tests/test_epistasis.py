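"""Two-locus partition: orthogonality, power, invariances."""

import numpy as np
import pytest

from linkld import epistasis as epi
from linkld import synthetic_data as syn
from conftest import make_matrix, make_pheno


def balanced_design(effect=0.0, seed=0, n_per_cell=30):
    rng = np.random.default_rng(seed)
    xa = np.repeat([0, 1, 2], 3 * n_per_cell)
    xb = np.tile(np.repeat([0, 1, 2], n_per_cell), 3)
    y = rng.standard_normal(len(xa)) + effect * (xa - 1) * (xb - 1) * (
        (xa == 1) * 1.0 - 0.5
    ) * ((xb == 1) * 1.0 - 0.5) * 4
    g = make_matrix(np.column_stack([xa, xb]).astype(float))
    return g, make_pheno(g.individuals, y)


def test_balanced_components_sum_to_interaction_ss():
    """Under an equal-count HWE/LE-free design the four orthogonal
    contrasts reproduce the classical Kempthorne decomposition."""
    g, pheno = balanced_design(effect=0.8, seed=1)
    for weighting in ("equal", "observed"):
        rec = epi.two_locus_partition(g, pheno, "H", "T1", 0, 1,
                                      weighting=weighting)
        comp_sum = sum(ss for ss, _ in rec.components.values())
        assert comp_sum == pytest.approx(rec.ss_int, rel=1e-9)
        assert rec.df_int == 4


def test_pure_additive_phenotype_has_no_interaction():
    rng = np.random.default_rng(2)
    xa = rng.binomial(2, 0.5, 400).astype(float)
    xb = rng.binomial(2, 0.4, 400).astype(float)
    y = 0.8 * xa - 0.5 * xb + rng.standard_normal(400)
    g = make_matrix(np.column_stack([xa, xb]))
    rec = epi.two_locus_partition(g, make_pheno(g.individuals, y), "H", "T1",
                                  0, 1)
    assert rec.contribution < 0.03
    assert rec.p_interaction > 0.001


def test_planted_dxd_detected_with_largest_component():
    detected, dd_largest = 0, 0
    for rep in range(10):
        cfg = syn.PanelConfig(
            subpop_sizes=(100, 100, 100), subpop_labels=("S", "NW", "NE"),
            fst=0.1, n_regions=2, region_length=20000, snps_per_region=150,
            maf_dist="uniform", seed=900 + rep,
        )
        pair = syn.EpiPairSpec(
            {"target_maf": 0.4, "chrom": "Chr01"},
            {"target_maf": 0.4, "chrom": "Chr02"}, pve=0.12,
        )
        g, pheno, truth = syn.simulate_panel(cfg, epi_pairs=[pair])
        ja = truth["epi_pairs"][0]["site_a"]
        jb = truth["epi_pairs"][0]["site_b"]
        rec = epi.two_locus_partition(g, pheno, "H", "T2", ja, jb)
        detected += rec.p_interaction < 0.001
        comps = {k: v[0] for k, v in rec.components.items()}
        dd_largest += max(comps, key=comps.get) == "dxd"
    assert detected >= 8
    assert dd_largest >= 8


def test_contribution_invariant_to_affine_phenotype():
    g, pheno = balanced_design(effect=0.6, seed=3)
    rec1 = epi.two_locus_partition(g, pheno, "H", "T1", 0, 1)
    data2 = pheno.data.copy()
    data2["value"] = 3.0 * data2["value"] + 7.0
    rec2 = epi.two_locus_partition(g, type(pheno)(data2), "H", "T1", 0, 1)
    assert rec2.contribution == pytest.approx(rec1.contribution, rel=1e-9)
    assert rec2.p_interaction == pytest.approx(rec1.p_interaction, rel=1e-6)


def test_pair_swap_permutes_axd_dxa_only():
    g, pheno = balanced_design(effect=0.6, seed=4)
    r12 = epi.two_locus_partition(g, pheno, "H", "T1", 0, 1)
    r21 = epi.two_locus_partition(g, pheno, "H", "T1", 1, 0)
    assert r21.p_interaction == pytest.approx(r12.p_interaction, rel=1e-9)
    assert r21.contribution == pytest.approx(r12.contribution, rel=1e-9)
    assert r21.components["axd"][0] == pytest.approx(
        r12.components["dxa"][0], rel=1e-9
    )
    assert r21.components["dxa"][0] == pytest.approx(
        r12.components["axd"][0], rel=1e-9
    )


def test_monomorphic_and_sparse_pairs_rejected():
    g = make_matrix(np.column_stack([np.zeros(40), np.tile([0.0, 1.0], 20)]))
    pheno = make_pheno(g.individuals, np.random.default_rng(0).normal(size=40))
    with pytest.raises(ValueError, match="monomorphic"):
        epi.two_locus_partition(g, pheno, "H", "T1", 0, 1)
    # two biallelic sites but only 4 populated cells -> skipped
    xa = np.array([0.0] * 20 + [2.0] * 20)
    xb = np.array([0.0, 2.0] * 20)
    g2 = make_matrix(np.column_stack([xa, xb]))
    with pytest.raises(epi.SkippedPair):
        epi.two_locus_partition(g2, pheno, "H", "T1", 0, 1)


def test_scan_retains_planted_pair_among_decoys():
    cfg = syn.PanelConfig(
        subpop_sizes=(100, 100, 100), subpop_labels=("S", "NW", "NE"),
        fst=0.1, n_regions=2, region_length=20000, snps_per_region=40,
        maf_dist="uniform", seed=11,
    )
    pair = syn.EpiPairSpec(
        {"target_maf": 0.4, "chrom": "Chr01"},
        {"target_maf": 0.4, "chrom": "Chr02"}, pve=0.15,
    )
    g, pheno, truth = syn.simulate_panel(cfg, epi_pairs=[pair])
    ja = truth["epi_pairs"][0]["site_a"]
    jb = truth["epi_pairs"][0]["site_b"]
    cand = np.unique(np.concatenate([[ja, jb], np.arange(0, 30)]))
    recs, log = epi.epistasis_scan(g, pheno, "H", "T2", candidates=cand,
                                  alpha=0.001)
    assert any({r.site_a, r.site_b} == {ja, jb} for r in recs)
    recs_empty, _ = epi.epistasis_scan(g, pheno, "H", "T2",
                                       candidates=np.array([], dtype=int))
    assert recs_empty == []
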