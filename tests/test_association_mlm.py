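"""Mixed-model association, effect decomposition, hotspots, signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from linkld import association_mlm as amlm
from linkld import ld_analysis as ld
from linkld import synthetic_data as syn
from linkld.data_model import GenomicInterval
from conftest import make_matrix, make_pheno


def test_threshold_arithmetic():
    thr = amlm.compute_thresholds(52_949)
    assert thr.suggestive == pytest.approx(1.9e-5, rel=0.01)
    assert thr.significant == pytest.approx(9.4e-7, rel=0.01)
    thr1 = amlm.compute_thresholds(1)
    assert thr1.suggestive == 1.0 and thr1.significant == 0.05
    assert thr.significant < thr.suggestive


def test_kinship_duplicates_symmetry_structure():
    rng = np.random.default_rng(0)
    dos = rng.binomial(2, 0.4, size=(20, 300)).astype(float)
    dos[1] = dos[0]  # duplicate individuals
    g = make_matrix(dos)
    K = amlm.estimate_kinship(g)
    assert K[0, 1] == pytest.approx(1.0)
    np.testing.assert_array_equal(K, K.T)
    assert np.all(np.diag(K) == 1.0)

    cfg = syn.PanelConfig(
        subpop_sizes=(40, 40), subpop_labels=("A", "B"), fst=0.2,
        n_regions=2, snps_per_region=200, maf_dist="uniform", seed=1,
    )
    gp, _, _ = syn.simulate_panel(cfg)
    Kp = amlm.estimate_kinship(gp)
    within = np.concatenate([Kp[:40, :40][np.triu_indices(40, 1)],
                             Kp[40:, 40:][np.triu_indices(40, 1)]])
    between = Kp[:40, 40:].ravel()
    assert within.mean() > between.mean()


def test_mlm_with_identity_kinship_matches_ols():
    """With K = I and no structure covariates the GLS Wald P-values
    reduce to ordinary least-squares regression P-values."""
    rng = np.random.default_rng(2)
    n, m = 80, 12
    dos = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    y = rng.standard_normal(n) + 0.4 * dos[:, 3]
    g = make_matrix(dos)
    pheno = make_pheno(g.individuals, y)
    recs = amlm.mlm_scan(g, pheno, "H", "T1", K=np.eye(n), Q=np.empty((n, 0)))
    for r in recs:
        x = dos[:, r.site_index]
        slope, _, _, p_ols, _ = sps.linregress(x, y)
        assert r.p == pytest.approx(p_ols, rel=1e-4)
        assert r.beta == pytest.approx(slope, rel=1e-4)


def test_permuted_phenotype_gives_uniform_pvalues(small_panel):
    g, pheno, _ = small_panel
    rng = np.random.default_rng(3)
    y = pheno.values_for("H", "T2", g.individuals)
    perm = make_pheno(g.individuals, rng.permutation(y))
    K = amlm.estimate_kinship(g)
    Q = amlm.structure_covariates(g, "labels")
    recs = amlm.mlm_scan(g, perm, "H", "T1", K=K, Q=Q)
    pvals = np.array([r.p for r in recs])
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_classify_effect_textbook_class_means():
    rng = np.random.default_rng(4)
    x = np.array([0.0] * 30 + [1.0] * 30 + [2.0] * 30)
    noise = rng.normal(0, 0.1, 90)
    g = make_matrix(x[:, None])
    # means (10, 15, 20) -> purely additive: a = 5, d = 0
    y_add = 10 + 5 * x + noise
    eff = amlm.classify_effect(g, make_pheno(g.individuals, y_add), "H", "T1", 0)
    assert eff["effect_class"] == "additive"
    assert eff["a"] == pytest.approx(5.0, abs=0.1)
    assert eff["d"] == pytest.approx(0.0, abs=0.1)
    # means (10, 20, 10) -> purely dominant: a = 0, d = 10
    y_dom = 10 + 10 * (x == 1.0) + noise
    eff = amlm.classify_effect(g, make_pheno(g.individuals, y_dom), "H", "T1", 0)
    assert eff["effect_class"] == "dominant"
    assert eff["a"] == pytest.approx(0.0, abs=0.1)
    assert eff["d"] == pytest.approx(10.0, abs=0.1)


def test_effect_invariant_to_homozygote_swap():
    rng = np.random.default_rng(5)
    x = np.array([0.0] * 25 + [1.0] * 25 + [2.0] * 25)
    y = 1.5 * x + 0.8 * (x == 1.0) + rng.normal(0, 0.5, 75)
    g = make_matrix(x[:, None])
    g_swap = make_matrix((2.0 - x)[:, None])
    pheno = make_pheno(g.individuals, y)
    e1 = amlm.classify_effect(g, pheno, "H", "T1", 0)
    e2 = amlm.classify_effect(g_swap, pheno, "H", "T1", 0)
    assert e1["a"] == pytest.approx(-e2["a"], abs=1e-9)
    assert e1["d"] == pytest.approx(e2["d"], abs=1e-9)


def test_classify_effect_monomorphic_and_sparse_classes():
    g = make_matrix(np.zeros((30, 1)))
    pheno = make_pheno(g.individuals, np.random.default_rng(0).normal(size=30))
    with pytest.raises(ValueError):
        amlm.classify_effect(g, pheno, "H", "T1", 0)
    x = np.array([0.0] * 28 + [1.0, 2.0])  # classes with < 3 members
    g2 = make_matrix(x[:, None])
    eff = amlm.classify_effect(g2, pheno, "H", "T1", 0)
    assert eff["restricted"] is True
    assert np.isnan(eff["d"])


@pytest.mark.parametrize(
    "values,expected",
    [
        (np.full(9, 0.1), "level"),
        (np.linspace(0.02, 0.3, 9), "increasing"),
        (np.linspace(0.3, 0.02, 9), "decreasing"),
        (np.concatenate([np.linspace(0.02, 0.25, 4), np.full(5, 0.25)]),
         "increase-then-level"),
        (np.array([0.1, 0.2]), "unclassified"),
    ],
)
def test_trajectory_rules(values, expected):
    assert amlm.classify_trajectory(values) == expected


def test_trajectory_simulated_ramp_plateau():
    rng = np.random.default_rng(6)
    ok = 0
    for _ in range(20):
        v = syn.pve_trajectory("increase-then-level", 0.2, 9)
        v = np.clip(v + rng.normal(0, 0.01, 9), 0, 1)
        ok += amlm.classify_trajectory(v, tol=0.05) == "increase-then-level"
    assert ok >= 18


def _record(site, trait, tp, p):
    return amlm.AssociationRecord(site, "Chr01", 100 + site * 50, trait, tp,
                                  p, 1.0, 0.1, 0.05)


def test_hotspot_features_planted_pleiotropy():
    sets = [("H", f"T{k}") for k in range(27)]
    records, features = [], {}
    # feature gA: SNP 0 associated in 20 sets; gB: SNP 1 in 1 set
    for trait, tp in sets[:20]:
        records.append(_record(0, trait, tp, 1e-8))
    records.append(_record(1, "H", "T0", 1e-8))
    # background SNPs mapping to decoy features, one set each
    for k in range(2, 30):
        records.append(_record(k, sets[k % 27][0], sets[k % 27][1], 1e-8))
        features[k] = [f"decoy{k}"]
    features[0] = ["gA"]
    features[1] = ["gB"]
    out = amlm.find_hotspot_features(
        records, features, p_threshold=1e-5, k_min=12, n_perm=300, seed=0
    )
    gA = out[out.feature == "gA"].iloc[0]
    gB = out[out.feature == "gB"].iloc[0]
    assert gA.n_sets == 20 and bool(gA.hotspot)
    assert gB.n_sets == 1 and not gB.hotspot
    empty = amlm.find_hotspot_features([], features, 1e-5)
    assert empty.empty


def test_lead_snp_clusters_rules():
    recs = [_record(0, "H", "T1", 1e-9), _record(1, "H", "T1", 1e-7),
            _record(2, "H", "T1", 1e-6)]
    pairs = pd.DataFrame(
        {
            "site_a": [0, 0, 1], "site_b": [1, 2, 2],
            "pos_a": [100, 100, 150], "pos_b": [150, 200, 200],
            "dist_bp": [50, 100, 50],
            "r2": [0.95, 0.0, 0.0], "p": [1e-4] * 3,
        }
    )
    ldres = ld.LDResult(pairs=pairs, site_index=np.array([0, 1, 2]), n=100)
    signals = amlm.lead_snp_clusters(recs, ldres, r2_cut=0.2)
    assert len(signals) == 2
    assert signals[0]["lead"].site_index == 0  # lowest P leads
    assert {m.site_index for m in signals[0]["members"]} == {0, 1}
    # tie in P -> smaller genomic coordinate leads
    recs_tie = [_record(5, "H", "T1", 1e-6), _record(3, "H", "T1", 1e-6)]
    ld_empty = ld.LDResult(pairs=pairs.iloc[0:0], site_index=np.array([]), n=100)
    signals = amlm.lead_snp_clusters(recs_tie, ld_empty)
    assert signals[0]["lead"].site_index == 3


def test_candidate_features_within_10kb():
    lead = _record(0, "H", "T1", 1e-9)  # pos 100
    ivs = [GenomicInterval("Chr01", 5000, 6000, "near"),
           GenomicInterval("Chr01", 30000, 31000, "far"),
           GenomicInterval("Chr02", 120, 400, "other_chrom")]
    assert amlm.candidate_features_near(lead, ivs) == ["near"]
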