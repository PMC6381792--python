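"""Interval-mapping scans, permutation thresholds, MQM, hotspots."""

import numpy as np
import pandas as pd
import pytest

from linkld import linkage_qtl as lq
from linkld import synthetic_data as syn


@pytest.fixture(scope="module")
def family_and_grid(small_family):
    data, truth = small_family
    return data, truth, lq.build_grid(data)


def test_scan_at_marker_equals_single_marker_regression(family_and_grid):
    """At a fully informative marker position the Haley-Knott statistic
    collapses to the closed-form single-marker regression LOD."""
    data, _, grid = family_and_grid
    scan = lq.interval_scan(data, "H", "T_01", grid=grid)
    marker_row = data.lg_markers("LG_01").iloc[10]
    y = data.phenotypes.values_for("H", "T_01", list(data.calls.index))
    x = data.calls[marker_row["marker"]].to_numpy(dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    lod_direct = -(len(y) / 2) * np.log10(1 - r**2)
    prof = scan.lod_profile("LG_01")
    k = np.argmin(np.abs(prof["cM"].to_numpy() - marker_row["cM"]))
    assert prof["lod"].to_numpy()[k] == pytest.approx(lod_direct, abs=1e-6)


def test_lod_zero_for_constant_phenotype(family_and_grid):
    data, _, grid = family_and_grid
    pheno = data.phenotypes.data.copy()
    pheno.loc[
        (pheno.trait == "H") & (pheno.timepoint == "T_02"), "value"
    ] = 1.0
    data2 = type(data)(data.map, data.calls, type(data.phenotypes)(pheno))
    scan = lq.interval_scan(data2, "H", "T_02", grid=grid)
    assert np.all(scan.positions["lod"] == 0.0)


def test_lod_invariant_to_affine_phenotype(family_and_grid):
    data, _, grid = family_and_grid
    scan1 = lq.interval_scan(data, "H", "T_01", grid=grid)
    pheno = data.phenotypes.data.copy()
    sel = (pheno.trait == "H") & (pheno.timepoint == "T_01")
    pheno.loc[sel, "value"] = 3.0 * pheno.loc[sel, "value"] - 7.0
    data2 = type(data)(data.map, data.calls, type(data.phenotypes)(pheno))
    scan2 = lq.interval_scan(data2, "H", "T_01", grid=grid)
    np.testing.assert_allclose(
        scan1.positions["lod"], scan2.positions["lod"], atol=1e-8
    )


def test_planted_qtn_recovered_with_support_interval(family_and_grid):
    data, truth, grid = family_and_grid
    scan = lq.interval_scan(data, "H", "T_01", grid=grid)
    hits = [q for q in scan.qtls if q.lg == "LG_01"]
    assert hits
    best = max(hits, key=lambda q: q.lod)
    assert best.ci_lo <= best.cM <= best.ci_hi
    assert abs(best.cM - 30.0) < 8.0
    assert 0.0 <= best.pve < 1.0


def test_permutation_threshold_seeded_and_monotone(family_and_grid):
    data, _, grid = family_and_grid
    t1 = lq.permutation_threshold(
        data, "H", "T_01", n_perm=200, seed=11, grid=grid
    )
    t2 = lq.permutation_threshold(
        data, "H", "T_01", n_perm=200, seed=11, grid=grid
    )
    assert t1 == t2
    t10 = lq.permutation_threshold(
        data, "H", "T_01", n_perm=200, alpha=0.10, seed=11, grid=grid
    )
    tmin = lq.permutation_threshold(
        data, "H", "T_01", n_perm=200, alpha=1.0, seed=11, grid=grid
    )
    assert t10 <= t1
    assert tmin <= t10
    # threshold at desk scale sits in the neighbourhood of the classic 3.0
    assert 1.5 < t1 < 4.5


def test_null_scan_rarely_beats_threshold():
    """Permuted/no-QTN phenotypes exceed the 5% genome-wide threshold in
    about 5% of replicates (checked loosely at 20 replicates)."""
    exceed = 0
    for rep in range(20):
        cfg = syn.FamilyConfig.test_scale(
            seed=3000 + rep, n_progeny=200, n_lg=2, markers_per_lg=20,
            n_timepoints=1,
        )
        data, _ = syn.simulate_fullsib(cfg)
        grid = lq.build_grid(data)
        thr = lq.permutation_threshold(
            data, "H", "T_01", n_perm=200, seed=rep, grid=grid
        )
        scan = lq.interval_scan(data, "H", "T_01", grid=grid)
        exceed += scan.positions["lod"].max() > thr
    assert exceed <= 4


def test_support_interval_symmetry_and_boundary():
    pos = pd.DataFrame(
        {
            "lg": ["L"] * 21,
            "cM": np.arange(21.0),
            "lod": 5.0 - 0.3 * np.abs(np.arange(21.0) - 10.0),
        }
    )
    scan = lq.QTLScanResult(pos, [], "H", "T", 100)
    lo, hi = lq.support_interval(scan, "L", 10.0)
    assert (10.0 - lo) == (hi - 10.0) > 0
    # peak at the LG start gives a one-sided interval
    pos2 = pos.copy()
    pos2["lod"] = 5.0 - 0.3 * pos2["cM"]
    scan2 = lq.QTLScanResult(pos2, [], "H", "T", 100)
    lo2, hi2 = lq.support_interval(scan2, "L", 0.0)
    assert lo2 == 0.0 and hi2 > 0.0


def test_mqm_without_signal_equals_interval_scan(null_family):
    grid = lq.build_grid(null_family)
    mqm = lq.mqm_scan(null_family, "H", "T_01", threshold=3.5, grid=grid)
    base = lq.interval_scan(null_family, "H", "T_01", grid=grid)
    assert mqm.cofactors == []
    np.testing.assert_allclose(
        mqm.positions["lod"], base.positions["lod"], atol=1e-9
    )


def test_mqm_separates_two_linked_qtns():
    """Two QTNs 30 cM apart on one LG recovered as separate peaks after
    cofactor rescans (majority of replicates)."""
    both = 0
    for rep in range(10):
        cfg = syn.FamilyConfig.test_scale(
            seed=4000 + rep, n_progeny=400, n_lg=2, n_timepoints=1
        )
        data, _ = syn.simulate_fullsib(
            cfg,
            [
                syn.QTNSpec(("LG_01", 20.0), pve=0.15),
                syn.QTNSpec(("LG_01", 50.0), pve=0.15),
            ],
        )
        grid = lq.build_grid(data)
        scan = lq.mqm_scan(data, "H", "T_01", grid=grid)
        near20 = any(q.lg == "LG_01" and abs(q.cM - 20) < 8 for q in scan.qtls)
        near50 = any(q.lg == "LG_01" and abs(q.cM - 50) < 8 for q in scan.qtls)
        both += near20 and near50
    assert both >= 7


def test_colocalization_clustering_rules():
    def peak(lg, cm, lo, hi, tp):
        return lq.QTLPeak(lg, cm, 5.0, 0.1, lo, hi, "H", tp)

    # peaks 0.5 cM apart with overlapping intervals -> one region
    regions = lq.cluster_colocalized(
        [peak("L1", 10.0, 8, 12, "T1"), peak("L1", 10.5, 9, 13, "T2")]
    )
    assert len(regions) == 1
    assert regions[0].coverage == [("H", "T1"), ("H", "T2")]
    # peaks 1.5 cM apart -> two regions even with overlapping intervals
    regions = lq.cluster_colocalized(
        [peak("L1", 10.0, 8, 12, "T1"), peak("L1", 11.5, 9, 13, "T2")]
    )
    assert len(regions) == 2
    assert lq.cluster_colocalized([]) == []


def test_hotspot_extreme_and_degenerate_cases():
    lengths = {"L1": 50.0, "L2": 50.0}
    qtls = [
        lq.QTLPeak("L1", 10.3, 5, 0.1, 9, 11, "H", f"T{k}") for k in range(30)
    ] + [
        lq.QTLPeak("L2", float(5 * k), 5, 0.1, 1, 2, "H", f"T{k}")
        for k in range(10)
    ]
    res = lq.hotspot_test(qtls, lengths, n_perm=300, seed=1)
    hot_bins = res.hotspots
    assert any(
        (hot_bins["lg"] == "L1")
        & (hot_bins["bin_lo"] <= 10.3)
        & (10.3 < hot_bins["bin_hi"])
    )
    # 0 or 1 QTL -> no hotspot possible
    res0 = lq.hotspot_test([], lengths, n_perm=100, seed=1)
    assert len(res0.hotspots) == 0
    res1 = lq.hotspot_test(qtls[:1], lengths, n_perm=100, seed=1)
    assert len(res1.hotspots) == 0
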