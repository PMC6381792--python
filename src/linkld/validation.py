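"""Simulation-based validation experiments.

Each function runs one seeded end-to-end experiment on synthetic data —
statistical calibration on null models, or recovery of planted truth —
and returns the measured quantities.  They are used by the acceptance
test suite and by ``scripts/acceptance.py``; all randomness flows from
the ``seed`` argument.

Problem sizes are desk-scale versions of the study designs: families of
200-400 progeny on 2-3 linkage groups, panels of 150-300 individuals in
the three-subpopulation Balding-Nichols structure, SHR-like regions at
the study's SNP density (about one SNP per 45 bp of filtered common
variation).
"""

from __future__ import annotations

import numpy as np

from . import linkage_qtl as lq
from . import popgen_selection as pg
from . import synthetic_data as syn
from .association_mlm import (
    classify_effect,
    estimate_kinship,
    genomic_inflation,
    mlm_scan,
    structure_covariates,
)
from .data_model import GenomicInterval
from .epistasis import SkippedPair, two_locus_partition
from .ld_analysis import LDResult, fit_decay, hill_weir_expectation


def neutral_panel_calibration(seed: int, n_snps: int = 2000) -> dict:
    """Neutral two-subpopulation Balding-Nichols panel at F = 0.10.

    Returns the genome-wide ratio-of-sums Weir-Cockerham Fst (expected
    near 0.10) and the mean window Tajima's D in both subpopulations
    (expected near 0 under the neutral ancestral spectrum)."""
    n_regions = max(1, n_snps // 250)
    cfg = syn.PanelConfig(
        subpop_sizes=(100, 100), subpop_labels=("A", "B"), fst=0.10,
        n_regions=n_regions, region_length=25_000,
        snps_per_region=n_snps // n_regions, seed=seed,
    )
    g, _, _ = syn.simulate_panel(cfg)
    sp = g.subpop_indices()
    a, b, c = pg.weir_cockerham_components(
        g.dosage[sp["A"]], g.dosage[sp["B"]]
    )
    fst = float(np.nansum(a) / np.nansum(a + b + c))
    ivs = [
        GenomicInterval(f"Chr{r + 1:02d}", 0, cfg.region_length)
        for r in range(n_regions)
    ]
    windows = pg.make_windows(ivs, 250)
    ds = []
    for lab in ("A", "B"):
        div = pg.window_diversity(g, windows, lab)
        ds.append(div["D"].dropna().to_numpy())
    d_all = np.concatenate(ds)
    return {
        "mean_fst": fst,
        "mean_tajima_d": float(d_all.mean()),
        "n_windows_with_d": int(len(d_all)),
        "n_snps": g.n_sites,
    }


def structured_null_lambda(seed: int, n_snps: int = 2000) -> dict:
    """Genomic inflation of the mixed model on a structured null
    (F = 0.2, polygenic background, no causal SNPs)."""
    cfg = syn.PanelConfig(
        subpop_sizes=(100, 100), subpop_labels=("A", "B"), fst=0.2,
        n_regions=8, region_length=25_000, snps_per_region=n_snps // 8,
        maf_dist="uniform", seed=seed,
    )
    g, pheno, _ = syn.simulate_panel(cfg)
    K = estimate_kinship(g)
    recs = mlm_scan(g, pheno, "H", "T2", K=K)
    pvals = np.array([r.p for r in recs])
    return {"lambda": genomic_inflation(pvals), "n_snps": len(pvals)}


def epistasis_type1(seed: int, n_pairs: int = 20_000) -> dict:
    """Type-I error of the two-locus interaction test at P < 0.001 on a
    structured null panel with no planted interactions."""
    cfg = syn.PanelConfig(
        subpop_sizes=(50, 50, 50), subpop_labels=("S", "NW", "NE"),
        fst=0.1, n_regions=2, region_length=25_000, snps_per_region=150,
        maf_dist="uniform", seed=seed,
    )
    g, pheno, _ = syn.simulate_panel(cfg)
    maf = g.maf()
    jdx = np.flatnonzero(maf >= 0.1)
    rng = np.random.default_rng(seed + 1)
    hits = tested = 0
    while tested < n_pairs:
        a, b = rng.choice(jdx, 2, replace=False)
        try:
            rec = two_locus_partition(g, pheno, "H", "T2", int(a), int(b))
        except (SkippedPair, ValueError):
            continue
        tested += 1
        hits += rec.p_interaction < 0.001
    return {"rate": hits / tested, "n_pairs": tested, "nominal": 0.001}


def qtl_null_exceedance(seed: int, n_reps: int = 200) -> dict:
    """Fraction of no-QTN families whose genome-wide max LOD beats their
    own 5% permutation threshold (nominal: ~5%)."""
    exceed = 0
    for rep in range(n_reps):
        cfg = syn.FamilyConfig.test_scale(
            seed=seed + rep, n_progeny=200, n_lg=2, markers_per_lg=20,
            n_timepoints=1,
        )
        data, _ = syn.simulate_fullsib(cfg)
        grid = lq.build_grid(data)
        thr = lq.permutation_threshold(
            data, "H", "T_01", n_perm=200, seed=seed + rep, grid=grid
        )
        scan = lq.interval_scan(data, "H", "T_01", grid=grid)
        exceed += scan.positions["lod"].max() > thr
    return {"rate": exceed / n_reps, "n_reps": n_reps, "nominal": 0.05}


def hotspot_false_positive_rate(seed: int, n_reps: int = 100) -> dict:
    """Fraction of uniform-peak replicates in which the hotspot test
    declares any hotspot (FWER, nominal <= ~5%)."""
    rng = np.random.default_rng(seed)
    lengths = {f"L{k}": 60.0 for k in range(4)}
    total = sum(lengths.values())
    false_pos = 0
    for rep in range(n_reps):
        qtls = []
        for _ in range(40):
            u = rng.uniform(0, total)
            for lg, ln in lengths.items():
                if u < ln:
                    qtls.append(
                        lq.QTLPeak(lg, float(u), 5.0, 0.1, u - 1, u + 1,
                                   "H", "T")
                    )
                    break
                u -= ln
        res = lq.hotspot_test(qtls, lengths, n_perm=300, seed=seed + rep)
        false_pos += len(res.hotspots) > 0
    return {"rate": false_pos / n_reps, "n_reps": n_reps, "nominal": 0.05}


def qtn_interval_coverage(seed: int, n_reps: int = 100) -> dict:
    """Planted QTN (PVE 0.20, 400 progeny): fraction of replicates whose
    1-LOD support interval covers the true position."""
    covered = detected = 0
    for rep in range(n_reps):
        cfg = syn.FamilyConfig.test_scale(seed=seed + rep, n_progeny=400)
        data, _ = syn.simulate_fullsib(
            cfg, [syn.QTNSpec(locus=("LG_02", 40.0), pve=0.2)]
        )
        grid = lq.build_grid(data)
        scan = lq.interval_scan(data, "H", "T_01", grid=grid)
        hits = [q for q in scan.qtls if q.lg == "LG_02"]
        detected += bool(hits)
        covered += any(q.ci_lo <= 40.0 <= q.ci_hi for q in hits)
    return {
        "coverage": covered / n_reps,
        "detection": detected / n_reps,
        "n_reps": n_reps,
    }


def sweep_recovery(seed: int, n_reps: int = 10) -> dict:
    """Planted sweep (rho = 0.05, F = 0.10, 150-member panel) against
    the joint top-1% criterion: window sensitivity, neutral-window FPR
    and the rate of Tajima's-D confirmation of the swept region.

    The sweep spans 2 kb of a 360-kb scan domain (8 SHR-like regions at
    one SNP per 45 bp of common variation); objective subpopulation S,
    reference NE."""
    iv = GenomicInterval("Chr01", 20_000, 22_000)
    sens, fpr = [], []
    confirmed = 0
    for rep in range(n_reps):
        cfg = syn.PanelConfig.test_scale(
            seed=seed + rep, n_regions=8, region_length=45_000,
            snps_per_region=1000, maf_dist="uniform",
        )
        g, _, _ = syn.simulate_panel(
            cfg, sweeps=[syn.SweepSpec(iv, "S", 0.05)]
        )
        shrs = [
            GenomicInterval(f"Chr{r + 1:02d}", 0, 45_000) for r in range(8)
        ]
        stats, regions = pg.selection_scan(g, shrs, ("S", "NE"), q=0.01,
                                           flank=0)
        inside = (
            (stats["chrom"] == "Chr01")
            & (stats["start"] >= iv.start)
            & (stats["end"] <= iv.end)
        )
        defined = stats["fst_S_NE"].notna() & (stats["pi_NE"] > 0)
        di = defined & inside
        if di.sum():
            sens.append(float(stats.loc[di, "flagged"].mean()))
        fpr.append(float(stats.loc[~inside & defined, "flagged"].mean()))
        confirmed += any(
            (r.tajima_confirmed is True) and r.interval.overlaps(iv)
            for r in regions
        )
    return {
        "sensitivity": float(np.mean(sens)),
        "neutral_fpr": float(np.mean(fpr)),
        "tajima_confirmed_rate": confirmed / n_reps,
        "n_reps": n_reps,
    }


def effect_recovery(seed: int, n_reps: int = 20) -> dict:
    """Planted additive and dominant SNPs (PVE 0.20, 300 individuals):
    effect-class recovery rate and fraction of a-hat/d-hat estimates
    within 2 SE of their planted values."""
    out = {}
    within = total = 0
    for kind, ratio in (("additive", 0.0), ("dominant", float("inf"))):
        ok = 0
        for rep in range(n_reps):
            cfg = syn.PanelConfig(
                subpop_sizes=(100, 100, 100),
                subpop_labels=("S", "NW", "NE"), fst=0.1, n_regions=2,
                region_length=20_000, snps_per_region=150,
                maf_dist="uniform", seed=seed + rep,
            )
            q = syn.QTNSpec(
                {"target_maf": 0.4, "chrom": "Chr01"}, pve=0.2,
                dominance_ratio=ratio,
            )
            g, pheno, truth = syn.simulate_panel(cfg, [q])
            j = truth["qtns"][0]["site"]
            Q = structure_covariates(g, "labels")
            eff = classify_effect(g, pheno, "H", "T2", j, Q=Q)
            ok += eff["effect_class"] == kind
            scale = truth["qtns"][0]["a_by_timepoint"][5]
            a_true = scale if kind == "additive" else 0.0
            d_true = scale if kind == "dominant" else 0.0
            within += abs(eff["a"] - a_true) < 2 * eff["se_a"]
            within += abs(eff["d"] - d_true) < 2 * eff["se_d"]
            total += 2
        out[f"{kind}_class_rate"] = ok / n_reps
    out["within_2se_rate"] = within / total
    out["n_reps"] = n_reps
    return out


def dxd_detection(seed: int, n_reps: int = 20) -> dict:
    """Planted pure dominance-by-dominance pair (PVE 0.12, 300
    individuals): detection at P < 0.001 and the rate at which the d x d
    component carries the largest component sum of squares."""
    detected = dd_largest = 0
    for rep in range(n_reps):
        cfg = syn.PanelConfig(
            subpop_sizes=(100, 100, 100), subpop_labels=("S", "NW", "NE"),
            fst=0.1, n_regions=2, region_length=20_000, snps_per_region=150,
            maf_dist="uniform", seed=seed + rep,
        )
        pair = syn.EpiPairSpec(
            {"target_maf": 0.4, "chrom": "Chr01"},
            {"target_maf": 0.4, "chrom": "Chr02"}, pve=0.12,
        )
        g, pheno, truth = syn.simulate_panel(cfg, epi_pairs=[pair])
        ja = truth["epi_pairs"][0]["site_a"]
        jb = truth["epi_pairs"][0]["site_b"]
        rec = two_locus_partition(g, pheno, "H", "T2", ja, jb)
        detected += rec.p_interaction < 0.001
        comps = {k: v[0] for k, v in rec.components.items()}
        dd_largest += max(comps, key=comps.get) == "dxd"
    return {
        "detection_rate": detected / n_reps,
        "dxd_largest_rate": dd_largest / n_reps,
        "n_reps": n_reps,
    }


def ld_decay_recovery(seed: int, n_pairs: int = 600) -> dict:
    """Hill-Weir curves with known rho plus noise: relative error of the
    refitted rho."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_chrom, rho = 300, 2e-4
    d = rng.uniform(50, 50_000, n_pairs)
    r2 = hill_weir_expectation(rho * d, n_chrom) + rng.normal(0, 0.02, n_pairs)
    res = LDResult(
        pairs=pd.DataFrame(
            {
                "site_a": 0, "site_b": 1, "pos_a": 0,
                "pos_b": d.astype(int), "dist_bp": d.astype(int),
                "r2": np.clip(r2, 0, 1), "p": 0.0,
            }
        ),
        site_index=np.array([0, 1]),
        n=n_chrom // 2,
    )
    fit = fit_decay(res, n_chromosomes=n_chrom)
    return {
        "rho_true": rho,
        "rho_hat": fit["rho_hat"],
        "rel_error": abs(fit["rho_hat"] - rho) / rho,
        "n_pairs": n_pairs,
    }
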