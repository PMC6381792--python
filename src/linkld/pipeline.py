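"""End-to-end orchestration of the linkage-LD mapping stages.

Stage order: simulate -> qtl -> hotspots -> shr -> popgen -> ld ->
assoc -> epistasis -> report.  Each stage writes its outputs (TSV /
BED / JSON) into the output directory and later stages reload them
from disk when not in memory, so runs are resumable.  Every random
stage draws its seed from the config; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    annotation,
    association_mlm as amlm,
    data_model as dm,
    epistasis as epi,
    ld_analysis as ld,
    linkage_qtl as lq,
    popgen_selection as pg,
    shr_projection as shr_mod,
    synthetic_data as syn,
)

logger = logging.getLogger("linkld")

STAGES = (
    "simulate",
    "qtl",
    "hotspots",
    "shr",
    "popgen",
    "ld",
    "assoc",
    "epistasis",
    "report",
)


def _json_default(o):
    if hasattr(o, "item"):
        return o.item()
    return str(o)


class StageError(RuntimeError):
    """A stage's upstream output is missing."""

    def __init__(self, stage: str, missing: str):
        super().__init__(
            f"stage '{stage}' requires missing upstream output: {missing}"
        )
        self.stage = stage


def default_config(seed: int = 0) -> dict:
    """Desk-scale synthetic configuration exercising every stage."""
    return {
        "seed": seed,
        "stages": {s: True for s in STAGES},
        "family": {
            "n_progeny": 300,
            "n_lg": 3,
            "markers_per_lg": 30,
            "n_timepoints": 4,
        },
        "family_qtns": [
            {"lg": "LG_01", "cM": 30.0, "pve": 0.2, "pve_class": "level"}
        ],
        "panel": {
            "subpop_sizes": [60, 40, 50],
            "n_regions": 3,
            "region_length": 25000,
            "snps_per_region": 250,
            "maf_dist": "uniform",
        },
        "panel_qtns": [
            {"site": {"target_maf": 0.3, "chrom": "Chr02"}, "pve": 0.15,
             "dominance_ratio": 0.0}
        ],
        "panel_sweep": {"region": 0, "start": 8500, "end": 10500,
                       "subpop": "NW", "rho_sweep": 0.05},
        "qtl": {"traits": ["H"], "timepoints": ["T_01", "T_02"],
                "n_perm": 200, "alpha": 0.05},
        "popgen": {"q": 0.05, "flank": 10000},
        "ld": {"n_perm": 1000, "max_sites": 60, "flank": 5000},
        "assoc": {"traits": ["H"], "timepoints": ["T1-01", "T2"],
                  "threshold": "suggestive"},
        "epistasis": {"alpha": 0.001, "max_candidates": 15},
    }


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Run the enabled stages in order; returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    provenance = {
        "config_sha1": hashlib.sha1(cfg_text.encode()).hexdigest(),
        "stages_run": [],
    }
    stages = config.get("stages", {s: True for s in STAGES})
    state: dict = {"config": config, "out": out}
    for stage in STAGES:
        if not stages.get(stage, True):
            logger.info("stage %s disabled", stage)
            continue
        _RUNNERS[stage](state)
        provenance["stages_run"].append(stage)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(state: dict) -> None:
    cfg = state["config"]
    out = state["out"]
    seed = int(cfg.get("seed", 0))
    fam_cfg = syn.FamilyConfig(seed=seed, **cfg.get("family", {}))
    qtns = [
        syn.QTNSpec(locus=(q["lg"], q["cM"]), pve=q.get("pve", 0.2),
                    pve_class=q.get("pve_class", "level"))
        for q in cfg.get("family_qtns", [])
    ]
    data, fam_truth = syn.simulate_fullsib(fam_cfg, qtns)
    dm.write_linkage_inputs(
        data, out / "map.tsv", out / "calls.tsv", out / "pheno_family.tsv"
    )
    pan_kwargs = dict(cfg.get("panel", {}))
    if "subpop_sizes" in pan_kwargs:
        pan_kwargs["subpop_sizes"] = tuple(pan_kwargs["subpop_sizes"])
    pan_cfg = syn.PanelConfig(seed=seed + 1, **pan_kwargs)
    sweeps = []
    sw = cfg.get("panel_sweep")
    if sw:
        chrom = f"Chr{sw['region'] + 1:02d}"
        sweeps.append(
            syn.SweepSpec(
                dm.GenomicInterval(chrom, sw["start"], sw["end"]),
                sw["subpop"],
                sw.get("rho_sweep", 0.05),
            )
        )
    pqtns = [
        syn.QTNSpec(locus=q["site"], pve=q.get("pve", 0.1),
                    dominance_ratio=q.get("dominance_ratio", 0.0))
        for q in cfg.get("panel_qtns", [])
    ]
    g, pheno, pan_truth = syn.simulate_panel(pan_cfg, pqtns, sweeps)
    region = dm.GenomicInterval("Chr01", 0, pan_cfg.region_length)
    models, seqs = syn.simulate_gene_models(3, region, seed=seed + 2)
    # reconcile Chr01 ref/alt alleles with the toy reference sequence
    seq = seqs["Chr01"]
    for j in g.sites.index[g.sites["chrom"] == "Chr01"]:
        ref = seq[int(g.sites.at[j, "pos"]) - 1]
        if g.sites.at[j, "alt"] == ref:
            g.sites.at[j, "alt"] = g.sites.at[j, "ref"]
        g.sites.at[j, "ref"] = ref
        if g.sites.at[j, "alt"] == ref:
            g.sites.at[j, "alt"] = "A" if ref != "A" else "G"
    dm.write_vcf(g, out / "panel.vcf")
    dm.write_subpops(g, out / "subpops.tsv")
    pheno.data.to_csv(out / "pheno_panel.tsv", sep="\t", index=False)
    # anchors: map the first LGs linearly onto the panel regions
    rows = []
    for r in range(pan_cfg.n_regions):
        lg = f"LG_{r + 1:02d}"
        if lg not in data.lgs:
            break
        grp = data.lg_markers(lg)
        lg_len = float(grp["cM"].max())
        chrom = f"Chr{r + 1:02d}"
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            cm = frac * lg_len
            k = int(np.argmin(np.abs(grp["cM"].to_numpy() - cm)))
            rows.append(
                (
                    grp["marker"].iloc[k],
                    lg,
                    float(grp["cM"].iloc[k]),
                    chrom,
                    int(
                        round(
                            grp["cM"].iloc[k] / lg_len
                            * (pan_cfg.region_length - 1)
                        )
                    )
                    + 1,
                )
            )
    anchors = pd.DataFrame(rows, columns=["marker", "lg", "cM", "chrom", "bp"])
    anchors.drop_duplicates(subset=["marker"]).to_csv(
        out / "anchors.tsv", sep="\t", index=False
    )
    dm.write_gff3(models, out / "genes.gff3")
    dm.write_fasta(seqs, out / "ref.fasta")
    truth = {"family": fam_truth, "panel": pan_truth}
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=_json_default))
    state.update(family=data, panel=g, panel_pheno=pheno, truth=truth,
                 anchors=anchors, models=models, seqs=seqs)


def _need_family(state: dict, stage: str):
    if "family" not in state:
        out = state["out"]
        paths = [out / p for p in ("map.tsv", "calls.tsv", "pheno_family.tsv")]
        if not all(p.exists() for p in paths):
            raise StageError(stage, "simulate outputs (map/calls/pheno)")
        state["family"] = dm.read_linkage_inputs(*map(str, paths))
    return state["family"]


def _need_panel(state: dict, stage: str):
    if "panel" not in state:
        out = state["out"]
        vcf, sub = out / "panel.vcf", out / "subpops.tsv"
        if not (vcf.exists() and sub.exists()):
            raise StageError(stage, "simulate outputs (panel.vcf/subpops.tsv)")
        g = dm.read_vcf(str(vcf))
        g.subpop = dm.read_subpops(str(sub)).reindex(g.individuals)
        state["panel"] = g
        state["panel_pheno"] = dm.PhenotypeTable(
            pd.read_csv(out / "pheno_panel.tsv", sep="\t")
        )
    return state["panel"]


def _stage_qtl(state: dict) -> None:
    cfg = state["config"]
    out = state["out"]
    data = _need_family(state, "qtl")
    qcfg = cfg.get("qtl", {})
    seed = int(cfg.get("seed", 0))
    grid = lq.build_grid(data)
    all_qtls: list[lq.QTLPeak] = []
    lod_rows = []
    for trait in qcfg.get("traits", ["H"]):
        for tp in qcfg.get("timepoints", ["T_01"]):
            thr = lq.permutation_threshold(
                data, trait, tp, n_perm=qcfg.get("n_perm", 200),
                alpha=qcfg.get("alpha", 0.05), seed=seed, grid=grid,
            )
            scan = lq.mqm_scan(data, trait, tp, threshold=max(thr, 3.0),
                               grid=grid)
            all_qtls.extend(scan.qtls)
            prof = scan.positions.copy()
            prof["trait"] = trait
            prof["timepoint"] = tp
            prof["threshold"] = thr
            lod_rows.append(prof)
    pd.concat(lod_rows).to_csv(out / "lod.tsv", sep="\t", index=False)
    qtl_df = pd.DataFrame(
        [
            {
                "lg": q.lg, "cM": q.cM, "lod": q.lod, "pve": q.pve,
                "ci_lo": q.ci_lo, "ci_hi": q.ci_hi, "trait": q.trait,
                "timepoint": q.timepoint,
            }
            for q in all_qtls
        ]
    )
    qtl_df.to_csv(out / "qtl.tsv", sep="\t", index=False)
    state["qtls"] = all_qtls


def _need_qtls(state: dict, stage: str) -> list[lq.QTLPeak]:
    if "qtls" not in state:
        path = state["out"] / "qtl.tsv"
        if not path.exists():
            raise StageError(stage, "qtl.tsv")
        df = pd.read_csv(path, sep="\t")
        state["qtls"] = [
            lq.QTLPeak(r.lg, r.cM, r.lod, r.pve, r.ci_lo, r.ci_hi, r.trait,
                       r.timepoint)
            for r in df.itertuples(index=False)
        ]
    return state["qtls"]


def _stage_hotspots(state: dict) -> None:
    out = state["out"]
    data = _need_family(state, "hotspots")
    qtls = _need_qtls(state, "hotspots")
    lengths = {
        lg: float(data.lg_markers(lg)["cM"].max()) for lg in data.lgs
    }
    res = lq.hotspot_test(
        qtls, lengths, seed=int(state["config"].get("seed", 0))
    )
    res.bins.to_csv(out / "hotspot_bins.tsv", sep="\t", index=False)
    res.hotspots.to_csv(out / "hotspots.tsv", sep="\t", index=False)
    state["hotspots"] = res


def _stage_shr(state: dict) -> None:
    out = state["out"]
    qtls = _need_qtls(state, "shr")
    if "anchors" not in state:
        path = out / "anchors.tsv"
        if not path.exists():
            raise StageError("shr", "anchors.tsv")
        state["anchors"] = shr_mod.read_anchor_table(str(path))
    regions = lq.cluster_colocalized(qtls)
    shrs, failures = shr_mod.project_regions(regions, state["anchors"])
    dm.write_intervals([s.interval for s in shrs], out / "shr.bed")
    meta = [
        {
            "name": s.interval.name,
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "n_qtl": s.n_qtl,
            "scale_cM_per_Mb": s.scale_cM_per_Mb,
            "extrapolated": s.extrapolated,
        }
        for s in shrs
    ]
    (out / "shr.json").write_text(
        json.dumps({"shrs": meta, "failures": failures}, indent=2, default=_json_default)
    )
    state["shrs"] = shrs


def _need_shrs(state: dict, stage: str) -> list[dm.GenomicInterval]:
    if "shrs" in state:
        return [s.interval for s in state["shrs"]]
    path = state["out"] / "shr.bed"
    if not path.exists():
        raise StageError(stage, "shr.bed")
    return dm.read_intervals(str(path))


def _stage_popgen(state: dict) -> None:
    cfg = state["config"].get("popgen", {})
    out = state["out"]
    g = _need_panel(state, "popgen")
    shrs = _need_shrs(state, "popgen")
    labels = list(g.subpop_indices())
    all_stats, region_rows = [], []
    for i, obj in enumerate(labels):
        for ref in labels[i + 1 :]:
            stats, regions = pg.selection_scan(
                g, shrs, (obj, ref), q=cfg.get("q", 0.01),
                flank=cfg.get("flank", pg.SCAN_FLANK_BP),
            )
            stats["pair"] = f"{obj}_vs_{ref}"
            all_stats.append(stats)
            for reg in regions:
                region_rows.append(
                    {
                        "chrom": reg.interval.chrom,
                        "start": reg.interval.start,
                        "end": reg.interval.end,
                        "pair": f"{obj}_vs_{ref}",
                        "mean_fst": reg.mean_fst,
                        "mean_logratio": reg.mean_logratio,
                        "tajima_confirmed": reg.tajima_confirmed,
                        "tajima_p": reg.tajima_p,
                    }
                )
    pd.concat(all_stats).to_csv(out / "windows.tsv", sep="\t", index=False)
    regions_df = pd.DataFrame(region_rows)
    regions_df.to_csv(out / "selective_regions.tsv", sep="\t", index=False)
    fix = pg.classify_fixation(g)
    fix.to_csv(out / "fixation.tsv", sep="\t", index=False)
    state["selective_regions"] = regions_df

    # functional annotation of the simulated gene-model region
    models = state.get("models")
    seqs = state.get("seqs")
    if models is None and (out / "genes.gff3").exists() and (out / "ref.fasta").exists():
        models = dm.read_gff3(str(out / "genes.gff3"))
        seqs = dm.read_fasta(str(out / "ref.fasta"))
    if models is not None:
        chroms = {gm.chrom for gm in models.genes}
        mask = g.sites["chrom"].isin(chroms).to_numpy()
        sub = g.subset_sites(mask)
        anns = annotation.annotate_snps(sub, models, seqs)
        annotation.annotations_frame(anns).to_csv(
            out / "annotations.tsv", sep="\t", index=False
        )
        div = annotation.diversity_by_class(sub, anns)
        div.to_csv(out / "diversity_by_class.tsv", sep="\t", index=False)


def _stage_ld(state: dict) -> None:
    cfg = state["config"].get("ld", {})
    out = state["out"]
    g = _need_panel(state, "ld")
    shrs = _need_shrs(state, "ld")
    seed = int(state["config"].get("seed", 0))
    pair_frames, block_ivs, decay = [], [], {}
    state["ld_results"] = {}
    flank = int(cfg.get("flank", 0))
    for shr in shrs:
        domain = dm.GenomicInterval(
            shr.chrom, max(0, shr.start - flank), shr.end + flank, shr.name
        )
        res = ld.pairwise_r2(
            g, domain, n_perm=cfg.get("n_perm", 1000), seed=seed
        )
        if cfg.get("max_sites") and len(res.site_index) > cfg["max_sites"]:
            keep = res.site_index[: cfg["max_sites"]]
            res.pairs = res.pairs[
                res.pairs.site_a.isin(keep) & res.pairs.site_b.isin(keep)
            ]
            res.site_index = keep
        ld.detect_blocks(res, g)
        df = res.pairs.copy()
        df["shr"] = shr.name
        pair_frames.append(df)
        block_ivs.extend(res.blocks)
        if len(res.pairs) >= 50:
            try:
                decay[shr.name or shr.chrom] = ld.fit_decay(res)
            except (RuntimeError, ValueError) as exc:
                decay[shr.name or shr.chrom] = {"error": str(exc)}
        state["ld_results"][shr.name or shr.chrom] = res
    pd.concat(pair_frames).to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    dm.write_intervals(block_ivs, out / "ld_blocks.bed")
    (out / "ld_decay.json").write_text(json.dumps(decay, indent=2, default=_json_default))


def _stage_assoc(state: dict) -> None:
    cfg = state["config"].get("assoc", {})
    out = state["out"]
    g = _need_panel(state, "assoc")
    g = g.apply_filter(dm.FilterConfig())
    state["panel_filtered"] = g
    pheno = state["panel_pheno"]
    thr = amlm.compute_thresholds(g.n_sites)
    cut = (
        thr.significant
        if cfg.get("threshold", "suggestive") == "significant"
        else thr.suggestive
    )
    K = amlm.estimate_kinship(g)
    Q = amlm.structure_covariates(g, "labels")
    records: list[amlm.AssociationRecord] = []
    traits = cfg.get("traits", ["H"])
    tps = cfg.get("timepoints", ["T1-01"])
    for trait in traits:
        for tp in tps:
            recs = amlm.mlm_scan(g, pheno, trait, tp, K=K, Q=Q)
            for r in recs:
                if r.p < cut:
                    eff = amlm.classify_effect(
                        g, pheno, trait, tp, r.site_index, Q=Q
                    )
                    r.a = eff["a"]
                    r.d = eff["d"]
                    r.p_additive = eff["p_additive"]
                    r.p_dominance = eff["p_dominance"]
                    r.effect_class = eff["effect_class"]
            records.extend(recs)
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(out / "assoc.tsv", sep="\t", index=False)
    state["assoc_records"] = records
    state["assoc_thresholds"] = thr


def _stage_epistasis(state: dict) -> None:
    cfg = state["config"].get("epistasis", {})
    out = state["out"]
    g = state.get("panel_filtered")
    if g is None:
        g = _need_panel(state, "epistasis").apply_filter(dm.FilterConfig())
    pheno = state["panel_pheno"]
    records = state.get("assoc_records")
    if records is None:
        path = out / "assoc.tsv"
        if not path.exists():
            raise StageError("epistasis", "assoc.tsv")
        adf = pd.read_csv(path, sep="\t")
    else:
        adf = pd.DataFrame([vars(r) for r in records])
    if adf.empty:
        epi.records_frame([]).to_csv(out / "epistasis.tsv", sep="\t",
                                     index=False)
        return
    thr = state.get("assoc_thresholds") or amlm.compute_thresholds(g.n_sites)
    sig = adf[adf["p"] < thr.suggestive]
    cand = sig["site_index"].unique()
    if len(cand) < 2:
        # fall back to the strongest marginal SNPs so the stage always runs
        cand = adf.sort_values("p")["site_index"].unique()[:10]
    max_c = cfg.get("max_candidates", 15)
    cand = np.sort(cand[:max_c])
    trait, tp = adf["trait"].iloc[0], adf["timepoint"].iloc[0]
    recs, scan_log = epi.epistasis_scan(
        g, pheno, trait, tp, candidates=cand, alpha=cfg.get("alpha", 0.001)
    )
    epi.records_frame(recs).to_csv(out / "epistasis.tsv", sep="\t",
                                   index=False)
    state["epistasis_records"] = recs
    state["epistasis_log"] = scan_log


def _stage_report(state: dict) -> None:
    out = state["out"]
    rep: dict = {"counts": {}}
    tables = {
        "qtl": "qtl.tsv",
        "hotspots": "hotspots.tsv",
        "selective_regions": "selective_regions.tsv",
        "ld_pairs": "ld_pairs.tsv",
        "assoc": "assoc.tsv",
        "epistasis": "epistasis.tsv",
    }
    for key, fname in tables.items():
        p = out / fname
        if p.exists():
            try:
                rep["counts"][key] = int(len(pd.read_csv(p, sep="\t")))
            except pd.errors.EmptyDataError:
                rep["counts"][key] = 0
    shr_path = out / "shr.json"
    if shr_path.exists():
        rep["counts"]["shrs"] = len(json.loads(shr_path.read_text())["shrs"])
    truth_path = out / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        rep["truth_recovery"] = _recovery_metrics(state, truth)
    (out / "report.json").write_text(json.dumps(rep, indent=2, default=_json_default))
    lines = ["linkld pipeline report", "=" * 30]
    for k, v in rep["counts"].items():
        lines.append(f"{k:>20}: {v}")
    if "truth_recovery" in rep:
        for k, v in rep["truth_recovery"].items():
            lines.append(f"{k:>30}: {v}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    state["report"] = rep


def _recovery_metrics(state: dict, truth: dict) -> dict:
    out: dict = {}
    qtl_path = state["out"] / "qtl.tsv"
    planted = truth.get("family", {}).get("qtns", [])
    if qtl_path.exists() and planted:
        try:
            qdf = pd.read_csv(qtl_path, sep="\t")
        except pd.errors.EmptyDataError:
            qdf = pd.DataFrame()
        found = 0
        for q in planted:
            if qdf.empty:
                break
            hit = qdf[
                (qdf["lg"] == q["lg"])
                & (qdf["ci_lo"] <= q["cM"])
                & (q["cM"] <= qdf["ci_hi"])
            ]
            found += int(len(hit) > 0)
        out["family_qtn_covered"] = f"{found}/{len(planted)}"
    sel_path = state["out"] / "selective_regions.tsv"
    sweeps = truth.get("panel", {}).get("sweeps", [])
    if sel_path.exists() and sweeps:
        try:
            sdf = pd.read_csv(sel_path, sep="\t")
        except pd.errors.EmptyDataError:
            sdf = pd.DataFrame()
        found = 0
        for sw in sweeps:
            if sdf.empty:
                break
            hit = sdf[
                (sdf["chrom"] == sw["chrom"])
                & (sdf["start"] < sw["end"])
                & (sdf["end"] > sw["start"])
            ]
            found += int(len(hit) > 0)
        out["sweeps_recovered"] = f"{found}/{len(sweeps)}"
    return out


_RUNNERS = {
    "simulate": _stage_simulate,
    "qtl": _stage_qtl,
    "hotspots": _stage_hotspots,
    "shr": _stage_shr,
    "popgen": _stage_popgen,
    "ld": _stage_ld,
    "assoc": _stage_assoc,
    "epistasis": _stage_epistasis,
    "report": _stage_report,
}
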