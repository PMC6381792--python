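"""Synthetic study populations with known ground truth.

Two designs are emulated:

* a pseudo-testcross full-sib family genotyped on a multi-LG linkage map,
  with planted time-varying QTL (quantitative trait nucleotides, QTNs)
  driving longitudinal stem-growth phenotypes; and
* a structured association panel of three subpopulations differentiated
  under the Balding–Nichols model, with planted selective sweeps and
  planted additive / dominant / epistatic causal SNPs across 27
  trait x timepoint phenotype sets.

Every simulator takes an explicit seed and returns a truth record naming
the planted loci, so downstream scans can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    GeneModel,
    GeneModelSet,
    GenomicInterval,
    GenotypeMatrix,
    LinkageDataset,
    PhenotypeTable,
)

PANEL_TIMEPOINTS = (
    "T1-01",
    "T1-02",
    "T1-03",
    "T1-04",
    "T1-05",
    "T2",
    "T3",
    "T4",
    "T5",
)
FAMILY_TIMEPOINTS = tuple(f"T_{i:02d}" for i in range(1, 13))
TRAITS = ("H", "BD", "V")

PVE_CLASSES = ("increasing", "decreasing", "level", "increase-then-level")


def haldane_r(d_cM: float) -> float:
    """Recombination fraction for a Haldane map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def pve_trajectory(pve_class: str, peak_pve: float, n_t: int) -> np.ndarray:
    """Per-timepoint target PVE for one of the four trajectory shapes."""
    t = np.linspace(0.0, 1.0, n_t)
    if pve_class == "increasing":
        return peak_pve * (0.2 + 0.8 * t)
    if pve_class == "decreasing":
        return peak_pve * (1.0 - 0.8 * t)
    if pve_class == "level":
        return np.full(n_t, peak_pve)
    if pve_class == "increase-then-level":
        return peak_pve * np.minimum(1.0, 0.2 + 2.4 * t)
    raise ValueError(f"unknown PVE class {pve_class!r}")


@dataclass(frozen=True)
class QTNSpec:
    """A planted causal locus.

    locus: for the family, (lg, cM); for the panel, a site index or
        (chrom, pos).  Effects are parameterised by a target PVE
    trajectory; the simulator back-solves the additive effect size.
    """

    locus: object
    pve: float = 0.1
    pve_class: str = "level"
    dominance_ratio: float = 0.0  # d / a
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        if not (0.0 <= self.pve < 1.0):
            raise ValueError("target PVE must be in [0, 1)")
        if self.pve_class not in PVE_CLASSES:
            raise ValueError(f"pve_class must be one of {PVE_CLASSES}")


@dataclass(frozen=True)
class EpiPairSpec:
    """A planted two-locus interaction with no marginal effects."""

    locus_a: object
    locus_b: object
    pve: float = 0.05
    kind: str = "dxd"  # only dominance-by-dominance planted
    traits: tuple[str, ...] = TRAITS


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep: minor-allele frequencies in the
    objective subpopulation are multiplied by rho_sweep inside the
    target interval (rho -> 0 is a complete sweep)."""

    interval: GenomicInterval
    subpop: str
    rho_sweep: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_sweep <= 1.0):
            raise ValueError("rho_sweep must be in (0, 1]")


@dataclass(frozen=True)
class FamilyConfig:
    """Full-sib family design.

    Defaults follow the study family: 1,200 progeny, 19 LGs with a mean
    marker interval of 2.3 cM, 12 timepoints.  Tests use the desk-scale
    `test_scale()` preset (300 progeny, fewer LGs).
    """

    n_progeny: int = 1200
    n_lg: int = 19
    markers_per_lg: int = 67
    mean_interval_cM: float = 2.3
    n_timepoints: int = 12
    residual_ar1: float = 0.6
    missing_rate: float = 0.0
    seed: int = 0

    @staticmethod
    def test_scale(**kw) -> "FamilyConfig":
        base = dict(n_progeny=300, n_lg=3, markers_per_lg=30, seed=0)
        base.update(kw)
        return FamilyConfig(**base)


@dataclass(frozen=True)
class PanelConfig:
    """Association-panel design.

    Defaults follow the study panel: 435 individuals in three climatic
    subpopulations S/NW/NE of sizes 180/95/160.  `test_scale()` gives the
    desk-scale 150-member panel (60/40/50).
    """

    subpop_sizes: tuple[int, ...] = (180, 95, 160)
    subpop_labels: tuple[str, ...] = ("S", "NW", "NE")
    fst: float | tuple[float, ...] = 0.10
    n_regions: int = 4
    region_length: int = 25_000
    snps_per_region: int = 250
    missing_rate: float = 0.0
    maf_dist: str = "neutral"  # or "uniform"
    maf_gamma: float = 1.35
    maf_lo: float = 2.5e-4
    maf_hi: float = 0.9
    ld_mode: str = "independent"  # or "copying"
    n_founder_haplotypes: int = 20
    copy_switch_bp: float = 2000.0
    # (region_index, start_bp, end_bp) spans of low haplotype diversity:
    # within each span every subpop carries just two local haplotypes,
    # so its segregating sites form a high-LD block
    block_segments: tuple[tuple[int, int, int], ...] = ()
    timepoints: tuple[str, ...] = PANEL_TIMEPOINTS
    traits: tuple[str, ...] = TRAITS
    polygenic_pve: float = 0.2
    seed: int = 0

    @staticmethod
    def test_scale(**kw) -> "PanelConfig":
        base = dict(subpop_sizes=(60, 40, 50), seed=0)
        base.update(kw)
        return PanelConfig(**base)

    def fst_for(self, k: int) -> float:
        if isinstance(self.fst, tuple):
            return self.fst[k]
        return float(self.fst)


# ---------------------------------------------------------------------------
# full-sib family
# ---------------------------------------------------------------------------


def _simulate_chain(rng: np.random.Generator, n: int, pos_cM: np.ndarray) -> np.ndarray:
    """Markov chain of 0/1 inheritance states along one LG (Haldane)."""
    m = len(pos_cM)
    g = np.empty((n, m), dtype=np.int8)
    g[:, 0] = rng.integers(0, 2, size=n)
    for k in range(1, m):
        r = haldane_r(pos_cM[k] - pos_cM[k - 1])
        flip = rng.random(n) < r
        g[:, k] = np.where(flip, 1 - g[:, k - 1], g[:, k - 1])
    return g


def simulate_fullsib(
    config: FamilyConfig, qtns: list[QTNSpec] | None = None
) -> tuple[LinkageDataset, dict]:
    """Simulate a pseudo-testcross full-sib family with planted QTNs.

    All markers segregate 1:1 in two-class coding {0, 1}; progeny
    genotypes follow Markovian recombination along each LG under the
    Haldane map function (no interference).  Phenotypes are the sum of
    planted QTN effects plus an AR(1)-correlated residual across
    timepoints.  Returns the dataset and a ground-truth record.
    """
    qtns = qtns or []
    rng = np.random.default_rng(config.seed)
    lgs = [f"LG_{i + 1:02d}" for i in range(config.n_lg)]

    # map: exponential inter-marker gaps with the configured mean
    map_rows = []
    for lg in lgs:
        gaps = rng.exponential(config.mean_interval_cM, config.markers_per_lg - 1)
        gaps = np.maximum(gaps, 0.05)
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        for j, p in enumerate(pos):
            map_rows.append((lg, f"{lg}_m{j + 1:03d}", round(float(p), 4)))
    map_df = pd.DataFrame(map_rows, columns=["lg", "marker", "cM"])

    # attach QTN loci to their LG, simulate markers+QTN jointly, drop QTN
    qtn_by_lg: dict[str, list[tuple[int, QTNSpec]]] = {}
    for i, q in enumerate(qtns):
        lg, cm = q.locus
        if lg not in lgs:
            raise ValueError(f"QTN locus LG {lg!r} not on simulated map")
        qtn_by_lg.setdefault(lg, []).append((i, q))

    n = config.n_progeny
    progeny = [f"P{i + 1:04d}" for i in range(n)]
    call_cols: dict[str, np.ndarray] = {}
    qtn_geno = np.empty((n, len(qtns)), dtype=np.int8)
    for lg in lgs:
        grp = map_df[map_df["lg"] == lg]
        mpos = grp["cM"].to_numpy(dtype=float)
        extra = [(i, float(q.locus[1])) for i, q in qtn_by_lg.get(lg, [])]
        allpos = np.concatenate([mpos, [p for _, p in extra]])
        order = np.argsort(allpos, kind="stable")
        chain = _simulate_chain(rng, n, allpos[order])
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        for k, marker in enumerate(grp["marker"]):
            call_cols[marker] = chain[:, inv[k]].astype(float)
        for j, (qi, _) in enumerate(extra):
            qtn_geno[:, qi] = chain[:, inv[len(mpos) + j]]
    calls = pd.DataFrame(call_cols, index=progeny)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(mask)

    # phenotypes: per trait, AR(1) residual + QTN effects back-solved
    # from target PVE (marker variance is 1/4 under 1:1 segregation)
    tps = [f"T_{i:02d}" for i in range(1, config.n_timepoints + 1)]
    rho = config.residual_ar1
    truth_effects = []
    rows = []
    for trait in TRAITS:
        eps = rng.standard_normal((n, len(tps)))
        resid = np.empty_like(eps)
        resid[:, 0] = eps[:, 0]
        for t in range(1, len(tps)):
            resid[:, t] = rho * resid[:, t - 1] + np.sqrt(1 - rho**2) * eps[:, t]
        y = resid.copy()
        for qi, q in enumerate(qtns):
            if trait not in q.traits:
                continue
            pves = pve_trajectory(q.pve_class, q.pve, len(tps))
            if np.any(pves >= 1.0):
                raise ValueError("requested PVE unattainable (>= 1)")
            a_t = np.sqrt(pves / (0.25 * (1.0 - pves)))  # residual var = 1
            y += (qtn_geno[:, qi : qi + 1] - 0.5) * a_t[None, :]
            truth_effects.append(
                {
                    "qtn": qi,
                    "trait": trait,
                    "lg": q.locus[0],
                    "cM": float(q.locus[1]),
                    "pve_by_timepoint": pves.tolist(),
                    "a_by_timepoint": a_t.tolist(),
                }
            )
        for t, tp in enumerate(tps):
            for i in range(n):
                rows.append((progeny[i], trait, tp, y[i, t]))
    pheno = PhenotypeTable(
        pd.DataFrame(rows, columns=["individual", "trait", "timepoint", "value"])
    )
    truth = {
        "kind": "fullsib",
        "seed": config.seed,
        "qtns": [
            {"lg": q.locus[0], "cM": float(q.locus[1]), "pve": q.pve,
             "pve_class": q.pve_class}
            for q in qtns
        ],
        "effects": truth_effects,
        "note": "phenotype model is this simulator's choice: QTN effects "
        "plus AR(1) residuals; no empirical generative model exists",
    }
    return LinkageDataset(map_df, calls, pheno), truth


# ---------------------------------------------------------------------------
# association panel
# ---------------------------------------------------------------------------


def _ancestral_frequencies(
    rng: np.random.Generator, n_sites: int, config: PanelConfig
) -> np.ndarray:
    """Ancestral derived-allele frequencies.

    "neutral" (default): density proportional to x^(-gamma) on
    (maf_lo, maf_hi).  gamma is calibrated (1.35) so that after the
    Balding–Nichols drift step the within-subpopulation site frequency
    spectra are approximately neutral (window Tajima's D centred near
    zero at F = 0.10).  "uniform": Uniform(0.05, 0.5) minor-allele
    frequencies, an intermediate-frequency-rich spectrum useful for
    association-power studies."""
    if config.maf_dist == "uniform":
        return rng.uniform(0.05, 0.5, n_sites)
    if config.maf_dist != "neutral":
        raise ValueError("maf_dist must be 'neutral' or 'uniform'")
    lo, hi, gamma = config.maf_lo, config.maf_hi, config.maf_gamma
    u = rng.uniform(size=n_sites)
    if abs(gamma - 1.0) < 1e-9:
        return lo * (hi / lo) ** u
    g1 = 1.0 - gamma
    return (lo**g1 + u * (hi**g1 - lo**g1)) ** (1.0 / g1)


def _bn_frequencies(
    rng: np.random.Generator, p_anc: np.ndarray, F: float
) -> np.ndarray:
    """Balding–Nichols subpopulation frequencies given ancestral freqs."""
    if F <= 0:
        return p_anc.copy()
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return rng.beta(a, b)


def _apply_sweep(
    rng: np.random.Generator, p: np.ndarray, rho: float
) -> np.ndarray:
    """Sweep a single favoured haplotype toward fixation.

    One haplotype is drawn from the pre-sweep pool (its allele at each
    site is Bernoulli(p)); residual frequencies are compressed toward
    that haplotype's alleles by factor rho, so diversity collapses by
    ~rho while sites where the favoured haplotype carries the locally
    rarer allele become near-fixed differences."""
    favored_alt = rng.random(p.shape) < p
    return np.where(favored_alt, 1.0 - rho * (1.0 - p), rho * p)


def simulate_panel(
    config: PanelConfig,
    qtns: list[QTNSpec] | None = None,
    sweeps: list[SweepSpec] | None = None,
    epi_pairs: list[EpiPairSpec] | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Simulate the structured association panel.

    Sites live on `n_regions` SHR-like regions.  Ancestral minor-allele
    frequencies are Uniform(0.05, 0.5); per-subpopulation frequencies
    follow Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are
    Hardy–Weinberg within subpopulation (or drawn from a founder-
    haplotype copying model when ``ld_mode="copying"``, which induces
    local LD).  Sweeps multiply objective-subpopulation minor-allele
    frequencies by rho_sweep inside their interval.  Phenotypes for all
    trait x timepoint sets are additive + dominance + pairwise epistatic
    deviations + a polygenic term with covariance proportional to the
    realized kinship + iid noise.
    """
    qtns = qtns or []
    sweeps = sweeps or []
    epi_pairs = epi_pairs or []
    rng = np.random.default_rng(config.seed)

    # --- sites ---
    chroms, poss, region_of = [], [], []
    for r in range(config.n_regions):
        chrom = f"Chr{r + 1:02d}"
        pos = np.sort(
            rng.choice(
                np.arange(1, config.region_length + 1),
                size=config.snps_per_region,
                replace=False,
            )
        )
        chroms.extend([chrom] * len(pos))
        poss.extend(pos.tolist())
        region_of.extend([r] * len(pos))
    n_sites = len(poss)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt_off = rng.integers(1, 4, n_sites)
    alt = bases[(np.char.find("ACGT", ref.astype("U1")) + alt_off) % 4]
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": ref, "alt": alt})

    p_anc = _ancestral_frequencies(rng, n_sites, config)

    labels = []
    for sz, lab in zip(config.subpop_sizes, config.subpop_labels):
        labels.extend([lab] * sz)
    n_ind = len(labels)
    individuals = [f"I{i + 1:04d}" for i in range(n_ind)]

    dosage = np.empty((n_ind, n_sites), dtype=float)
    sweep_site_mask = {s.subpop: np.zeros(n_sites, dtype=bool) for s in sweeps}
    site_iv = [
        GenomicInterval(sites.chrom[j], int(sites.pos[j]) - 1, int(sites.pos[j]))
        for j in range(n_sites)
    ]
    row0 = 0
    subpop_freqs = {}
    for k, (sz, lab) in enumerate(zip(config.subpop_sizes, config.subpop_labels)):
        p_sub = _bn_frequencies(rng, p_anc, config.fst_for(k))
        for sw in sweeps:
            if sw.subpop != lab:
                continue
            in_iv = np.array([iv.overlaps(sw.interval) for iv in site_iv])
            p_sub = np.where(
                in_iv, _apply_sweep(rng, p_sub, sw.rho_sweep), p_sub
            )
            sweep_site_mask[lab] |= in_iv
        subpop_freqs[lab] = p_sub
        if config.ld_mode == "copying":
            dosage[row0 : row0 + sz] = _copying_genotypes(
                rng, p_sub, sz, config, sites
            )
        else:
            dosage[row0 : row0 + sz] = rng.binomial(
                2, p_sub[None, :], size=(sz, n_sites)
            ).astype(float)
        row0 += sz

    # low-haplotype-diversity segments: two panel-wide local haplotypes,
    # subpop haplotype frequencies drifted Balding–Nichols style
    for reg_i, seg_lo, seg_hi in config.block_segments:
        chrom = f"Chr{reg_i + 1:02d}"
        jseg = np.flatnonzero(
            (sites["chrom"].to_numpy() == chrom)
            & (sites["pos"].to_numpy() - 1 >= seg_lo)
            & (sites["pos"].to_numpy() - 1 < seg_hi)
        )
        if len(jseg) == 0:
            continue
        hapA = (rng.random(len(jseg)) < p_anc[jseg]).astype(float)
        hapB = (rng.random(len(jseg)) < p_anc[jseg]).astype(float)
        fA = rng.uniform(0.3, 0.7)
        row0 = 0
        for k, sz in enumerate(config.subpop_sizes):
            F = config.fst_for(k)
            fA_sub = float(
                _bn_frequencies(rng, np.array([fA]), F)[0]
            )
            pick = rng.random((sz, 2)) < fA_sub
            hap_mat = np.where(
                pick[:, :, None], hapA[None, None, :], hapB[None, None, :]
            )
            dosage[row0 : row0 + sz][:, jseg] = hap_mat.sum(axis=1)
            row0 += sz

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    g = GenotypeMatrix(individuals, sites, dosage, np.array(labels))

    pheno, pheno_truth = _panel_phenotypes(rng, g, config, qtns, epi_pairs)

    truth = {
        "kind": "panel",
        "seed": config.seed,
        "subpop_sizes": list(config.subpop_sizes),
        "sweeps": [
            {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "subpop": s.subpop,
                "rho_sweep": s.rho_sweep,
            }
            for s in sweeps
        ],
        "qtns": pheno_truth["qtns"],
        "epi_pairs": pheno_truth["epi_pairs"],
        "note": "all phenotype distributions are this simulator's choices",
    }
    return g, pheno, truth


def _copying_genotypes(rng, p_sub, sz, config: PanelConfig, sites) -> np.ndarray:
    """Founder-haplotype copying model: per region, each haplotype is a
    mosaic of K founder haplotypes with Poisson switch points; induces
    block-like LD with decay scale ``copy_switch_bp``."""
    n_sites = len(p_sub)
    out = np.zeros((sz, n_sites), dtype=float)
    for chrom, grp in sites.groupby("chrom", sort=False):
        jdx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        K = config.n_founder_haplotypes
        founders = (rng.random((K, len(jdx))) < p_sub[jdx][None, :]).astype(np.int8)
        p_switch = 1.0 - np.exp(-np.diff(pos) / config.copy_switch_bp)
        for hap in range(2):
            src = rng.integers(0, K, size=sz)
            h = np.empty((sz, len(jdx)), dtype=np.int8)
            h[:, 0] = founders[src, 0]
            for t in range(1, len(jdx)):
                switch = rng.random(sz) < p_switch[t - 1]
                src = np.where(switch, rng.integers(0, K, size=sz), src)
                h[:, t] = founders[src, t]
            out[:, jdx] += h
    return out


def _locus_index(g: GenotypeMatrix, locus) -> int:
    """Resolve a planted-locus spec to a site index.

    Accepts a plain site index, a (chrom, pos) pair, or a dict
    {"target_maf": q[, "chrom": c]} selecting the segregating site whose
    realized panel MAF is closest to q (deterministic given the panel)."""
    if isinstance(locus, (int, np.integer)):
        return int(locus)
    if isinstance(locus, dict):
        maf = g.maf()
        cand = np.flatnonzero(maf >= 0.05)
        if "chrom" in locus:
            cand = cand[g.sites["chrom"].to_numpy()[cand] == locus["chrom"]]
        if len(cand) == 0:
            raise ValueError(f"no segregating site matches locus spec {locus}")
        return int(cand[np.argmin(np.abs(maf[cand] - locus["target_maf"]))])
    chrom, pos = locus
    hit = g.sites[(g.sites["chrom"] == chrom) & (g.sites["pos"] == pos)]
    if hit.empty:
        raise ValueError(f"locus {locus} not among simulated sites")
    return int(hit.index[0])


def _panel_phenotypes(rng, g, config, qtns, epi_pairs):
    n = g.n_individuals
    tps = list(config.timepoints)

    # polygenic background with covariance proportional to realized kinship
    d = np.nan_to_num(g.dosage, nan=1.0)
    p = d.mean(axis=0) / 2.0
    keep = (p > 0.01) & (p < 0.99)
    z = (d[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    K = z @ z.T / keep.sum()
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 1e-8, None)
    Kroot = U * np.sqrt(w)

    qtn_truth, epi_truth = [], []
    rows = []
    for trait in config.traits:
        # polygenic effect shared across timepoints of a trait; iid noise
        upoly = Kroot @ rng.standard_normal(n)
        upoly = upoly / upoly.std()
        sig_poly = np.sqrt(
            config.polygenic_pve / max(1e-9, 1.0 - config.polygenic_pve)
        )
        y = sig_poly * upoly[:, None] + rng.standard_normal((n, len(tps)))
        for q in qtns:
            if trait not in q.traits:
                continue
            j = _locus_index(g, q.locus)
            x = np.nan_to_num(g.dosage[:, j], nan=np.nanmean(g.dosage[:, j]))
            pves = pve_trajectory(q.pve_class, q.pve, len(tps))
            xa = x - 1.0
            xd = (x == 1.0).astype(float)
            xd = xd - xd.mean()
            # genetic score with dominance_ratio d/a, scaled to hit the
            # target PVE; an infinite ratio means a purely dominant locus
            if np.isinf(q.dominance_ratio):
                score = xd
            else:
                score = xa + q.dominance_ratio * xd
            sv = score.var()
            if sv <= 0:
                raise ValueError(f"planted SNP {q.locus} is monomorphic")
            a_t = np.sqrt(pves / (sv * (1.0 - pves)))
            y += score[:, None] * a_t[None, :]
            qtn_truth.append(
                {
                    "site": j,
                    "chrom": str(g.sites.chrom[j]),
                    "pos": int(g.sites.pos[j]),
                    "trait": trait,
                    "pve": q.pve,
                    "pve_class": q.pve_class,
                    "dominance_ratio": q.dominance_ratio,
                    "a_by_timepoint": a_t.tolist(),
                }
            )
        for ep in epi_pairs:
            if trait not in ep.traits:
                continue
            ja = _locus_index(g, ep.locus_a)
            jb = _locus_index(g, ep.locus_b)
            za = (np.nan_to_num(g.dosage[:, ja], nan=1.0) == 1.0).astype(float)
            zb = (np.nan_to_num(g.dosage[:, jb], nan=1.0) == 1.0).astype(float)
            inter = (za - za.mean()) * (zb - zb.mean())
            iv = inter.var()
            if iv <= 0:
                raise ValueError("planted epistatic pair has no variance")
            e = np.sqrt(ep.pve / (iv * (1.0 - ep.pve)))
            y += e * inter[:, None]
            epi_truth.append(
                {"site_a": ja, "site_b": jb, "trait": trait, "pve": ep.pve,
                 "kind": ep.kind}
            )
        for t, tp in enumerate(tps):
            for i in range(n):
                rows.append((g.individuals[i], trait, tp, y[i, t]))
    pheno = PhenotypeTable(
        pd.DataFrame(rows, columns=["individual", "trait", "timepoint", "value"])
    )
    return pheno, {"qtns": qtn_truth, "epi_pairs": epi_truth}


# ---------------------------------------------------------------------------
# toy gene models + reference sequence
# ---------------------------------------------------------------------------


def simulate_gene_models(
    n_genes: int,
    region: GenomicInterval,
    seed: int = 0,
    n_ncrna: int = 2,
    gene_length: int = 3000,
) -> tuple[GeneModelSet, dict[str, str]]:
    """Place non-overlapping toy genes (UTR5-CDS-intron-CDS-UTR3) in a
    region, plus a few ncRNA records, and a random reference sequence.

    CDS total length is always divisible by 3.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    span = len(region)
    slot = span // max(1, n_genes + n_ncrna)
    if slot < gene_length + 200:
        raise ValueError("region too short for requested gene count")
    genes, ncrnas, ncrna_class = [], [], {}
    for i in range(n_genes):
        s0 = region.start + i * slot + int(rng.integers(0, slot - gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = 150
        cds1 = 300 + 3 * int(rng.integers(0, 100))
        intron = 200 + int(rng.integers(0, 200))
        cds2 = 300 + 3 * int(rng.integers(0, 100))
        utr3_len = 150
        a = s0
        b = a + utr5_len
        c = b + cds1
        dd = c + intron
        e = dd + cds2
        f = e + utr3_len
        if strand == "+":
            utr5, utr3 = [(a, b)], [(e, f)]
        else:
            utr5, utr3 = [(e, f)], [(a, b)]
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:03d}",
                chrom=region.chrom,
                start=a,
                end=f,
                strand=strand,
                exons=[(a, c), (dd, f)],
                cds=[(b, c), (dd, e)],
                utr5=utr5,
                utr3=utr3,
            )
        )
    for i in range(n_ncrna):
        s0 = region.start + (n_genes + i) * slot + int(rng.integers(0, slot // 2))
        ln = 200 + int(rng.integers(0, 400))
        name = f"ncrna{i + 1:02d}"
        ncrnas.append(GenomicInterval(region.chrom, s0, s0 + ln, name))
        ncrna_class[name] = "lncRNA" if i % 2 == 0 else "pre-miRNA"
    models = GeneModelSet(genes, ncrnas, ncrna_class)
    models.validate_frames()
    seq = "".join(rng.choice(list("ACGT"), size=region.end))
    return models, {region.chrom: seq}
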