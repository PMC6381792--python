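"""Mixed-linear-model association with additive/dominance decomposition.

The model is y = Q beta + x b + u + e with u ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I): Q holds structure covariates (subpopulation
indicator columns by default, top PCs optionally), K is an
identity-by-state kinship matrix.  Variance components are estimated
once per phenotype set on the no-SNP model by restricted likelihood on
the spectral decomposition of K (the population-parameters-previously-
determined approximation); each SNP is then tested by a generalized-
least-squares Wald test.  Missing dosages are mean-imputed per SNP in
this module only.

Significance thresholds follow the modified Bonferroni convention:
suggestive P = 1/n and significant P = 0.05/n for n markers.

Additive / dominance decomposition uses least-squares means of the
three genotype classes under the Q-adjusted linear model:
a = (mean(AA) - mean(aa))/2, d = mean(Aa) - (mean(AA) + mean(aa))/2,
each contrast tested at P < 0.001 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .data_model import GenotypeMatrix, PhenotypeTable
from .ld_analysis import LDResult

logger = logging.getLogger("linkld")

EFFECT_ALPHA = 0.001


@dataclass(frozen=True)
class Thresholds:
    n_markers: int

    @property
    def suggestive(self) -> float:
        return 1.0 / self.n_markers

    @property
    def significant(self) -> float:
        return 0.05 / self.n_markers


def compute_thresholds(n_markers: int) -> Thresholds:
    """Modified Bonferroni thresholds: suggestive 1/n, significant 0.05/n."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return Thresholds(n_markers)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def estimate_kinship(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state similarity over non-missing shared
    sites: 1 - mean(|d_i - d_j|)/2.  Diagonal exactly 1; symmetric."""
    if g.n_sites < 100:
        logger.warning("estimate_kinship: only %d SNPs", g.n_sites)
    D = g.dosage
    has = ~np.isnan(D)
    drop = ~has.any(axis=1)
    if drop.any():
        logger.warning(
            "estimate_kinship: %d individuals all-missing, excluded",
            int(drop.sum()),
        )
    Df = np.where(has, D, 0.0)
    n = D.shape[0]
    K = np.empty((n, n))
    # |di-dj| = di + dj - 2 min; expand via dosage one-hot for exactness
    onehot = np.stack([(Df == k) & has for k in (0.0, 1.0, 2.0)], axis=0)
    # sum over sites of |a-b| for shared non-missing sites
    absdiff = np.zeros((n, n))
    shared = has.astype(float) @ has.astype(float).T
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (
                onehot[a].astype(float) @ onehot[b].astype(float).T
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        K = 1.0 - absdiff / (2.0 * shared)
    K[shared == 0] = 0.0
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


def bend_psd(K: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Floor negative eigenvalues so K is positive semi-definite."""
    w, U = np.linalg.eigh(K)
    if w.min() >= 0:
        return K
    logger.info("kinship bent: min eigenvalue %.3g floored", w.min())
    w = np.clip(w, floor, None)
    return (U * w) @ U.T


def structure_covariates(
    g: GenotypeMatrix, method: str = "labels", n_pc: int = 3
) -> np.ndarray:
    """Q matrix: subpopulation indicator columns (drop-first) or top
    principal components of standardized dosage."""
    if method == "labels":
        labels = g.subpop.values
        cats = pd.unique(labels)[1:]
        return np.column_stack([(labels == c).astype(float) for c in cats])
    if method == "pca":
        D = np.where(np.isnan(g.dosage), np.nanmean(g.dosage, axis=0), g.dosage)
        Z = D - D.mean(axis=0)
        sd = Z.std(axis=0)
        Z = Z[:, sd > 0] / sd[sd > 0]
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        return U[:, :n_pc] * s[:n_pc]
    raise ValueError("method must be 'labels' or 'pca'")


# ---------------------------------------------------------------------------
# REML / GLS machinery
# ---------------------------------------------------------------------------


@dataclass
class MLMContext:
    """Variance components and rotated design shared across SNPs of one
    phenotype set (single REML fit; no per-SNP re-estimation)."""

    U: np.ndarray  # eigenvectors of K
    S: np.ndarray  # eigenvalues of K
    delta: float  # sigma_e^2 / sigma_g^2
    ystar: np.ndarray
    Xstar: np.ndarray  # rotated [1, Q]
    mask: np.ndarray  # individuals used


def _reml_neg_loglik(
    log_delta: float, ystar: np.ndarray, Xstar: np.ndarray, S: np.ndarray
) -> float:
    delta = np.exp(log_delta)
    w = S + delta
    Xw = Xstar / w[:, None]
    XtWX = Xstar.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ ystar)
    except np.linalg.LinAlgError:
        return 1e30
    r = ystar - Xstar @ beta
    n, p = Xstar.shape
    rss = float(r @ (r / w))
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return 1e30
    return 0.5 * (
        (n - p) * np.log(rss / (n - p)) + np.sum(np.log(w)) + logdet_x
    )


def fit_mlm_context(
    y: np.ndarray, Q: np.ndarray | None, K: np.ndarray
) -> MLMContext:
    """One REML fit of delta on the no-SNP model via the spectral
    decomposition of K."""
    mask = ~np.isnan(y)
    if mask.sum() < 50:
        logger.warning("mlm: only %d phenotyped individuals", int(mask.sum()))
    ym = y[mask]
    X = np.ones((mask.sum(), 1))
    if Q is not None and Q.size:
        X = np.column_stack([X, Q[mask]])
    Km = bend_psd(K[np.ix_(mask, mask)])
    S, U = np.linalg.eigh(Km)
    S = np.clip(S, 1e-9, None)
    ystar = U.T @ ym
    Xstar = U.T @ X
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        args=(ystar, Xstar, S),
        method="bounded",
    )
    return MLMContext(U, S, float(np.exp(res.x)), ystar, Xstar, mask)


def _gls_snp(
    ctx: MLMContext, xstar: np.ndarray
) -> tuple[float, float, float, float]:
    """GLS Wald test of the SNP term given the fitted context.
    Returns (beta, se, p, pve)."""
    w = ctx.S + ctx.delta
    X0 = ctx.Xstar
    X1 = np.column_stack([X0, xstar])
    sw = np.sqrt(w)
    A0 = X0 / sw[:, None]
    A1 = X1 / sw[:, None]
    yw = ctx.ystar / sw
    b0, rss0 = _ols(A0, yw)
    b1, rss1 = _ols(A1, yw)
    n, p1 = A1.shape
    dof = n - p1
    if dof <= 0 or rss1 <= 0:
        return float("nan"), float("nan"), 1.0, 0.0
    sigma2 = rss1 / dof
    XtX_inv = np.linalg.pinv(A1.T @ A1)
    se = float(np.sqrt(max(XtX_inv[-1, -1] * sigma2, 1e-30)))
    beta = float(b1[-1])
    t = beta / se
    p = float(2.0 * sps.t.sf(abs(t), dof))
    pve = float(max(0.0, 1.0 - rss1 / rss0)) if rss0 > 0 else 0.0
    return beta, se, p, pve


def _ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return coef, float(r @ r)


@dataclass
class AssociationRecord:
    site_index: int
    chrom: str
    pos: int
    trait: str
    timepoint: str
    p: float
    beta: float
    se: float
    pve: float
    a: float = float("nan")
    d: float = float("nan")
    p_additive: float = float("nan")
    p_dominance: float = float("nan")
    effect_class: str = ""


def mlm_scan(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    timepoint: str,
    K: np.ndarray | None = None,
    Q: np.ndarray | None = None,
    sites: np.ndarray | None = None,
) -> list[AssociationRecord]:
    """Association scan of one phenotype set over all (or `sites`) SNPs."""
    if K is None:
        K = estimate_kinship(g)
    if Q is None and g.subpop is not None:
        Q = structure_covariates(g, "labels")
    y = pheno.values_for(trait, timepoint, g.individuals)
    ctx = fit_mlm_context(y, Q, K)
    jdx = np.arange(g.n_sites) if sites is None else np.asarray(sites)
    out = []
    D = g.dosage[ctx.mask][:, jdx]
    D = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    Xrot = ctx.U.T @ D
    for k, j in enumerate(jdx):
        if D[:, k].std() == 0:
            continue
        beta, se, p, pve = _gls_snp(ctx, Xrot[:, k])
        out.append(
            AssociationRecord(
                site_index=int(j),
                chrom=str(g.sites.chrom[j]),
                pos=int(g.sites.pos[j]),
                trait=trait,
                timepoint=timepoint,
                p=p,
                beta=beta,
                se=se,
                pve=pve,
            )
        )
    return out


def genomic_inflation(pvals: np.ndarray) -> float:
    """Lambda_GC: median association chi-square over its null median."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals) & (pvals > 0)]
    chi2 = sps.chi2.isf(pvals, df=1)
    return float(np.median(chi2) / sps.chi2.isf(0.5, df=1))


# ---------------------------------------------------------------------------
# additive / dominance decomposition
# ---------------------------------------------------------------------------


def classify_effect(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    timepoint: str,
    snp: int,
    Q: np.ndarray | None = None,
    alpha: float = EFFECT_ALPHA,
) -> dict:
    """Least-squares-means decomposition at one SNP.

    a = (LSmean(AA) - LSmean(aa))/2; d = LSmean(Aa) - midpoint.
    Additive significant if the homozygote contrast P < alpha; dominant
    significant if the heterozygote-vs-homozygote-mean contrast
    P < alpha.  When any genotype class has < 3 individuals only the
    additive (dosage-regression) test is run, flagged `restricted`.
    """
    y = pheno.values_for(trait, timepoint, g.individuals)
    x = g.dosage[:, snp]
    mask = ~np.isnan(y) & ~np.isnan(x)
    ym, xm = y[mask], x[mask]
    if len(np.unique(xm)) < 2:
        raise ValueError(f"SNP {snp} is monomorphic among phenotyped samples")
    Qm = Q[mask] if Q is not None and Q.size else np.empty((mask.sum(), 0))
    counts = {k: int(np.sum(xm == k)) for k in (0.0, 1.0, 2.0)}
    if min(counts.values()) < 3:
        X = np.column_stack([np.ones(len(ym)), Qm, xm])
        coef, se, pvals, _ = _ols_infer(X, ym)
        return {
            "a": float(coef[-1]),
            "d": float("nan"),
            "se_a": float(se[-1]),
            "se_d": float("nan"),
            "p_additive": float(pvals[-1]),
            "p_dominance": float("nan"),
            "effect_class": "additive" if pvals[-1] < alpha else "none",
            "restricted": True,
        }
    het = (xm == 1.0).astype(float)
    hom2 = (xm == 2.0).astype(float)
    X = np.column_stack([np.ones(len(ym)), Qm, het, hom2])
    coef, se, pvals, cov = _ols_infer(X, ym)
    # contrasts on (.., beta_het, beta_hom2): a = b_hom2/2,
    # d = b_het - b_hom2/2
    p = X.shape[1]
    c_a = np.zeros(p)
    c_a[-1] = 0.5
    c_d = np.zeros(p)
    c_d[-2] = 1.0
    c_d[-1] = -0.5
    dof = len(ym) - p
    res = {}
    for name, c in (("additive", c_a), ("dominance", c_d)):
        est = float(c @ coef)
        sec = float(np.sqrt(max(c @ cov @ c, 1e-30)))
        pv = float(2.0 * sps.t.sf(abs(est / sec), dof))
        res[name] = (est, pv, sec)
    a, p_a, se_a = res["additive"]
    d, p_d, se_d = res["dominance"]
    sig_a, sig_d = p_a < alpha, p_d < alpha
    cls = {
        (True, True): "both",
        (True, False): "additive",
        (False, True): "dominant",
        (False, False): "none",
    }[(sig_a, sig_d)]
    return {
        "a": a,
        "d": d,
        "se_a": se_a,
        "se_d": se_d,
        "p_additive": p_a,
        "p_dominance": p_d,
        "effect_class": cls,
        "restricted": False,
    }


def _ols_infer(X: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = (r @ r) / max(dof, 1)
    cov = np.linalg.pinv(X.T @ X) * sigma2
    se = np.sqrt(np.clip(np.diag(cov), 1e-30, None))
    pvals = 2.0 * sps.t.sf(np.abs(coef / se), max(dof, 1))
    return coef, se, pvals, cov


# ---------------------------------------------------------------------------
# PVE trajectory patterns
# ---------------------------------------------------------------------------


def classify_trajectory(
    pve_by_timepoint: np.ndarray, tol: float = 0.02
) -> str:
    """Rule-based trajectory class of PVE over timepoints.

    Slopes (per normalized time span) are fitted overall and in each
    half; increasing = both halves above +tol, decreasing = both below
    -tol, level = both within +-tol, increase-then-level = first above
    +tol and second within +-tol; anything else (or < 4 timepoints) is
    'unclassified'."""
    v = np.asarray(pve_by_timepoint, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        return "unclassified"
    t = np.linspace(0.0, 1.0, len(v))
    h = len(v) // 2
    s1 = np.polyfit(t[: h + 1], v[: h + 1], 1)[0]
    s2 = np.polyfit(t[h:], v[h:], 1)[0]
    if s1 > tol and s2 > tol:
        return "increasing"
    if s1 < -tol and s2 < -tol:
        return "decreasing"
    if abs(s1) <= tol and abs(s2) <= tol:
        return "level"
    if s1 > tol and abs(s2) <= tol:
        return "increase-then-level"
    return "unclassified"


# ---------------------------------------------------------------------------
# association hotspots and lead-SNP signals
# ---------------------------------------------------------------------------


def find_hotspot_features(
    records: list[AssociationRecord],
    snp_features: dict[int, list[str]],
    p_threshold: float,
    k_min: int = 12,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Features (genes / ncRNAs) repeatedly associated across phenotype
    sets.

    For each feature, count distinct phenotype sets containing >= 1
    SNP association at `p_threshold`.  The permutation null shuffles
    phenotype-set labels over the association events; a feature is a
    hotspot when its count >= k_min AND exceeds the 95th-percentile
    null maximum count."""
    events = [
        (r.site_index, (r.trait, r.timepoint))
        for r in records
        if r.p < p_threshold and snp_features.get(r.site_index)
    ]
    if not events:
        return pd.DataFrame(columns=["feature", "n_sets", "hotspot"])
    snps = [e[0] for e in events]
    sets = [e[1] for e in events]

    def counts_for(set_labels) -> dict[str, int]:
        acc: dict[str, set] = {}
        for s, lab in zip(snps, set_labels):
            for f in snp_features[s]:
                acc.setdefault(f, set()).add(lab)
        return {f: len(v) for f, v in acc.items()}

    obs = counts_for(sets)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(sets))
        null_max[b] = max(counts_for([sets[i] for i in perm]).values())
    cut = np.percentile(null_max, 100 * (1 - alpha))
    rows = [
        (f, c, bool(c >= k_min and c > cut)) for f, c in sorted(obs.items())
    ]
    df = pd.DataFrame(rows, columns=["feature", "n_sets", "hotspot"])
    df.attrs["null_95pct"] = float(cut)
    return df


def lead_snp_clusters(
    records: list[AssociationRecord],
    ld: LDResult,
    r2_cut: float = 0.2,
) -> list[dict]:
    """Greedy unique-signal clustering for one phenotype set.

    Lead = lowest-P significant SNP (ties: smaller genomic coordinate);
    all significant SNPs with r2 >= r2_cut to the lead join its signal;
    repeat on the remainder."""
    lookup = ld.r2_lookup()
    remaining = sorted(records, key=lambda r: (r.p, r.chrom, r.pos))
    signals = []
    while remaining:
        lead = remaining[0]
        members = [lead]
        rest = []
        for r in remaining[1:]:
            r2 = lookup.get((lead.site_index, r.site_index), 0.0)
            (members if r2 >= r2_cut else rest).append(r)
        signals.append(
            {
                "lead": lead,
                "members": members,
                "n_members": len(members),
            }
        )
        remaining = rest
    return signals


def candidate_features_near(
    lead: AssociationRecord,
    feature_intervals: list,
    within_bp: int = 10_000,
) -> list[str]:
    """Feature names within `within_bp` of the lead SNP."""
    out = []
    for iv in feature_intervals:
        if iv.chrom != lead.chrom:
            continue
        pos0 = lead.pos - 1
        if iv.start - within_bp <= pos0 < iv.end + within_bp:
            out.append(iv.name)
    return out
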