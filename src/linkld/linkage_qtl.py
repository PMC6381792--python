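"""Interval-mapping QTL scans on the full-sib linkage map.

The scan is Haley–Knott regression for a two-class pseudo-testcross:
at each grid position the expected QTL genotype score is computed from
the flanking markers via Haldane recombination fractions, and the
phenotype is regressed on that score (plus any cofactor markers).

    LOD = (n/2) * log10(RSS0 / RSS1),    PVE = 1 - 10^(-2*LOD/n)

Genome-wide significance comes from phenotype permutations (the
1 - alpha quantile of the permuted genome-wide maximum LOD).  A
cofactor (multiple-QTL-model style) rescan, 1-LOD support intervals,
co-localisation clustering of QTL across trait x timepoint sets, and a
permutation QTL-hotspot test complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LinkageDataset
from .synthetic_data import haldane_r

logger = logging.getLogger("linkld")

DEFAULT_LOD_CUTOFF = 3.0  # uniform reporting cut-off
COFACTOR_P = 0.02
COFACTOR_WINDOW_CM = 10.0


@dataclass
class QTLPeak:
    lg: str
    cM: float
    lod: float
    pve: float
    ci_lo: float
    ci_hi: float
    trait: str = ""
    timepoint: str = ""
    pve_marginal: float | None = None

    @property
    def support(self) -> tuple[float, float]:
        return (self.ci_lo, self.ci_hi)


@dataclass
class QTLScanResult:
    positions: pd.DataFrame  # lg, cM, lod
    qtls: list[QTLPeak]
    trait: str
    timepoint: str
    n: int
    cofactors: list[str] = field(default_factory=list)
    converged: bool = True

    def lod_profile(self, lg: str) -> pd.DataFrame:
        return self.positions[self.positions["lg"] == lg]


@dataclass
class OverlapRegion:
    lg: str
    cM_lo: float
    cM_hi: float
    peak_lo: float
    peak_hi: float
    members: list[QTLPeak]

    @property
    def coverage(self) -> list[tuple[str, str]]:
        return sorted({(q.trait, q.timepoint) for q in self.members})


@dataclass
class HotspotResult:
    bins: pd.DataFrame  # lg, bin_lo, bin_hi, count
    threshold: float
    hotspots: pd.DataFrame  # rows of `bins` exceeding threshold


# ---------------------------------------------------------------------------
# expected genotype scores
# ---------------------------------------------------------------------------


def _transition(calls: np.ndarray, target: int, r: float) -> np.ndarray:
    """P(observed call -> state `target`) under recombination fraction r;
    missing calls contribute an uninformative 0.5."""
    out = np.where(calls == target, 1.0 - r, r)
    return np.where(np.isnan(calls), 0.5, out)


def expected_scores(
    calls: np.ndarray, marker_cM: np.ndarray, grid_cM: np.ndarray
) -> np.ndarray:
    """Expected P(Q=1 | flanking markers) at each grid position.

    calls: (n_progeny, n_markers) in {0,1,NaN}; marker_cM sorted.
    Returns (n_progeny, n_grid).
    """
    n = calls.shape[0]
    out = np.empty((n, len(grid_cM)))
    for k, p in enumerate(grid_cM):
        il = int(np.searchsorted(marker_cM, p, side="right")) - 1
        ir = int(np.searchsorted(marker_cM, p, side="left"))
        il = max(il, 0)
        ir = min(ir, len(marker_cM) - 1)
        rL = haldane_r(p - marker_cM[il])
        rR = haldane_r(marker_cM[ir] - p)
        a = calls[:, il]
        b = calls[:, ir]
        w1 = _transition(a, 1, rL) * _transition(b, 1, rR)
        w0 = _transition(a, 0, rL) * _transition(b, 0, rR)
        out[:, k] = w1 / (w1 + w0)
    return out


@dataclass
class ScanGrid:
    """Precomputed grid positions and expected-score matrix for a dataset."""

    grid: pd.DataFrame  # lg, cM
    scores: np.ndarray  # (n_progeny, n_positions)
    progeny: list[str]


def build_grid(data: LinkageDataset, step: float = 1.0) -> ScanGrid:
    """Grid = per-LG union of a `step`-spaced lattice and the marker
    positions themselves (so marker-exact tests are possible)."""
    lgs, cms, blocks = [], [], []
    calls = data.calls
    for lg in data.lgs:
        grp = data.lg_markers(lg)
        mpos = grp["cM"].to_numpy(dtype=float)
        lattice = np.arange(mpos[0], mpos[-1] + 1e-9, step)
        pos = np.unique(np.round(np.concatenate([lattice, mpos]), 6))
        sub = calls[grp["marker"]].to_numpy(dtype=float)
        blocks.append(expected_scores(sub, mpos, pos))
        lgs.extend([lg] * len(pos))
        cms.extend(pos.tolist())
    grid = pd.DataFrame({"lg": lgs, "cM": cms})
    return ScanGrid(grid, np.concatenate(blocks, axis=1), list(calls.index))


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _lod_no_cofactors(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Haley-Knott LOD for every score column (no cofactors)."""
    n = len(y)
    yc = y - y.mean()
    ss_y = yc @ yc
    Sc = S - S.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Sc, Sc)
    ok = (ss_x > 1e-12) & (ss_y > 0)
    r2 = np.zeros(S.shape[1])
    cov = yc @ Sc
    r2[ok] = cov[ok] ** 2 / (ss_x[ok] * ss_y)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    return -(n / 2.0) * np.log10(1.0 - r2)


def _residualize(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after OLS projection on Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def interval_scan(
    data: LinkageDataset,
    trait: str,
    timepoint: str,
    cofactors: list[str] | None = None,
    step: float = 1.0,
    grid: ScanGrid | None = None,
) -> QTLScanResult:
    """Haley–Knott interval scan of one phenotype set.

    `cofactors` are marker names used as covariates; a cofactor within
    10 cM of the test position (same LG) is excluded at that position.
    """
    cofactors = list(cofactors or [])
    if grid is None:
        grid = build_grid(data, step)
    y_all = data.phenotypes.values_for(trait, timepoint, grid.progeny)
    mask = ~np.isnan(y_all)
    if mask.sum() < 50:
        logger.warning(
            "interval_scan: only %d progeny with phenotype", int(mask.sum())
        )
    y = y_all[mask]
    S = grid.scores[mask]
    n = len(y)

    if y.std() == 0:
        lod = np.zeros(S.shape[1])
    elif not cofactors:
        lod = _lod_no_cofactors(S, y)
    else:
        mk = data.map.set_index("marker")
        co_lg = mk.loc[cofactors, "lg"].to_numpy()
        co_cm = mk.loc[cofactors, "cM"].to_numpy(dtype=float)
        C = data.calls[cofactors].to_numpy(dtype=float)[mask]
        C = np.where(np.isnan(C), np.nanmean(C, axis=0), C)
        lod = np.empty(S.shape[1])
        glg = grid.grid["lg"].to_numpy()
        gcm = grid.grid["cM"].to_numpy(dtype=float)
        # group positions by identical cofactor-exclusion pattern
        excl = (glg[:, None] == co_lg[None, :]) & (
            np.abs(gcm[:, None] - co_cm[None, :]) < COFACTOR_WINDOW_CM
        )
        keys, inverse = np.unique(excl, axis=0, return_inverse=True)
        for ke in range(len(keys)):
            cols = np.flatnonzero(inverse == ke)
            kept = ~keys[ke]
            Z = np.column_stack([np.ones(n), C[:, kept]])
            ry = _residualize(Z, y[:, None])[:, 0]
            rX = _residualize(Z, S[:, cols])
            ss_y = ry @ ry
            ss_x = np.einsum("ij,ij->j", rX, rX)
            cov = ry @ rX
            ok = (ss_x > 1e-12) & (ss_y > 0)
            r2 = np.zeros(len(cols))
            r2[ok] = cov[ok] ** 2 / (ss_x[ok] * ss_y)
            r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
            lod[cols] = -(n / 2.0) * np.log10(1.0 - r2)

    positions = grid.grid.copy()
    positions["lod"] = lod
    res = QTLScanResult(positions, [], trait, timepoint, n, cofactors)
    res.qtls = find_qtls(res)
    return res


def permutation_threshold(
    data: LinkageDataset,
    trait: str,
    timepoint: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step: float = 1.0,
    grid: ScanGrid | None = None,
) -> float:
    """(1-alpha) quantile of the genome-wide max LOD over phenotype
    permutations (genome-wide error rate alpha)."""
    if n_perm < 100:
        logger.warning("permutation_threshold: n_perm=%d is low", n_perm)
    if grid is None:
        grid = build_grid(data, step)
    rng = np.random.default_rng(seed)
    y_all = data.phenotypes.values_for(trait, timepoint, grid.progeny)
    mask = ~np.isnan(y_all)
    y = y_all[mask]
    S = grid.scores[mask]
    n = len(y)
    Sc = S - S.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", Sc, Sc))
    ok = norm > 1e-9
    Sn = Sc[:, ok] / norm[ok]
    yc = y - y.mean()
    ys = yc / np.sqrt(yc @ yc)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(ys)
    r = Sn.T @ perms  # (positions, n_perm)
    r2max = np.clip(np.max(r**2, axis=0), 0.0, 1.0 - 1e-12)
    max_lod = -(n / 2.0) * np.log10(1.0 - r2max)
    return float(np.quantile(max_lod, 1.0 - alpha))


# ---------------------------------------------------------------------------
# peaks, support intervals, MQM
# ---------------------------------------------------------------------------


def support_interval(
    scan: QTLScanResult, lg: str, peak_cM: float, drop: float = 1.0
) -> tuple[float, float]:
    """Maximal interval around the peak where LOD >= peak LOD - drop,
    clipped to the LG ends."""
    prof = scan.lod_profile(lg)
    cm = prof["cM"].to_numpy(dtype=float)
    lod = prof["lod"].to_numpy(dtype=float)
    k = int(np.argmin(np.abs(cm - peak_cM)))
    cut = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = k
    while hi < len(cm) - 1 and lod[hi + 1] >= cut:
        hi += 1
    return float(cm[lo]), float(cm[hi])


def find_qtls(
    scan: QTLScanResult,
    threshold: float = DEFAULT_LOD_CUTOFF,
    sep_drop: float = 1.0,
) -> list[QTLPeak]:
    """Extract QTL peaks above `threshold` with 1-LOD support intervals.

    Local maxima above the threshold count as distinct QTL only when the
    profile between two maxima dips at least `sep_drop` LOD below the
    smaller of the two (a real valley); shoulders of one peak are not
    reported twice."""
    n = scan.n
    out: list[QTLPeak] = []
    for lg in pd.unique(scan.positions["lg"]):
        prof = scan.lod_profile(lg)
        cm = prof["cM"].to_numpy(dtype=float)
        lod = prof["lod"].to_numpy(dtype=float)
        m = len(lod)
        cand = [
            k
            for k in range(m)
            if lod[k] >= threshold
            and (k == 0 or lod[k] >= lod[k - 1])
            and (k == m - 1 or lod[k] >= lod[k + 1])
        ]
        accepted: list[int] = []
        for k in sorted(cand, key=lambda i: -lod[i]):
            ok = True
            for j in accepted:
                lo_i, hi_i = min(k, j), max(k, j)
                valley = lod[lo_i : hi_i + 1].min()
                if valley > min(lod[k], lod[j]) - sep_drop:
                    ok = False
                    break
            if ok:
                accepted.append(k)
        for k in accepted:
            lo, hi = support_interval(scan, lg, cm[k])
            pve = 1.0 - 10.0 ** (-2.0 * lod[k] / n)
            out.append(
                QTLPeak(
                    lg=lg,
                    cM=float(cm[k]),
                    lod=float(lod[k]),
                    pve=float(pve),
                    ci_lo=lo,
                    ci_hi=hi,
                    trait=scan.trait,
                    timepoint=scan.timepoint,
                )
            )
    return sorted(out, key=lambda q: (q.lg, q.cM))


def _nearest_marker(data: LinkageDataset, lg: str, cM: float) -> str:
    grp = data.lg_markers(lg)
    k = int(np.argmin(np.abs(grp["cM"].to_numpy(dtype=float) - cM)))
    return str(grp["marker"].iloc[k])


def mqm_scan(
    data: LinkageDataset,
    trait: str,
    timepoint: str,
    threshold: float = DEFAULT_LOD_CUTOFF,
    max_iter: int = 10,
    step: float = 1.0,
    grid: ScanGrid | None = None,
) -> QTLScanResult:
    """Cofactor-assisted multiple-QTL rescan.

    Iteratively: scan, take the marker nearest each peak as a candidate
    cofactor, retain candidates with partial-regression P < 0.02, rescan
    with the retained set, until the cofactor set is stable (or
    `max_iter` reached, in which case the result is flagged)."""
    if grid is None:
        grid = build_grid(data, step)
    cofactors: list[str] = []
    converged = False
    scan = interval_scan(data, trait, timepoint, step=step, grid=grid)
    marginal = {(_q.lg, round(_q.cM, 3)): _q.pve for _q in scan.qtls}
    for _ in range(max_iter):
        peaks = find_qtls(scan, threshold)
        candidates = sorted(
            {_nearest_marker(data, q.lg, q.cM) for q in peaks} | set(cofactors)
        )
        kept = _select_cofactors(data, trait, timepoint, candidates)
        if set(kept) == set(cofactors):
            converged = True
            break
        cofactors = kept
        scan = interval_scan(
            data, trait, timepoint, cofactors=cofactors, step=step, grid=grid
        )
    if not converged:
        logger.warning("mqm_scan: cofactor set did not stabilise")
    scan.converged = converged
    scan.qtls = find_qtls(scan, threshold)
    base = interval_scan(data, trait, timepoint, step=step, grid=grid)
    prof = {
        lg: base.lod_profile(lg) for lg in pd.unique(base.positions["lg"])
    }
    for q in scan.qtls:
        p = prof[q.lg]
        k = int(np.argmin(np.abs(p["cM"].to_numpy(dtype=float) - q.cM)))
        lod_m = float(p["lod"].to_numpy()[k])
        q.pve_marginal = 1.0 - 10.0 ** (-2.0 * lod_m / scan.n)
    return scan


def _select_cofactors(
    data: LinkageDataset, trait: str, timepoint: str, candidates: list[str]
) -> list[str]:
    """Joint regression on candidate markers; keep P < 0.02 terms."""
    if not candidates:
        return []
    y_all = data.phenotypes.values_for(
        trait, timepoint, list(data.calls.index)
    )
    mask = ~np.isnan(y_all)
    y = y_all[mask]
    C = data.calls[candidates].to_numpy(dtype=float)[mask]
    C = np.where(np.isnan(C), np.nanmean(C, axis=0), C)
    X = np.column_stack([np.ones(len(y)), C])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - rank
    if dof <= 0:
        return candidates
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 1e-30, None))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return [m for m, p in zip(candidates, pvals[1:]) if p < COFACTOR_P]


# ---------------------------------------------------------------------------
# co-localisation and hotspots
# ---------------------------------------------------------------------------


def cluster_colocalized(
    qtls: list[QTLPeak], max_peak_gap_cM: float = 1.0
) -> list[OverlapRegion]:
    """Single-linkage clustering of QTL across trait x timepoint sets:
    two QTL join when their support intervals overlap AND their peaks
    are less than `max_peak_gap_cM` apart (same LG)."""
    if not qtls:
        return []
    parent = list(range(len(qtls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(qtls)):
        for j in range(i + 1, len(qtls)):
            a, b = qtls[i], qtls[j]
            if a.lg != b.lg:
                continue
            if abs(a.cM - b.cM) >= max_peak_gap_cM:
                continue
            if a.ci_lo <= b.ci_hi and b.ci_lo <= a.ci_hi:
                union(i, j)
    groups: dict[int, list[QTLPeak]] = {}
    for i, q in enumerate(qtls):
        groups.setdefault(find(i), []).append(q)
    out = []
    for members in groups.values():
        out.append(
            OverlapRegion(
                lg=members[0].lg,
                cM_lo=min(q.ci_lo for q in members),
                cM_hi=max(q.ci_hi for q in members),
                peak_lo=min(q.cM for q in members),
                peak_hi=max(q.cM for q in members),
                members=sorted(members, key=lambda q: q.cM),
            )
        )
    return sorted(out, key=lambda r: (r.lg, r.cM_lo))


def hotspot_test(
    qtls: list[QTLPeak],
    lg_lengths: dict[str, float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    bin_cM: float = 1.0,
    seed: int = 0,
    null: str = "max",
) -> HotspotResult:
    """Permutation test for QTL hotspots.

    Peaks are binned per `bin_cM` interval; the null redistributes all
    peaks uniformly over the map `n_perm` times.  With ``null="max"``
    (default, FWER-controlling) the threshold is the 95th percentile of
    the genome-wide maximum per-bin count; ``null="per_bin"`` pools all
    per-bin null counts instead.  Bins with observed count strictly
    greater than the threshold are hotspots.
    """
    rows = []
    for lg, length in lg_lengths.items():
        edges = np.arange(0.0, length + bin_cM, bin_cM)
        for lo, hi in zip(edges[:-1], edges[1:]):
            rows.append((lg, lo, hi))
    bins = pd.DataFrame(rows, columns=["lg", "bin_lo", "bin_hi"])
    counts = np.zeros(len(bins), dtype=int)
    widths = (bins["bin_hi"] - bins["bin_lo"]).to_numpy(dtype=float)
    for q in qtls:
        hit = bins[
            (bins["lg"] == q.lg)
            & (bins["bin_lo"] <= q.cM)
            & (q.cM < bins["bin_hi"])
        ]
        if len(hit):
            counts[hit.index[0]] += 1
    bins["count"] = counts

    n_peaks = len(qtls)
    if n_peaks <= 1:
        return HotspotResult(bins, float("inf"), bins.iloc[0:0])
    rng = np.random.default_rng(seed)
    probs = widths / widths.sum()
    null_counts = rng.multinomial(n_peaks, probs, size=n_perm)
    if null == "max":
        stat = null_counts.max(axis=1)
        threshold = float(np.percentile(stat, 100 * (1 - alpha)))
    elif null == "per_bin":
        threshold = float(np.percentile(null_counts.ravel(), 100 * (1 - alpha)))
    else:
        raise ValueError("null must be 'max' or 'per_bin'")
    hot = bins[bins["count"] > threshold]
    return HotspotResult(bins, threshold, hot)
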