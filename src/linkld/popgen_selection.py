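"""Windowed diversity / differentiation statistics and selection scans.

Statistics are computed in fixed non-overlapping 250-bp windows over the
SHRs (plus 10-kb flanks for the selection scan):

* pi — Nei's per-bp nucleotide diversity; per site 2c(n-c)/(n(n-1)),
  summed over sites and divided by the window length in bp (monomorphic
  positions count toward the denominator);
* theta_w — Watterson's estimator, (S/a1)/length;
* Tajima's D — (pi_total - S/a1)/sqrt(e1*S + e2*S(S-1)) with the
  Tajima (1989) constants; undefined (NaN), not zero, when S = 0;
* Fst — Weir & Cockerham (1984) variance components, windowed by
  ratio of sums; negative values reported raw and flagged;
* ROD — reduction of diversity, 1 - pi_obj/pi_ref.

Haplotype counts are taken as 2 x non-missing diploids per site
(no phasing); missing genotypes are never imputed here.

The selection scan flags windows jointly in the top q of Fst and the
top q of diversity reduction (log pi_ref/pi_obj) for a subpopulation
pair, merges adjacent flagged windows into candidate regions, and
confirms regions by a one-sided rank-sum test for lower Tajima's D in
the objective population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import GenomicInterval, GenotypeMatrix

logger = logging.getLogger("linkld")

WINDOW_BP = 250
SCAN_FLANK_BP = 10_000


# ---------------------------------------------------------------------------
# Tajima constants
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) a1..e2 for a sample of n haplotypes."""
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites, haplotype count and the summed
    (per-window, not per-bp) pairwise diversity.  NaN when S = 0."""
    if S == 0:
        return float("nan")
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 haplotypes")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_total - S / k["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------


def _site_counts(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, haplotype count) per site, complete-case."""
    nm = (~np.isnan(dos)).sum(axis=0)
    c = np.nansum(dos, axis=0)
    return c, 2 * nm


def per_site_pi(dos: np.ndarray) -> np.ndarray:
    """Nei's unbiased per-site heterozygosity 2c(n-c)/(n(n-1))."""
    c, n = _site_counts(dos)
    out = np.zeros(dos.shape[1])
    ok = n >= 2
    out[ok] = 2.0 * c[ok] * (n[ok] - c[ok]) / (n[ok] * (n[ok] - 1.0))
    return out


def rod_statistic(pi_obj: float, pi_ref: float) -> float:
    """Reduction of diversity, 1 - pi_obj/pi_ref; NaN when pi_ref = 0."""
    if pi_ref <= 0 or np.isnan(pi_ref):
        return float("nan")
    return 1.0 - pi_obj / pi_ref


def weir_cockerham_components(
    dosA: np.ndarray, dosB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components (a, b, c)
    for two subpopulations of diploids (r = 2)."""
    comps = []
    for dos in (dosA, dosB):
        nm = (~np.isnan(dos)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(dos, axis=0) / (2.0 * nm)
            h = np.nansum(dos == 1.0, axis=0) / nm
        comps.append((nm, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    ok = (n1 >= 2) & (n2 >= 2) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~ok] = np.nan
    return a, b, c


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(
    intervals: list[GenomicInterval],
    size: int = WINDOW_BP,
    flank: int = 0,
) -> list[GenomicInterval]:
    """Tile each interval (optionally extended by `flank` bp each side)
    with non-overlapping `size`-bp windows."""
    out = []
    for iv in intervals:
        lo = max(0, iv.start - flank)
        hi = iv.end + flank
        for s in range(lo, hi, size):
            out.append(GenomicInterval(iv.chrom, s, min(s + size, hi)))
    return out


def _sites_in(g: GenotypeMatrix, w: GenomicInterval) -> np.ndarray:
    pos0 = g.sites["pos"].to_numpy() - 1  # 0-based
    return np.flatnonzero(
        (g.sites["chrom"].to_numpy() == w.chrom)
        & (pos0 >= w.start)
        & (pos0 < w.end)
    )


def window_diversity(
    g: GenotypeMatrix,
    windows: list[GenomicInterval],
    subpop: str | np.ndarray,
) -> pd.DataFrame:
    """Per-window pi (per bp), theta_w (per bp), S and Tajima's D for
    one subpopulation.  Windows with no usable site get NaN stats."""
    if isinstance(subpop, str):
        idx = g.subpop_indices()[subpop]
    else:
        idx = np.asarray(subpop)
    rows = []
    for w in windows:
        jdx = _sites_in(g, w)
        L = len(w)
        if len(jdx) == 0:
            rows.append((w.chrom, w.start, w.end, 0.0, 0.0, 0, float("nan")))
            continue
        dos = g.dosage[np.ix_(idx, jdx)]
        c, n = _site_counts(dos)
        usable = n >= 2
        if not usable.any():
            rows.append(
                (w.chrom, w.start, w.end, float("nan"), float("nan"), 0,
                 float("nan"))
            )
            continue
        pis = per_site_pi(dos)
        seg = usable & (c > 0) & (c < n)
        S = int(seg.sum())
        pi_total = float(pis.sum())
        # single n for Watterson/D: modal haplotype count among usable sites
        n_eff = int(np.median(n[usable]))
        k = tajima_constants(max(n_eff, 2))
        theta = (S / k["a1"]) / L
        D = tajimas_d(S, n_eff, pi_total) if (S > 0 and n_eff >= 4) else float("nan")
        rows.append((w.chrom, w.start, w.end, pi_total / L, theta, S, D))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pi", "theta_w", "S", "D"]
    )


def weir_cockerham_fst(
    g: GenotypeMatrix,
    windows: list[GenomicInterval],
    subpopA: str,
    subpopB: str,
) -> pd.DataFrame:
    """Windowed W&C Fst (ratio of sums).  Monomorphic windows -> NaN;
    negative estimates are reported raw with a flag."""
    sp = g.subpop_indices()
    ia, ib = sp[subpopA], sp[subpopB]
    rows = []
    for w in windows:
        jdx = _sites_in(g, w)
        if len(jdx) == 0:
            rows.append((w.chrom, w.start, w.end, float("nan"), False))
            continue
        a, b, c = weir_cockerham_components(
            g.dosage[np.ix_(ia, jdx)], g.dosage[np.ix_(ib, jdx)]
        )
        num = np.nansum(a)
        den = np.nansum(a + b + c)
        if den <= 0 or np.all(np.isnan(a)):
            rows.append((w.chrom, w.start, w.end, float("nan"), False))
        else:
            fst = float(num / den)
            rows.append((w.chrom, w.start, w.end, fst, fst < 0))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fst", "negative_flag"]
    )


def window_stats(
    g: GenotypeMatrix,
    windows: list[GenomicInterval],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Full per-window table: diversity per subpop plus pairwise
    Fst / log-ratio / ROD for each (objective, reference) pair."""
    labels = list(g.subpop_indices())
    base = None
    for lab in labels:
        d = window_diversity(g, windows, lab)
        d = d.rename(
            columns={k: f"{k}_{lab}" for k in ("pi", "theta_w", "S", "D")}
        )
        base = d if base is None else base.merge(
            d, on=["chrom", "start", "end"]
        )
    pairs = pairs or [
        (a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]
    ]
    for obj, ref in pairs:
        f = weir_cockerham_fst(g, windows, obj, ref)
        base[f"fst_{obj}_{ref}"] = f["fst"].values
        with np.errstate(divide="ignore", invalid="ignore"):
            base[f"logratio_{obj}_{ref}"] = np.log(
                base[f"pi_{obj}"] / base[f"pi_{ref}"]
            )
        base[f"rod_{obj}_{ref}"] = [
            rod_statistic(po, pr)
            for po, pr in zip(base[f"pi_{obj}"], base[f"pi_{ref}"])
        ]
    return base


# ---------------------------------------------------------------------------
# selection scan
# ---------------------------------------------------------------------------


def joint_outlier_windows(
    stats: pd.DataFrame, pair: tuple[str, str], q: float = 0.01
) -> pd.Series:
    """Boolean flag per window: in the top q of Fst AND the top q of
    diversity reduction (most negative log(pi_obj/pi_ref)) for the pair."""
    obj, ref = pair
    fst = stats[f"fst_{obj}_{ref}"]
    lr = stats[f"logratio_{obj}_{ref}"]
    # pi_obj = 0 (lr = -inf) is the strongest possible diversity
    # reduction and stays in the scan; pi_ref = 0 leaves the ratio
    # uninformative and the window undefined
    defined = fst.notna() & (stats[f"pi_{ref}"] > 0) & stats[f"pi_{obj}"].notna()
    lr = lr.clip(lower=-1e30)  # finite sentinel for pi_obj = 0
    if defined.sum() < 100:
        logger.warning(
            "joint_outlier_windows: only %d defined windows; quantiles "
            "may be unstable", int(defined.sum()),
        )
    if q >= 1.0:
        return defined
    fst_cut = np.quantile(fst[defined], 1.0 - q)
    lr_cut = np.quantile(lr[defined], q)
    return defined & (fst >= fst_cut) & (lr <= lr_cut)


@dataclass
class SelectiveRegion:
    interval: GenomicInterval
    pair: tuple[str, str]
    window_index: list[int]
    mean_fst: float
    mean_logratio: float
    tajima_confirmed: bool | None = None  # None = not evaluable
    tajima_p: float = float("nan")
    features: list[str] = field(default_factory=list)


def merge_regions(
    stats: pd.DataFrame,
    flags: pd.Series,
    pair: tuple[str, str],
    max_gap: int = 1,
) -> list[SelectiveRegion]:
    """Merge adjacent flagged windows (gap <= max_gap windows) into
    candidate selective regions."""
    obj, ref = pair
    flagged = stats[flags].sort_values(["chrom", "start"])
    out: list[SelectiveRegion] = []
    cur: list[int] = []

    def emit(idx: list[int]) -> None:
        sub = stats.loc[idx]
        out.append(
            SelectiveRegion(
                interval=GenomicInterval(
                    str(sub["chrom"].iloc[0]),
                    int(sub["start"].min()),
                    int(sub["end"].max()),
                ),
                pair=pair,
                window_index=list(idx),
                mean_fst=float(sub[f"fst_{obj}_{ref}"].mean()),
                mean_logratio=float(sub[f"logratio_{obj}_{ref}"].mean()),
            )
        )

    prev = None
    for idx, row in flagged.iterrows():
        if prev is not None and (
            row["chrom"] != prev["chrom"]
            or (row["start"] - prev["end"]) > max_gap * WINDOW_BP
        ):
            emit(cur)
            cur = []
        cur.append(idx)
        prev = row
    if cur:
        emit(cur)
    return out


def confirm_with_tajima(
    regions: list[SelectiveRegion],
    stats: pd.DataFrame,
    pair: tuple[str, str],
    alpha: float = 0.05,
) -> list[SelectiveRegion]:
    """One-sided rank-sum comparison of window Tajima's D (objective vs
    reference) per region; confirmed if P < alpha and mean D_obj <
    mean D_ref.  Regions with < 3 defined windows are 'not evaluable'
    (confirmed=None)."""
    obj, ref = pair
    for reg in regions:
        sub = stats.loc[reg.window_index]
        d_obj = sub[f"D_{obj}"].dropna()
        d_ref = sub[f"D_{ref}"].dropna()
        if len(d_obj) < 3 or len(d_ref) < 3:
            reg.tajima_confirmed = None
            reg.tajima_p = float("nan")
            continue
        stat = sps.mannwhitneyu(d_obj, d_ref, alternative="less")
        reg.tajima_p = float(stat.pvalue)
        reg.tajima_confirmed = bool(
            stat.pvalue < alpha and d_obj.mean() < d_ref.mean()
        )
    return regions


def selection_scan(
    g: GenotypeMatrix,
    shrs: list[GenomicInterval],
    pair: tuple[str, str],
    q: float = 0.01,
    flank: int = SCAN_FLANK_BP,
    max_gap: int = 1,
) -> tuple[pd.DataFrame, list[SelectiveRegion]]:
    """End-to-end scan for one (objective, reference) pair over the
    SHRs plus `flank` bp on each side."""
    windows = make_windows(shrs, WINDOW_BP, flank)
    stats = window_stats(g, windows, pairs=[pair])
    flags = joint_outlier_windows(stats, pair, q)
    regions = merge_regions(stats, flags, pair, max_gap)
    regions = confirm_with_tajima(regions, stats, pair)
    stats["flagged"] = flags
    return stats, regions


# ---------------------------------------------------------------------------
# fixation classes
# ---------------------------------------------------------------------------


def classify_fixation(g: GenotypeMatrix, snps: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP fixation class across subpopulations.

    completely_fixed: MAF = 0 in >= 1 subpopulation;
    nearly_fixed: 0 < MAF < 0.05 in >= 1 subpopulation;
    segregating: otherwise.  Subpops with all calls missing at a SNP are
    excluded and flagged."""
    sp = g.subpop_indices()
    jdx = np.arange(g.n_sites) if snps is None else np.asarray(snps)
    rows = []
    for j in jdx:
        mafs = {}
        excluded = []
        for lab, idx in sp.items():
            d = g.dosage[idx, j]
            nm = (~np.isnan(d)).sum()
            if nm == 0:
                excluded.append(lab)
                continue
            p = np.nansum(d) / (2.0 * nm)
            mafs[lab] = min(p, 1 - p)
        vals = np.array(list(mafs.values()))
        if len(vals) == 0:
            cls = "unclassifiable"
        elif np.any(vals == 0.0):
            cls = "completely_fixed"
        elif np.any(vals < 0.05):
            cls = "nearly_fixed"
        else:
            cls = "segregating"
        rows.append(
            (
                str(g.sites.chrom[j]),
                int(g.sites.pos[j]),
                cls,
                ";".join(f"{k}={v:.4f}" for k, v in mafs.items()),
                ";".join(excluded),
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "fixation_class", "subpop_maf", "excluded"]
    )
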