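"""Two-locus epistasis with an orthogonal Kempthorne-style partition.

For a SNP pair the genotypic value is modelled on the 3x3 genotype
classes.  Per locus, additive and dominance contrast scores are built
orthogonal to the mean under the *observed* genotype frequencies (the
extended-model behaviour, robust to Hardy–Weinberg and linkage
departures; classical equal-frequency contrasts are available for
oracle checks).  The four interaction contrasts (a x a, a x d, d x a,
d x d) are products of the per-locus scores, sequentially
orthogonalized against the main-effect space; their sums of squares
add up to the 4-df interaction sum of squares, which provides the
overall epistasis F-test.  The contribution of a pair is
c = SS_interaction / SS_total, bounded in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("linkld")

MIN_CLASSES = 5
MIN_PER_CLASS = 2


class SkippedPair(Exception):
    """Pair cannot be tested (too few populated classes / singular)."""


@dataclass
class EpistasisRecord:
    site_a: int
    site_b: int
    trait: str
    timepoint: str
    class_counts: np.ndarray  # 3x3
    class_means: np.ndarray  # 3x3 (NaN for empty)
    ss_int: float
    df_int: int
    p_interaction: float
    components: dict  # name -> (SS, P) for axa/axd/dxa/dxd
    contribution: float  # c = SS_int / SS_total


def _locus_scores(
    x: np.ndarray, weighting: str = "observed"
) -> tuple[np.ndarray, np.ndarray]:
    """Additive and dominance contrast scores per genotype {0,1,2},
    orthogonal to the intercept (and to each other) under the observed
    (or equal) genotype frequencies."""
    if weighting == "equal":
        f = np.full(3, 1.0 / 3.0)
    else:
        f = np.array([(x == k).mean() for k in (0.0, 1.0, 2.0)])
    levels = np.array([0.0, 1.0, 2.0])
    wa = levels - f @ levels
    h = (levels == 1.0).astype(float)
    # Gram-Schmidt of h against {1, wa} under f-weighted inner product
    wd = h - f @ h
    denom = f @ wa**2
    if denom > 1e-12:
        wd = wd - (f @ (wd * wa)) / denom * wa
    za = wa[x.astype(int)]
    zd = wd[x.astype(int)]
    return za, zd


def two_locus_partition(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    timepoint: str,
    snp_a: int,
    snp_b: int,
    weighting: str = "observed",
) -> EpistasisRecord:
    """Fixed-effects two-way partition at one SNP pair.

    Raises SkippedPair when fewer than 5 of the 9 genotype classes have
    >= 2 individuals, ValueError when either SNP is monomorphic."""
    y = pheno.values_for(trait, timepoint, g.individuals)
    xa = g.dosage[:, snp_a]
    xb = g.dosage[:, snp_b]
    mask = ~np.isnan(y) & ~np.isnan(xa) & ~np.isnan(xb)
    y, xa, xb = y[mask], xa[mask], xb[mask]
    if len(np.unique(xa)) < 2 or len(np.unique(xb)) < 2:
        raise ValueError("monomorphic SNP in pair")

    counts = np.zeros((3, 3), dtype=int)
    means = np.full((3, 3), np.nan)
    for i in range(3):
        for j in range(3):
            sel = (xa == i) & (xb == j)
            counts[i, j] = int(sel.sum())
            if counts[i, j]:
                means[i, j] = float(y[sel].mean())
    if int((counts >= MIN_PER_CLASS).sum()) < MIN_CLASSES:
        raise SkippedPair(
            f"only {(counts >= MIN_PER_CLASS).sum()} of 9 classes have "
            f">= {MIN_PER_CLASS} individuals"
        )

    zaA, zdA = _locus_scores(xa, weighting)
    zaB, zdB = _locus_scores(xb, weighting)
    n = len(y)
    one = np.ones(n)
    M = np.column_stack([one, zaA, zdA, zaB, zdB])
    inter_cols = {
        "axa": zaA * zaB,
        "axd": zaA * zdB,
        "dxa": zdA * zaB,
        "dxd": zdA * zdB,
    }
    T = np.column_stack(list(inter_cols.values()))
    full = np.column_stack([M, T])

    _, rss_main = _lstsq_rss(M, y)
    _, rss_full = _lstsq_rss(full, y)
    rank_main = np.linalg.matrix_rank(M)
    rank_full = np.linalg.matrix_rank(full)
    df_int = int(rank_full - rank_main)
    ss_int = max(0.0, rss_main - rss_full)
    dof_err = n - rank_full
    if df_int == 0 or dof_err <= 0:
        raise SkippedPair("singular design: no estimable interaction terms")
    F = (ss_int / df_int) / (rss_full / dof_err)
    p_int = float(sps.f.sf(F, df_int, dof_err))

    # sequential orthogonalization of the interaction columns against the
    # main-effect space (and each other) in data inner product
    components: dict[str, tuple[float, float]] = {}
    basis = _orth_basis(M)
    mse = rss_full / dof_err
    for name, col in inter_cols.items():
        res = col - basis @ (basis.T @ col)
        nrm2 = res @ res
        if nrm2 < 1e-12:
            components[name] = (0.0, float("nan"))
            continue
        proj = res @ y
        ss_c = proj**2 / nrm2
        Fc = ss_c / mse
        components[name] = (float(ss_c), float(sps.f.sf(Fc, 1, dof_err)))
        basis = np.column_stack([basis, res / np.sqrt(nrm2)])

    ss_total = float(((y - y.mean()) ** 2).sum())
    c = ss_int / ss_total if ss_total > 0 else 0.0
    return EpistasisRecord(
        site_a=snp_a,
        site_b=snp_b,
        trait=trait,
        timepoint=timepoint,
        class_counts=counts,
        class_means=means,
        ss_int=float(ss_int),
        df_int=df_int,
        p_interaction=p_int,
        components=components,
        contribution=float(min(max(c, 0.0), 1.0)),
    )


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return coef, float(r @ r)


def _orth_basis(M: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def epistasis_scan(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    timepoint: str,
    candidates: np.ndarray | None = None,
    alpha: float = 0.001,
    weighting: str = "observed",
    max_pairs: int | None = None,
) -> tuple[list[EpistasisRecord], dict]:
    """Test all unordered candidate SNP pairs; keep interaction
    P < alpha.  Returns (records, log) where log counts skipped pairs."""
    jdx = np.arange(g.n_sites) if candidates is None else np.asarray(candidates)
    records = []
    skipped = 0
    tested = 0
    for ai in range(len(jdx)):
        for bi in range(ai + 1, len(jdx)):
            if max_pairs is not None and tested >= max_pairs:
                break
            try:
                rec = two_locus_partition(
                    g, pheno, trait, timepoint, int(jdx[ai]), int(jdx[bi]),
                    weighting=weighting,
                )
                tested += 1
            except (SkippedPair, ValueError):
                skipped += 1
                continue
            if rec.p_interaction < alpha:
                records.append(rec)
    return records, {"tested": tested, "skipped": skipped}


def records_frame(records: list[EpistasisRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "site_a": r.site_a,
            "site_b": r.site_b,
            "trait": r.trait,
            "timepoint": r.timepoint,
            "ss_int": r.ss_int,
            "p_interaction": r.p_interaction,
            "contribution": r.contribution,
        }
        for name, (ss, p) in r.components.items():
            row[f"ss_{name}"] = ss
            row[f"p_{name}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
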