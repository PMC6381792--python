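"""Pairwise LD (composite r-squared), high-LD blocks and decay fitting.

r2 is the squared Pearson correlation of diploid dosage vectors
(composite LD; phase-free, monotone with haplotype r2 under HWE).
Permutation P-values use shared individual-label permutations with the
plus-one correction.  Blocks are maximal runs of consecutive sites
whose every within-run pair satisfies r2 >= 0.75 and P <= 1e-3 (the
block criterion itself, applied to runs).  Decay is fitted with the
Hill & Weir (1988) drift expectation

    E[r2] = [(10+C)/((2+C)(11+C))] *
            [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]

with C = rho * distance and n = number of sampled chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .data_model import GenomicInterval, GenotypeMatrix

logger = logging.getLogger("linkld")

MIN_PAIR_N = 10
BLOCK_R2 = 0.75
BLOCK_P = 1e-3


@dataclass
class LDResult:
    pairs: pd.DataFrame  # site_a, site_b, pos_a, pos_b, dist_bp, r2, p
    site_index: np.ndarray  # site indices (into the GenotypeMatrix) used
    n: int  # individuals
    blocks: list[GenomicInterval] = field(default_factory=list)
    block_members: list[list[int]] = field(default_factory=list)
    decay: dict | None = None

    def r2_lookup(self) -> dict[tuple[int, int], float]:
        out = {}
        for row in self.pairs.itertuples(index=False):
            key = (int(row.site_a), int(row.site_b))
            out[key] = row.r2
            out[key[::-1]] = row.r2
        return out


def hill_weir_expectation(C: np.ndarray, n: int) -> np.ndarray:
    """Drift expectation of r2 at scaled recombination C for sample of
    n chromosomes."""
    C = np.asarray(C, dtype=float)
    left = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    right = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return left * right


def pairwise_r2(
    g: GenotypeMatrix,
    shr: GenomicInterval | None = None,
    n_perm: int = 1000,
    min_maf: float = 0.05,
    seed: int = 0,
    min_n: int = MIN_PAIR_N,
) -> LDResult:
    """All pairwise composite r2 within one SHR (or the whole matrix).

    Observed r2 uses complete-case individuals per pair; pairs with
    fewer than 10 complete cases are skipped.  Permutation P-values are
    computed from shared label permutations on mean-imputed dosages
    (plus-one corrected).
    """
    if shr is not None:
        pos0 = g.sites["pos"].to_numpy() - 1
        jdx = np.flatnonzero(
            (g.sites["chrom"].to_numpy() == shr.chrom)
            & (pos0 >= shr.start)
            & (pos0 < shr.end)
        )
    else:
        jdx = np.arange(g.n_sites)
    maf = g.maf()
    jdx = jdx[maf[jdx] >= min_maf]
    m = len(jdx)
    D = g.dosage[:, jdx]
    n = D.shape[0]
    pos = g.sites["pos"].to_numpy()[jdx]

    # observed r2 with complete-case handling
    r2 = np.full((m, m), np.nan)
    counts = np.zeros((m, m), dtype=int)
    has = ~np.isnan(D)
    if has.all():
        Dc = D - D.mean(axis=0)
        norm = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
        ok = norm > 1e-12
        Dn = np.zeros_like(Dc)
        Dn[:, ok] = Dc[:, ok] / norm[ok]
        r2 = (Dn.T @ Dn) ** 2
        counts[:] = n
    else:
        for a in range(m):
            for b in range(a + 1, m):
                cc = has[:, a] & has[:, b]
                counts[a, b] = counts[b, a] = int(cc.sum())
                if counts[a, b] < min_n:
                    continue
                x, y = D[cc, a], D[cc, b]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                r2[a, b] = r2[b, a] = r * r

    # permutation P via shared permutations on imputed dosages
    rng = np.random.default_rng(seed)
    Di = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    Dc = Di - Di.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
    ok = norm > 1e-12
    Dn = np.zeros_like(Dc)
    Dn[:, ok] = Dc[:, ok] / norm[ok]
    exceed = np.zeros((m, m), dtype=int)
    obs = np.nan_to_num(r2, nan=2.0)  # NaN pairs never "exceeded"
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        r2p = (Dn[perm].T @ Dn) ** 2
        exceed += r2p >= obs - 1e-12
    pmat = (exceed + 1.0) / (n_perm + 1.0)

    rows = []
    for a in range(m):
        for b in range(a + 1, m):
            if counts[a, b] < min_n or np.isnan(r2[a, b]):
                continue
            rows.append(
                (
                    int(jdx[a]),
                    int(jdx[b]),
                    int(pos[a]),
                    int(pos[b]),
                    abs(int(pos[b]) - int(pos[a])),
                    float(r2[a, b]),
                    float(pmat[a, b]),
                )
            )
    pairs = pd.DataFrame(
        rows,
        columns=["site_a", "site_b", "pos_a", "pos_b", "dist_bp", "r2", "p"],
    )
    return LDResult(pairs=pairs, site_index=jdx, n=n)


def detect_blocks(
    ld: LDResult,
    g: GenotypeMatrix,
    r2_min: float = BLOCK_R2,
    p_max: float = BLOCK_P,
) -> LDResult:
    """Maximal runs of consecutive (position-ordered) sites where every
    within-run pair has r2 >= r2_min and P <= p_max; runs of >= 2 sites
    become blocks with their bp span."""
    jdx = ld.site_index
    order = np.argsort(g.sites["pos"].to_numpy()[jdx], kind="stable")
    sidx = jdx[order]
    pos = g.sites["pos"].to_numpy()[sidx]
    chrom_arr = g.sites["chrom"].to_numpy()[sidx]
    qual: dict[tuple[int, int], bool] = {}
    for row in ld.pairs.itertuples(index=False):
        good = row.r2 >= r2_min and row.p <= p_max
        qual[(int(row.site_a), int(row.site_b))] = good
        qual[(int(row.site_b), int(row.site_a))] = good

    m = len(sidx)
    blocks, members = [], []
    last_end = -1
    for i in range(m):
        e = i
        while e + 1 < m and chrom_arr[e + 1] == chrom_arr[i]:
            cand = e + 1
            if all(
                qual.get((int(sidx[k]), int(sidx[cand])), False)
                for k in range(i, cand)
            ):
                e = cand
            else:
                break
        if e > i and e > last_end:
            blocks.append(
                GenomicInterval(
                    str(chrom_arr[i]),
                    int(pos[i]) - 1,
                    int(pos[e]),
                    name=f"block{len(blocks) + 1}",
                )
            )
            members.append([int(s) for s in sidx[i : e + 1]])
            last_end = e
    ld.blocks = blocks
    ld.block_members = members
    return ld


def fit_decay(ld: LDResult, n_chromosomes: int | None = None) -> dict:
    """Nonlinear least-squares fit of the Hill–Weir expectation to the
    (distance, r2) cloud.  Reports rho_hat (per-bp recombination scale)
    and the distance where the fitted curve crosses r2 = 0.2 (None with
    flag "beyond data range" when it never does within the data span)."""
    pairs = ld.pairs
    if len(pairs) < 50:
        raise ValueError("need >= 50 pairs for a decay fit")
    d = pairs["dist_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    pos_d = d[d > 0]
    if pos_d.max() / max(pos_d.min(), 1.0) < 10.0:
        logger.warning("fit_decay: distance range spans < 10-fold")
    n = n_chromosomes or 2 * ld.n

    def model(dist, rho):
        return hill_weir_expectation(rho * dist, n)

    try:
        popt, _ = curve_fit(
            model, d, r2, p0=[1e-3], bounds=(1e-12, 10.0), maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit failed to converge: {exc}; "
            f"n_pairs={len(pairs)}, dist range=({d.min()}, {d.max()})"
        ) from exc
    rho = float(popt[0])
    lo, hi = max(d.min(), 1.0), d.max()
    cross = None
    flag = ""
    f_lo, f_hi = model(lo, rho) - 0.2, model(hi, rho) - 0.2
    if f_lo > 0 and f_hi < 0:
        cross = float(brentq(lambda x: model(x, rho) - 0.2, lo, hi))
    elif f_hi > 0:
        flag = "beyond data range"
    else:
        flag = "below 0.2 throughout data range"
    decay = {
        "rho_hat": rho,
        "n_chromosomes": n,
        "half_decay_bp_at_r2_0.2": cross,
        "flag": flag,
        "model": "Hill-Weir (1988) drift expectation",
    }
    ld.decay = decay
    return decay
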