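"""Projection of QTL confidence intervals (cM) onto genomic coordinates.

Anchor markers (gene-derived markers with both a map position and a
genomic position) define a piecewise-linear cM <-> bp map per linkage
group.  A region is only projected when at least three co-monotone
anchors span or flank it; regions whose anchors are locally inverted
are flagged, not projected.  Regions projecting to overlapping genomic
intervals are merged into a single segmental homology region (SHR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GenomicInterval
from .linkage_qtl import OverlapRegion

logger = logging.getLogger("linkld")

MIN_ANCHORS = 3


class ProjectionError(ValueError):
    pass


@dataclass
class AnchorMap:
    """Monotone piecewise-linear interpolation cM -> bp for one LG."""

    lg: str
    chrom: str
    cM: np.ndarray
    bp: np.ndarray
    increasing: bool  # bp increasing with cM

    def to_bp(self, cm: float) -> tuple[int, bool]:
        """Map a cM position to bp; second value flags extrapolation
        beyond the terminal anchors (nearest segment's slope is used)."""
        c, b = self.cM, self.bp
        extrapolated = cm < c[0] or cm > c[-1]
        if cm <= c[0]:
            slope = (b[1] - b[0]) / (c[1] - c[0])
            val = b[0] + slope * (cm - c[0])
        elif cm >= c[-1]:
            slope = (b[-1] - b[-2]) / (c[-1] - c[-2])
            val = b[-1] + slope * (cm - c[-1])
        else:
            val = float(np.interp(cm, c, b))
        return int(round(val)), extrapolated

    def to_cM(self, bp: float) -> float:
        b = self.bp if self.increasing else self.bp[::-1]
        c = self.cM if self.increasing else self.cM[::-1]
        return float(np.interp(bp, b, c))

    def scale_cM_per_Mb(self) -> float:
        return float(
            (self.cM[-1] - self.cM[0]) / (abs(self.bp[-1] - self.bp[0]) / 1e6)
        )


@dataclass
class SHRInterval:
    interval: GenomicInterval
    sources: list[OverlapRegion]
    n_qtl: int
    scale_cM_per_Mb: float
    extrapolated: bool = False


def read_anchor_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"marker", "lg", "cM", "chrom", "bp"}
    if not need.issubset(df.columns):
        raise ProjectionError(f"anchor table must have columns {sorted(need)}")
    return df


def fit_anchor_map(anchors: pd.DataFrame, lg: str) -> AnchorMap:
    """Fit the piecewise-linear cM<->bp map for one LG.

    Raises ProjectionError when fewer than three anchors are available
    or when the anchors are not co-monotone (local inversion /
    rearrangement)."""
    sub = anchors[anchors["lg"] == lg].sort_values("cM")
    if len(sub) < MIN_ANCHORS:
        raise ProjectionError(
            f"LG {lg}: only {len(sub)} anchors (need >= {MIN_ANCHORS})"
        )
    chroms = sub["chrom"].unique()
    if len(chroms) > 1:
        raise ProjectionError(f"LG {lg}: anchors map to multiple chromosomes")
    cm = sub["cM"].to_numpy(dtype=float)
    bp = sub["bp"].to_numpy(dtype=float)
    if np.any(np.diff(cm) <= 0):
        raise ProjectionError(f"LG {lg}: duplicate anchor cM positions")
    diffs = np.diff(bp)
    if np.all(diffs > 0):
        increasing = True
    elif np.all(diffs < 0):
        increasing = False
        # reflect so interpolation runs on increasing bp with cM
    else:
        raise ProjectionError(
            f"LG {lg}: anchors not co-monotone (inverted/rearranged); "
            "region not projected"
        )
    return AnchorMap(lg, str(chroms[0]), cm, bp, increasing)


def project_regions(
    regions: list[OverlapRegion],
    anchors: pd.DataFrame,
    merge: bool = True,
) -> tuple[list[SHRInterval], list[dict]]:
    """Project co-localisation regions to genomic SHR intervals.

    Per-region failures (too few anchors, inversions) are logged and
    returned as a failure list; the pipeline continues.  Overlapping
    projected intervals are merged into one SHR (so k projected regions
    can yield < k SHRs)."""
    projected: list[SHRInterval] = []
    failures: list[dict] = []
    maps: dict[str, AnchorMap] = {}
    for reg in regions:
        try:
            if reg.lg not in maps:
                maps[reg.lg] = fit_anchor_map(anchors, reg.lg)
            amap = maps[reg.lg]
        except ProjectionError as exc:
            logger.warning("projection skipped: %s", exc)
            failures.append({"lg": reg.lg, "cM_lo": reg.cM_lo, "reason": str(exc)})
            continue
        b1, e1 = amap.to_bp(reg.cM_lo)
        b2, e2 = amap.to_bp(reg.cM_hi)
        lo, hi = (b1, b2) if b1 < b2 else (b2, b1)
        lo = max(lo, 0)
        if hi <= lo:
            hi = lo + 1
        projected.append(
            SHRInterval(
                interval=GenomicInterval(amap.chrom, lo, hi),
                sources=[reg],
                n_qtl=len(reg.members),
                scale_cM_per_Mb=amap.scale_cM_per_Mb(),
                extrapolated=e1 or e2,
            )
        )
    if merge:
        projected = merge_shrs(projected)
    for i, shr in enumerate(projected):
        shr.interval = GenomicInterval(
            shr.interval.chrom,
            shr.interval.start,
            shr.interval.end,
            name=f"SHR{i + 1:02d}",
        )
    return projected, failures


def merge_shrs(shrs: list[SHRInterval]) -> list[SHRInterval]:
    """Merge SHRs whose genomic intervals overlap (>= 1 bp)."""
    shrs = sorted(shrs, key=lambda s: (s.interval.chrom, s.interval.start))
    out: list[SHRInterval] = []
    for s in shrs:
        if out and out[-1].interval.overlaps(s.interval):
            prev = out[-1]
            prev.interval = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, s.interval.end),
            )
            prev.sources.extend(s.sources)
            prev.n_qtl += s.n_qtl
            prev.extrapolated = prev.extrapolated or s.extrapolated
        else:
            out.append(s)
    return out
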