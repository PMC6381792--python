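"""SNP classification against gene models and diversity by class.

Each SNP gets exactly one primary class per overlapping transcript:
nonsynonymous / synonymous (codon-level, standard genetic code,
strand- and frame-aware), genic_noncoding (intron, UTR or <= 2-kb
flank) or intergenic.  ncRNA overlap is annotated independently of the
primary class, mirroring the intergenic-but-ncRNA category.  When a
SNP is hit by several transcripts the most severe class wins
(nonsynonymous > synonymous > genic_noncoding), with all classes kept
in a secondary field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .data_model import FilterConfig, GeneModel, GeneModelSet, GenotypeMatrix
from .popgen_selection import per_site_pi

logger = logging.getLogger("linkld")

SEVERITY = {"nonsynonymous": 3, "synonymous": 2, "genic_noncoding": 1,
            "intergenic": 0, "unannotatable": 1}


@dataclass
class SnpAnnotation:
    site_index: int
    chrom: str
    pos: int  # 1-based
    primary_class: str
    all_classes: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    ncrna: bool = False
    ncrna_names: list[str] = field(default_factory=list)


def _cds_offset(gene: GeneModel, pos0: int) -> int | None:
    """Offset of genomic position within the spliced CDS (transcription
    order), or None if not in CDS."""
    segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    off = 0
    for s, e in segs:
        if s <= pos0 < e:
            return off + (pos0 - s if gene.strand == "+" else e - 1 - pos0)
        off += e - s
    return None


def _spliced_cds(gene: GeneModel, seq: str) -> str:
    segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    parts = []
    for s, e in segs:
        sub = seq[s:e]
        if gene.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        parts.append(sub)
    return "".join(parts)


def _classify_in_gene(
    gene: GeneModel, seq: str, pos0: int, ref: str, alt: str
) -> str:
    off = _cds_offset(gene, pos0)
    if off is None:
        return "genic_noncoding"  # intron or UTR
    cds = _spliced_cds(gene, seq)
    if len(cds) % 3 != 0:
        return "unannotatable"
    if gene.strand == "-":
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())
    if cds[off].upper() != ref.upper():
        logger.warning(
            "%s: reference base mismatch at offset %d", gene.gene_id, off
        )
    codon_i = off // 3
    codon = list(cds[3 * codon_i : 3 * codon_i + 3])
    aa_ref = str(Seq("".join(codon)).translate())
    codon[off % 3] = alt
    aa_alt = str(Seq("".join(codon)).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def annotate_snps(
    g: GenotypeMatrix,
    genes: GeneModelSet,
    seqs: dict[str, str],
    filter: FilterConfig | None = None,
) -> list[SnpAnnotation]:
    """Classify every site of `g` against the gene models.

    `seqs` maps chrom -> reference sequence (0-based).  Flank width is
    FilterConfig.flank_bp (default 2,000 bp)."""
    flank = (filter or FilterConfig()).flank_bp
    genes.validate_frames()
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes.genes:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    nc_by_chrom: dict[str, list] = {}
    for nc in genes.ncrnas:
        nc_by_chrom.setdefault(nc.chrom, []).append(nc)

    out: list[SnpAnnotation] = []
    for j in range(g.n_sites):
        chrom = str(g.sites.chrom[j])
        pos0 = int(g.sites.pos[j]) - 1
        ref, alt = str(g.sites.ref[j]), str(g.sites.alt[j])
        classes, hits = [], []
        for gm in by_chrom.get(chrom, []):
            if gm.start - flank <= pos0 < gm.end + flank:
                if gm.start <= pos0 < gm.end:
                    cls = _classify_in_gene(gm, seqs[chrom], pos0, ref, alt)
                else:
                    cls = "genic_noncoding"  # flank
                classes.append(cls)
                hits.append(gm.gene_id)
        primary = (
            max(classes, key=lambda c: SEVERITY[c]) if classes else "intergenic"
        )
        nc_hits = [
            nc.name
            for nc in nc_by_chrom.get(chrom, [])
            if nc.start <= pos0 < nc.end
        ]
        out.append(
            SnpAnnotation(
                site_index=j,
                chrom=chrom,
                pos=pos0 + 1,
                primary_class=primary,
                all_classes=classes,
                genes=hits,
                ncrna=bool(nc_hits),
                ncrna_names=nc_hits,
            )
        )
    return out


def annotations_frame(annotations: list[SnpAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_index": [a.site_index for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "pos": [a.pos for a in annotations],
            "class": [a.primary_class for a in annotations],
            "genes": [";".join(a.genes) for a in annotations],
            "ncrna": [a.ncrna for a in annotations],
        }
    )


def diversity_by_class(
    g: GenotypeMatrix,
    annotations: list[SnpAnnotation],
    subpop: str | None = None,
) -> pd.DataFrame:
    """Mean per-variant-site pi by annotation class, plus the
    noncoding/coding and nonsynonymous/synonymous diversity ratios.

    Ratios involving an empty class are NaN (flagged by n_sites=0)."""
    idx = (
        np.arange(g.n_individuals)
        if subpop is None
        else g.subpop_indices()[subpop]
    )
    pis = per_site_pi(g.dosage[idx])
    cls = np.array([a.primary_class for a in annotations])
    rows = []
    means: dict[str, float] = {}
    for c in ("nonsynonymous", "synonymous", "genic_noncoding", "intergenic"):
        sel = cls == c
        mean_pi = float(pis[sel].mean()) if sel.any() else float("nan")
        means[c] = mean_pi
        rows.append((c, int(sel.sum()), mean_pi))
    df = pd.DataFrame(rows, columns=["class", "n_sites", "mean_pi"])
    coding = np.isin(cls, ["nonsynonymous", "synonymous"])
    noncoding = cls == "genic_noncoding"
    ratios = {
        "nonsyn_syn": (
            means["nonsynonymous"] / means["synonymous"]
            if means["synonymous"] and not np.isnan(means["synonymous"])
            else float("nan")
        ),
        "noncoding_coding": (
            float(pis[noncoding].mean() / pis[coding].mean())
            if coding.any() and noncoding.any() and pis[coding].mean() > 0
            else float("nan")
        ),
    }
    df.attrs["ratios"] = ratios
    return df
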