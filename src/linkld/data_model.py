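"""Shared domain types, coordinate conventions and file I/O.

All genomic intervals inside the package are 0-based half-open; 1-based
VCF/GFF3 coordinates are converted at the file boundary.  Panel genotypes
are dosage-coded (count of the alternate allele, 0/1/2, NaN for missing);
full-sib progeny markers use the two-class pseudo-testcross coding {0, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("linkld")

TRAITS = ("H", "BD", "V")


class FormatError(ValueError):
    """Malformed input file."""


class EmptyResultError(ValueError):
    """An operation produced no usable records."""


@dataclass(frozen=True)
class FilterConfig:
    """Site-level filter thresholds for panel SNPs.

    max_missing: drop sites with missing-call fraction above this.
    min_maf: drop sites with minor allele frequency (from non-missing
        calls) below this.
    flank_bp: gene flank width used by the annotation module.
    """

    max_missing: float = 0.10
    min_maf: float = 0.05
    flank_bp: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing <= 1.0 and 0.0 <= self.min_maf <= 1.0):
            raise ValueError("filter fractions must lie in [0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenotypeMatrix:
    """Panel individuals x biallelic sites, alt-dosage coded.

    dosage: float array (n_individuals, n_sites), values in {0, 1, 2} or NaN.
    sites: DataFrame with columns chrom, pos (1-based), ref, alt.
    subpop: region label per individual (aligned with `individuals`).
    """

    individuals: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    subpop: pd.Series | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("dosage shape does not match individuals x sites")
        self.sites = self.sites.reset_index(drop=True)
        if self.subpop is not None:
            self.subpop = pd.Series(
                np.asarray(self.subpop), index=self.individuals
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        inds = [self.individuals[i] for i in idx]
        sub = self.subpop.iloc[idx].values if self.subpop is not None else None
        return GenotypeMatrix(inds, self.sites.copy(), self.dosage[idx], sub)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            m = np.zeros(self.n_sites, dtype=bool)
            m[mask] = True
            mask = m
        sub = self.subpop.values if self.subpop is not None else None
        return GenotypeMatrix(
            list(self.individuals), self.sites.loc[mask], self.dosage[:, mask], sub
        )

    def apply_filter(self, cfg: FilterConfig) -> "GenotypeMatrix":
        """Drop sites failing the missingness / MAF thresholds. Idempotent."""
        keep = (self.missing_fraction() <= cfg.max_missing) & (
            self.maf() >= cfg.min_maf
        )
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("filter: dropped %d of %d sites", n_drop, self.n_sites)
        return self.subset_sites(keep)

    def subpop_indices(self) -> dict[str, np.ndarray]:
        if self.subpop is None:
            raise ValueError("no subpopulation labels attached")
        out: dict[str, np.ndarray] = {}
        for label in pd.unique(self.subpop.values):
            out[str(label)] = np.flatnonzero(self.subpop.values == label)
        return out


@dataclass
class PhenotypeTable:
    """Long-format phenotypes: individual x trait x timepoint.

    A (trait, timepoint) pair is one *phenotype set*.
    """

    data: pd.DataFrame  # columns: individual, trait, timepoint, value

    REQUIRED = ("individual", "trait", "timepoint", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        bad = self.data["value"].dropna()
        if not np.isfinite(bad.to_numpy(dtype=float)).all():
            raise ValueError("non-finite phenotype values present")

    def phenotype_sets(self) -> list[tuple[str, str]]:
        pairs = self.data[["trait", "timepoint"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]

    def values_for(
        self, trait: str, timepoint: str, individuals: list[str]
    ) -> np.ndarray:
        sub = self.data[
            (self.data["trait"] == trait) & (self.data["timepoint"] == timepoint)
        ]
        series = sub.set_index("individual")["value"]
        return series.reindex(individuals).to_numpy(dtype=float)


@dataclass
class LinkageDataset:
    """Linkage map + full-sib progeny calls + longitudinal phenotypes.

    map: DataFrame (lg, marker, cM), cM strictly increasing within an LG.
    calls: DataFrame progeny x marker, values {0, 1} or NaN.
    """

    map: pd.DataFrame
    calls: pd.DataFrame
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        self.map = self.map.reset_index(drop=True)
        offenders = []
        for lg, grp in self.map.groupby("lg", sort=False):
            cm = grp["cM"].to_numpy(dtype=float)
            if np.any(np.diff(cm) <= 0):
                offenders.append(str(lg))
        if offenders:
            raise ValueError(
                f"cM positions not strictly increasing within LG(s): {offenders}"
            )
        unknown = set(self.calls.columns) - set(self.map["marker"])
        if unknown:
            raise ValueError(
                f"progeny calls reference markers absent from map: {sorted(unknown)[:5]}"
            )

    @property
    def lgs(self) -> list[str]:
        return list(pd.unique(self.map["lg"]))

    @property
    def progeny(self) -> list[str]:
        return list(self.calls.index)

    def lg_markers(self, lg: str) -> pd.DataFrame:
        return self.map[self.map["lg"] == lg].reset_index(drop=True)

    @property
    def total_cM(self) -> float:
        return float(self.map.groupby("lg")["cM"].max().sum())


@dataclass
class GeneModel:
    """One gene: strand, exons, CDS (with frame implied by order), UTRs."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open span
    end: int
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModelSet:
    """Gene models plus ncRNA records (lncRNA / pre-miRNA intervals)."""

    genes: list[GeneModel]
    ncrnas: list[GenomicInterval] = field(default_factory=list)
    ncrna_class: dict[str, str] = field(default_factory=dict)  # name -> class

    def validate_frames(self) -> None:
        bad = [g.gene_id for g in self.genes if g.cds and g.cds_length() % 3 != 0]
        if bad:
            raise ValueError(f"CDS length not divisible by 3 for genes: {bad}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str, filter: FilterConfig | None = None) -> GenotypeMatrix:
    """Read a VCF with GT fields into a dosage GenotypeMatrix.

    Multi-allelic records are skipped (count logged). Sites failing the
    filter are removed; site order is preserved.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    if not rows:
        raise EmptyResultError(f"no biallelic records in {path}")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    g = GenotypeMatrix(individuals, sites, np.array(rows).T)
    if filter is not None:
        g = g.apply_filter(filter)
        if g.n_sites == 0:
            raise EmptyResultError("no sites survive filtering")
    return g


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 (GT only) for a dosage matrix."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        for j, site in enumerate(g.sites.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else _GT_CODE[d] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_subpops(g: GenotypeMatrix, path: str) -> None:
    pd.DataFrame(
        {"individual": g.individuals, "subpop": g.subpop.values}
    ).to_csv(path, sep="\t", index=False)


def read_subpops(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["subpop"].values, index=df["individual"].values)


def read_linkage_inputs(
    map_path: str, calls_path: str, pheno_path: str
) -> LinkageDataset:
    """Read map / progeny-call / phenotype TSVs into a LinkageDataset."""
    map_df = pd.read_csv(map_path, sep="\t")
    need = {"lg", "marker", "cM"}
    if not need.issubset(map_df.columns):
        raise FormatError(f"map file must have columns {sorted(need)}")
    calls = pd.read_csv(calls_path, sep="\t", index_col=0)
    pheno = PhenotypeTable(pd.read_csv(pheno_path, sep="\t"))
    return LinkageDataset(map_df, calls, pheno)


def write_linkage_inputs(
    data: LinkageDataset, map_path: str, calls_path: str, pheno_path: str
) -> None:
    data.map.to_csv(map_path, sep="\t", index=False)
    data.calls.to_csv(calls_path, sep="\t")
    data.phenotypes.data.to_csv(pheno_path, sep="\t", index=False)


def write_intervals(intervals: list[GenomicInterval], path: str) -> None:
    """Write intervals as a sorted BED file (0-based half-open)."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_intervals(path: str) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"bad BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else ""
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name)
            )
    return out


def write_gff3(models: GeneModelSet, path: str) -> None:
    """Write gene models (gene/exon/CDS/UTR + ncRNA) as GFF3, 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models.genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tlinkld\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tlinkld\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            # frame of each CDS segment follows transcription order
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            frames = {}
            for s, e in segs:
                frames[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s
            for s, e in g.cds:
                fh.write(
                    f"{g.chrom}\tlinkld\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{frames[(s, e)]}\tParent={g.gene_id}\n"
                )
            for s, e in g.utr5:
                fh.write(
                    f"{g.chrom}\tlinkld\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.chrom}\tlinkld\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
        for nc in models.ncrnas:
            cls = models.ncrna_class.get(nc.name, "lncRNA")
            fh.write(
                f"{nc.chrom}\tlinkld\tncRNA\t{nc.start + 1}\t{nc.end}\t.\t+\t.\tID={nc.name};ncrna_class={cls}\n"
            )


def read_gff3(path: str) -> GeneModelSet:
    """Read gene models written by :func:`write_gff3` (gene/exon/CDS/UTR/ncRNA)."""
    genes: dict[str, GeneModel] = {}
    ncrnas: list[GenomicInterval] = []
    ncrna_class: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            s, e = int(start) - 1, int(end)
            adict = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = adict["ID"]
                genes[gid] = GeneModel(gid, chrom, s, e, strand)
            elif ftype == "ncRNA":
                name = adict.get("ID", f"nc{len(ncrnas)}")
                ncrnas.append(GenomicInterval(chrom, s, e, name))
                ncrna_class[name] = adict.get("ncrna_class", "lncRNA")
            else:
                parent = adict.get("Parent")
                if parent not in genes:
                    continue
                g = genes[parent]
                if ftype == "exon":
                    g.exons.append((s, e))
                elif ftype == "CDS":
                    g.cds.append((s, e))
                elif ftype == "five_prime_UTR":
                    g.utr5.append((s, e))
                elif ftype == "three_prime_UTR":
                    g.utr3.append((s, e))
    for g in genes.values():
        g.exons.sort()
        g.cds.sort()
    return GeneModelSet(list(genes.values()), ncrnas, ncrna_class)


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
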