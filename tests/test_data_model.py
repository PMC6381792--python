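"""I/O round-trips, coordinate conventions and filtering contracts."""

import numpy as np
import pandas as pd
import pytest

from linkld import data_model as dm
from linkld import synthetic_data as syn
from conftest import make_matrix


def test_vcf_roundtrip_identity(tmp_path, small_panel):
    g, _, _ = small_panel
    path = tmp_path / "panel.vcf"
    dm.write_vcf(g, path)
    g2 = dm.read_vcf(str(path))
    assert g2.individuals == g.individuals
    np.testing.assert_array_equal(g2.dosage, g.dosage)
    pd.testing.assert_frame_equal(
        g2.sites, g.sites.astype({"pos": g2.sites["pos"].dtype})
    )


def test_vcf_gt_coding_and_multiallelic_skip(tmp_path):
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=Chr01>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc",
            "Chr01\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "Chr01\t200\t.\tG\tC,A\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "Chr01\t300\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t0/1\t0/0",
            "",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    g = dm.read_vcf(str(path))
    assert g.n_sites == 2  # multi-allelic record skipped
    np.testing.assert_array_equal(g.dosage[:, 0], [0.0, 1.0, 2.0])
    assert np.isnan(g.dosage[0, 1]) and g.dosage[1, 1] == 1.0


def test_filter_drops_high_missingness_site():
    # 20% missing at site 0 with max_missing = 0.10 -> dropped
    dos = np.tile([0.0, 1.0, 2.0, 1.0, 0.0], (2, 1)).T
    dos[0, 0] = np.nan
    g = make_matrix(dos)
    filt = g.apply_filter(dm.FilterConfig(max_missing=0.10, min_maf=0.0))
    assert filt.n_sites == 1
    assert filt.sites["pos"].tolist() == [150]


def test_filter_is_idempotent(small_panel):
    g, _, _ = small_panel
    cfg = dm.FilterConfig()
    once = g.apply_filter(cfg)
    twice = once.apply_filter(cfg)
    assert once.n_sites == twice.n_sites
    np.testing.assert_array_equal(once.dosage, twice.dosage)


def test_dosage_and_missing_counts_sum_to_n():
    rng = np.random.default_rng(0)
    dos = rng.choice([0.0, 1.0, 2.0, np.nan], size=(30, 20))
    g = make_matrix(dos)
    present = (~np.isnan(g.dosage)).sum(axis=0)
    missing = np.isnan(g.dosage).sum(axis=0)
    assert np.all(present + missing == g.n_individuals)


def test_linkage_roundtrip_and_validation(tmp_path, small_family):
    data, _ = small_family
    paths = [tmp_path / p for p in ("map.tsv", "calls.tsv", "pheno.tsv")]
    dm.write_linkage_inputs(data, *paths)
    back = dm.read_linkage_inputs(*map(str, paths))
    pd.testing.assert_frame_equal(back.map, data.map)
    pd.testing.assert_frame_equal(back.calls, data.calls)

    # calls referencing an unknown marker are rejected by name
    bad_calls = data.calls.rename(columns={data.calls.columns[0]: "ghost"})
    with pytest.raises(ValueError, match="ghost"):
        dm.LinkageDataset(data.map, bad_calls, data.phenotypes)

    # non-monotone cM within an LG names the offender
    bad_map = data.map.copy()
    bad_map.loc[1, "cM"] = 0.0
    with pytest.raises(ValueError, match="LG_01"):
        dm.LinkageDataset(bad_map, data.calls, data.phenotypes)


def test_bed_coordinate_convention(tmp_path):
    # 1-based inclusive 9,970,001-10,030,000 == 0-based half-open below
    iv = dm.GenomicInterval("Chr14", 9_970_000, 10_030_000, "SHR18")
    path = tmp_path / "iv.bed"
    dm.write_intervals([iv], path)
    assert path.read_text() == "Chr14\t9970000\t10030000\tSHR18\n"


def test_bed_sorting_empty_and_roundtrip(tmp_path):
    ivs = [
        dm.GenomicInterval("Chr02", 50, 80, "b"),
        dm.GenomicInterval("Chr01", 100, 200, "a"),
        dm.GenomicInterval("Chr01", 10, 20, "c"),
    ]
    path = tmp_path / "iv.bed"
    dm.write_intervals(ivs, path)
    back = dm.read_intervals(str(path))
    assert [iv.name for iv in back] == ["c", "a", "b"]
    assert back == sorted(back, key=lambda i: (i.chrom, i.start))

    dm.write_intervals([], path)
    assert path.read_text() == ""
    assert dm.read_intervals(str(path)) == []


def test_interval_validation():
    with pytest.raises(ValueError):
        dm.GenomicInterval("Chr01", 10, 10)


def test_gff3_roundtrip(tmp_path):
    models, _ = syn.simulate_gene_models(
        3, dm.GenomicInterval("Chr01", 0, 40000), seed=1
    )
    path = tmp_path / "genes.gff3"
    dm.write_gff3(models, path)
    back = dm.read_gff3(str(path))
    assert len(back.genes) == 3
    for a, b in zip(models.genes, back.genes):
        assert (a.gene_id, a.strand, a.start, a.end) == (
            b.gene_id, b.strand, b.start, b.end,
        )
        assert a.cds == b.cds
    assert len(back.ncrnas) == len(models.ncrnas)


# --- property tests ------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def interval_lists(draw):
    n = draw(st.integers(0, 8))
    out = []
    for k in range(n):
        start = draw(st.integers(0, 10_000))
        length = draw(st.integers(1, 5_000))
        chrom = draw(st.sampled_from(["Chr01", "Chr02", "Chr14"]))
        out.append(dm.GenomicInterval(chrom, start, start + length, f"iv{k}"))
    return out


@settings(max_examples=30, deadline=None, derandomize=True)
@given(interval_lists())
def test_bed_roundtrip_property(tmp_path_factory, ivs):
    path = tmp_path_factory.mktemp("bed") / "x.bed"
    dm.write_intervals(ivs, path)
    back = dm.read_intervals(str(path))
    assert sorted(back, key=lambda i: (i.chrom, i.start, i.end, i.name)) == \
        sorted(ivs, key=lambda i: (i.chrom, i.start, i.end, i.name))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.sampled_from([0.0, 1.0, 2.0, np.nan]), min_size=6,
                 max_size=6),
        min_size=4, max_size=12,
    )
)
def test_filter_idempotent_property(rows):
    g = make_matrix(np.array(rows))
    cfg = dm.FilterConfig(max_missing=0.25, min_maf=0.1)
    once = g.apply_filter(cfg)
    twice = once.apply_filter(cfg)
    np.testing.assert_array_equal(once.dosage, twice.dosage)
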