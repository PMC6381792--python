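import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("linkld", database=None, deadline=None)
settings.load_profile("linkld")

from linkld import synthetic_data as syn
from linkld.data_model import GenotypeMatrix, PhenotypeTable


@pytest.fixture(scope="session")
def small_family():
    """300-progeny family, 3 LGs, one planted QTN at 30 cM on LG_01."""
    cfg = syn.FamilyConfig.test_scale(seed=42, n_timepoints=4)
    data, truth = syn.simulate_fullsib(
        cfg, [syn.QTNSpec(locus=("LG_01", 30.0), pve=0.2)]
    )
    return data, truth


@pytest.fixture(scope="session")
def null_family():
    """Family with no planted QTN (pure noise phenotypes)."""
    cfg = syn.FamilyConfig.test_scale(seed=43, n_timepoints=2)
    data, truth = syn.simulate_fullsib(cfg, [])
    return data


@pytest.fixture(scope="session")
def small_panel():
    """150-member three-subpopulation panel, common-variant spectrum."""
    cfg = syn.PanelConfig.test_scale(
        seed=7, n_regions=2, region_length=20000, snps_per_region=150,
        maf_dist="uniform",
    )
    g, pheno, truth = syn.simulate_panel(cfg)
    return g, pheno, truth


def make_matrix(dosage, subpop=None, chrom="Chr01", start_pos=100, spacing=50):
    """GenotypeMatrix from a plain dosage array (individuals x sites)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": [start_pos + k * spacing for k in range(m)],
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    inds = [f"i{k:03d}" for k in range(n)]
    return GenotypeMatrix(inds, sites, dosage, subpop)


def make_pheno(individuals, values, trait="H", timepoint="T1"):
    return PhenotypeTable(
        pd.DataFrame(
            {
                "individual": individuals,
                "trait": trait,
                "timepoint": timepoint,
                "value": np.asarray(values, dtype=float),
            }
        )
    )
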