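import numpy as np
import pandas as pd
import pytest

from crcprs.io import GenotypeMatrix, VariantPanel
from crcprs.simulate import GroupSpec, SimulationConfig, simulate_cohort


def make_panel(betas, eafs=None, r2=None, genotyped=None) -> VariantPanel:
    """Small hand-built variant panel for unit tests."""
    m = len(betas)
    eafs = [0.3] * m if eafs is None else eafs
    r2 = [0.9] * m if r2 is None else r2
    genotyped = [False] * m if genotyped is None else genotyped
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(m)],
            "chrom": ["1"] * m,
            "pos": [(i + 1) * 1000 for i in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "beta": betas,
            "eaf": eafs,
            "imputation_r2": [np.nan if g else v for v, g in zip(r2, genotyped)],
            "genotyped": genotyped,
            "included": True,
        }
    )
    return VariantPanel(table)


def make_geno(dosages, panel=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    vids = [f"rs{i}" for i in range(m)] if panel is None else list(panel.table["variant_id"])
    return GenotypeMatrix([f"I{i}" for i in range(n)], vids, dosages)


SMALL_GROUPS = {
    "fcrc": GroupSpec(60, 48.72, 12.40, (16, 82), 0.5582,
                      famhx_crc_rate=0.51, multiple_crc_rate=0.08, deceased_rate=0.08),
    "sp": GroupSpec(16, 52.29, 12.60, (8, 75), 0.6625,
                    famhx_crc_rate=0.375, multiple_crc_rate=0.11),
    "sporadic_crc": GroupSpec(120, 66.87, 10.88, (23, 91), 0.6518,
                              famhx_crc_rate=0.1226, famhx_unknown_rate=0.1588),
    "control": GroupSpec(300, 62.40, 10.25, (24, 92), 0.5085,
                         famhx_crc_rate=0.0512, famhx_unknown_rate=0.3337),
}


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced four-group synthetic study shared across tests."""
    cfg = SimulationConfig(seed=11, n_population=8000, liability_h2=0.3,
                           groups=dict(SMALL_GROUPS))
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
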