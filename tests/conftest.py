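import numpy as np
import pandas as pd
import pytest

from nactmeth.io_model import MValueMatrix, SampleSheet
from nactmeth.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort (study design, 300 CpGs)."""
    cfg = SimulationConfig(n_cpg=300, n_affected_cpgs=50, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def paired_sheet_factory():
    """Build a fully paired sample sheet with n patients."""

    def make(n, prefix="P", group="survivor"):
        rows = []
        for i in range(n):
            for tp in ("pre", "post"):
                rows.append(
                    {
                        "sample_id": f"{prefix}{i}_{tp}",
                        "patient_id": f"{prefix}{i}",
                        "timepoint": tp,
                        "survival_group": group,
                        "survival_time": 5.0,
                        "event": 0,
                    }
                )
        return SampleSheet(pd.DataFrame(rows))

    return make


@pytest.fixture()
def m_matrix_factory():
    def make(values: np.ndarray, sample_ids):
        idx = [f"cg{i:04d}" for i in range(values.shape[0])]
        return MValueMatrix(pd.DataFrame(values, index=idx, columns=list(sample_ids)))

    return make
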