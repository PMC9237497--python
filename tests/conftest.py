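import numpy as np
import pandas as pd
import pytest

from breedvar import SimParams, Treatment, TrialDesign


@pytest.fixture
def small_design():
    """Three treatments, 6 lines x 3 replicates, all ten traits."""
    return TrialDesign(
        treatments=(
            Treatment("C"),
            Treatment("G1", gamma_gy=100.0),
            Treatment("S1", sa_percent=0.01),
        ),
        lines_per_treatment=6,
        replications=3,
    )


@pytest.fixture
def default_params():
    return SimParams()


def make_cell_table(values_by_line, variety="V", generation="M2",
                    treatment="T", trait="PY"):
    """Long-format table for a single (variety, generation, treatment, trait)
    cell from a {line: [replicate values]} mapping."""
    rows = []
    for line, values in values_by_line.items():
        for k, v in enumerate(values, start=1):
            rows.append((variety, generation, treatment, line, k, trait, float(v)))
    return pd.DataFrame(
        rows,
        columns=["variety", "generation", "treatment", "line",
                 "replicate", "trait", "value"],
    )


@pytest.fixture
def anova_cell():
    """The hand-checked 3-line x 2-replicate cell: MSG=32, MSE=2."""
    return make_cell_table({"A": [10, 12], "B": [14, 16], "C": [18, 20]})


def balanced_cell(rng, n_lines, r, sigma_g, sigma_e, mean=50.0, **kwargs):
    """Simulate one balanced cell directly from the variance-component model."""
    line_effects = rng.normal(0.0, sigma_g, size=n_lines)
    values = {
        f"L{i:03d}": mean + line_effects[i] + rng.normal(0.0, sigma_e, size=r)
        for i in range(n_lines)
    }
    return make_cell_table(values, **kwargs)
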