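import numpy as np
import pandas as pd
import pytest

from licoqams import study_data as sd
from licoqams.doe import FactorDef, bbd_design, fit_quadratic
from licoqams.scoring import ExtractionTable
from licoqams.synthetic import GeneratorConfig, SyntheticGenerator


@pytest.fixture(scope="session")
def study_design():
    """The 17-run Box-Behnken design at the study's factor levels."""
    return bbd_design([FactorDef(n, c, s) for n, c, s in sd.BBD_FACTORS])


@pytest.fixture(scope="session")
def study_model(study_design):
    """Quadratic model fitted to the published 17 responses."""
    return fit_quadratic(study_design, sd.BBD_RESPONSES)


@pytest.fixture()
def water_table():
    """The water-content single-factor block as an ExtractionTable."""
    rows = sd.SINGLE_FACTOR_RATES["water content/%"]
    rates = pd.DataFrame([r[1] for r in rows], index=[r[0] for r in rows],
                         columns=list(sd.COMPOUNDS))
    return ExtractionTable(group_label="water content/%", rates=rates)


@pytest.fixture()
def generator():
    return SyntheticGenerator(GeneratorConfig(seed=12345))


@pytest.fixture()
def noiseless_generator():
    return SyntheticGenerator(GeneratorConfig(
        seed=0, multiplicative_rsd_pct=0.0, additive_sd=0.0))
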