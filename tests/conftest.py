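import numpy as np
import pandas as pd
import pytest

from coexprot import simulate as sim
from coexprot.design import design_frame, generate_design
from coexprot.matrix import AbundanceMatrix


@pytest.fixture(scope="session")
def study_design() -> pd.DataFrame:
    """The study layout: 2 x 2 x 5 factorial, 3 replicates, aborted cell."""
    return design_frame(generate_design(3, drop_cell=True))


@pytest.fixture(scope="session")
def seeded_dataset(study_design):
    """A modest synthetic dataset with planted effects and modules."""
    truth = sim.generate_truth(
        120, module_specs=sim.default_module_specs(), seed=7,
    )
    matrix = sim.simulate_abundances(study_design, truth, seed=8)
    return truth, matrix


@pytest.fixture(scope="session")
def null_matrix(study_design) -> AbundanceMatrix:
    """Fully null data: no factor effects, no modules."""
    truth = sim.generate_null_truth(80, seed=11)
    return sim.simulate_abundances(study_design, truth, seed=12)


def make_matrix(values, design, log_scale=True) -> AbundanceMatrix:
    """Convenience constructor from a plain array."""
    vals = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=pd.Index([f"p{i}" for i in range(np.shape(values)[0])], name="protein_id"),
        columns=design.index,
    )
    return AbundanceMatrix(vals, design, log_scale=log_scale)
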