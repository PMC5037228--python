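import logging

import numpy as np
import pytest

from ssica.hybrid_simulator import SimDesign, default_patches, generate_dataset
from ssica.multilevel_reduction import SubjectSeries, build_reduction

logging.getLogger("ssica").setLevel(logging.ERROR)


def random_series(rng, t=30, m=120, subject_id="s", group_id="g1", tr=2.0):
    return SubjectSeries(rng.standard_normal((t, m)), tr,
                         subject_id=subject_id, group_id=group_id)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_dataset(rng):
    """2 groups x 3 subjects of plain random series (no planted structure)."""
    out = []
    for g in ("g1", "g2"):
        for i in range(3):
            out.append(random_series(rng, t=40, m=150,
                                     subject_id=f"{g}_s{i}", group_id=g))
    return out


@pytest.fixture
def small_reduction(small_dataset):
    return build_reduction(small_dataset, (12, 8, 8, 10))


@pytest.fixture(scope="session")
def recovery_fixture():
    """One full simulate + constrained fit on the default recovery design,
    shared by the engine / reconstruction / acceptance tests."""
    from ssica.cli_io import RECOVERY_DIMS, _mk_config, fit_dataset

    design = SimDesign(patches=default_patches("recovery"), seed=1)
    dataset = generate_dataset(design)
    reduction, result = fit_dataset(dataset, RECOVERY_DIMS,
                                    _mk_config(RECOVERY_DIMS, seed=1))
    return dataset, reduction, result
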