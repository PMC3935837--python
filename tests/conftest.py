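import numpy as np
import pytest
from dataclasses import replace

from pyretk import ExposureScenario, ParameterSet, simulate, table2_mean


@pytest.fixture(scope="session")
def table2():
    return table2_mean()


@pytest.fixture(scope="session")
def dermal_accept_params(table2):
    """Table 2 internals with the published dermal inference setup:
    absorption fraction 0.01 for both isomers."""
    return ParameterSet(
        cis=replace(table2.cis, f_abs_dermal=0.01),
        trans=replace(table2.trans, f_abs_dermal=0.01),
        shared=table2.shared, label="dermal-inference",
    )


@pytest.fixture(scope="session")
def oral_result(table2):
    """Single oral unit bolus (50:50) run to urinary plateau."""
    scen = ExposureScenario.single_bolus("oral", 1.0, cis_fraction=0.5,
                                         duration=500.0)
    return simulate(table2, scen)


@pytest.fixture(scope="session")
def dermal_result(dermal_accept_params):
    """Single dermal unit bolus (50:50), no wash-off, run to plateau."""
    scen = ExposureScenario.single_bolus("dermal", 1.0, cis_fraction=0.5,
                                         duration=900.0)
    return simulate(dermal_accept_params, scen)


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random physiologically-shaped parameter set (for oracle studies)."""
    from pyretk import IsomerParams, SharedParams

    def iso():
        k_met = rng.uniform(1.0, 30.0)
        k_elim = rng.uniform(0.05, 0.5)
        y_dcca = rng.uniform(0.05, 0.6)
        y_pba = rng.uniform(0.02, 0.3)
        k_elim3 = shared_kelim3
        return IsomerParams(
            k_abs_oral=rng.uniform(0.05, 2.0),
            k_abs_dermal=rng.uniform(0.01, 0.2),
            f_abs_oral=rng.uniform(0.3, 1.0),
            f_abs_dermal=rng.uniform(0.005, 0.05),
            k_BS=rng.uniform(0.5, 20.0),
            k_SB=rng.uniform(0.01, 0.3),
            k_metabolism=k_met,
            k_elim=k_elim,
            omega=y_dcca * k_met * k_elim,
            omega_3PBA=y_pba * k_met * k_elim3,
        )

    shared_kelim3 = rng.uniform(0.05, 0.5)
    return ParameterSet(cis=iso(), trans=iso(),
                        shared=SharedParams(k_elim_3PBA=shared_kelim3),
                        label="random")
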