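import pytest

from lsjoint.model_core import (
    BaselineHazard,
    DesignSpec,
    ModelSpec,
    ParameterVector,
    polynomial_basis,
)
from lsjoint.simulate import assemble_dataset, fitting_spec, scenario_config


@pytest.fixture(scope="session")
def scenario_a():
    return scenario_config("A", N=80)


@pytest.fixture(scope="session")
def data_a(scenario_a):
    """A small scenario-A cohort shared across tests."""
    return assemble_dataset(scenario_a, seed=42)


@pytest.fixture(scope="session")
def spec_a(scenario_a):
    return fitting_spec(scenario_a)


@pytest.fixture(scope="session")
def truth_pv_a(scenario_a, spec_a):
    """Generating truth expressed over the fitting specification."""
    from lsjoint.simulate import truth_params

    pv_t = truth_params(scenario_a)
    return ParameterVector.from_parts(
        spec_a, pv_t.beta, pv_t.mu, Sigma=scenario_a.Sigma,
        alpha=[pv_t.alpha(k) for k in (1, 2)],
        baseline=[pv_t.baseline(k) for k in (1, 2)])


@pytest.fixture()
def linear_design():
    return DesignSpec(mean_basis=polynomial_basis(1), var_basis=polynomial_basis(1))


def make_spec(mean_degree=1, var_degree=1, random_mean_idx=(0, 1),
              random_var_idx=(0, 1), baselines=("weibull",),
              association=None, re_structure="independent", **design_kw):
    """Convenience ModelSpec builder for tests."""
    design = DesignSpec(mean_basis=polynomial_basis(mean_degree),
                        var_basis=polynomial_basis(var_degree),
                        random_mean_idx=random_mean_idx,
                        random_var_idx=random_var_idx, **design_kw)
    bhs = tuple(b if isinstance(b, BaselineHazard) else BaselineHazard(b)
                for b in baselines)
    if association is None:
        association = tuple(("value", "slope", "sigma") for _ in bhs)
    return ModelSpec(design=design, baselines=bhs, association=association,
                     re_structure=re_structure)
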