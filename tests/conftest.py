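import numpy as np
import pytest

from skewtlst import estimator, lst_spec


@pytest.fixture(scope="session")
def default_mixture():
    return lst_spec.default_fixture(delta_T=2.8)


@pytest.fixture(scope="session")
def spec2():
    """Two-class design with two occasions (observed dimension 4)."""
    return lst_spec.LSTModelSpec(n_occasions=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def normal_submodel_run():
    """200 replications of a well-specified single-class normal submodel.

    Shared by the SE-consistency (seb) and coverage oracle checks: j=2,
    N=1000, delta_T and nu fixed at their normal-limit values.  Returns the
    spec, true parameters, and per-replication estimate/SE arrays restricted
    to converged fits with standard errors.
    """
    spec = lst_spec.LSTModelSpec(
        n_occasions=2, n_classes=1, fixed={"delta_T": 0.0, "nu": 10000.0}
    )
    cp = lst_spec.LSTClassParams(
        lambda_T2=0.9,
        alpha_2=0.2,
        mu_T=1.0,
        sigma2_T=0.8,
        delta_T=0.0,
        nu=10000.0,
        var_IST2=0.3,
        var_O=0.5,
        var_E1=0.5,
        var_Ej=0.35,
    )
    truth = lst_spec.MixtureParams(class_params=(cp,))
    params = lst_spec.build_class_moments(spec, cp)
    from skewtlst.rmst_core import rmst_sample

    estimates, ses = [], []
    for rep in range(200):
        data = rmst_sample(params, 1000, seed=50_000 + rep)
        fit = estimator.fit_mixture(data, spec, start=truth)
        if fit.converged and fit.standard_errors is not None:
            estimates.append(lst_spec.truth_vector(fit.estimates, spec))
            ses.append(fit.standard_errors)
    return spec, truth, np.array(estimates), np.array(ses)
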