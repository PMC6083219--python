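"""Shared independent oracles for the estimator tests."""

import numpy as np
from scipy import linalg

from skewtlst import lst_spec
from skewtlst.lst_spec import (
    LSTClassParams,
    LSTModelSpec,
    MixtureParams,
    build_class_moments,
    default_fixture,
)

NORMAL_FIX = {"delta_T": 0.0, "nu": 10000.0}


def normal_single_class() -> tuple[LSTModelSpec, MixtureParams]:
    """Single-class submodel with skewness and tails fixed at normality."""
    from dataclasses import replace

    spec = LSTModelSpec(n_occasions=2, n_classes=1, fixed=NORMAL_FIX)
    cp = replace(default_fixture().class_params[0], delta_T=0.0, nu=10000.0)
    return spec, MixtureParams(class_params=(cp,))


def expected_information_ses(
    spec: LSTModelSpec, mp: MixtureParams, n: int, h: float = 1e-6
) -> np.ndarray:
    """Normal-theory SEM standard errors from the expected information.

    I_ab = dmu_a' S^-1 dmu_b + 0.5 tr(S^-1 dS_a S^-1 dS_b), per observation,
    with derivatives of the model-implied (mu, Sigma) taken numerically on
    the reporting scale.
    """
    theta = lst_spec.truth_vector(mp, spec)

    def moments(t):
        kwargs = dict(zip(spec.free_class_param_names, t))
        kwargs.update(spec.fixed)
        params = build_class_moments(spec, LSTClassParams(**kwargs))
        return params.mu, params.sigma

    mu0, sig0 = moments(theta)
    siginv = linalg.inv(sig0)
    k = theta.size
    dmu, dsig = [], []
    for a in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[a] += h
        tm[a] -= h
        mup, sigp = moments(tp)
        mum, sigm = moments(tm)
        dmu.append((mup - mum) / (2 * h))
        dsig.append((sigp - sigm) / (2 * h))
    info = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            info[a, b] = dmu[a] @ siginv @ dmu[b] + 0.5 * np.trace(
                siginv @ dsig[a] @ siginv @ dsig[b]
            )
    return np.sqrt(np.diag(linalg.inv(n * info)))
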