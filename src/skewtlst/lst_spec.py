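"""Two-class mixture latent state-trait (LST) measurement model.

Within each latent class the observed vector stacks 2 indicators over j
occasions (occasion-major order: y_1_1, y_2_1, y_1_2, y_2_2, ...).  Each
observation decomposes into a common trait (restricted skew-t distributed),
an indicator-specific trait residual for indicator 2, occasion-specific
factors, and measurement error.  Identification fixes lambda_T1 = 1,
lambda_I2 = 1, both occasion loadings to 1, and the first indicator's
intercept to 0; measurement invariance holds all intercepts, loadings and
occasion variances equal over time, with the sole exception of a larger
error variance at the first occasion.

Under the shared t-mixing construction (all latent components within a class
divided by the same sqrt(W)) the observed vector is itself exactly rMST,
which is what makes the mixture likelihood available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .rmst_core import NU_MIN, NU_NORMAL_LIMIT, RmstParams

__all__ = [
    "CLASS_PARAM_NAMES",
    "LOG_SCALE_PARAMS",
    "LSTClassParams",
    "LSTModelSpec",
    "MixtureParams",
    "build_class_moments",
    "constraint_map",
    "count_free_parameters",
    "default_fixture",
    "free_param_names",
    "pack_params",
    "unpack_params",
]

# Per-class free parameters of the paper-style design, in packing order.
CLASS_PARAM_NAMES: tuple[str, ...] = (
    "lambda_T2",
    "alpha_2",
    "mu_T",
    "sigma2_T",
    "delta_T",
    "nu",
    "var_IST2",
    "var_O",
    "var_E1",
    "var_Ej",
)

# Parameters packed on the log scale (positivity).  nu uses log(nu - NU_MIN).
LOG_SCALE_PARAMS: frozenset[str] = frozenset(
    {"sigma2_T", "var_IST2", "var_O", "var_E1", "var_Ej"}
)


@dataclass(frozen=True)
class LSTClassParams:
    """Free parameters of one latent class.

    ``sigma2_T`` / ``delta_T`` / ``nu`` are the trait's rMST scale, skewness
    and degrees of freedom; ``var_*`` are scale parameters of the normal
    latent residual components (equal to variances in the normal limit).
    """

    lambda_T2: float
    alpha_2: float
    mu_T: float
    sigma2_T: float
    delta_T: float
    nu: float
    var_IST2: float
    var_O: float
    var_E1: float
    var_Ej: float

    def __post_init__(self) -> None:
        for name in ("sigma2_T", "var_IST2", "var_O", "var_E1", "var_Ej"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.nu > 2.0:
            raise ValueError("nu must exceed 2")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in CLASS_PARAM_NAMES}


@dataclass(frozen=True)
class MixtureParams:
    """Class-specific parameter blocks plus the class-1 membership logit."""

    class_params: tuple[LSTClassParams, ...]
    logit_pi1: float = 0.0

    @property
    def n_classes(self) -> int:
        return len(self.class_params)

    @property
    def pi(self) -> np.ndarray:
        """Mixing proportions (pi_1, pi_2) — or (1.0,) for a single class."""
        if self.n_classes == 1:
            return np.array([1.0])
        if self.n_classes != 2:
            raise NotImplementedError("only 1 or 2 classes supported")
        p1 = 1.0 / (1.0 + np.exp(-self.logit_pi1))
        return np.array([p1, 1.0 - p1])

    def swapped(self) -> "MixtureParams":
        """Exchange class blocks and flip the logit sign (label permutation)."""
        return MixtureParams(
            class_params=tuple(reversed(self.class_params)),
            logit_pi1=-self.logit_pi1,
        )


@dataclass(frozen=True)
class LSTModelSpec:
    """Structural description of the mixture LST design.

    ``fixed`` maps class-parameter names to values that are held fixed (not
    estimated) in every class, e.g. ``{"delta_T": 0.0, "nu": 10000.0}`` for
    the normal submodel.
    """

    n_occasions: int
    n_indicators: int = 2
    n_classes: int = 2
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_indicators != 2:
            raise ValueError("design supports exactly 2 indicators")
        if not 2 <= self.n_occasions <= 6:
            raise ValueError("n_occasions must be in 2..6")
        if self.n_classes not in (1, 2):
            raise ValueError("n_classes must be 1 or 2")
        unknown = set(self.fixed) - set(CLASS_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
        object.__setattr__(self, "fixed", MappingProxyType(dict(self.fixed)))

    @property
    def p(self) -> int:
        """Observed dimension, 2 indicators per occasion."""
        return self.n_indicators * self.n_occasions

    @property
    def free_class_param_names(self) -> tuple[str, ...]:
        return tuple(n for n in CLASS_PARAM_NAMES if n not in self.fixed)

    @property
    def n_free_parameters(self) -> int:
        """Free-parameter count by direct arithmetic (hot path); equals
        :func:`count_free_parameters` from the constraint table."""
        return self.n_classes * len(self.free_class_param_names) + (self.n_classes - 1)


def constraint_map(spec: LSTModelSpec) -> pd.DataFrame:
    """Enumerate every saturated model parameter with its constraint status.

    Columns: ``parameter`` (saturated name), ``class``, ``status``
    (``fixed`` or ``free``), ``value`` (for fixed entries), ``group``
    (equality class; all free entries sharing a group are one estimated
    parameter).  The mixing logit appears once with class 0.
    """
    rows: list[dict] = []
    j = spec.n_occasions
    for c in range(1, spec.n_classes + 1):
        for occ in range(1, j + 1):
            rows += [
                dict(parameter=f"alpha_1_{occ}", cls=c, status="fixed", value=0.0, group=""),
                dict(parameter=f"alpha_2_{occ}", cls=c, status="free", value=np.nan, group="alpha_2"),
                dict(parameter=f"lambda_T1_{occ}", cls=c, status="fixed", value=1.0, group=""),
                dict(parameter=f"lambda_T2_{occ}", cls=c, status="free", value=np.nan, group="lambda_T2"),
                dict(parameter=f"lambda_I2_{occ}", cls=c, status="fixed", value=1.0, group=""),
                dict(parameter=f"lambda_O1_{occ}", cls=c, status="fixed", value=1.0, group=""),
                dict(parameter=f"lambda_O2_{occ}", cls=c, status="fixed", value=1.0, group=""),
                dict(parameter=f"var_O_{occ}", cls=c, status="free", value=np.nan, group="var_O"),
            ]
            for i in (1, 2):
                group = "var_E1" if occ == 1 else "var_Ej"
                rows.append(
                    dict(parameter=f"var_E{i}_{occ}", cls=c, status="free", value=np.nan, group=group)
                )
        rows += [
            dict(parameter="mu_T", cls=c, status="free", value=np.nan, group="mu_T"),
            dict(parameter="sigma2_T", cls=c, status="free", value=np.nan, group="sigma2_T"),
            dict(parameter="delta_T", cls=c, status="free", value=np.nan, group="delta_T"),
            dict(parameter="nu", cls=c, status="free", value=np.nan, group="nu"),
            dict(parameter="var_IST2", cls=c, status="free", value=np.nan, group="var_IST2"),
            dict(parameter="mean_IST2", cls=c, status="fixed", value=0.0, group=""),
        ]
        for occ in range(1, j + 1):
            rows.append(
                dict(parameter=f"mean_O_{occ}", cls=c, status="fixed", value=0.0, group="")
            )
    for _ in range(spec.n_classes - 1):
        rows.append(dict(parameter="logit_pi1", cls=0, status="free", value=np.nan, group="logit_pi1"))
    df = pd.DataFrame(rows).rename(columns={"cls": "class"})
    # apply user-fixed class parameters
    for name, value in spec.fixed.items():
        mask = df["group"] == name
        df.loc[mask, ["status", "value", "group"]] = ["fixed", float(value), ""]
    return df


def count_free_parameters(spec: LSTModelSpec) -> int:
    """Number of estimated parameters after all constraints (incl. logit)."""
    df = constraint_map(spec)
    free = df[df["status"] == "free"]
    return int(free.groupby(["class", "group"]).ngroups)


def free_param_names(spec: LSTModelSpec) -> list[str]:
    """Estimated-parameter labels in packing order, e.g. ``mu_T[1]``."""
    names = [
        f"{name}[{c}]"
        for c in range(1, spec.n_classes + 1)
        for name in spec.free_class_param_names
    ]
    if spec.n_classes == 2:
        names.append("logit_pi1")
    return names


def _moment_arrays(
    j: int, cp: Mapping[str, float] | LSTClassParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mu, Sigma, delta) arrays of one class, without parameter validation."""
    get = cp.get if isinstance(cp, Mapping) else lambda k: getattr(cp, k)
    lambda_T2 = get("lambda_T2")
    p = 2 * j
    lam_t = np.tile([1.0, lambda_T2], j)
    lam_i = np.tile([0.0, 1.0], j)
    lam = np.zeros((p, 2 + j))
    lam[:, 0] = lam_t
    lam[:, 1] = lam_i
    for occ in range(j):
        lam[2 * occ : 2 * occ + 2, 2 + occ] = 1.0
    phi = np.diag([get("sigma2_T"), get("var_IST2")] + [get("var_O")] * j)
    theta = np.diag([get("var_E1")] * 2 + [get("var_Ej")] * (2 * (j - 1)))
    alpha = np.tile([0.0, get("alpha_2")], j)
    mu = alpha + lam_t * get("mu_T")
    sigma = lam @ phi @ lam.T + theta
    delta = lam_t * get("delta_T")
    return mu, sigma, delta


def build_class_moments(spec: LSTModelSpec, cp: LSTClassParams) -> RmstParams:
    """Observed-variable rMST parameters implied by one class's LST structure.

    mu = alpha + lambda_T * mu_T;  Sigma = Lambda Phi Lambda' + Theta;
    delta = lambda_T * delta_T;  nu = class nu.  Row order within the
    loading matrix is occasion-major (indicator 1 then 2 per occasion).
    """
    mu, sigma, delta = _moment_arrays(spec.n_occasions, cp)
    return RmstParams(mu=mu, sigma=sigma, delta=delta, nu=cp.nu)


def column_names(spec: LSTModelSpec) -> list[str]:
    """Observed-variable labels y_<indicator>_<occasion>, occasion-major."""
    return [
        f"y_{i}_{occ}"
        for occ in range(1, spec.n_occasions + 1)
        for i in (1, 2)
    ]


# ---------------------------------------------------------------------------
# packing: free-parameter vector <-> MixtureParams


def _to_packed(name: str, value: float) -> float:
    if name in LOG_SCALE_PARAMS:
        return float(np.log(value))
    if name == "nu":
        return float(np.log(value - NU_MIN))
    return float(value)


def _from_packed(name: str, value: float) -> float:
    if name in LOG_SCALE_PARAMS:
        return float(np.exp(value))
    if name == "nu":
        return float(min(NU_MIN + np.exp(value), NU_NORMAL_LIMIT))
    return float(value)


def pack_params(mp: MixtureParams, spec: LSTModelSpec) -> np.ndarray:
    """Flatten a MixtureParams into the transformed free-parameter vector."""
    if mp.n_classes != spec.n_classes:
        raise ValueError("class count mismatch between params and spec")
    theta = [
        _to_packed(name, getattr(cp, name))
        for cp in mp.class_params
        for name in spec.free_class_param_names
    ]
    if spec.n_classes == 2:
        theta.append(float(mp.logit_pi1))
    return np.array(theta)


def unpack_params(theta: np.ndarray, spec: LSTModelSpec) -> MixtureParams:
    """Inverse of :func:`pack_params`; fixed parameters come from the spec."""
    theta = np.asarray(theta, dtype=float)
    expected = spec.n_free_parameters
    if theta.shape != (expected,):
        raise ValueError(f"theta has shape {theta.shape}, expected ({expected},)")
    names = spec.free_class_param_names
    k = len(names)
    classes = []
    for c in range(spec.n_classes):
        block = theta[c * k : (c + 1) * k]
        kwargs = {name: _from_packed(name, val) for name, val in zip(names, block)}
        kwargs.update({name: float(v) for name, v in spec.fixed.items()})
        classes.append(LSTClassParams(**kwargs))
    logit = float(theta[-1]) if spec.n_classes == 2 else 0.0
    return MixtureParams(class_params=tuple(classes), logit_pi1=logit)


def reporting_scale_jacobian(theta: np.ndarray, spec: LSTModelSpec) -> np.ndarray:
    """d(reported parameter)/d(packed parameter), one entry per coordinate.

    The packing transforms are coordinatewise, so the Jacobian is diagonal;
    used for delta-method standard errors on the reporting scale.
    """
    theta = np.asarray(theta, dtype=float)
    names = spec.free_class_param_names
    jac = np.ones_like(theta)
    idx = 0
    for _ in range(spec.n_classes):
        for name in names:
            if name in LOG_SCALE_PARAMS or name == "nu":
                jac[idx] = np.exp(theta[idx])
            idx += 1
    return jac


def truth_vector(mp: MixtureParams, spec: LSTModelSpec) -> np.ndarray:
    """Free parameters of ``mp`` on the reporting (untransformed) scale."""
    values = [
        float(getattr(cp, name))
        for cp in mp.class_params
        for name in spec.free_class_param_names
    ]
    if spec.n_classes == 2:
        values.append(float(mp.logit_pi1))
    return np.array(values)


def default_fixture(delta_T: float = 2.8, nu: float = 5.0) -> MixtureParams:
    """Illustrative two-class population values for simulation fixtures.

    These are package defaults chosen to satisfy the documented ordering
    constraints of the design (class 1 larger, with lower trait location,
    larger trait scale, larger occasion-specific and residual variances, and
    a larger first-occasion error variance); they are not estimates from any
    dataset.  The trait skewness and degrees of freedom are shared by both
    classes at generation but estimated per class.
    """
    class1 = LSTClassParams(
        lambda_T2=0.9,
        alpha_2=0.2,
        mu_T=1.0,
        sigma2_T=0.8,
        delta_T=delta_T,
        nu=nu,
        var_IST2=0.3,
        var_O=0.5,
        var_E1=0.5,
        var_Ej=0.35,
    )
    class2 = LSTClassParams(
        lambda_T2=1.1,
        alpha_2=-0.1,
        mu_T=2.0,
        sigma2_T=0.3,
        delta_T=delta_T,
        nu=nu,
        var_IST2=0.15,
        var_O=0.2,
        var_E1=0.25,
        var_Ej=0.15,
    )
    return MixtureParams(class_params=(class1, class2), logit_pi1=1.15)


def with_delta(mp: MixtureParams, delta_T: float) -> MixtureParams:
    """Copy of ``mp`` with the trait skewness replaced in every class."""
    return MixtureParams(
        class_params=tuple(replace(cp, delta_T=delta_T) for cp in mp.class_params),
        logit_pi1=mp.logit_pi1,
    )
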