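"""Monte Carlo data generation over the simulation design grid.

The full grid crosses sample size {125, 250, 500, 1000}, number of occasions
{2..6} and trait skewness {2.8, 6} — 40 cells, 500 planned replications each
by default.  Class labels are drawn from the design logit (1.15, a 76/24
split), then rows are sampled from each class's observed-variable rMST
distribution.  True labels are retained for oracle testing only; the
estimator never sees them.

Seeding: every replication derives its stream from
``SeedSequence((base_seed, condition_key, rep_index))`` so any single
replication is reproducible in isolation and replications are independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import lst_spec
from .lst_spec import LSTClassParams, LSTModelSpec, MixtureParams
from .rmst_core import rmst_sample

__all__ = [
    "DEFAULT_N_LEVELS",
    "DEFAULT_OCCASION_LEVELS",
    "DEFAULT_SKEW_LEVELS",
    "SimCondition",
    "SimDataset",
    "enumerate_conditions",
    "simulate_class_factorwise",
    "simulate_dataset",
]

DEFAULT_N_LEVELS: tuple[int, ...] = (125, 250, 500, 1000)
DEFAULT_OCCASION_LEVELS: tuple[int, ...] = (2, 3, 4, 5, 6)
DEFAULT_SKEW_LEVELS: tuple[float, ...] = (2.8, 6.0)
DEFAULT_N_REPS = 500


@dataclass(frozen=True)
class SimCondition:
    """One cell of the design grid."""

    N: int
    n_occasions: int
    delta_T: float
    n_reps: int = DEFAULT_N_REPS
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.n_reps < 1:
            raise ValueError("N and n_reps must be positive")

    @property
    def key(self) -> int:
        """Stable integer identifying the cell (used in seed derivation)."""
        return self.N * 10_000 + self.n_occasions * 100 + int(round(self.delta_T * 10))

    @property
    def label(self) -> str:
        return f"N={self.N},j={self.n_occasions},skew={self.delta_T:g}"

    def spec(self, n_classes: int = 2) -> LSTModelSpec:
        return LSTModelSpec(n_occasions=self.n_occasions, n_classes=n_classes)


@dataclass(frozen=True, eq=False)
class SimDataset:
    """One generated replication: data matrix plus true class labels."""

    data: np.ndarray
    true_class: np.ndarray
    condition: SimCondition
    rep_index: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        spec = self.condition.spec()
        df = pd.DataFrame(self.data, columns=lst_spec.column_names(spec))
        df["true_class"] = self.true_class
        return df


def enumerate_conditions(
    n_levels: Sequence[int] = DEFAULT_N_LEVELS,
    occasion_levels: Sequence[int] = DEFAULT_OCCASION_LEVELS,
    skew_levels: Sequence[float] = DEFAULT_SKEW_LEVELS,
    n_reps: int = DEFAULT_N_REPS,
    base_seed: int = 0,
) -> list[SimCondition]:
    """Cartesian product of the design factors, in stable (N, j, skew) order."""
    if not (n_levels and occasion_levels and skew_levels):
        raise ValueError("every factor needs at least one level")
    return [
        SimCondition(N=n, n_occasions=j, delta_T=s, n_reps=n_reps, base_seed=base_seed)
        for n, j, s in itertools.product(n_levels, occasion_levels, skew_levels)
    ]


def _replication_rng(cond: SimCondition, rep_index: int) -> tuple[np.random.Generator, int]:
    seq = np.random.SeedSequence((cond.base_seed, cond.key, rep_index))
    seed = int(seq.generate_state(1)[0])
    return np.random.default_rng(seq), seed


def simulate_dataset(
    cond: SimCondition, rep_index: int, truth: MixtureParams
) -> SimDataset:
    """Generate one replication of the mixture LST design.

    Class labels follow Bernoulli(pi_1) with pi_1 from the truth logit; rows
    are then drawn from the class-specific observed rMST distributions.
    Deterministic given (base_seed, condition, rep_index).
    """
    if abs(truth.class_params[0].delta_T - cond.delta_T) > 1e-12:
        raise ValueError("truth delta_T inconsistent with condition")
    spec = cond.spec()
    rng, seed = _replication_rng(cond, rep_index)
    pi1 = truth.pi[0]
    labels = np.where(rng.random(cond.N) < pi1, 1, 2)
    data = np.empty((cond.N, spec.p))
    for c in (1, 2):
        idx = np.flatnonzero(labels == c)
        if idx.size:
            params = lst_spec.build_class_moments(spec, truth.class_params[c - 1])
            data[idx] = rmst_sample(params, idx.size, seed=rng)
    return SimDataset(
        data=data, true_class=labels, condition=cond, rep_index=rep_index, seed=seed
    )


def simulate_class_factorwise(
    spec: LSTModelSpec,
    cp: LSTClassParams,
    n: int,
    rng: np.random.Generator,
    shared_mixing: bool = True,
) -> np.ndarray:
    """Generate one class's data factor by factor (oracle path).

    Builds observations from explicit trait, indicator-specific trait
    residual, occasion and error draws rather than from the collapsed
    observed-variable distribution.  With ``shared_mixing=True`` (default)
    all components divide by the same sqrt(W), so the result is exactly rMST
    and must match :func:`~skewtlst.lst_spec.build_class_moments`; with
    ``False`` the non-trait components are independent normals, the
    convention under which the observed vector is only approximately rMST.
    """
    j = spec.n_occasions
    w = rng.gamma(shape=cp.nu / 2.0, scale=2.0 / cp.nu, size=n)
    scale = 1.0 / np.sqrt(w)
    u0 = np.abs(rng.standard_normal(n))
    xi = (cp.delta_T * u0 + np.sqrt(cp.sigma2_T) * rng.standard_normal(n)) * scale
    trait = cp.mu_T + xi
    resid_scale = scale if shared_mixing else np.ones(n)
    ist2 = np.sqrt(cp.var_IST2) * rng.standard_normal(n) * resid_scale
    occ = np.sqrt(cp.var_O) * rng.standard_normal((n, j)) * resid_scale[:, None]
    y = np.empty((n, spec.p))
    for occ_idx in range(j):
        e_var = cp.var_E1 if occ_idx == 0 else cp.var_Ej
        err = np.sqrt(e_var) * rng.standard_normal((n, 2)) * resid_scale[:, None]
        y[:, 2 * occ_idx] = trait + occ[:, occ_idx] + err[:, 0]
        y[:, 2 * occ_idx + 1] = (
            cp.alpha_2 + cp.lambda_T2 * trait + ist2 + occ[:, occ_idx] + err[:, 1]
        )
    return y
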