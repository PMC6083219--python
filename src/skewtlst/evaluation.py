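"""Evaluation criteria for the Monte Carlo study.

Per condition and parameter the module computes

* peb  — mean relative deviation of the estimates from the population value,
* seb  — mean relative deviation of the reported SEs from the empirical SD
         of the estimates over the included replications,
* MSE  — mean squared deviation from the population value (raw scale),
* coverage — share of replications whose 95% Wald interval covers the truth,

and classifies them against the usual cut-offs: |peb|, |seb| <= 0.1
acceptable, <= 0.3 medium, above large; coverage acceptable in
[0.91, 0.98].
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lst_spec
from .estimator import FitResult
from .lst_spec import LSTModelSpec, MixtureParams

__all__ = [
    "build_eval_table",
    "classify_coverage",
    "classify_criteria",
    "compute_coverage",
    "compute_mse",
    "compute_peb",
    "compute_seb",
    "summarize_condition",
]

PEB_ACCEPTABLE = 0.1
PEB_LARGE = 0.3
COVERAGE_BAND = (0.91, 0.98)


def compute_peb(
    estimates: Sequence[float], theta_true: float, aggregate: str = "mean"
) -> float:
    """Signed relative parameter-estimation bias averaged over replications."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one replication")
    if theta_true == 0:
        raise ZeroDivisionError("peb undefined for a zero population value")
    rel = (est - theta_true) / theta_true
    agg = np.median if aggregate == "median" else np.mean
    return float(agg(rel))


def compute_seb(
    ses: Sequence[float], estimates: Sequence[float], aggregate: str = "mean"
) -> float:
    """Relative SE bias: reported SEs against the empirical SD of estimates."""
    ses = np.asarray(ses, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least two replications for the empirical SD")
    sd = float(np.std(est, ddof=1))
    if sd == 0:
        raise ZeroDivisionError("seb undefined for zero empirical SD")
    rel = (ses - sd) / sd
    agg = np.median if aggregate == "median" else np.mean
    return float(agg(rel))


def compute_mse(estimates: Sequence[float], theta_true: float) -> float:
    """Mean squared error on the raw parameter scale."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one replication")
    return float(np.mean((est - theta_true) ** 2))


def compute_coverage(
    estimates: Sequence[float],
    ses: Sequence[float],
    theta_true: float,
    level: float = 0.95,
) -> float:
    """Share of per-replication Wald intervals that contain the truth.

    Replications without a usable SE (NaN) are dropped from the denominator.
    """
    est = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(ses) & np.isfinite(est)
    if not ok.any():
        raise ValueError("no replications with standard errors")
    if level >= 1.0:
        return 1.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = est[ok] - z * ses[ok]
    hi = est[ok] + z * ses[ok]
    return float(np.mean((lo <= theta_true) & (theta_true <= hi)))


def classify_criteria(value: float, kind: str = "bias") -> str:
    """Threshold label for one criterion value.

    ``kind='bias'`` (peb/seb): |v| <= 0.1 acceptable, <= 0.3 medium, else
    large.  ``kind='coverage'``: below 0.91 low, above 0.98 high, else
    acceptable.
    """
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if kind == "coverage":
        return classify_coverage(value)
    v = abs(value)
    if v <= PEB_ACCEPTABLE:
        return "acceptable"
    if v <= PEB_LARGE:
        return "medium"
    return "large"


def classify_coverage(value: float) -> str:
    lo, hi = COVERAGE_BAND
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "acceptable"


def build_eval_table(
    fits: Iterable[FitResult],
    truth: MixtureParams,
    spec: LSTModelSpec,
    condition: str = "",
    aggregate: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Per-parameter criteria over the included replications of one condition.

    ``fits`` must already be relabeled and filtered.  Coverage uses only the
    replications that carry standard errors.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no included replications")
    names = lst_spec.free_param_names(spec)
    truth_vec = lst_spec.truth_vector(truth, spec)
    est = np.array([lst_spec.truth_vector(f.estimates, f.spec or spec) for f in fits])
    ses = np.array(
        [
            f.standard_errors
            if f.standard_errors is not None
            else np.full(len(names), np.nan)
            for f in fits
        ]
    )
    rows = []
    for k, name in enumerate(names):
        peb = compute_peb(est[:, k], truth_vec[k], aggregate=aggregate)
        if np.isfinite(ses[:, k]).any() and est.shape[0] >= 2:
            try:
                seb = compute_seb(
                    ses[:, k][np.isfinite(ses[:, k])], est[:, k], aggregate=aggregate
                )
            except ZeroDivisionError:  # constant estimates in a toy run
                seb = np.nan
        else:
            seb = np.nan
        mse = compute_mse(est[:, k], truth_vec[k])
        cov = (
            compute_coverage(est[:, k], ses[:, k], truth_vec[k])
            if np.isfinite(ses[:, k]).any()
            else np.nan
        )
        rows.append(
            dict(
                condition=condition,
                parameter=name,
                truth=truth_vec[k],
                peb=peb,
                seb=seb,
                mse=mse,
                coverage=cov,
                n_included=est.shape[0],
                peb_label=classify_criteria(peb),
                seb_label=classify_criteria(seb) if np.isfinite(seb) else "",
                coverage_label=classify_coverage(cov) if np.isfinite(cov) else "",
            )
        )
    return pd.DataFrame(rows)


def plot_condition(table: pd.DataFrame, path: str, kind: str = "mse") -> None:
    """Write a quick-look bar chart of per-parameter MSE (or |peb|/|seb|)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = table["mse"] if kind == "mse" else table[kind].abs()
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(table["parameter"], values)
    ax.set_ylabel(kind)
    ax.set_title(str(table["condition"].iloc[0]))
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def summarize_condition(table: pd.DataFrame, n_params_expected: int | None = None) -> dict:
    """Across-parameter summary for one condition's evaluation rows."""
    if n_params_expected is not None and len(table) != n_params_expected:
        missing = n_params_expected - len(table)
        raise ValueError(f"expected {n_params_expected} parameter rows, off by {missing}")
    cov = table["coverage"].dropna()
    return dict(
        condition=table["condition"].iloc[0] if len(table) else "",
        n_included=int(table["n_included"].iloc[0]),
        mean_abs_peb=float(table["peb"].abs().mean()),
        mean_abs_seb=float(table["seb"].abs().mean()),
        mean_mse=float(table["mse"].mean()),
        n_peb_exceed=int((table["peb"].abs() > PEB_ACCEPTABLE).sum()),
        n_seb_exceed=int((table["seb"].abs() > PEB_ACCEPTABLE).sum()),
        n_coverage_exceed=int(
            ((cov < COVERAGE_BAND[0]) | (cov > COVERAGE_BAND[1])).sum()
        ),
    )
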