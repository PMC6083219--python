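"""Label-switching handling and replication inclusion rules.

A two-class mixture likelihood is invariant to permuting the class labels,
so raw fits must be screened before evaluation.  The decision rules operate
purely on the estimates (the only information available post hoc):

* estimated class-1 proportion inside [0.40, 0.60] -> excluded, separation
  too ambiguous to decide which class is which;
* proportion below 0.40 with BOTH a lower trait scale AND a higher trait
  location in class 1 -> labels swapped, replication retained;
* exactly one of the two swap criteria -> excluded as ambiguous;
* otherwise labels are kept and the replication proceeds to the warning
  screen (non-converged fits and fits with any warning flag are excluded).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .estimator import FitResult
from .lst_spec import MixtureParams

__all__ = [
    "MIN_INCLUDED",
    "ReplicationStatus",
    "apply_inclusion_filter",
    "class1_proportion",
    "detect_label_switch",
    "swap_labels",
]

SEPARATION_BAND = (0.40, 0.60)

# Conditions retaining fewer included replications than this are flagged as
# insufficient for performance summaries.
MIN_INCLUDED = 50

REASONS = ("ok", "nonconverged", "warning", "ambiguous_separation", "ambiguous_label")


@dataclass(frozen=True)
class ReplicationStatus:
    included: bool
    reason: str
    labels_swapped: bool = False

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if (self.reason == "ok") != self.included:
            raise ValueError("reason 'ok' must coincide with inclusion")


def class1_proportion(
    fit: FitResult, data: np.ndarray | None = None, method: str = "mixing"
) -> float:
    """Estimated class-1 share, from the mixing weight (default) or from the
    most-likely-class assignment counts when ``data`` is supplied."""
    if method == "mixing":
        return fit.estimated_class1_proportion
    if method == "assignment":
        if data is None:
            raise ValueError("assignment method requires data")
        from . import lst_spec
        from .rmst_core import rmst_logpdf

        spec = fit.spec
        mp = fit.estimates
        log_pi = np.log(mp.pi)
        scores = np.stack(
            [
                log_pi[c] + rmst_logpdf(lst_spec.build_class_moments(spec, cp), data)
                for c, cp in enumerate(mp.class_params)
            ]
        )
        return float(np.mean(np.argmax(scores, axis=0) == 0))
    raise ValueError(f"unknown method {method!r}")


def swap_labels(fit: FitResult) -> FitResult:
    """Exchange the class parameter blocks and flip the logit sign.

    An involution; leaves the log-likelihood untouched.  Standard errors are
    permuted to follow their parameters.
    """
    spec = fit.spec
    swapped = fit.estimates.swapped()
    se = fit.standard_errors
    theta = fit.theta
    k = len(spec.free_class_param_names)
    perm = np.concatenate([np.arange(k, 2 * k), np.arange(k), [2 * k]]).astype(int)
    if se is not None:
        se = np.asarray(se)[perm]
    if theta is not None:
        theta = np.asarray(theta)[perm].copy()
        theta[-1] = -theta[-1]
    return dc_replace(
        fit,
        estimates=swapped,
        standard_errors=se,
        theta=theta,
        estimated_class1_proportion=1.0 - fit.estimated_class1_proportion,
    )


def detect_label_switch(
    fit: FitResult, truth: MixtureParams | None = None
) -> tuple[ReplicationStatus, FitResult]:
    """Classify one fit and relabel it if the swap criteria both hold.

    ``truth`` is accepted for interface symmetry but unused: the decision
    rules are functions of the estimates alone.
    """
    p1 = fit.estimated_class1_proportion
    lo, hi = SEPARATION_BAND
    if lo <= p1 <= hi:
        return ReplicationStatus(False, "ambiguous_separation"), fit
    if p1 < lo:
        cp1, cp2 = fit.estimates.class_params
        lower_scale = cp1.sigma2_T < cp2.sigma2_T
        higher_loc = cp1.mu_T > cp2.mu_T
        if lower_scale and higher_loc:
            return ReplicationStatus(True, "ok", labels_swapped=True), swap_labels(fit)
        if lower_scale or higher_loc:
            return ReplicationStatus(False, "ambiguous_label"), fit
    return ReplicationStatus(True, "ok"), fit


def apply_inclusion_filter(
    fits: list[tuple[FitResult, ReplicationStatus]],
) -> tuple[list[FitResult], dict[str, int]]:
    """Keep replications that converged, carry no warnings, and have an
    unambiguous labeling; return them with an exclusion tally by reason."""
    included: list[FitResult] = []
    tally: Counter[str] = Counter()
    for fit, status in fits:
        if not status.included:
            tally[status.reason] += 1
            continue
        if not fit.converged:
            tally["nonconverged"] += 1
            continue
        if fit.warnings:
            tally["warning"] += 1
            continue
        included.append(fit)
        tally["ok"] += 1
    return included, dict(tally)


def status_table(
    statuses: list[ReplicationStatus], fits: list[FitResult]
) -> pd.DataFrame:
    """Per-replication status as a flat table (rep, included, reason, swap)."""
    rows = []
    for rep, (status, fit) in enumerate(zip(statuses, fits)):
        reason = status.reason
        included = status.included
        if included and not fit.converged:
            included, reason = False, "nonconverged"
        elif included and fit.warnings:
            included, reason = False, "warning"
        rows.append(
            dict(
                rep=rep,
                included=included,
                reason=reason,
                labels_swapped=status.labels_swapped,
                converged=fit.converged,
                n_warnings=len(fit.warnings),
            )
        )
    return pd.DataFrame(rows)
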