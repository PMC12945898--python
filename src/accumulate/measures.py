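"""Derived subject-level measures: EEA, SEA and condition-averaged drift.

Efficiency of evidence accumulation (EEA) is the average, across task
conditions, of the difference between the matching and mismatching
accumulator rates; it indexes how selectively a subject accumulates
task-relevant evidence.  Speed of evidence accumulation (SEA) is the
average, across conditions, of the mean of the two rates; it indexes how
fast evidence accumulates regardless of its quality.  The two are an
invertible linear map of the condition-averaged rates: adding a constant
to both rates in every condition leaves EEA unchanged and shifts SEA
one-to-one.  The DDM's drift is averaged over the same condition set.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import FitResult


class MissingConditionError(KeyError):
    pass


def _check_conditions(v_match: Mapping[str, float],
                      v_mismatch: Mapping[str, float]) -> list[str]:
    only_m = set(v_match) - set(v_mismatch)
    only_mm = set(v_mismatch) - set(v_match)
    if only_m or only_mm:
        raise MissingConditionError(
            f"condition sets differ: missing mismatch rates for {sorted(only_m)}, "
            f"missing match rates for {sorted(only_mm)}"
        )
    if not v_match:
        raise MissingConditionError("no conditions supplied")
    return sorted(v_match)


def compute_eea(v_match: Mapping[str, float],
                v_mismatch: Mapping[str, float]) -> float:
    """Mean over conditions of (v_match[c] - v_mismatch[c])."""
    conds = _check_conditions(v_match, v_mismatch)
    return float(np.mean([v_match[c] - v_mismatch[c] for c in conds]))


def compute_sea(v_match: Mapping[str, float],
                v_mismatch: Mapping[str, float]) -> float:
    """Mean over conditions of (v_match[c] + v_mismatch[c]) / 2."""
    conds = _check_conditions(v_match, v_mismatch)
    return float(np.mean([(v_match[c] + v_mismatch[c]) / 2.0 for c in conds]))


def compute_v_mean(v: Mapping[str, float]) -> float:
    """Unweighted mean of the DDM's condition-wise drift rates."""
    if not v:
        raise MissingConditionError("no conditions supplied")
    return float(np.mean(list(v.values())))


def _rates_from_fit(fit: FitResult, summary: str = "mean"):
    point = (fit.posterior_mean() if summary == "mean"
             else fit.posterior_median())
    conds = fit.spec.design.conditions
    if fit.model == "lba":
        v_match = {c: point[f"v_{c}_match"] for c in conds}
        v_mismatch = {c: point[f"v_{c}_mismatch"] for c in conds}
        return v_match, v_mismatch
    return {c: point[f"v_{c}"] for c in conds}


def measures_from_fits(fit_lba: FitResult, fit_ddm: FitResult | None = None,
                       summary: str = "mean") -> dict:
    """EEA/SEA (and v_mean when a DDM fit is supplied) for one subject."""
    if fit_lba.model != "lba":
        raise ValueError("first fit must be an LBA fit")
    v_match, v_mismatch = _rates_from_fit(fit_lba, summary)
    row = {
        "subject": fit_lba.subject_id,
        "task": fit_lba.task,
        "EEA": compute_eea(v_match, v_mismatch),
        "SEA": compute_sea(v_match, v_mismatch),
        "converged_lba": fit_lba.converged,
    }
    if fit_ddm is not None:
        if fit_ddm.model != "ddm":
            raise ValueError("second fit must be a DDM fit")
        if fit_ddm.subject_id != fit_lba.subject_id:
            raise ValueError("fits belong to different subjects")
        row["v_mean"] = compute_v_mean(_rates_from_fit(fit_ddm, summary))
        row["converged_ddm"] = fit_ddm.converged
    return row


def measures_table(lba_fits, ddm_fits=None, summary: str = "mean"
                   ) -> pd.DataFrame:
    """Subject-level table of EEA, SEA, v_mean and convergence flags."""
    ddm_by_subject = {}
    if ddm_fits is not None:
        ddm_by_subject = {f.subject_id: f for f in ddm_fits}
    rows = [
        measures_from_fits(f, ddm_by_subject.get(f.subject_id), summary)
        for f in lba_fits
    ]
    return pd.DataFrame(rows)
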