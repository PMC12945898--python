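"""Trial-level choice/RT data: loading, validation, quality control, summaries.

The universal input is a long-format trial table, one row per trial, with
columns ``subject``, ``task``, ``condition``, ``response`` and ``rt``
(seconds; empty for omitted trials), plus optional nesting columns such as
``family`` and ``site``.  Data are grouped into one :class:`SubjectDataset`
per subject.

Quality control follows the convention common in large-cohort accumulation
modelling: a subject is excluded when their accuracy over responded trials
falls below 55% or when more than 25% of their trials are omissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tasks import OMITTED, TaskDesign, get_task

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)

#: default mapping from schema roles to column headers
DEFAULT_SCHEMA = {
    "subject": "subject",
    "task": "task",
    "condition": "condition",
    "response": "response",
    "rt": "rt",
}


class SchemaError(ValueError):
    """A required column is missing or cannot be interpreted."""


class ValidationError(ValueError):
    """A trial row violates an invariant (e.g. negative RT)."""


@dataclass
class Trial:
    subject_id: str
    task: str
    condition: str
    response: str  # response option or tasks.OMITTED
    rt: float | None  # seconds; None iff omitted
    correct: bool | None  # None iff omitted

    @property
    def omitted(self) -> bool:
        return self.response == OMITTED


@dataclass
class SubjectDataset:
    """All trials of one subject on one task."""

    subject_id: str
    task: str
    trials: pd.DataFrame  # columns: condition, response, rt, correct
    response_window: float
    nesting: dict[str, str] = field(default_factory=dict)

    @property
    def design(self) -> TaskDesign:
        return get_task(self.task)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def omission_rate(self) -> float:
        if self.n_trials == 0:
            return float("nan")
        return float((self.trials["response"] == OMITTED).mean())

    @property
    def accuracy(self) -> float:
        """Proportion correct among responded trials (NaN if none responded)."""
        responded = self.trials[self.trials["response"] != OMITTED]
        if len(responded) == 0:
            return float("nan")
        return float(responded["correct"].mean())

    def iter_trials(self) -> Iterable[Trial]:
        for row in self.trials.itertuples(index=False):
            yield Trial(
                subject_id=self.subject_id,
                task=self.task,
                condition=row.condition,
                response=row.response,
                rt=None if row.response == OMITTED else float(row.rt),
                correct=None if row.response == OMITTED else bool(row.correct),
            )

    def to_frame(self) -> pd.DataFrame:
        out = self.trials.copy()
        out.insert(0, "task", self.task)
        out.insert(0, "subject", self.subject_id)
        for k, v in self.nesting.items():
            out[k] = v
        return out


def make_dataset(
    subject_id: str,
    task: str,
    condition: Sequence[str],
    response: Sequence[str],
    rt: Sequence[float | None],
    nesting: Mapping[str, str] | None = None,
    window: float | None = None,
) -> SubjectDataset:
    """Assemble a validated :class:`SubjectDataset` from parallel sequences."""
    design = get_task(task)
    df = pd.DataFrame(
        {
            "condition": np.asarray(condition, dtype=object),
            "response": np.asarray(response, dtype=object),
            "rt": [np.nan if r is None else float(r) for r in rt],
        }
    )
    expected = df["condition"].map(design.correct_response)
    df["correct"] = np.where(
        df["response"] == OMITTED, np.nan, (df["response"] == expected).astype(float)
    )
    ds = SubjectDataset(
        subject_id=str(subject_id),
        task=design.name,
        trials=df,
        response_window=design.window if window is None else float(window),
        nesting=dict(nesting or {}),
    )
    _validate(ds)
    return ds


def _validate(ds: SubjectDataset) -> None:
    design = ds.design
    df = ds.trials
    bad_cond = sorted(set(df["condition"]) - set(design.conditions))
    if bad_cond:
        raise ValidationError(
            f"subject {ds.subject_id}: conditions {bad_cond} are not part of "
            f"task {design.name!r} (expected {list(design.conditions)})"
        )
    bad_resp = sorted(set(df["response"]) - set(design.responses) - {OMITTED})
    if bad_resp:
        raise ValidationError(
            f"subject {ds.subject_id}: responses {bad_resp} are not options of "
            f"task {design.name!r}"
        )
    responded = df["response"] != OMITTED
    rts = df.loc[responded, "rt"]
    if rts.isna().any():
        rows = df.index[responded & df["rt"].isna()].tolist()
        raise ValidationError(
            f"subject {ds.subject_id}: responded trials without RT at rows {rows}"
        )
    if (rts <= 0).any():
        rows = df.index[responded & (df["rt"] <= 0)].tolist()
        raise ValidationError(
            f"subject {ds.subject_id}: non-positive RT at rows {rows}"
        )
    if df.loc[~responded, "rt"].notna().any():
        rows = df.index[~responded & df["rt"].notna()].tolist()
        raise ValidationError(
            f"subject {ds.subject_id}: omitted trials with an RT at rows {rows}"
        )
    if len(rts) and float(rts.median()) > 100:
        raise ValidationError(
            f"subject {ds.subject_id}: median RT {rts.median():.0f} suggests "
            "milliseconds; RTs must be supplied in seconds"
        )
    over = responded & (df["rt"] > ds.response_window)
    if over.any():
        rows = df.index[over].tolist()
        raise ValidationError(
            f"subject {ds.subject_id}: RT exceeds the {ds.response_window:g}-s "
            f"response window at rows {rows}"
        )


def load_trials(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[SubjectDataset]:
    """Read a delimited trial table into one :class:`SubjectDataset` per subject.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping from the roles ``subject, task, condition, response,
        rt`` to the actual column headers; unmapped extra columns are treated
        as nesting factors (constant per subject).
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, sep=sep, dtype={colmap["subject"]: str})
    missing = [c for c in colmap.values() if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    # 'correct' is derived on load; anything else unmapped is a nesting factor
    nest_cols = [c for c in df.columns if c not in colmap and c != "correct"]
    df["rt"] = pd.to_numeric(df["rt"], errors="coerce")
    df["response"] = df["response"].fillna(OMITTED).astype(str)

    datasets = []
    for (subj, task), grp in df.groupby(["subject", "task"], sort=True):
        nesting = {}
        for c in nest_cols:
            vals = grp[c].dropna().unique()
            if len(vals):
                nesting[c] = str(vals[0])
        try:
            ds = make_dataset(
                subj,
                task,
                grp["condition"].astype(str).tolist(),
                grp["response"].tolist(),
                [None if pd.isna(r) else r for r in grp["rt"]],
                nesting=nesting,
            )
        except ValidationError as err:
            # report positions in the source file, not group-local ones
            raise ValidationError(f"{path}: {err} (0-based data rows)") from None
        datasets.append(ds)
    return datasets


def write_trials(datasets: Iterable[SubjectDataset], path, sep: str = ",") -> None:
    """Write datasets back to a delimited trial table (inverse of load_trials)."""
    frames = [ds.to_frame() for ds in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


@dataclass
class Exclusion:
    dataset: SubjectDataset
    reason: str


def apply_qc(
    datasets: Sequence[SubjectDataset],
    accuracy_floor: float = 0.55,
    omission_ceiling: float = 0.25,
) -> tuple[list[SubjectDataset], list[Exclusion]]:
    """Partition subjects into retained and excluded-with-reason.

    A subject is excluded when accuracy over responded trials is below
    ``accuracy_floor``, or when the omission rate over all trials exceeds
    ``omission_ceiling``.  A subject with no responded trials at all is
    excluded with reason ``"no responses"``.
    """
    retained: list[SubjectDataset] = []
    excluded: list[Exclusion] = []
    for ds in datasets:
        n_resp = int((ds.trials["response"] != OMITTED).sum())
        if n_resp == 0:
            excluded.append(Exclusion(ds, "no responses"))
            continue
        reasons = []
        if ds.accuracy < accuracy_floor:
            reasons.append(f"accuracy {ds.accuracy:.3f} < {accuracy_floor:g}")
        if ds.omission_rate > omission_ceiling:
            reasons.append(
                f"omission rate {ds.omission_rate:.3f} > {omission_ceiling:g}"
            )
        if reasons:
            excluded.append(Exclusion(ds, "; ".join(reasons)))
        else:
            retained.append(ds)
    return retained, excluded


def rt_quantiles(rts: np.ndarray, probs: Sequence[float] = RT_QUANTILES) -> np.ndarray:
    """RT quantiles by linear interpolation between order statistics."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        return np.full(len(probs), np.nan)
    return np.quantile(rts, probs, method="linear")


def summarize(ds: SubjectDataset, min_count: int = 5) -> pd.DataFrame:
    """Per-condition response proportions, omission proportion and RT quantiles.

    Returns a tidy frame with one row per (condition, response) cell, where
    ``response`` includes the omission category.  Within a condition the
    ``proportion`` column sums to 1 over all rows.  Cells with fewer than
    ``min_count`` trials are flagged ``low_n`` and their quantiles are still
    reported (NaN when the cell is empty).
    """
    design = ds.design
    rows = []
    for cond in design.conditions:
        sub = ds.trials[ds.trials["condition"] == cond]
        n_cond = len(sub)
        for resp in (*design.responses, OMITTED):
            cell = sub[sub["response"] == resp]
            n = len(cell)
            prop = n / n_cond if n_cond else np.nan
            if resp == OMITTED:
                qs = np.full(len(RT_QUANTILES), np.nan)
            else:
                qs = rt_quantiles(cell["rt"].to_numpy())
            row = {
                "condition": cond,
                "response": resp,
                "n": n,
                "proportion": prop,
                "low_n": bool(n < min_count),
            }
            row.update({f"q{int(100 * p)}": q for p, q in zip(RT_QUANTILES, qs)})
            rows.append(row)
    return pd.DataFrame(rows)


def measures_frame(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Subject-level accuracy/omission/mean-RT overview table."""
    rows = []
    for ds in datasets:
        responded = ds.trials[ds.trials["response"] != OMITTED]
        rows.append(
            {
                "subject": ds.subject_id,
                "task": ds.task,
                "n_trials": ds.n_trials,
                "accuracy": ds.accuracy,
                "omission_rate": ds.omission_rate,
                "mean_rt": float(responded["rt"].mean()) if len(responded) else np.nan,
                **ds.nesting,
            }
        )
    return pd.DataFrame(rows)
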