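"""Posterior predictive checks for fitted choice/RT models.

For a sample of posterior draws, a dataset with the observed per-condition
trial counts is simulated from the fitted model and summarized exactly like
the data (response proportions and RT quantiles at .1/.3/.5/.7/.9); the
observed statistics are then compared with the median and 2.5/97.5
percentiles of their predictive distribution, cell by cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import ddm as ddm_mod
from . import lba as lba_mod
from .fitting import FitResult
from .tasks import OMITTED
from .trial_data import RT_QUANTILES, SubjectDataset, summarize

_STATS = ["proportion"] + [f"q{int(100 * p)}" for p in RT_QUANTILES]


def simulate_from_draw(fit: FitResult, draw: np.ndarray,
                       n_per_condition, window: float,
                       rng: np.random.Generator) -> SubjectDataset:
    """Simulate one dataset from a single natural-scale posterior draw."""
    params = fit.spec.params_from_natural(draw)
    if fit.model == "lba":
        return lba_mod.lba_simulate(params, fit.spec.design, n_per_condition,
                                    window=window, seed=rng)
    return ddm_mod.ddm_simulate(params, fit.spec.design, n_per_condition,
                                window=window, seed=rng)


def posterior_predictive(dataset: SubjectDataset, fit: FitResult,
                         n_draws: int = 100, seed=None) -> pd.DataFrame:
    """Observed vs model-predicted summary statistics per condition cell.

    Returns a tidy frame with columns ``condition, response, statistic,
    observed, predicted_median, lo, hi`` where ``lo``/``hi`` are the 2.5
    and 97.5 percentiles over posterior draws.  Response categories the
    model never produces get predicted proportion 0 and absent quantiles.
    """
    if not fit.converged:
        warnings.warn(
            f"subject {fit.subject_id}: posterior predictive check on a "
            "non-converged fit"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = dataset.trials["condition"].value_counts().to_dict()
    obs = summarize(dataset, min_count=0)

    flat = fit.samples.flat("natural")
    idx = rng.choice(flat.shape[0], size=n_draws, replace=n_draws > flat.shape[0])
    predicted = []
    for i in idx:
        sim = simulate_from_draw(fit, flat[i], counts,
                                 dataset.response_window, rng)
        predicted.append(summarize(sim, min_count=0))

    pred_all = pd.concat(predicted, ignore_index=True)
    grouped = pred_all.groupby(["condition", "response"])
    rows = []
    for _, orow in obs.iterrows():
        cond, resp = orow["condition"], orow["response"]
        cell_pred = grouped.get_group((cond, resp))
        for stat in _STATS:
            if resp == OMITTED and stat != "proportion":
                continue
            pred = cell_pred[stat].to_numpy(dtype=float)
            finite = pred[np.isfinite(pred)]
            if finite.size:
                med, lo, hi = np.percentile(finite, [50, 2.5, 97.5])
            else:
                med = lo = hi = np.nan
            rows.append(
                {
                    "condition": cond,
                    "response": resp,
                    "statistic": stat,
                    "observed": orow[stat],
                    "predicted_median": med,
                    "lo": lo,
                    "hi": hi,
                    "n_pred_finite": int(finite.size),
                }
            )
    return pd.DataFrame(rows)


def coverage(ppc_table: pd.DataFrame) -> float:
    """Fraction of observed cells inside their 95% predictive interval.

    Cells with undefined observed or predicted values (e.g. empty RT cells)
    are left out of the denominator.
    """
    t = ppc_table
    ok = np.isfinite(t["observed"]) & np.isfinite(t["lo"]) & np.isfinite(t["hi"])
    t = t[ok]
    if len(t) == 0:
        return float("nan")
    inside = (t["observed"] >= t["lo"]) & (t["observed"] <= t["hi"])
    return float(inside.mean())


def plot_ppc(ppc_table: pd.DataFrame, ax=None):
    """Cumulative-probability-by-quintile display of a predictive check.

    For each condition, plots observed (open) and predicted (filled) RT
    quintiles at heights equal to the cumulative response probability —
    the conventional layout for assessing joint fit of choice proportions
    and RT distributions.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conds = ppc_table["condition"].unique()
    fig, axes = plt.subplots(1, len(conds), figsize=(4 * len(conds), 3.5),
                             squeeze=False)
    qcols = [f"q{int(100 * p)}" for p in RT_QUANTILES]
    for ax_, cond in zip(axes[0], conds):
        sub = ppc_table[ppc_table["condition"] == cond]
        for resp, style in zip(
                [r for r in sub["response"].unique() if r != OMITTED],
                ["-", "--", ":"]):
            cell = sub[sub["response"] == resp]
            p_obs = cell.loc[cell["statistic"] == "proportion", "observed"]
            p_pred = cell.loc[cell["statistic"] == "proportion",
                              "predicted_median"]
            q_obs = [cell.loc[cell["statistic"] == q, "observed"].iloc[0]
                     for q in qcols]
            q_pred = [cell.loc[cell["statistic"] == q,
                               "predicted_median"].iloc[0] for q in qcols]
            h_obs = float(p_obs.iloc[0]) * np.asarray(RT_QUANTILES)
            h_pred = float(p_pred.iloc[0]) * np.asarray(RT_QUANTILES)
            ax_.plot(q_obs, h_obs, style, color="red", marker="o",
                     mfc="none", label=f"{resp} observed")
            ax_.plot(q_pred, h_pred, style, color="black", marker="o",
                     label=f"{resp} predicted")
        ax_.set_title(cond)
        ax_.set_xlabel("RT quantile (s)")
        ax_.set_ylabel("cumulative probability")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    return fig
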