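"""Individual-subject Bayesian estimation for the LBA and DDM.

Each (model, task) pair defines a flat parameter vector, its priors, and a
likelihood evaluated for a whole batch of parameter vectors at once — the
DE-MCMC ensemble proposes all chains simultaneously, so the likelihood is
vectorized over chains as well as trials.

Parameterizations mirror common practice for these tasks: n-back designs
estimate condition-wise rates with a single threshold gap, numerosity
designs add response-specific threshold gaps (B_many, B_few); the DDM
estimates condition-wise drifts with a single boundary separation and a
relative start point.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ddm as ddm_mod
from . import lba as lba_mod
from .demcmc import PosteriorSamples, demcmc_sample, gelman_rubin_all
from .priors import Prior, PriorSpec, interval_prior, positive_prior, rate_prior
from .tasks import OMITTED, TaskDesign
from .trial_data import SubjectDataset

logger = logging.getLogger(__name__)

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss(n: int):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


# ---------------------------------------------------------------------------
# model specifications


def default_priors(model: str, design: TaskDesign) -> PriorSpec:
    """Broad priors covering published DDM/LBA parameter ranges."""
    priors: dict[str, Prior] = {}
    if model == "lba":
        for c in design.conditions:
            priors[f"v_{c}_match"] = rate_prior()
        for c in design.conditions:
            priors[f"v_{c}_mismatch"] = rate_prior()
        if design.response_specific_thresholds:
            for r in design.responses:
                priors[f"B_{r}"] = positive_prior()
        else:
            priors["B"] = positive_prior()
        priors["A"] = positive_prior()
        priors["t0"] = interval_prior(0.05, 1.0)
        priors["p_gf"] = interval_prior(0.0, 0.2)
        priors["sv_mismatch"] = positive_prior()
    elif model == "ddm":
        for c in design.conditions:
            priors[f"v_{c}"] = rate_prior()
        priors["a"] = positive_prior()
        priors["z_rel"] = interval_prior(0.05, 0.95)
        priors["Ter"] = interval_prior(0.05, 1.0)
        priors["st0"] = interval_prior(0.0, 0.5)
        priors["p_gf"] = interval_prior(0.0, 0.2)
    else:
        raise ValueError("model must be 'lba' or 'ddm'")
    return PriorSpec(priors)


@dataclass
class ModelSpec:
    model: str
    design: TaskDesign
    prior: PriorSpec
    t0_order: int = 11  # DDM nondecision-time quadrature order

    @property
    def names(self) -> list[str]:
        return self.prior.names

    def _col(self, nat: np.ndarray, name: str) -> np.ndarray:
        return nat[:, self.names.index(name)]

    def params_from_natural(self, vec: np.ndarray):
        """Build an LBAParams/DDMParams object from one natural-scale vector."""
        vals = dict(zip(self.names, np.asarray(vec, dtype=float)))
        d = self.design
        if self.model == "lba":
            if d.response_specific_thresholds:
                B = {r: vals[f"B_{r}"] for r in d.responses}
            else:
                B = {r: vals["B"] for r in d.responses}
            return lba_mod.LBAParams(
                v_match={c: vals[f"v_{c}_match"] for c in d.conditions},
                v_mismatch={c: vals[f"v_{c}_mismatch"] for c in d.conditions},
                A=vals["A"], B=B, t0=vals["t0"], p_gf=vals["p_gf"],
                sv_mismatch=vals["sv_mismatch"],
            )
        return ddm_mod.DDMParams(
            v={c: vals[f"v_{c}"] for c in d.conditions},
            a=vals["a"], z_rel=vals["z_rel"], Ter=vals["Ter"],
            st0=vals["st0"], p_gf=vals["p_gf"],
        )

    # -- data preparation ----------------------------------------------
    def _b_index(self, response: str) -> int:
        if self.design.response_specific_thresholds:
            return self.names.index(f"B_{response}")
        return self.names.index("B")

    def prepare(self, dataset: SubjectDataset) -> dict:
        """Flatten a dataset into gather-index arrays for the batch likelihood."""
        d = self.design
        prep = {"window": dataset.response_window, "cells": [], "n_omit": {}}
        rt_all, ivw, ivl, mw, ml, ibw, ibl = [], [], [], [], [], [], []
        iv_ddm, upper_ddm = [], []
        for cond in d.conditions:
            sub = dataset.trials[dataset.trials["condition"] == cond]
            if len(sub) == 0:
                continue
            prep["n_omit"][cond] = int((sub["response"] == OMITTED).sum())
            correct = d.correct_response[cond]
            for r in d.responses:
                rts = sub.loc[sub["response"] == r, "rt"].to_numpy(dtype=float)
                if rts.size == 0:
                    continue
                prep["cells"].append((cond, r, rts))
                m = rts.size
                rt_all.append(rts)
                if self.model == "lba":
                    other = [x for x in d.responses if x != r][0]
                    is_match = r == correct
                    win_v = f"v_{cond}_match" if is_match else f"v_{cond}_mismatch"
                    lose_v = f"v_{cond}_mismatch" if is_match else f"v_{cond}_match"
                    ivw += [self.names.index(win_v)] * m
                    ivl += [self.names.index(lose_v)] * m
                    mw += [is_match] * m
                    ml += [not is_match] * m
                    ibw += [self._b_index(r)] * m
                    ibl += [self._b_index(other)] * m
                else:
                    iv_ddm += [self.names.index(f"v_{cond}")] * m
                    upper_ddm += [r == correct] * m
        prep["rt"] = (np.concatenate(rt_all) if rt_all
                      else np.empty(0))
        if self.model == "lba":
            prep["ivw"] = np.array(ivw, dtype=np.intp)
            prep["ivl"] = np.array(ivl, dtype=np.intp)
            prep["mw"] = np.array(mw, dtype=bool)
            prep["ml"] = np.array(ml, dtype=bool)
            prep["ibw"] = np.array(ibw, dtype=np.intp)
            prep["ibl"] = np.array(ibl, dtype=np.intp)
        else:
            prep["iv"] = np.array(iv_ddm, dtype=np.intp)
            prep["upper"] = np.array(upper_ddm, dtype=bool)
        return prep

    # -- batched likelihoods -------------------------------------------
    def loglik_batch(self, prep: dict, nat: np.ndarray) -> np.ndarray:
        nat = np.atleast_2d(nat)
        if self.model == "lba":
            return self._lba_loglik_batch(prep, nat)
        return self._ddm_loglik_batch(prep, nat)

    def _lba_acc(self, nat, cond, response):
        """(v, sv, b) column vectors of the accumulator for ``response``."""
        d = self.design
        A = self._col(nat, "A")
        if d.response_specific_thresholds:
            b = A + self._col(nat, f"B_{response}")
        else:
            b = A + self._col(nat, "B")
        if response == d.correct_response[cond]:
            return self._col(nat, f"v_{cond}_match"), np.ones(nat.shape[0]), b
        return self._col(nat, f"v_{cond}_mismatch"), self._col(nat, "sv_mismatch"), b

    def _lba_loglik_batch(self, prep, nat):
        d = self.design
        n = nat.shape[0]
        A = self._col(nat, "A")
        t0 = self._col(nat, "t0")
        p_gf = self._col(nat, "p_gf")
        sv_mm = self._col(nat, "sv_mismatch")
        total = np.zeros(n)
        window = prep["window"]

        # omission terms, per condition with omissions
        x24, w24 = _leggauss(24)
        for cond, n_om in prep["n_omit"].items():
            if n_om == 0:
                continue
            upper = np.maximum(window - t0, 0.0)
            tn = 0.5 * upper[:, None] * (x24 + 1.0)
            wt = 0.5 * upper[:, None] * w24
            fF = {}
            for r in d.responses:
                v, sv, b = self._lba_acc(nat, cond, r)
                fF[r] = lba_mod._node_f_and_cdf(
                    tn, b[:, None], A[:, None], v[:, None], sv[:, None])
            p_resp = np.zeros(n)
            for r in d.responses:
                dens = fF[r][0]
                for r2 in d.responses:
                    if r2 != r:
                        dens = dens * (1.0 - fF[r2][1])
                p_resp += np.sum(wt * dens, axis=1)
            p_om = p_gf + (1.0 - p_gf) * np.clip(1.0 - p_resp, 0.0, 1.0)
            with np.errstate(divide="ignore"):
                total += n_om * np.log(p_om)

        # responded trials: numba kernel over all (chain, trial) pairs
        rt = prep["rt"]
        if rt.size:
            total += lba_mod._resp_loglik_kernel(
                rt, prep["ivw"], prep["ivl"], prep["mw"], prep["ml"],
                prep["ibw"], prep["ibl"], np.ascontiguousarray(nat),
                self.names.index("A"), self.names.index("t0"),
                self.names.index("p_gf"), self.names.index("sv_mismatch"),
            )
        return total

    def _ddm_loglik_batch(self, prep, nat):
        d = self.design
        n = nat.shape[0]
        a = self._col(nat, "a")
        z_rel = self._col(nat, "z_rel")
        Ter = self._col(nat, "Ter")
        st0 = self._col(nat, "st0")
        p_gf = self._col(nat, "p_gf")
        window = prep["window"]
        total = np.where(Ter - st0 / 2.0 < 0.0, -np.inf, 0.0)

        xq, wq = _leggauss(self.t0_order)
        t0n = Ter[:, None] + 0.5 * st0[:, None] * xq  # (n, q)
        wts = 0.5 * wq

        for cond, n_om in prep["n_omit"].items():
            if n_om == 0:
                continue
            v = self._col(nat, f"v_{cond}")
            surv = ddm_mod.wiener_survival(
                window - t0n, a[:, None], z_rel[:, None], v[:, None])
            p_late = np.clip(np.sum(surv * wts, axis=1), 0.0, 1.0)
            p_om = p_gf + (1.0 - p_gf) * p_late
            with np.errstate(divide="ignore"):
                total += n_om * np.log(p_om)

        rt = prep["rt"]
        if rt.size:
            # accuracy coding: correct responses absorb at the upper boundary,
            # implemented by flipping (v, w) for upper-boundary trials
            sign = np.where(prep["upper"], -1.0, 1.0)
            v_t = nat[:, prep["iv"]] * sign[None, :]  # (n, m)
            w_t = np.where(prep["upper"], 1.0 - z_rel[:, None], z_rel[:, None])
            t = np.ascontiguousarray(rt[None, :, None] - t0n[:, None, :])
            dens = ddm_mod._wiener_dens_3d(t, a, w_t, v_t)
            avg = np.sum(dens * wts, axis=2)
            lik = (1.0 - p_gf)[:, None] * avg
            with np.errstate(divide="ignore"):
                total += np.sum(
                    np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf),
                    axis=1,
                )
        return total

    def log_posterior(self, prep: dict):
        """Sampling-scale log posterior as a vectorized callable."""

        def logpost(y: np.ndarray) -> np.ndarray:
            y = np.atleast_2d(y)
            lp = self.prior.log_prior_sampling(y)
            out = np.full(y.shape[0], -np.inf)
            ok = np.isfinite(lp)
            if ok.any():
                nat = self.prior.to_natural(y[ok])
                out[ok] = lp[ok] + self.loglik_batch(prep, nat)
            return out

        return logpost


def model_spec(model: str, design: TaskDesign,
               prior: PriorSpec | None = None) -> ModelSpec:
    return ModelSpec(model=model, design=design,
                     prior=prior or default_priors(model, design))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    """DE-MCMC settings (DMC-style defaults, all overridable)."""

    n_chains: int | None = None  # default 3 * n_params
    burn_in: int = 500
    block: int = 500
    max_iter: int = 10_000  # cap on sampling iterations after burn-in
    gamma: float | None = None  # default 2.38 / sqrt(2 d)
    jitter_eps: float = 1e-3
    migration_prob: float = 0.05  # applied during burn-in only
    rhat_threshold: float = 1.10
    thin: int = 1
    seed: int | None = None

    def chains_for(self, d: int) -> int:
        return self.n_chains if self.n_chains is not None else 3 * d


@dataclass
class FitResult:
    subject_id: str
    model: str
    task: str
    samples: PosteriorSamples  # post burn-in
    rhat: dict[str, float]
    converged: bool
    summary: pd.DataFrame  # per-parameter posterior summaries
    accept_rate: float
    spec: ModelSpec = field(repr=False, default=None)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def posterior_mean(self) -> dict[str, float]:
        flat = self.samples.flat("natural")
        return dict(zip(self.samples.names, flat.mean(axis=0)))

    def posterior_median(self) -> dict[str, float]:
        flat = self.samples.flat("natural")
        return dict(zip(self.samples.names, np.median(flat, axis=0)))

    def point_params(self, summary: str = "mean"):
        pm = self.posterior_mean() if summary == "mean" else self.posterior_median()
        return self.spec.params_from_natural(
            np.array([pm[name] for name in self.spec.names]))

    def save(self, path, chains: bool = False) -> None:
        """Write the posterior summary as CSV; optionally the full chains.

        With ``chains=True`` an ``.npz`` array container with the natural-
        and sampling-scale chains and log-posterior is written next to the
        summary.
        """
        from pathlib import Path

        path = Path(path)
        meta = self.summary.copy()
        meta["rhat"] = meta["parameter"].map(self.rhat)
        meta.insert(0, "subject", self.subject_id)
        meta.insert(1, "model", self.model)
        meta["converged"] = self.converged
        meta.to_csv(path, index=False)
        if chains:
            np.savez_compressed(
                path.with_suffix(".npz"),
                names=np.array(self.samples.names),
                natural=self.samples.natural,
                sampling=self.samples.values,
                log_post=self.samples.log_post,
            )


def _summary_table(samples: PosteriorSamples) -> pd.DataFrame:
    flat = samples.flat("natural")
    qs = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "parameter": samples.names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "median": qs[1],
            "ci_lo": qs[0],
            "ci_hi": qs[2],
        }
    )


def fit_subject(dataset: SubjectDataset, model: str = "lba",
                config: FitConfig | None = None,
                prior: PriorSpec | None = None) -> FitResult:
    """Fit one subject by DE-MCMC with convergence gating.

    Runs a migration-assisted burn-in, then sampling blocks until the
    largest second-half R-hat falls below the threshold or the iteration
    cap is reached; the result carries a ``converged`` flag either way.
    """
    config = config or FitConfig()
    spec = model_spec(model, dataset.design, prior)
    prep = spec.prepare(dataset)
    logpost = spec.log_posterior(prep)
    d = spec.prior.n_params
    n_chains = config.chains_for(d)
    rng = np.random.default_rng(config.seed)

    burn = demcmc_sample(
        logpost, spec.prior, n_chains, config.burn_in,
        gamma=config.gamma, jitter_eps=config.jitter_eps,
        migration_prob=config.migration_prob, seed=rng,
    )
    logger.info("subject %s %s burn-in: accept %.2f", dataset.subject_id,
                model, burn.accept_rate)

    samples = None
    state, logp = burn.final_state, burn.final_logp
    done = 0
    converged = False
    rhat: dict[str, float] = {}
    while done < config.max_iter:
        block = demcmc_sample(
            logpost, spec.prior, n_chains, config.block,
            gamma=config.gamma, jitter_eps=config.jitter_eps,
            migration_prob=0.0, seed=rng,
            init_state=state, init_logp=logp, thin=config.thin,
        )
        state, logp = block.final_state, block.final_logp
        samples = block if samples is None else samples.extend(block)
        done += config.block
        rhat = gelman_rubin_all(samples, second_half=True)
        max_r = max(rhat.values())
        logger.info("subject %s %s: %d iters, accept %.2f, max R-hat %.3f",
                    dataset.subject_id, model, done, block.accept_rate, max_r)
        if max_r < config.rhat_threshold:
            converged = True
            break

    return FitResult(
        subject_id=dataset.subject_id,
        model=model,
        task=dataset.task,
        samples=samples,
        rhat=rhat,
        converged=converged,
        summary=_summary_table(samples),
        accept_rate=samples.accept_rate,
        spec=spec,
    )


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed; independent of fitting order or workers."""
    h = zlib.crc32(str(subject_id).encode("utf8"))
    return int((master_seed * 2654435761 + h) % (2**31 - 1))


def fit_cohort(datasets, model: str = "lba", config: FitConfig | None = None,
               master_seed: int = 0, prior: PriorSpec | None = None
               ) -> list[FitResult]:
    """Fit every subject independently with per-subject derived seeds."""
    config = config or FitConfig()
    results = []
    for ds in datasets:
        cfg = replace(config, seed=subject_seed(master_seed, ds.subject_id))
        results.append(fit_subject(ds, model=model, config=cfg, prior=prior))
    return results
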