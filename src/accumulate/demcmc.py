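"""Differential-evolution MCMC and convergence diagnostics.

DE-MCMC runs an ensemble of chains; each proposal moves a chain by a
scaled difference of two other randomly chosen chains plus a small uniform
jitter, which automatically adapts the proposal geometry to correlated
posteriors.  An optional ring-migration step occasionally swaps states
between a random subset of chains, which rescues chains stranded in the
tails during burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .priors import PriorSpec


@dataclass
class PosteriorSamples:
    """DE-MCMC output: chains x iterations x parameters.

    ``values`` are on the sampling (unconstrained) scale, ``natural`` on the
    model's natural scale.
    """

    names: list[str]
    values: np.ndarray  # (n_chains, n_iter, d), sampling scale
    natural: np.ndarray  # (n_chains, n_iter, d), natural scale
    log_post: np.ndarray  # (n_chains, n_iter)
    accept_rate: float
    final_state: np.ndarray = field(repr=False, default=None)
    final_logp: np.ndarray = field(repr=False, default=None)

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_iter(self) -> int:
        return self.values.shape[1]

    def flat(self, scale: str = "natural") -> np.ndarray:
        arr = self.natural if scale == "natural" else self.values
        return arr.reshape(-1, arr.shape[-1])

    def param(self, name: str, scale: str = "natural") -> np.ndarray:
        j = self.names.index(name)
        arr = self.natural if scale == "natural" else self.values
        return arr[:, :, j]

    def extend(self, other: "PosteriorSamples") -> "PosteriorSamples":
        return PosteriorSamples(
            names=self.names,
            values=np.concatenate([self.values, other.values], axis=1),
            natural=np.concatenate([self.natural, other.natural], axis=1),
            log_post=np.concatenate([self.log_post, other.log_post], axis=1),
            accept_rate=other.accept_rate,
            final_state=other.final_state,
            final_logp=other.final_logp,
        )


def gelman_rubin(chains: np.ndarray) -> float:
    """Univariate potential scale reduction factor R-hat.

    ``chains`` is an (n_chains, n_iter) array, used exactly as passed.
    With m chains of length n, chain means x̄_j and within-chain variances
    s²_j:  W = mean(s²_j), B/n = var(x̄_j), and

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Zero within-chain variance makes the statistic undefined (returned as
    ``inf`` so it reads as non-converged) unless the between-chain variance
    is also zero, in which case the chains are constant and identical.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least two iterations per chain")
    means = chains.mean(axis=1)
    W = float(chains.var(axis=1, ddof=1).mean())
    B_over_n = float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin_all(samples: PosteriorSamples, second_half: bool = True
                     ) -> dict[str, float]:
    """R-hat per parameter, by default on the second halves of the chains."""
    start = samples.n_iter // 2 if second_half else 0
    out = {}
    for j, name in enumerate(samples.names):
        out[name] = gelman_rubin(samples.values[:, start:, j])
    return out


class InitializationError(RuntimeError):
    pass


def _init_chains(log_posterior, prior: PriorSpec, n_chains: int,
                 rng: np.random.Generator, max_tries: int = 200):
    state = prior.sample_sampling(rng, n_chains)
    logp = log_posterior(state)
    for _ in range(max_tries):
        bad = ~np.isfinite(logp)
        if not bad.any():
            return state, logp
        redraw = prior.sample_sampling(rng, int(bad.sum()))
        state[bad] = redraw
        logp[bad] = log_posterior(redraw)
    bad = ~np.isfinite(logp)
    raise InitializationError(
        f"could not initialize {int(bad.sum())} of {n_chains} chains at a "
        f"finite posterior after {max_tries} redraws (parameters: "
        f"{prior.names})"
    )


def demcmc_sample(
    log_posterior,
    prior: PriorSpec,
    n_chains: int,
    n_iter: int,
    gamma: float | None = None,
    jitter_eps: float = 1e-3,
    migration_prob: float = 0.0,
    seed=None,
    init_state: np.ndarray | None = None,
    init_logp: np.ndarray | None = None,
    thin: int = 1,
) -> PosteriorSamples:
    """Sample with differential-evolution MCMC.

    ``log_posterior`` must accept an (n, d) sampling-scale matrix and
    return a length-n vector.  ``gamma`` defaults to the classic
    ``2.38 / sqrt(2 d)``.  Chains start from prior draws with finite
    posterior unless an explicit ``init_state`` is given.  Fully
    reproducible under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = prior.n_params
    if n_chains < 2 * d:
        raise ValueError(f"DE-MCMC needs n_chains >= 2*d = {2 * d}, got {n_chains}")
    if gamma is None:
        gamma = 2.38 / np.sqrt(2.0 * d)
    if gamma == 0.0 and jitter_eps == 0.0:
        warnings.warn("gamma = 0 and jitter_eps = 0: chains cannot move")

    if init_state is None:
        state, logp = _init_chains(log_posterior, prior, n_chains, rng)
    else:
        state = np.array(init_state, dtype=float)
        logp = (np.asarray(init_logp, dtype=float) if init_logp is not None
                else log_posterior(state))

    keep = n_iter // thin
    values = np.empty((n_chains, keep, d))
    logs = np.empty((n_chains, keep))
    n_accept = 0
    n_prop = 0
    idx = np.arange(n_chains)

    for it in range(n_iter):
        # choose distinct partners a, b != self for every chain at once
        r1 = rng.integers(0, n_chains - 1, size=n_chains)
        r1 += r1 >= idx
        r2 = rng.integers(0, n_chains - 2, size=n_chains)
        lo = np.minimum(idx, r1)
        hi = np.maximum(idx, r1)
        r2 += r2 >= lo
        r2 += r2 >= hi
        # random scale in [0.5, 1] x gamma keeps the ensemble mixing on
        # posteriors whose local scales differ from the global one
        g = gamma * rng.uniform(0.5, 1.0)
        jitter = rng.uniform(-jitter_eps, jitter_eps, size=(n_chains, d))
        prop = state + g * (state[r1] - state[r2]) + jitter
        logp_prop = log_posterior(prop)
        with np.errstate(invalid="ignore"):
            accept = np.log(rng.random(n_chains)) < (logp_prop - logp)
        accept &= np.isfinite(logp_prop)
        state[accept] = prop[accept]
        logp[accept] = logp_prop[accept]
        n_accept += int(accept.sum())
        n_prop += n_chains

        if migration_prob > 0 and rng.random() < migration_prob:
            # ring migration over a random subset: each selected chain is
            # offered its predecessor's state, accepted by Metropolis
            k = int(rng.integers(1, n_chains + 1))
            subset = rng.choice(n_chains, size=k, replace=False)
            donor = np.roll(subset, 1)
            u = np.log(rng.random(k))
            ok = u < (logp[donor] - logp[subset])
            state[subset[ok]] = state[donor[ok]]
            logp[subset[ok]] = logp[donor[ok]]

        if (it + 1) % thin == 0:
            j = (it + 1) // thin - 1
            if j < keep:
                values[:, j, :] = state
                logs[:, j] = logp

    natural = np.stack(
        [prior.to_natural(values[c]) for c in range(n_chains)], axis=0
    )
    return PosteriorSamples(
        names=prior.names,
        values=values,
        natural=natural,
        log_post=logs,
        accept_rate=n_accept / max(n_prop, 1),
        final_state=state.copy(),
        final_logp=logp.copy(),
    )
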