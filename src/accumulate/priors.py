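"""Prior specifications and sampling-scale transforms.

Each parameter carries a proper prior on its natural scale (truncated
normal or uniform) together with a transform used for sampling: positive
parameters are sampled on the log scale and interval-bounded parameters on
the probit scale, so the sampler works on an unconstrained space.  The
log-posterior on the sampling scale includes the log-Jacobian of the
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm, truncnorm, uniform

_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class Prior:
    """Prior for one scalar parameter.

    dist: ``"normal"`` (loc/scale on the real line), ``"truncnorm"``
    (loc/scale truncated to [lower, upper]) or ``"uniform"`` (lower/upper).
    transform: ``"identity"``, ``"log"`` (natural = exp(sampled)) or
    ``"probit"`` (natural = lower + (upper-lower) * Phi(sampled)).
    """

    dist: str
    loc: float = 0.0
    scale: float = 1.0
    lower: float = -np.inf
    upper: float = np.inf
    transform: str = "identity"

    def _frozen(self):
        if self.dist == "normal":
            return norm(self.loc, self.scale)
        if self.dist == "truncnorm":
            a = (self.lower - self.loc) / self.scale
            b = (self.upper - self.loc) / self.scale
            return truncnorm(a, b, loc=self.loc, scale=self.scale)
        if self.dist == "uniform":
            return uniform(self.lower, self.upper - self.lower)
        raise ValueError(f"unknown prior distribution {self.dist!r}")

    def sample(self, rng: np.random.Generator, size=None):
        return self._frozen().rvs(size=size, random_state=rng)

    def logpdf(self, x):
        """Closed-form log density (avoids frozen-distribution overhead)."""
        x = np.asarray(x, dtype=float)
        if self.dist == "normal":
            z = (x - self.loc) / self.scale
            return -0.5 * z * z - np.log(self.scale) - _LOG_SQRT2PI
        if self.dist == "truncnorm":
            z = (x - self.loc) / self.scale
            za = (self.lower - self.loc) / self.scale
            zb = (self.upper - self.loc) / self.scale
            log_z = np.log(ndtr(zb) - ndtr(za))
            core = -0.5 * z * z - np.log(self.scale) - _LOG_SQRT2PI - log_z
            return np.where((x >= self.lower) & (x <= self.upper), core, -np.inf)
        if self.dist == "uniform":
            with np.errstate(divide="ignore"):
                return np.where(
                    (x >= self.lower) & (x <= self.upper),
                    -np.log(self.upper - self.lower),
                    -np.inf,
                )
        raise ValueError(f"unknown prior distribution {self.dist!r}")

    # --- sampling-scale transform -------------------------------------
    def to_natural(self, y):
        y = np.asarray(y, dtype=float)
        if self.transform == "identity":
            return y
        if self.transform == "log":
            with np.errstate(over="ignore"):
                return np.exp(y)
        if self.transform == "probit":
            return self.lower + (self.upper - self.lower) * ndtr(y)
        raise ValueError(f"unknown transform {self.transform!r}")

    def to_sampling(self, x):
        x = np.asarray(x, dtype=float)
        if self.transform == "identity":
            return x
        if self.transform == "log":
            return np.log(np.maximum(x, 1e-300))
        if self.transform == "probit":
            u = (x - self.lower) / (self.upper - self.lower)
            return ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
        raise ValueError(f"unknown transform {self.transform!r}")

    def log_jacobian(self, y):
        """log |d natural / d sampling| at sampling-scale value y."""
        y = np.asarray(y, dtype=float)
        if self.transform == "identity":
            return np.zeros_like(y)
        if self.transform == "log":
            return y
        if self.transform == "probit":
            return (np.log(self.upper - self.lower)
                    - 0.5 * np.square(y) - _LOG_SQRT2PI)
        raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class PriorSpec:
    """Ordered collection of named parameter priors."""

    priors: dict[str, Prior]

    @property
    def names(self) -> list[str]:
        return list(self.priors)

    @property
    def n_params(self) -> int:
        return len(self.priors)

    def sample_natural(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cols = [p.sample(rng, size=n) for p in self.priors.values()]
        return np.column_stack(cols)

    def sample_sampling(self, rng: np.random.Generator, n: int) -> np.ndarray:
        nat = self.sample_natural(rng, n)
        return self.to_sampling(nat)

    def to_natural(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        return np.column_stack(
            [p.to_natural(y[:, j]) for j, p in enumerate(self.priors.values())]
        )

    def to_sampling(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.column_stack(
            [p.to_sampling(x[:, j]) for j, p in enumerate(self.priors.values())]
        )

    def log_prior_sampling(self, y: np.ndarray) -> np.ndarray:
        """Log prior density of sampling-scale points, Jacobian included."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        nat = self.to_natural(y)
        total = np.zeros(y.shape[0])
        for j, p in enumerate(self.priors.values()):
            with np.errstate(divide="ignore", invalid="ignore"):
                total += p.logpdf(nat[:, j]) + p.log_jacobian(y[:, j])
        return total


def rate_prior() -> Prior:
    """Broad prior for accumulation/drift rates: N(1, 3) on the real line."""
    return Prior("normal", loc=1.0, scale=3.0)


def positive_prior() -> Prior:
    """Broad positive prior for a, A, B, sv: N(1, 2) truncated to (0, inf)."""
    return Prior("truncnorm", loc=1.0, scale=2.0, lower=1e-6, upper=np.inf,
                 transform="log")


def interval_prior(lower: float, upper: float) -> Prior:
    return Prior("uniform", lower=lower, upper=upper, transform="probit")
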