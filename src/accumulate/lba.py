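"""Linear ballistic accumulator (LBA) likelihood and simulator.

The LBA describes a binary (or n-ary) choice as a race between independent
deterministic accumulators.  On each trial accumulator ``j`` starts at a
point drawn uniformly from ``[0, A]`` and rises linearly at a rate drawn
from ``Normal(v_j, sv_j)`` toward a threshold ``b_j = A + B_j``; the first
accumulator to reach its threshold produces its response at decision time
``(b_j - start) / rate``, and the observed RT adds a nondecision time
``t0``.  Rates are untruncated: an accumulator that draws a negative rate
never finishes, and the event that no accumulator finishes contributes to
the omission probability.  Omissions arise from three sources: a
go-failure mixture (probability ``p_gf``), no accumulator finishing, and
responses falling after the response window (censoring).

The matching accumulator's rate SD is fixed to 1 as the scaling constant;
multiplying all of ``v, sv, A, B`` by a common factor leaves choice
probabilities unchanged and only rescales decision times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numba import njit
from scipy.special import ndtr

from .tasks import OMITTED, TaskDesign
from .trial_data import SubjectDataset, make_dataset

_SQRT2PI = np.sqrt(2.0 * np.pi)
_A_LIMIT = 1e-6  # below this, use the analytic A -> 0 expressions


def _phi(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


class ParameterError(ValueError):
    pass


@dataclass
class LBAParams:
    """Per-subject LBA parameters for one task design.

    ``v_match[c]``/``v_mismatch[c]`` are the mean rates of the accumulators
    matching / mismatching the correct response in condition ``c``;
    ``B[r]`` is the threshold gap for response option ``r`` (threshold
    ``b = A + B``); ``A`` the start-point range; ``t0`` nondecision time in
    seconds; ``p_gf`` the go-failure probability.
    """

    v_match: dict[str, float]
    v_mismatch: dict[str, float]
    A: float
    B: dict[str, float]
    t0: float
    p_gf: float = 0.0
    sv_match: float = 1.0
    sv_mismatch: float = 1.0

    def __post_init__(self) -> None:
        if self.sv_match != 1.0:
            raise ParameterError("sv_match is the scaling constant, fixed to 1")
        if self.sv_mismatch <= 0:
            raise ParameterError("sv_mismatch must be > 0")
        if self.A < 0 or self.t0 < 0:
            raise ParameterError("A and t0 must be >= 0")
        if any(b < 0 for b in self.B.values()):
            raise ParameterError("threshold gaps B must be >= 0")
        if not 0.0 <= self.p_gf <= 1.0:
            raise ParameterError("p_gf must lie in [0, 1]")

    def threshold(self, response: str) -> float:
        return self.A + self.B[response]

    def accumulators(self, design: TaskDesign, condition: str):
        """(v, sv, b) per response option for one condition, match-aware."""
        correct = design.correct_response[condition]
        out = {}
        for r in design.responses:
            if r == correct:
                out[r] = (self.v_match[condition], self.sv_match, self.threshold(r))
            else:
                out[r] = (self.v_mismatch[condition], self.sv_mismatch, self.threshold(r))
        return out

    def to_flat(self) -> dict[str, float]:
        """Flat ``name -> value`` mapping (JSON-compatible serialization)."""
        flat: dict[str, float] = {}
        for c, v in self.v_match.items():
            flat[f"v_{c}_match"] = v
        for c, v in self.v_mismatch.items():
            flat[f"v_{c}_mismatch"] = v
        if len(set(np.round(list(self.B.values()), 12))) == 1:
            flat["B"] = next(iter(self.B.values()))
        else:
            for r, b in self.B.items():
                flat[f"B_{r}"] = b
        flat.update(A=self.A, t0=self.t0, p_gf=self.p_gf, sv_mismatch=self.sv_mismatch)
        return flat


def lba_node_cdf(t, b, A, v, sv):
    """P(single accumulator finishes by decision time t); defective CDF.

    All arguments broadcast.  ``A -> 0`` is handled by the analytic limit
    (finish time ``b / rate``), avoiding catastrophic cancellation.
    """
    t, b, A, v, sv = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (t, b, A, v, sv)]
    )
    if np.any(sv <= 0):
        raise ParameterError("sv must be > 0")
    out = np.zeros(t.shape)
    pos = t > 0
    if not np.any(pos):
        return out if out.ndim else float(out)
    ts, bs, As, vs, svs = (x[pos] for x in (t, b, A, v, sv))
    small = As < _A_LIMIT
    Asafe = np.where(small, 1.0, As)
    denom = ts * svs
    g = (bs - Asafe - ts * vs) / denom
    h = (bs - ts * vs) / denom
    F = 1.0 + ((bs - Asafe - ts * vs) / Asafe) * ndtr(g) \
        - ((bs - ts * vs) / Asafe) * ndtr(h) \
        + (denom / Asafe) * (_phi(g) - _phi(h))
    # A -> 0: finish iff rate > b / t
    F0 = ndtr((vs - bs / ts) / svs)
    res = np.where(small, F0, F)
    out[pos] = np.clip(res, 0.0, 1.0)
    return out if out.ndim else float(out)


def lba_node_density(t, b, A, v, sv):
    """Defective density of a single accumulator's finishing time."""
    t, b, A, v, sv = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (t, b, A, v, sv)]
    )
    if np.any(sv <= 0):
        raise ParameterError("sv must be > 0")
    out = np.zeros(t.shape)
    pos = t > 0
    if not np.any(pos):
        return out if out.ndim else float(out)
    ts, bs, As, vs, svs = (x[pos] for x in (t, b, A, v, sv))
    small = As < _A_LIMIT
    Asafe = np.where(small, 1.0, As)
    denom = ts * svs
    g = (bs - Asafe - ts * vs) / denom
    h = (bs - ts * vs) / denom
    f = (vs * (ndtr(h) - ndtr(g)) + svs * (_phi(g) - _phi(h))) / Asafe
    f0 = (bs / ts**2) * _phi((bs / ts - vs) / svs) / svs
    res = np.where(small, f0, f)
    out[pos] = np.maximum(res, 0.0)
    return out if out.ndim else float(out)


def _node_f_and_cdf(t, b, A, v, sv):
    """Density and CDF of one accumulator in a single pass (no validation).

    Fast path for batched likelihoods: all inputs are broadcast-compatible
    float arrays, ``sv > 0``, and ``A`` is clamped to 1e-3 with the
    analytic ``A -> 0`` branch taking over below the clamp.
    """
    small = A < 1e-3
    any_small = bool(np.any(small))
    Asafe = np.where(small, 1.0, A) if any_small else A
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom = t * sv
        btv = b - t * v
        g = (btv - Asafe) / denom
        h = btv / denom
        Pg, Ph = ndtr(g), ndtr(h)
        pg, ph = _phi(g), _phi(h)
        dphi = pg - ph
        F = 1.0 + ((btv - Asafe) * Pg - btv * Ph + denom * dphi) / Asafe
        f = (v * (Ph - Pg) + sv * dphi) / Asafe
        if any_small:
            # A -> 0 limit: finish time is b / rate
            F0 = ndtr((v - b / t) / sv)
            f0 = (b / (t * t)) * _phi((b / t - v) / sv) / sv
            F = np.where(small, F0, F)
            f = np.where(small, f0, f)
    pos = t > 0
    F = np.clip(np.where(pos, F, 0.0), 0.0, 1.0)
    f = np.maximum(np.where(pos, f, 0.0), 0.0)
    return f, F


@njit(cache=False, fastmath=True)
def _resp_loglik_kernel(rt, ivw, ivl, mw, ml, ibw, ibl, nat,
                        iA, it0, ipgf, isv):  # pragma: no cover - numba
    """Summed log-likelihood of all responded trials, per parameter row.

    Scalar re-implementation of the two-Phi/two-phi node formulas for the
    DE-MCMC hot path; must agree with ``_node_f_and_cdf`` (tested).
    """
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)
    n = nat.shape[0]
    m = rt.size
    out = np.zeros(n)
    for c in range(n):
        A = nat[c, iA]
        t0 = nat[c, it0]
        pgf = nat[c, ipgf]
        svm = nat[c, isv]
        if svm <= 0.0 or A < 0.0 or pgf >= 1.0:
            out[c] = -np.inf
            continue
        log1mpgf = math.log(1.0 - pgf)
        small = A < 1e-3
        Asafe = 1e-3 if small else A
        total = 0.0
        for j in range(m):
            t = rt[j] - t0
            if t <= 0.0:
                total = -np.inf
                break
            vw = nat[c, ivw[j]]
            vl = nat[c, ivl[j]]
            svw = 1.0 if mw[j] else svm
            svl = 1.0 if ml[j] else svm
            bw = A + nat[c, ibw[j]]
            bl = A + nat[c, ibl[j]]
            # winner density
            if small:
                x = (bw / t - vw) / svw
                f = (bw / (t * t)) * inv_sqrt2pi * math.exp(-0.5 * x * x) / svw
            else:
                denom = t * svw
                btv = bw - t * vw
                g = (btv - Asafe) / denom
                h = btv / denom
                Pg = 0.5 * math.erfc(-g * inv_sqrt2)
                Ph = 0.5 * math.erfc(-h * inv_sqrt2)
                pg = inv_sqrt2pi * math.exp(-0.5 * g * g)
                ph = inv_sqrt2pi * math.exp(-0.5 * h * h)
                f = (vw * (Ph - Pg) + svw * (pg - ph)) / Asafe
            if f <= 0.0:
                total = -np.inf
                break
            # loser survival
            if small:
                x = (vl - bl / t) / svl
                F = 0.5 * math.erfc(-x * inv_sqrt2)
            else:
                denom = t * svl
                btv = bl - t * vl
                g = (btv - Asafe) / denom
                h = btv / denom
                Pg = 0.5 * math.erfc(-g * inv_sqrt2)
                Ph = 0.5 * math.erfc(-h * inv_sqrt2)
                pg = inv_sqrt2pi * math.exp(-0.5 * g * g)
                ph = inv_sqrt2pi * math.exp(-0.5 * h * h)
                F = 1.0 + ((btv - Asafe) * Pg - btv * Ph
                           + denom * (pg - ph)) / Asafe
                if F < 0.0:
                    F = 0.0
                elif F > 1.0:
                    F = 1.0
            lik = f * (1.0 - F)
            if lik <= 0.0:
                total = -np.inf
                break
            total += math.log(lik) + log1mpgf
        out[c] = total
    return out


def lba_defective_density(t, response: str, params: LBAParams,
                          condition: str, design: TaskDesign):
    """Density that ``response`` wins the race at decision time ``t``."""
    acc = params.accumulators(design, condition)
    if response not in acc:
        raise ParameterError(f"{response!r} is not a response of {design.name}")
    v, sv, b = acc[response]
    dens = lba_node_density(t, b, params.A, v, sv)
    for r, (vj, svj, bj) in acc.items():
        if r != response:
            dens = dens * (1.0 - lba_node_cdf(t, bj, params.A, vj, svj))
    return dens


def lba_never_finish_prob(params: LBAParams, condition: str,
                          design: TaskDesign) -> float:
    """P(no accumulator ever finishes) = prod_j P(rate_j <= 0)."""
    acc = params.accumulators(design, condition)
    p = 1.0
    for v, sv, _ in acc.values():
        p *= float(ndtr(-v / sv))
    return p


def _gl_nodes(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def lba_response_probs(params: LBAParams, condition: str, design: TaskDesign,
                       window: float | None = None, n_nodes: int = 96
                       ) -> dict[str, float]:
    """P(each response is recorded) within the window (ignoring go failure).

    ``window=None`` integrates over all decision times (no censoring).
    """
    unbounded = window is None
    upper = 50.0 if unbounded else max(window - params.t0, 0.0)
    probs = {r: 0.0 for r in design.responses}
    if upper <= 0:
        return probs
    x, w = _gl_nodes(n_nodes)
    # panel the domain: the defective density peaks early, so a single rule
    # over a long interval undersamples it
    edges = [e for e in (0.0, 1.0, 3.0, 10.0, 50.0) if e < upper] + [upper]
    t_all, wt_all = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        t_all.append(0.5 * (hi - lo) * (x + 1.0) + lo)
        wt_all.append(0.5 * (hi - lo) * w)
    if unbounded:
        # tail (upper, inf) via u = 1/t: integrand ~ 1/t^2 from near-zero rates
        u = 0.5 * (1.0 / upper) * (x + 1.0)
        wu = 0.5 * (1.0 / upper) * w
        np.clip(u, 1e-12, None, out=u)
        t_all.append(1.0 / u)
        wt_all.append(wu / u**2)
    t = np.concatenate(t_all)
    wt = np.concatenate(wt_all)
    for r in design.responses:
        dens = lba_defective_density(t, r, params, condition, design)
        probs[r] = float(np.sum(wt * dens))
    return probs


def lba_omission_prob(params: LBAParams, condition: str, design: TaskDesign,
                      window: float) -> float:
    """Probability a trial is recorded as an omission.

    Mixture of go failure with the probability that the race produces no
    response inside the window: ``p_gf + (1 - p_gf) * (1 - P(response))``.
    A window at or below ``t0`` makes every trial an omission.
    """
    if window <= params.t0:
        import warnings

        warnings.warn("response window does not exceed t0; omission certain")
        return 1.0
    p_resp = sum(lba_response_probs(params, condition, design, window).values())
    p_resp = min(max(p_resp, 0.0), 1.0)
    return params.p_gf + (1.0 - params.p_gf) * (1.0 - p_resp)


def lba_loglik(dataset: SubjectDataset, params: LBAParams) -> float:
    """Total log-likelihood of a subject's trials under ``params``.

    Responded trials contribute ``log[(1 - p_gf) * defective density]`` at
    decision time ``rt - t0``; omitted trials contribute the log omission
    probability of their condition.  A responded trial with zero density
    (e.g. ``rt <= t0``) yields ``-inf``.
    """
    design = dataset.design
    present = set(dataset.trials["condition"])
    missing = present - set(params.v_match) | present - set(params.v_mismatch)
    if missing:
        raise ParameterError(f"parameters missing for conditions {sorted(missing)}")
    total = 0.0
    window = dataset.response_window
    for cond in sorted(present):
        sub = dataset.trials[dataset.trials["condition"] == cond]
        n_om = int((sub["response"] == OMITTED).sum())
        if n_om:
            p_om = lba_omission_prob(params, cond, design, window)
            total += n_om * (np.log(p_om) if p_om > 0 else -np.inf)
        for r in design.responses:
            rts = sub.loc[sub["response"] == r, "rt"].to_numpy(dtype=float)
            if rts.size == 0:
                continue
            t = rts - params.t0
            dens = lba_defective_density(t, r, params, cond, design)
            lik = (1.0 - params.p_gf) * dens
            with np.errstate(divide="ignore"):
                total += float(np.sum(np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf)))
    return total


def lba_simulate(params: LBAParams, design: TaskDesign,
                 n_per_condition: int | Mapping[str, int],
                 window: float | None = None,
                 seed: int | np.random.Generator | None = None,
                 subject_id: str = "sim") -> SubjectDataset:
    """Draw a subject dataset by simulating the race trial by trial.

    Start points are uniform on ``[0, A]``, rates Normal per accumulator,
    the winner is the minimum finishing time, and trials are recorded as
    omitted on go failure, when no accumulator finishes, or when
    ``RT > window``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    window = design.window if window is None else window
    if isinstance(n_per_condition, int):
        n_per_condition = {c: n_per_condition for c in design.conditions}
    conds, resps, rts = [], [], []
    for cond, n in n_per_condition.items():
        if n < 1:
            raise ParameterError("trials per condition must be >= 1")
        acc = params.accumulators(design, cond)
        names = list(acc)
        finish = np.full((n, len(names)), np.inf)
        for j, r in enumerate(names):
            v, sv, b = acc[r]
            rate = rng.normal(v, sv, size=n)
            start = rng.uniform(0.0, params.A, size=n) if params.A > 0 else np.zeros(n)
            ok = rate > 0
            finish[ok, j] = (b - start[ok]) / rate[ok]
        win = np.argmin(finish, axis=1)
        t_dec = finish[np.arange(n), win]
        rt = t_dec + params.t0
        gofail = rng.random(n) < params.p_gf
        omitted = gofail | ~np.isfinite(rt) | (rt > window)
        resp = np.array(names, dtype=object)[win]
        resp[omitted] = OMITTED
        rt = np.where(omitted, np.nan, rt)
        conds.append(np.full(n, cond, dtype=object))
        resps.append(resp)
        rts.append(rt)
    return make_dataset(
        subject_id,
        design.name,
        np.concatenate(conds),
        np.concatenate(resps),
        np.concatenate(rts),
        window=window,
    )
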