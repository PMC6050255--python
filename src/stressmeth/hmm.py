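"""Two-state hidden Markov model on position-ordered z-scores.

The hidden chain alternates between a null state (emission fixed at the
standard normal) and an alternative state whose emission is a free
two-component normal mixture, so positive and negative effects can occupy
separate components.  The chain is restarted independently at every
chromosome boundary.  Fitting is by EM with scaled forward-backward; the
local index of significance (LIS) at a probe is the posterior probability of
the null state given the whole z sequence.

Internally the mixture-emission chain is expanded to three states
(null, alt-component-1, alt-component-2) whose transition matrix factorises
as block transition x mixture weight; EM updates are exact for that
parameterisation and the log-likelihood is non-decreasing every iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigurationError, PipelineError

# Alternative-state z-scores are true signals convolved with N(0,1) noise,
# so their emission SD cannot drop below 1; a minimum mean separation of one
# null SD keeps the mixture identifiable against the null under sparse or
# absent signal (otherwise EM can split the null itself).
_SD_FLOOR = 1.0
_MEAN_FLOOR = 1.0
_PROB_FLOOR = 1e-10


@dataclass
class HmmModel:
    """Fitted parameters and the EM trace."""

    initial: np.ndarray  # length-3 distribution over (null, alt1, alt2)
    transition: np.ndarray  # 2x2 block transition (null, alternative)
    weights: np.ndarray  # mixture weights within the alternative state
    means: np.ndarray
    sds: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    restart_used: int = 0

    @property
    def initial_null(self) -> float:
        return float(self.initial[0])

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def expanded_transition(self) -> np.ndarray:
        return _expand(self.transition, self.weights)


def _expand(a2: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 transition of the expanded chain: destination alternative
    component is drawn from the mixture weights."""
    a3 = np.empty((3, 3))
    for i in range(3):
        b = 0 if i == 0 else 1
        a3[i, 0] = a2[b, 0]
        a3[i, 1] = a2[b, 1] * w[0]
        a3[i, 2] = a2[b, 1] * w[1]
    return a3


def _log_norm_pdf(z: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((z - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def emission_matrix(z: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Densities (n, 3): null N(0,1) then the two alternative components."""
    logb = np.stack(
        [
            _log_norm_pdf(z, 0.0, 1.0),
            _log_norm_pdf(z, float(means[0]), float(sds[0])),
            _log_norm_pdf(z, float(means[1]), float(sds[1])),
        ],
        axis=1,
    )
    # per-row shift cancels in the posteriors and is added back to the loglik
    shift = logb.max(axis=1)
    return np.exp(logb - shift[:, None]), shift


@njit(cache=True)
def _forward_backward(b, a3, init):  # pragma: no cover - numba-compiled
    n, s = b.shape
    alpha = np.empty((n, s))
    c = np.empty(n)
    tot = 0.0
    for j in range(s):
        alpha[0, j] = init[j] * b[0, j]
        tot += alpha[0, j]
    if tot <= 0.0:
        tot = 1e-300
    c[0] = tot
    for j in range(s):
        alpha[0, j] /= tot
    for t in range(1, n):
        tot = 0.0
        for j in range(s):
            acc = 0.0
            for i in range(s):
                acc += alpha[t - 1, i] * a3[i, j]
            alpha[t, j] = acc * b[t, j]
            tot += alpha[t, j]
        if tot <= 0.0:
            tot = 1e-300
        c[t] = tot
        for j in range(s):
            alpha[t, j] /= tot
    gamma = np.empty((n, s))
    xi = np.zeros((s, s))
    bprev = np.ones(s)
    for j in range(s):
        gamma[n - 1, j] = alpha[n - 1, j]
    for t in range(n - 2, -1, -1):
        tmp = np.empty(s)
        for j in range(s):
            tmp[j] = b[t + 1, j] * bprev[j]
        bt = np.empty(s)
        for i in range(s):
            acc = 0.0
            for j in range(s):
                acc += a3[i, j] * tmp[j]
            bt[i] = acc / c[t + 1]
        g = 0.0
        for j in range(s):
            gamma[t, j] = alpha[t, j] * bt[j]
            g += gamma[t, j]
        if g > 0.0:
            for j in range(s):
                gamma[t, j] /= g
        for i in range(s):
            for j in range(s):
                xi[i, j] += alpha[t, i] * a3[i, j] * tmp[j] / c[t + 1]
        bprev = bt
    ll = 0.0
    for t in range(n):
        ll += math.log(c[t])
    return gamma, xi, ll


def _initial_params(rng: np.random.Generator | None) -> dict:
    """Default initialisation: null-heavy chain, alternative means at +/-2.
    Restarts jitter the means and transition masses."""
    a2 = np.array([[0.95, 0.05], [0.3, 0.7]])
    means = np.array([-2.0, 2.0])
    sds = np.array([1.0, 1.0])
    w = np.array([0.5, 0.5])
    init = np.array([0.95, 0.025, 0.025])
    if rng is not None:
        means = means + rng.normal(0.0, 0.75, 2)
        stay = float(rng.uniform(0.85, 0.99))
        back = float(rng.uniform(0.15, 0.5))
        a2 = np.array([[stay, 1.0 - stay], [back, 1.0 - back]])
    return {"a2": a2, "w": w, "means": means, "sds": sds, "init": init}


def _em(
    z: np.ndarray,
    segments: list[np.ndarray],
    params: dict,
    max_iter: int,
    tol: float,
) -> tuple[HmmModel, np.ndarray]:
    a2 = params["a2"].copy()
    w = params["w"].copy()
    means = params["means"].copy()
    sds = params["sds"].copy()
    init = params["init"].copy()
    n = len(z)
    trace: list[float] = []
    gamma_all = np.empty((n, 3))

    def e_step():
        b, shift = emission_matrix(z, means, sds)
        a3 = _expand(a2, w)
        xi_tot = np.zeros((3, 3))
        init_tot = np.zeros(3)
        ll = 0.0
        pos = 0
        for seg in segments:
            g, xi, seg_ll = _forward_backward(b[seg], a3, init)
            gamma_all[pos : pos + len(seg)] = g
            xi_tot += xi
            init_tot += g[0]
            ll += seg_ll + shift[seg].sum()
            pos += len(seg)
        return xi_tot, init_tot, ll

    for _ in range(max_iter):
        xi_tot, init_tot, ll = e_step()
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * max(1.0, abs(trace[-2])):
            break
        # M-step
        init = np.clip(init_tot / init_tot.sum(), _PROB_FLOOR, None)
        init /= init.sum()
        block = np.empty((2, 2))
        block[0, 0] = xi_tot[0, 0]
        block[0, 1] = xi_tot[0, 1] + xi_tot[0, 2]
        block[1, 0] = xi_tot[1, 0] + xi_tot[2, 0]
        block[1, 1] = xi_tot[1:, 1:].sum()
        a2 = np.clip(block, _PROB_FLOOR, None)
        a2 /= a2.sum(axis=1, keepdims=True)
        occ = gamma_all.sum(axis=0)
        alt_occ = occ[1] + occ[2]
        if alt_occ > _PROB_FLOOR:
            w = np.clip(occ[1:] / alt_occ, _PROB_FLOOR, None)
            w /= w.sum()
            for k in (0, 1):
                g = gamma_all[:, k + 1]
                tot = g.sum()
                if tot > _PROB_FLOOR:
                    mu = float(g @ z) / tot
                    if abs(mu) < _MEAN_FLOOR:
                        # constrained M-step: project onto |mu| >= floor,
                        # keeping the side the unconstrained estimate favours
                        side = math.copysign(1.0, mu) if mu != 0 else math.copysign(1.0, means[k])
                        mu = side * _MEAN_FLOOR
                    means[k] = mu
                    sds[k] = max(_SD_FLOOR, math.sqrt(float(g @ (z - means[k]) ** 2) / tot))
    else:
        # iteration cap reached after an M-step: refresh posteriors so the
        # returned LIS matches the returned parameters
        _, _, ll = e_step()
        trace.append(ll)
    model = HmmModel(
        initial=init,
        transition=a2,
        weights=w,
        means=means,
        sds=sds,
        loglik_trace=trace,
    )
    return model, gamma_all[:, 0]


def posterior_lis(z: np.ndarray, chrom: np.ndarray, model: HmmModel) -> np.ndarray:
    """LIS under fixed parameters (no fitting): posterior null probability
    at each probe given the whole z sequence."""
    z = np.asarray(z, dtype=float)
    chrom = np.asarray(chrom)
    b, _ = emission_matrix(z, model.means, model.sds)
    a3 = model.expanded_transition()
    lis = np.empty(len(z))
    start = 0
    for i in range(1, len(z) + 1):
        if i == len(z) or chrom[i] != chrom[start]:
            seg = np.arange(start, i)
            g, _, _ = _forward_backward(b[seg], a3, model.initial)
            lis[seg] = g[:, 0]
            start = i
    return lis


def fit_hmm_lis(
    z: np.ndarray,
    chrom: np.ndarray,
    seed: int = 0,
    restarts: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[HmmModel, np.ndarray]:
    """Fit the chain to z-scores ordered by (chromosome, position) and return
    the fitted model plus per-probe LIS (posterior null probability).

    ``chrom`` labels each z with its chromosome; each chromosome forms an
    independent segment.  ``restarts`` EM runs (the first from the default
    initialisation, the rest jittered) compete on final log-likelihood.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 100:
        raise ConfigurationError("need >= 100 probes to fit the HMM")
    if not np.all(np.isfinite(z)):
        raise ConfigurationError("z-scores must be finite")
    chrom = np.asarray(chrom)
    segments = []
    start = 0
    for i in range(1, len(z) + 1):
        if i == len(z) or chrom[i] != chrom[start]:
            segments.append(np.arange(start, i))
            start = i
    rng = np.random.default_rng(seed)
    best: tuple[HmmModel, np.ndarray] | None = None
    for r in range(max(1, restarts)):
        params = _initial_params(None if r == 0 else rng)
        model, lis = _em(z, segments, params, max_iter, tol)
        model.restart_used = r
        if np.all(np.isfinite(lis)) and (best is None or model.loglik > best[0].loglik):
            best = (model, lis)
    if best is None or not np.isfinite(best[0].loglik):
        raise PipelineError("HMM EM failed to produce a finite log-likelihood")
    return best
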