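"""Daily weight-update rules for a single synapse and a single cluster.

One simulated time step corresponds to one day.  Each active synapse receives
a stochastic LTP increment and an independent stochastic LTD decrement, both
proportional to the preexisting weight and to a volatility factor that makes
small synapses fluctuate relatively more.  The mean LTP amplitude falls as
more synapses in the cluster are strong (resource competition).  An active
synapse whose updated weight drops below the silencing threshold becomes
silent at a basal weight; a silent synapse can regenerate, but only when a
chain-adjacent synapse was strong at the start of the day.

All functions here are pure and accept scalars or numpy arrays; the cluster
step :func:`step_cluster` is the naive per-synapse loop and also serves as
the reference semantics for the vectorized ensemble driver.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "SynapseState",
    "ClusterState",
    "volatility",
    "ltp_mean_amplitude",
    "draw_increment",
    "ltp_amplitude",
    "ltd_amplitude",
    "regeneration_probability",
    "draw_day_randoms",
    "increments_from_draws",
    "step_cluster",
]


@dataclasses.dataclass
class SynapseState:
    """One synapse: a nonnegative weight and an active/silent flag."""

    W: float
    active: bool = True


@dataclasses.dataclass
class ClusterState:
    """Ordered chain of synapses on one dendritic branch.

    ``weights[i]`` and ``active[i]`` describe synapse ``i``; synapse ``i`` is
    adjacent to ``i - 1`` and ``i + 1`` (endpoints have one neighbour).  The
    chain length never changes: silencing and regeneration toggle status.
    """

    weights: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.weights.shape != self.active.shape or self.weights.ndim != 1:
            raise ValueError("weights and active must be 1-D arrays of equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @classmethod
    def from_synapses(cls, synapses: Sequence[SynapseState]) -> "ClusterState":
        return cls(
            weights=np.array([s.W for s in synapses], dtype=float),
            active=np.array([s.active for s in synapses], dtype=bool),
        )

    @classmethod
    def uniform(cls, params: ModelParams, W: float = 1.0) -> "ClusterState":
        """All-active cluster with every weight set to ``W``."""
        return cls(
            weights=np.full(params.N_cl, float(W)),
            active=np.ones(params.N_cl, dtype=bool),
        )

    @property
    def n_cl(self) -> int:
        return self.weights.size

    def n_strong(self, params: ModelParams) -> int:
        """Number of strong synapses (``W > T_st``), denoted N_st."""
        return int(np.count_nonzero(self.weights > params.T_st))

    def copy(self) -> "ClusterState":
        return ClusterState(self.weights.copy(), self.active.copy())


# ---------------------------------------------------------------------------
# per-synapse update factors
# ---------------------------------------------------------------------------


def volatility(W, params: ModelParams):
    """Volatility factor: decreases from ``v_hi`` at W = 0 toward ``v_lo``.

    ``VO(W) = v_hi - (v_hi - v_lo) * W / (W + W_med)``; at ``W = W_med`` it
    is midway between the bounds.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("volatility: weight must be nonnegative")
    out = params.v_hi - (params.v_hi - params.v_lo) * (W / (W + params.W_med))
    return out[()] if out.ndim == 0 else out


def ltp_mean_amplitude(n_st, params: ModelParams):
    """Mean LTP increment a1 as a function of the cluster's strong count.

    Falls linearly from ``x2`` (no strong synapses) to ``x1`` (all strong):
    ``a1 = x2 - (x2 - x1) * N_st / N_cl``.  In the ``fixed_ltp`` variant the
    cluster coupling is removed and ``a1_fixed`` is returned regardless.
    """
    n_st = np.asarray(n_st)
    if np.any((n_st < 0) | (n_st > params.N_cl)):
        raise ValueError(f"ltp_mean_amplitude: N_st must lie in [0, {params.N_cl}]")
    if params.variant == "fixed_ltp":
        out = np.full(n_st.shape, params.a1_fixed)
    else:
        out = params.x2 - (params.x2 - params.x1) * (n_st / params.N_cl)
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def draw_increment(mean, params: ModelParams, rng: np.random.Generator,
                   kind: str = "ltp", size=None):
    """Draw a nonnegative stochastic increment r1 (LTP) or r2 (LTD).

    Standard and ``fixed_ltp`` variants: Gaussian with the given mean and
    sd = mean / sd_ratio, negatives clamped to zero.  In the
    ``exponential_increments`` variant the draw is exponential with rate
    ``lambda1`` (LTP) or ``lambda2`` (LTD); the mean argument only selects
    which rate applies.
    """
    if kind not in ("ltp", "ltd"):
        raise ValueError(f"kind must be 'ltp' or 'ltd', got {kind!r}")
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("draw_increment: mean must be positive")
    if params.variant == "exponential_increments":
        lam = params.lambda1 if kind == "ltp" else params.lambda2
        return rng.exponential(1.0 / lam, size=size)
    sd = mean / params.sd_ratio
    draw = rng.normal(mean, sd, size=size)
    return np.maximum(draw, 0.0)


def ltp_amplitude(W, r1, params: ModelParams):
    """LTP amplitude: ``W * r1 * VO(W) * (1 - k_hi * W / (W + W_hi))``.

    Proportional to the preexisting weight and the volatility factor; the
    final bracket saturates growth of very large synapses.
    """
    W = np.asarray(W, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if np.any(W < 0) or np.any(r1 < 0):
        raise ValueError("ltp_amplitude: W and r1 must be nonnegative")
    out = W * r1 * volatility(W, params) * (1.0 - params.k_hi * W / (W + params.W_hi))
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def ltd_amplitude(W, r2, params: ModelParams):
    """LTD amplitude: ``W * r2 * VO(W)``."""
    W = np.asarray(W, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(W < 0) or np.any(r2 < 0):
        raise ValueError("ltd_amplitude: W and r2 must be nonnegative")
    out = W * r2 * volatility(W, params)
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def regeneration_probability(n_st, params: ModelParams):
    """Per-day regeneration probability of a silent synapse.

    ``P_ACT = P_bas * N_st / N_cl``, rising to the ceiling ``P_bas`` when
    every synapse in the cluster is strong.  Zero under the
    ``no_regeneration`` variant.
    """
    n_st = np.asarray(n_st)
    if np.any((n_st < 0) | (n_st > params.N_cl)):
        raise ValueError(f"regeneration_probability: N_st must lie in [0, {params.N_cl}]")
    if params.variant == "no_regeneration":
        out = np.zeros(n_st.shape)
    else:
        out = params.P_bas * (n_st / params.N_cl)
    out = np.asarray(out, dtype=float)
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# one simulated day for one cluster
# ---------------------------------------------------------------------------


def draw_day_randoms(params: ModelParams, rng: np.random.Generator, shape):
    """Raw random draws for one day, in a fixed state-independent order.

    ``shape`` is the synapse-array shape, e.g. ``(N_cl,)`` for one cluster or
    ``(n_clusters, N_cl)`` for an ensemble.  Returns ``(e1, e2, u)`` where
    ``e1``/``e2`` feed the LTP/LTD increments (standard normals, or uniforms
    for the exponential variant) and ``u`` are the regeneration uniforms.
    Draw order is cluster-major, synapse index, LTP draw then LTD draw,
    followed by all regeneration uniforms.  Draws are made for every synapse
    regardless of status, so the stream layout does not depend on the state.
    """
    shape = tuple(shape)
    if params.variant == "exponential_increments":
        e = rng.random(shape + (2,))
    else:
        e = rng.standard_normal(shape + (2,))
    u = rng.random(shape)
    return e[..., 0], e[..., 1], u


def increments_from_draws(e1, e2, a1, params: ModelParams):
    """Map raw draws to nonnegative increments (r1, r2).

    ``a1`` is the (possibly cluster-dependent) mean LTP amplitude; the
    increment sd tracks the mean through the fixed mean/sd ratio.  In the
    ``fixed_ltp`` variant the configured ``sd1_fixed`` is used instead, and
    in the ``exponential_increments`` variant the raw uniforms are mapped
    through the inverse exponential CDF.
    """
    if params.variant == "exponential_increments":
        r1 = -np.log1p(-np.asarray(e1)) / params.lambda1
        r2 = -np.log1p(-np.asarray(e2)) / params.lambda2
        return r1, r2
    if params.variant == "fixed_ltp":
        sd1 = params.sd1_fixed
    else:
        sd1 = a1 / params.sd_ratio
    r1 = np.maximum(a1 + sd1 * np.asarray(e1), 0.0)
    r2 = np.maximum(params.a2 + (params.a2 / params.sd_ratio) * np.asarray(e2), 0.0)
    return r1, r2


def step_cluster(cluster: ClusterState, params: ModelParams,
                 rng: np.random.Generator | None = None,
                 draws=None, return_delta: bool = False):
    """Advance one cluster by one day (naive per-synapse loop).

    The day proceeds synchronously: (a) the strong flags and ``N_st`` are
    snapshotted from the start-of-day state; (b) each active synapse receives
    the net update ``W + A_LTP - A_LTD``; (c) an active synapse whose updated
    weight fell below ``T_wk`` is silenced to ``W_sil``; (d) each synapse
    that was silent at day start regenerates with probability ``P_ACT`` iff
    at least one chain neighbour was strong in the snapshot, resetting its
    weight to ``W_reset``.  A synapse can never be silenced and regenerate on
    the same day.

    ``draws`` optionally supplies the raw randoms ``(e1, e2, u)`` (as from
    :func:`draw_day_randoms`) so that a shared draw schedule can be replayed;
    otherwise they are drawn from ``rng``.

    Returns the new ``ClusterState``; with ``return_delta=True`` also the
    per-synapse pre-silencing weight change (NaN for synapses silent at day
    start).
    """
    n = cluster.n_cl
    if n != params.N_cl:
        raise ValueError(f"cluster has {n} synapses but params.N_cl = {params.N_cl}")
    if draws is None:
        if rng is None:
            raise ValueError("step_cluster needs either rng or draws")
        e1, e2, u = draw_day_randoms(params, rng, (n,))
    else:
        e1, e2, u = draws

    strong = cluster.weights > params.T_st
    n_st = int(np.count_nonzero(strong))
    a1 = ltp_mean_amplitude(n_st, params)
    p_act = regeneration_probability(n_st, params)
    r1, r2 = increments_from_draws(e1, e2, a1, params)

    w_new = cluster.weights.copy()
    active_new = cluster.active.copy()
    delta = np.full(n, np.nan)
    for i in range(n):
        if not cluster.active[i]:
            continue
        w = cluster.weights[i]
        d = ltp_amplitude(w, r1[i], params) - ltd_amplitude(w, r2[i], params)
        delta[i] = d
        w_updated = w + d
        if w_updated < params.T_wk:
            w_new[i] = params.W_sil
            active_new[i] = False
        else:
            w_new[i] = w_updated
    for i in range(n):
        if cluster.active[i]:
            continue  # regeneration applies only to synapses silent at day start
        neighbour_strong = (i > 0 and strong[i - 1]) or (i < n - 1 and strong[i + 1])
        if neighbour_strong and u[i] < p_act:
            w_new[i] = params.W_reset
            active_new[i] = True
    out = ClusterState(w_new, active_new)
    if return_delta:
        return out, delta
    return out
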