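"""Vectorized simulation of many independent clusters.

The ensemble holds the weights and status flags of ``n_clusters`` chains of
``N_cl`` synapses as 2-D arrays and advances them day by day with the same
synchronous semantics as :func:`spinedyn.model_core.step_cluster`: strong
flags are snapshotted at day start, all active synapses are updated, then
silencing is applied, then adjacency-gated regeneration of synapses that
were silent at day start.  Both drivers consume raw randoms produced by
:func:`spinedyn.model_core.draw_day_randoms`, so given the same draws the
vectorized day step and the per-synapse loop agree bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .model_core import draw_day_randoms, increments_from_draws
from .params import ModelParams

__all__ = ["EnsembleState", "TrajectoryRecord", "init_ensemble", "run", "day_step_arrays"]

logger = logging.getLogger(__name__)

RECORD_FIELDS = ("weights", "deltas", "n_strong", "n_active")


@dataclasses.dataclass
class EnsembleState:
    """Weights and status of all clusters, plus the day counter and RNG."""

    weights: np.ndarray  # (n_clusters, N_cl) float
    active: np.ndarray   # (n_clusters, N_cl) bool
    day: int
    rng: np.random.Generator

    @property
    def n_clusters(self) -> int:
        return self.weights.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.weights.size

    def n_strong(self, params: ModelParams) -> np.ndarray:
        """Per-cluster strong count N_st."""
        return np.count_nonzero(self.weights > params.T_st, axis=1)

    def copy_with_rng(self, rng: np.random.Generator) -> "EnsembleState":
        """Independent copy of the synaptic state driven by a new stream."""
        return EnsembleState(self.weights.copy(), self.active.copy(), self.day, rng)


@dataclasses.dataclass
class TrajectoryRecord:
    """Per-day recorded quantities along a run.

    All arrays share the recorded-day axis.  ``weights`` are end-of-day
    weights; ``deltas`` are the pre-silencing daily weight changes of
    synapses active at day start (NaN elsewhere); regeneration jumps are not
    counted as deltas.
    """

    days: np.ndarray                      # (T,)
    weights: np.ndarray | None = None     # (T, n_clusters, N_cl)
    deltas: np.ndarray | None = None      # (T, n_clusters, N_cl)
    n_strong: np.ndarray | None = None    # (T, n_clusters)
    n_active: np.ndarray | None = None    # (T,)

    def summary_frame(self, params: ModelParams) -> pd.DataFrame:
        """Per-day summary table: day, mean weight, active count, mean N_st."""
        cols: dict[str, np.ndarray] = {"day": self.days}
        if self.weights is not None:
            cols["mean_W"] = self.weights.mean(axis=(1, 2))
        if self.n_active is not None:
            cols["n_active"] = self.n_active
        if self.n_strong is not None:
            cols["mean_N_st"] = self.n_strong.mean(axis=1)
        return pd.DataFrame(cols)

    def long_frame(self) -> pd.DataFrame:
        """Long-format table (day, cluster, synapse, W, delta_W)."""
        if self.weights is None:
            raise ValueError("weights were not recorded")
        t, c, n = self.weights.shape
        days = np.repeat(self.days, c * n)
        cluster = np.tile(np.repeat(np.arange(c), n), t)
        synapse = np.tile(np.arange(n), t * c)
        data = {
            "day": days,
            "cluster": cluster,
            "synapse": synapse,
            "W": self.weights.ravel(),
        }
        if self.deltas is not None:
            data["delta_W"] = self.deltas.ravel()
        return pd.DataFrame(data)


def init_ensemble(n_clusters: int, params: ModelParams, seed) -> EnsembleState:
    """Fresh ensemble: every synapse active at weight 1.0, day 0.

    ``seed`` may be an integer, a SeedSequence, or a Generator; the run is
    fully determined by it.  The all-active uniform start is erased by
    burn-in before any quantity is measured.
    """
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1 (got {n_clusters})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return EnsembleState(
        weights=np.ones((n_clusters, params.N_cl)),
        active=np.ones((n_clusters, params.N_cl), dtype=bool),
        day=0,
        rng=rng,
    )


def day_step_arrays(W: np.ndarray, active: np.ndarray, params: ModelParams,
                    e1: np.ndarray, e2: np.ndarray, u: np.ndarray):
    """Vectorized one-day update of ``(n_clusters, N_cl)`` state arrays.

    Returns ``(W_new, active_new, delta, n_st)`` where ``delta`` is the
    pre-silencing weight change (NaN for synapses silent at day start) and
    ``n_st`` the start-of-day per-cluster strong count.
    """
    p = params
    strong = W > p.T_st
    n_st = np.count_nonzero(strong, axis=1)  # (C,)
    if p.variant == "fixed_ltp":
        a1 = np.full(n_st.shape, p.a1_fixed)
    else:
        a1 = p.x2 - (p.x2 - p.x1) * (n_st / p.N_cl)
    r1, r2 = increments_from_draws(e1, e2, a1[:, None], p)

    vo = p.v_hi - (p.v_hi - p.v_lo) * (W / (W + p.W_med))
    a_ltp = W * r1 * vo * (1.0 - p.k_hi * W / (W + p.W_hi))
    a_ltd = W * r2 * vo
    delta = a_ltp - a_ltd
    w_updated = W + delta

    w_new = np.where(active, w_updated, W)
    silenced = active & (w_updated < p.T_wk)
    w_new = np.where(silenced, p.W_sil, w_new)
    active_new = active & ~silenced

    # adjacency-gated regeneration of synapses silent at day start
    if p.variant == "no_regeneration":
        p_act = np.zeros(n_st.shape)
    else:
        p_act = p.P_bas * (n_st / p.N_cl)
    left = np.zeros_like(strong)
    right = np.zeros_like(strong)
    left[:, 1:] = strong[:, :-1]
    right[:, :-1] = strong[:, 1:]
    eligible = (~active) & (left | right)
    regen = eligible & (u < p_act[:, None])
    w_new = np.where(regen, p.W_reset, w_new)
    active_new = active_new | regen

    delta = np.where(active, delta, np.nan)
    return w_new, active_new, delta, n_st


def run(ensemble: EnsembleState, n_days: int, params: ModelParams,
        record_every: int | None = 1,
        fields: tuple[str, ...] = RECORD_FIELDS,
        log_every: int = 1000) -> TrajectoryRecord:
    """Advance every cluster by ``n_days``, recording along the way.

    The ensemble is mutated in place and reflects the final day.  State is
    recorded on every day whose offset from the start is a multiple of
    ``record_every`` (counting the day just completed, so the final day is
    recorded whenever ``n_days`` is a multiple); ``record_every=None``
    disables recording (burn-in mode).  ``fields`` selects which quantities
    are kept, to bound memory on long recorded runs.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1 (got {n_days})")
    unknown = set(fields) - set(RECORD_FIELDS)
    if unknown:
        raise ValueError(f"unknown record fields: {sorted(unknown)}")
    if ensemble.weights.shape[1] != params.N_cl:
        raise ValueError("ensemble cluster size does not match params.N_cl")

    rec_days: list[int] = []
    rec: dict[str, list] = {f: [] for f in fields}
    W, active = ensemble.weights, ensemble.active
    for i in range(n_days):
        e1, e2, u = draw_day_randoms(params, ensemble.rng, W.shape)
        W, active, delta, n_st = day_step_arrays(W, active, params, e1, e2, u)
        ensemble.day += 1
        if record_every is not None and (i + 1) % record_every == 0:
            rec_days.append(ensemble.day)
            if "weights" in rec:
                rec["weights"].append(W.copy())
            if "deltas" in rec:
                rec["deltas"].append(delta)
            if "n_strong" in rec:
                rec["n_strong"].append(np.count_nonzero(W > params.T_st, axis=1))
            if "n_active" in rec:
                rec["n_active"].append(int(np.count_nonzero(active)))
        if log_every and (i + 1) % log_every == 0:
            logger.info(
                "day %d: mean W %.4f, active %d/%d",
                ensemble.day, W.mean(), int(np.count_nonzero(active)), W.size,
            )
    ensemble.weights, ensemble.active = W, active

    return TrajectoryRecord(
        days=np.asarray(rec_days, dtype=int),
        weights=np.asarray(rec["weights"]) if "weights" in rec and rec_days else None,
        deltas=np.asarray(rec["deltas"]) if "deltas" in rec and rec_days else None,
        n_strong=np.asarray(rec["n_strong"]) if "n_strong" in rec and rec_days else None,
        n_active=np.asarray(rec["n_active"]) if "n_active" in rec and rec_days else None,
    )
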