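"""Scripted experiments: steady state, perturbation, memory imprint,
decorrelation, and cluster stability.

Each protocol is fully determined by its parameters and seed, runs its own
ensemble (1,000 clusters by default) through burn-in, and returns a
:class:`ProtocolResult` bundling named scalar summaries and tabular outputs.
Burn-in defaults to 50,000 days so that every quantity is measured at steady
state; the distribution is stationary well before that, so shorter burn-ins
can be requested for quicker, statistically equivalent runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import analysis
from .ensemble import EnsembleState, day_step_arrays, init_ensemble, run
from .model_core import draw_day_randoms
from .params import ModelParams

__all__ = [
    "ProtocolResult",
    "steady_state_protocol",
    "perturbation_protocol",
    "memory_imprint_protocol",
    "decorrelation_protocol",
    "cluster_stability_protocol",
]

DEFAULT_CLUSTERS = 1_000
DEFAULT_BURN_IN = 50_000


@dataclasses.dataclass
class ProtocolResult:
    """Outcome of one scripted experiment.

    ``summaries`` are named scalar statistics; ``tables`` are the tabular
    outputs (histograms, time courses, profiles); ``artifacts`` records the
    paths of any files written for this result.
    """

    name: str
    params_used: ModelParams
    seed: int
    summaries: dict[str, float]
    tables: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    artifacts: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.summaries.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite summaries: {bad}")


def _one_recorded_day(ens: EnsembleState, params: ModelParams):
    """Advance one day; return (W_pre, active_pre, delta) for that day."""
    w_pre = ens.weights.copy()
    active_pre = ens.active.copy()
    e1, e2, u = draw_day_randoms(params, ens.rng, w_pre.shape)
    w_new, active_new, delta, _ = day_step_arrays(w_pre, active_pre, params, e1, e2, u)
    ens.weights, ens.active = w_new, active_new
    ens.day += 1
    return w_pre, active_pre, delta


def steady_state_protocol(params: ModelParams, seed: int,
                          n_clusters: int = DEFAULT_CLUSTERS,
                          burn_in_days: int = DEFAULT_BURN_IN,
                          n_bins: int = 80,
                          delta_fit_epsilon: float = 0.01) -> ProtocolResult:
    """Steady-state distribution and daily-change statistics.

    Runs the ensemble past burn-in, then takes one further day to collect the
    synchronous weight updates.  Produces the 80-bin log-spaced weight
    histogram with its log-normal fits (MLE on active synapses, plus a
    histogram least-squares fit for parity with figure-style fits), the
    daily-change histogram with a normal fit excluding the sharp near-zero
    peak, the mean relative daily change, the active count, and the binned
    profile of the daily change against the preexisting weight.
    """
    ens = init_ensemble(n_clusters, params, seed)
    run(ens, burn_in_days, params, record_every=None)
    w_pre, active_pre, delta = _one_recorded_day(ens, params)

    d_active = delta[active_pre]
    w_active_pre = w_pre[active_pre]

    hist_all = analysis.weight_histogram(ens.weights, scope="all", n_bins=n_bins)
    fit_mle = analysis.fit_lognormal(ens.weights[ens.active], method="mle")
    fit_hist = analysis.fit_lognormal(ens.weights[ens.active], method="histogram")
    fit_dw = analysis.fit_normal(
        d_active, method="histogram", exclude_epsilon=delta_fit_epsilon, n_bins=n_bins
    )
    fit_dw_moments = analysis.fit_normal(d_active, method="moments")
    profile = analysis.delta_vs_w_profile(w_active_pre, d_active, n_bins=n_bins)

    dw_counts, dw_edges = np.histogram(d_active, bins=n_bins)
    dw_hist = pd.DataFrame(
        {"bin_low": dw_edges[:-1], "bin_high": dw_edges[1:], "count": dw_counts}
    )

    n_active = int(ens.active.sum())
    lw = np.log(ens.weights[ens.active])
    summaries = {
        "seed": float(seed),
        "n_synapses": float(ens.n_synapses),
        "n_active": float(n_active),
        "silent_fraction": float(1.0 - n_active / ens.n_synapses),
        "mean_w_all": float(ens.weights.mean()),
        "mean_w_active": float(ens.weights[ens.active].mean()),
        "percent_daily_change": analysis.percent_daily_change(w_active_pre, d_active),
        "lognormal_mu": fit_mle.params["mu"],
        "lognormal_sigma": fit_mle.params["sigma"],
        "lognormal_sigma_histfit": fit_hist.params["sigma"],
        "delta_sd_histfit": fit_dw.params["sd"],
        "delta_mean_histfit": fit_dw.params["mean"],
        "delta_sd_moments": fit_dw_moments.params["sd"],
        "mean_n_strong": float(ens.n_strong(params).mean()),
        "active_log_range": float(lw.max() - lw.min()),
    }
    return ProtocolResult(
        name="steady_state",
        params_used=params,
        seed=seed,
        summaries=summaries,
        tables={"weight_histogram": hist_all.frame(), "delta_histogram": dw_hist,
                "delta_vs_w_profile": profile},
    )


def perturbation_protocol(params: ModelParams, seed: int, ltp_scale: float,
                          n_clusters: int = DEFAULT_CLUSTERS,
                          burn_in_days: int = DEFAULT_BURN_IN,
                          post_days: int = 20_000) -> ProtocolResult:
    """Response of the steady state to a scaled mean LTP amplitude.

    Runs to steady state, snapshots the baseline, then continues a copy of
    the equilibrated ensemble under parameters with the mean LTP amplitude
    multiplied by ``ltp_scale`` (both ``x1`` and ``x2`` in the standard
    model; ``a1_fixed`` and ``sd1_fixed`` in the fixed-LTP variant) for
    ``post_days`` of re-equilibration.  Reports the relative change of the
    mean weight over all synapses (silent ones sit at their basal weight) and
    over active synapses only, plus the perturbed silent percentage.
    """
    if not (0 < ltp_scale <= 1):
        raise ValueError(f"ltp_scale must lie in (0, 1], got {ltp_scale}")
    ens = init_ensemble(n_clusters, params, np.random.SeedSequence(seed).spawn(1)[0])
    run(ens, burn_in_days, params, record_every=None)
    mean_base_all = float(ens.weights.mean())
    mean_base_active = float(ens.weights[ens.active].mean())

    perturbed = params.scaled_ltp(ltp_scale)
    child = np.random.SeedSequence(seed).spawn(2)[1]
    ens_p = ens.copy_with_rng(np.random.default_rng(child))
    run(ens_p, post_days, perturbed, record_every=None)

    mean_pert_all = float(ens_p.weights.mean())
    active = ens_p.active
    mean_pert_active = float(ens_p.weights[active].mean()) if active.any() else float(
        ens_p.weights.mean()
    )
    summaries = {
        "seed": float(seed),
        "ltp_scale": float(ltp_scale),
        "mean_w_baseline": mean_base_all,
        "mean_w_perturbed": mean_pert_all,
        "mean_w_decrease_pct": 100.0 * (mean_base_all - mean_pert_all) / mean_base_all,
        "mean_w_baseline_active": mean_base_active,
        "mean_w_perturbed_active": mean_pert_active,
        "mean_w_decrease_pct_active": 100.0
        * (mean_base_active - mean_pert_active) / mean_base_active,
        "silent_pct_perturbed": 100.0 * (1.0 - active.sum() / ens_p.n_synapses),
        "silent_pct_baseline": 100.0 * (1.0 - ens.active.sum() / ens.n_synapses),
    }
    return ProtocolResult(
        name="perturbation", params_used=perturbed, seed=seed, summaries=summaries
    )


def memory_imprint_protocol(params: ModelParams, seed: int,
                            t_reset: int = 200,
                            w_high: float = 5.0, w_low: float = 0.5,
                            follow_days: int = 700,
                            n_clusters: int = DEFAULT_CLUSTERS,
                            burn_in_days: int = DEFAULT_BURN_IN,
                            sample_every: int = 1) -> ProtocolResult:
    """Persistence of an imposed engram-like pattern of strong synapses.

    After burn-in the steady-state mean weight is recorded; ``t_reset`` days
    later the first half of each cluster is reset to ``w_high`` and the
    second half to ``w_low`` (all marked active), emulating strong imposed
    potentiation of a fixed subset.  The ensemble then evolves for
    ``follow_days`` while the mean and standard deviation of the imprinted
    subset's weights are tracked.
    """
    if w_high < params.T_wk or w_low < params.T_wk:
        raise ValueError("w_high and w_low must not fall below the silencing threshold")
    ens = init_ensemble(n_clusters, params, seed)
    run(ens, burn_in_days, params, record_every=None)
    steady_mean = float(ens.weights.mean())
    run(ens, t_reset, params, record_every=None)

    half = params.N_cl // 2
    ens.weights[:, :half] = w_high
    ens.weights[:, half:] = w_low
    ens.active[:, :] = True

    rows = [
        {
            "day": 0,
            "imprinted_mean": float(ens.weights[:, :half].mean()),
            "imprinted_sd": float(ens.weights[:, :half].std(ddof=1)),
            "other_mean": float(ens.weights[:, half:].mean()),
        }
    ]
    for start in range(0, follow_days, sample_every):
        step = min(sample_every, follow_days - start)
        run(ens, step, params, record_every=None)
        rows.append(
            {
                "day": start + step,
                "imprinted_mean": float(ens.weights[:, :half].mean()),
                "imprinted_sd": float(ens.weights[:, :half].std(ddof=1)),
                "other_mean": float(ens.weights[:, half:].mean()),
            }
        )
    trace = pd.DataFrame(rows)
    final = trace.iloc[-1]
    summaries = {
        "seed": float(seed),
        "steady_state_mean_w": steady_mean,
        "imprinted_mean_initial": float(trace["imprinted_mean"].iloc[0]),
        "imprinted_mean_final": float(final["imprinted_mean"]),
        "imprinted_sd_final": float(final["imprinted_sd"]),
        "imprinted_over_steady_ratio": float(final["imprinted_mean"] / steady_mean),
        "imprinted_minus_sd_final": float(
            final["imprinted_mean"] - final["imprinted_sd"]
        ),
    }
    return ProtocolResult(
        name="memory_imprint", params_used=params, seed=seed,
        summaries=summaries, tables={"imprint_trace": trace},
    )


def decorrelation_protocol(params: ModelParams, seed: int,
                           horizon: int = 1_500, sample_every: int = 10,
                           n_clusters: int = DEFAULT_CLUSTERS,
                           burn_in_days: int = DEFAULT_BURN_IN,
                           with_offset: bool = False) -> ProtocolResult:
    """Decay of the correlation between weights and an earlier snapshot.

    Fixes the reference weights of all synapses at a steady-state day, then
    evolves the unperturbed ensemble, computing the Pearson correlation
    against the reference every ``sample_every`` days out to ``horizon``,
    and fits an exponential decay to obtain the time constant tau.
    """
    ens = init_ensemble(n_clusters, params, seed)
    run(ens, burn_in_days, params, record_every=None)
    reference = ens.weights.ravel().copy()
    days = [0]
    r_values = [1.0]
    for start in range(0, horizon, sample_every):
        step = min(sample_every, horizon - start)
        run(ens, step, params, record_every=None)
        days.append(start + step)
        r_values.append(analysis.pearson_r(reference, ens.weights.ravel()))
    fit = analysis.fit_decay_time_constant(days, r_values, with_offset=with_offset)
    trace = pd.DataFrame({"day": days, "R": r_values})
    summaries = {
        "seed": float(seed),
        "tau_days": fit.params["tau"],
        "r_final": float(r_values[-1]),
        "r_initial": float(r_values[0]),
    }
    if with_offset:
        summaries["offset"] = fit.params["offset"]
    return ProtocolResult(
        name="decorrelation", params_used=params, seed=seed,
        summaries=summaries, tables={"correlation_trace": trace},
    )


def cluster_stability_protocol(params: ModelParams, seed: int,
                               horizon: int = 2_000,
                               n_clusters: int = DEFAULT_CLUSTERS,
                               burn_in_days: int = DEFAULT_BURN_IN,
                               n_sample_clusters: int = 5) -> ProtocolResult:
    """Stability of the per-cluster strong-synapse count over years.

    Records N_st for every cluster daily over ``horizon`` days at steady
    state and reports the fraction of cluster-days spent in the 4-7 band,
    together with distribution summaries used to diagnose bimodality of
    variant runs (silent fraction, median active weight).
    """
    ens = init_ensemble(n_clusters, params, seed)
    run(ens, burn_in_days, params, record_every=None)
    rec = run(ens, horizon, params, record_every=1, fields=("n_strong", "n_active"))
    n_st = rec.n_strong
    frac = float(np.mean((n_st >= 4) & (n_st <= 7)))
    active = ens.active
    summaries = {
        "seed": float(seed),
        "fraction_cluster_days_4_7": frac,
        "mean_n_strong": float(n_st.mean()),
        "sd_n_strong": float(n_st.std(ddof=1)),
        "silent_fraction_final": float(1.0 - active.sum() / ens.n_synapses),
        "median_active_w": float(np.median(ens.weights[active]))
        if active.any() else 0.0,
    }
    sample = pd.DataFrame(
        {"day": rec.days, **{f"cluster_{c}": n_st[:, c]
                             for c in range(min(n_sample_clusters, n_st.shape[1]))}}
    )
    return ProtocolResult(
        name="cluster_stability", params_used=params, seed=seed,
        summaries=summaries, tables={"n_strong_sample": sample},
    )
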