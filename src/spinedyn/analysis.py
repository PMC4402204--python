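"""Statistics applied to simulated trajectories.

Histograms with log-spaced bins, log-normal and normal distribution fits
(maximum likelihood and histogram least squares), the daily relative weight
change, binned profiles of the daily change against the preexisting weight,
the Pearson correlation used for decorrelation curves, exponential-decay time
constant fitting, and the empirical piecewise-linear spine-volume change
model used to calibrate the one-day time step.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "HistogramResult",
    "FitError",
    "weight_histogram",
    "fit_lognormal",
    "fit_normal",
    "percent_daily_change",
    "delta_vs_w_profile",
    "pearson_r",
    "fit_decay_time_constant",
    "yasumatsu_c1",
]


class FitError(RuntimeError):
    """Raised when a distribution or curve fit is degenerate or fails."""


@dataclasses.dataclass
class FitResult:
    """Fitted distribution or decay-curve parameters.

    ``family`` is one of ``lognormal`` (params ``mu``, ``sigma`` of ln W),
    ``normal`` (params ``mean``, ``sd``) or ``exponential_decay`` (params
    ``tau`` and optionally ``offset``).  ``n`` is the sample size and
    ``method`` how the estimate was obtained.
    """

    family: str
    params: dict[str, float]
    n: int
    method: str


@dataclasses.dataclass
class HistogramResult:
    """Binned counts; edges are log-spaced for weights, linear for changes."""

    bin_edges: np.ndarray
    counts: np.ndarray
    scope: str = "all"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def weight_histogram(weights, active=None, scope: str = "all",
                     n_bins: int = 80) -> HistogramResult:
    """Histogram of weights with bins of equal width in natural-log units.

    ``scope`` selects all synapses or only active ones (requires the
    ``active`` mask).  Counts are conserved: they sum to the number of
    in-scope synapses.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if scope not in ("all", "active-only"):
        raise ValueError(f"scope must be 'all' or 'active-only', got {scope!r}")
    if scope == "active-only":
        if active is None:
            raise ValueError("scope='active-only' requires the active mask")
        weights = weights[np.asarray(active, dtype=bool).ravel()]
    if weights.size == 0:
        raise ValueError("no weights in scope")
    if np.any(weights <= 0):
        raise ValueError("log binning requires strictly positive weights")
    lo, hi = np.log(weights.min()), np.log(weights.max())
    if lo == hi:  # all-equal degenerate case: one occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.exp(np.linspace(lo, hi, n_bins + 1))
    edges[0] = min(edges[0], weights.min())
    edges[-1] = max(edges[-1], weights.max())
    counts, _ = np.histogram(weights, bins=edges)
    return HistogramResult(bin_edges=edges, counts=counts, scope=scope)


def _gauss_curve(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_lognormal(weights, method: str = "mle", n_bins: int = 80) -> FitResult:
    """Fit a log-normal distribution to positive weights.

    ``method='mle'`` gives the maximum-likelihood estimates (mean and sd of
    ln W).  ``method='histogram'`` least-squares fits a Gaussian to the
    80-bin histogram of ln W, for parity with figure-style fits to binned
    curves; the two can differ when the sample departs from log-normality.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w <= 0):
        raise FitError("log-normal fit requires strictly positive weights")
    if w.size < 10:
        raise FitError(f"need at least 10 weights, got {w.size}")
    logw = np.log(w)
    if np.ptp(logw) == 0:
        raise FitError("degenerate sample: zero spread")
    if method == "mle":
        mu, sigma = float(logw.mean()), float(logw.std(ddof=1))
    elif method == "histogram":
        counts, edges = np.histogram(logw, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p0 = [float(counts.max()), float(logw.mean()), float(logw.std(ddof=1))]
        try:
            popt, _ = optimize.curve_fit(_gauss_curve, centers, counts, p0=p0)
        except RuntimeError as exc:  # pragma: no cover - solver failure
            raise FitError(f"histogram fit failed: {exc}") from exc
        mu, sigma = float(popt[1]), float(abs(popt[2]))
    else:
        raise ValueError(f"method must be 'mle' or 'histogram', got {method!r}")
    return FitResult(
        family="lognormal", params={"mu": mu, "sigma": sigma}, n=w.size, method=method
    )


def fit_normal(deltas, method: str = "moments", exclude_epsilon: float | None = None,
               n_bins: int = 80, hist_range=None) -> FitResult:
    """Fit a normal distribution to daily weight changes.

    ``method='moments'`` returns the sample mean and sd.  The peak-excluding
    variant discards values (or, with ``method='histogram'``, bins) with
    ``|x| <= exclude_epsilon`` before fitting, mirroring figure-style fits
    that ignore a sharp spike of near-zero changes: the histogram fit then
    recovers the sd of the broad component rather than the pooled moments.
    """
    x = np.asarray(deltas, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"need at least 10 finite values, got {x.size}")
    if method == "moments":
        if exclude_epsilon is not None:
            x = x[np.abs(x) > exclude_epsilon]
            if x.size < 10:
                raise FitError("peak exclusion removed nearly all values")
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            raise FitError("degenerate sample: zero spread")
    elif method == "histogram":
        if hist_range is None:
            half = float(np.quantile(np.abs(x), 0.999))
            hist_range = (-half, half)
        counts, edges = np.histogram(x, bins=n_bins, range=hist_range)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if exclude_epsilon is not None:
            keep = np.abs(centers) > exclude_epsilon
            counts, centers = counts[keep], centers[keep]
        p0 = [float(counts.max()), 0.0, float(x.std(ddof=1))]
        try:
            popt, _ = optimize.curve_fit(_gauss_curve, centers, counts, p0=p0)
        except RuntimeError as exc:  # pragma: no cover - solver failure
            raise FitError(f"histogram fit failed: {exc}") from exc
        mean, sd = float(popt[1]), float(abs(popt[2]))
    else:
        raise ValueError(f"method must be 'moments' or 'histogram', got {method!r}")
    return FitResult(family="normal", params={"mean": mean, "sd": sd},
                     n=x.size, method=method)


def percent_daily_change(w_pre, deltas) -> float:
    """Mean relative daily weight change, as a percentage.

    ``100 * mean(|delta| / W_pre)`` over matched arrays of start-of-day
    weights and pre-silencing daily changes of active synapses.
    """
    w_pre = np.asarray(w_pre, dtype=float).ravel()
    d = np.asarray(deltas, dtype=float).ravel()
    if w_pre.shape != d.shape:
        raise ValueError("w_pre and deltas must have matching shapes")
    keep = np.isfinite(d)
    w_pre, d = w_pre[keep], d[keep]
    if w_pre.size == 0:
        raise ValueError("no finite daily changes supplied")
    if np.any(w_pre <= 0):
        raise ValueError("start-of-day weights must be positive")
    return float(100.0 * np.mean(np.abs(d) / w_pre))


def delta_vs_w_profile(w_pre, deltas, n_bins: int = 80) -> pd.DataFrame:
    """Binned statistics of the daily change against the preexisting weight.

    Bins of ``W_pre`` are equally spaced on a log scale.  Returns per-bin
    signed mean and sd of the change together with the mean magnitude and
    the mean relative magnitude.
    """
    w_pre = np.asarray(w_pre, dtype=float).ravel()
    d = np.asarray(deltas, dtype=float).ravel()
    if w_pre.shape != d.shape:
        raise ValueError("w_pre and deltas must have matching shapes")
    keep = np.isfinite(d) & (w_pre > 0)
    w_pre, d = w_pre[keep], d[keep]
    if w_pre.size == 0:
        raise ValueError("no finite samples supplied")
    logw = np.log(w_pre)
    lo, hi = logw.min(), logw.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(logw, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        db = d[sel]
        rows.append(
            {
                "bin_low": float(np.exp(edges[b])),
                "bin_high": float(np.exp(edges[b + 1])),
                "w_center": float(np.exp(0.5 * (edges[b] + edges[b + 1]))),
                "n": n,
                "mean_dw": float(db.mean()),
                "sd_dw": float(db.std(ddof=1)) if n > 1 else np.nan,
                "mean_abs_dw": float(np.abs(db).mean()),
                "mean_rel_abs_dw": float(np.mean(np.abs(db) / w_pre[sel])),
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r needs two equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r is undefined for zero-variance samples")
    return float(stats.pearsonr(x, y).statistic)


def fit_decay_time_constant(days, r_values, with_offset: bool = False) -> FitResult:
    """Least-squares exponential time constant of a correlation decay curve.

    Fits ``R(t) = exp(-t / tau)`` or, with ``with_offset``, the form
    ``R(t) = c + (1 - c) * exp(-t / tau)``.
    """
    t = np.asarray(days, dtype=float).ravel()
    r = np.asarray(r_values, dtype=float).ravel()
    if t.shape != r.shape or t.size < 10:
        raise FitError("need at least 10 matched (day, R) samples")
    if np.ptp(r) < 1e-9:
        raise FitError("degenerate series: R does not decay")
    span = float(t.max() - t.min()) or 1.0
    try:
        if with_offset:
            popt, _ = optimize.curve_fit(
                lambda tt, tau, c: c + (1 - c) * np.exp(-tt / tau),
                t, r, p0=[span / 3.0, 0.0],
                bounds=([1e-6, -1.0], [np.inf, 1.0]),
            )
            params = {"tau": float(popt[0]), "offset": float(popt[1])}
        else:
            popt, _ = optimize.curve_fit(
                lambda tt, tau: np.exp(-tt / tau),
                t, r, p0=[span / 3.0], bounds=([1e-6], [np.inf]),
            )
            params = {"tau": float(popt[0])}
    except RuntimeError as exc:
        raise FitError(f"decay fit failed: {exc}") from exc
    return FitResult(family="exponential_decay", params=params, n=t.size,
                     method="least-squares")


def yasumatsu_c1(v):
    """Empirical piecewise-linear daily spine-volume change (model C-1).

    Maps a spine volume V (in cubic micrometres) to its expected daily
    change: ``-0.16 V + 0.01`` for V <= 0.25, ``0.12 V - 0.06`` for
    0.25 < V <= 0.5, and 0 for larger spines.  Used only to motivate the
    one-day time step; continuous at both branch boundaries.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("spine volume must be nonnegative")
    out = np.where(
        v <= 0.25, -0.16 * v + 0.01, np.where(v <= 0.5, 0.12 * v - 0.06, 0.0)
    )
    return out[()] if out.ndim == 0 else out
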