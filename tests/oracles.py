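"""Independent reference implementations used as test oracles.

Everything here is written with plain Python floats and the ``math`` module,
deliberately avoiding the package's own vectorized code paths, so that
agreement between the two is a meaningful check of the update semantics.
"""

from __future__ import annotations

import math


def volatility_ref(w: float, v_hi: float, v_lo: float, w_med: float) -> float:
    return v_hi - (v_hi - v_lo) * w / (w + w_med)


def cluster_day_ref(weights, active, params, e1, e2, u):
    """One simulated day for one cluster, coded from scratch.

    ``weights``/``active`` are plain lists; ``e1``/``e2`` are the raw
    standard-normal draws (uniforms for the exponential variant) and ``u``
    the regeneration uniforms, one of each per synapse.  Returns
    ``(new_weights, new_active, deltas)`` with ``None`` deltas for synapses
    silent at day start.
    """
    n = len(weights)
    strong = [w > params.T_st for w in weights]
    n_st = sum(strong)
    if params.variant == "fixed_ltp":
        a1, sd1 = params.a1_fixed, params.sd1_fixed
    else:
        a1 = params.x2 - (params.x2 - params.x1) * n_st / params.N_cl
        sd1 = a1 / params.sd_ratio
    sd2 = params.a2 / params.sd_ratio
    p_act = 0.0 if params.variant == "no_regeneration" else params.P_bas * n_st / params.N_cl

    new_w = list(weights)
    new_active = list(active)
    deltas = [None] * n
    for i in range(n):
        if not active[i]:
            continue
        w = weights[i]
        if params.variant == "exponential_increments":
            r1 = -math.log1p(-e1[i]) / params.lambda1
            r2 = -math.log1p(-e2[i]) / params.lambda2
        else:
            r1 = max(a1 + sd1 * e1[i], 0.0)
            r2 = max(params.a2 + sd2 * e2[i], 0.0)
        vo = volatility_ref(w, params.v_hi, params.v_lo, params.W_med)
        a_ltp = w * r1 * vo * (1.0 - params.k_hi * w / (w + params.W_hi))
        a_ltd = w * r2 * vo
        d = a_ltp - a_ltd
        deltas[i] = d
        wn = w + d
        if wn < params.T_wk:
            new_w[i] = params.W_sil
            new_active[i] = False
        else:
            new_w[i] = wn
    for i in range(n):
        if active[i]:
            continue
        left_strong = strong[i - 1] if i > 0 else False
        right_strong = strong[i + 1] if i < n - 1 else False
        if (left_strong or right_strong) and u[i] < p_act:
            new_w[i] = params.W_reset
            new_active[i] = True
    return new_w, new_active, deltas


def pearson_ref(x, y) -> float:
    """Textbook product-moment correlation, summed term by term."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    dx = sum((xi - mx) ** 2 for xi in x)
    dy = sum((yi - my) ** 2 for yi in y)
    return num / math.sqrt(dx * dy)
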