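"""Independent oracles used only by the tests.

These deliberately avoid the code paths they check: the release model is
re-derived by numerically integrating the underlying two-state ODE between
spikes; the rank-sum p-value by full enumeration of rank assignments; the
BH adjustment by the direct step-up formula.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.integrate import solve_ivp


def release_train_ode(U, tau_rec, tau_facil, A, pulse_times):
    """Release amplitudes by ODE integration between spikes.

    Between spikes: dR/dt = (1 - R) / tau_rec, du/dt = (U - u) / tau_facil.
    At spike k (state u_k, R_k): amplitude A*u_k*R_k, then R -> R*(1 - u_k),
    u -> u + U*(1 - u_k)... with the facilitation increment applied to the
    current u: u -> U + u*(1 - U) evaluated post-spike.
    """
    u, R = U, 1.0
    amps = []
    for k, t in enumerate(pulse_times):
        amps.append(A * u * R)
        if k + 1 == len(pulse_times):
            break
        dt = pulse_times[k + 1] - t
        R_post = R * (1.0 - u)
        u_post = U + u * (1.0 - U)
        sol = solve_ivp(
            lambda _, y: [(1.0 - y[0]) / tau_rec, (U - y[1]) / tau_facil],
            (0.0, dt),
            [R_post, u_post],
            rtol=1e-11,
            atol=1e-13,
        )
        R, u = sol.y[0, -1], sol.y[1, -1]
    return np.array(amps)


def ranksum_exact_p(x, y):
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    all_ranks = np.arange(1, n + m + 1)
    us = np.array(
        [all_ranks[list(idx)].sum() - n * (n + 1) / 2
         for idx in combinations(range(n + m), n)]
    )
    total = comb(n + m, n)
    p_le = np.sum(us <= u_obs) / total
    p_ge = np.sum(us >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_stepup(p):
    """Benjamini–Hochberg adjusted p-values by the direct formula."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
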