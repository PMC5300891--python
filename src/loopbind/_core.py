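"""Numerical core: the rate law and the fixed-step RK4 loop.

Compiled with numba when available (a pure-Python fallback keeps the
package importable without it, at a large speed cost).  The rate law here
must stay in lock-step with :func:`loopbind.model.mass_action_rhs`; a test
cross-checks the two on random states.

Species order in the state vector: R, P, C3, C4, CC, D.
Rate order in the parameter vector: kon3, koff3, kon4, koff4, kC3, kC4.
"""

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def rhs(y, k, out):
    R, P, C3, C4, CC, D = y[0], y[1], y[2], y[3], y[4], y[5]
    kon3, koff3, kon4, koff4, kC3, kC4 = k[0], k[1], k[2], k[3], k[4], k[5]

    a3 = kon3 * R * P
    a4 = kon4 * R * P
    b3 = kon4 * C3 * P
    b4 = kon3 * C4 * P
    open_cc = (koff3 + koff4) * CC
    open_d = (koff3 + koff4) * D

    # terms that map onto each other under a KH3<->KH4 label swap are
    # combined pairwise, so swapping the labels permutes the computed
    # derivatives bitwise-exactly (float addition is commutative)
    release = koff3 * C3 + koff4 * C4
    out[0] = release - (a3 + a4)
    out[1] = release - (a3 + a4) - (b3 + b4) + open_d
    out[2] = a3 - (koff3 + kC4) * C3 + koff4 * CC - b3 + koff4 * D
    out[3] = a4 - (koff4 + kC3) * C4 + koff3 * CC - b4 + koff3 * D
    out[4] = (kC4 * C3 + kC3 * C4) - open_cc
    out[5] = (b3 + b4) - open_d


@njit(cache=False)
def rk4_run(y0, k, dt, n_steps, store_every, clamp_protein):
    """Integrate ``n_steps`` classical RK4 steps from ``y0``.

    Stores the initial state, every ``store_every``-th step and the final
    step.  With ``clamp_protein`` the free-protein entry is pinned to zero
    at every stage evaluation and after every step (wash-out conditions:
    released protein leaves the system, so protein mass is deliberately
    not conserved).

    Returns ``(times, states)`` with ``states`` of shape (n_stored, 6).
    """
    n_stored = n_steps // store_every + 1
    if n_steps % store_every != 0:
        n_stored += 1
    times = np.empty(n_stored)
    states = np.empty((n_stored, 6))

    y = y0.copy()
    if clamp_protein:
        y[1] = 0.0
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    yt = np.empty(6)

    times[0] = 0.0
    states[0] = y
    idx = 1
    for step in range(1, n_steps + 1):
        rhs(y, k, k1)
        for i in range(6):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        if clamp_protein:
            yt[1] = 0.0
        rhs(yt, k, k2)
        for i in range(6):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        if clamp_protein:
            yt[1] = 0.0
        rhs(yt, k, k3)
        for i in range(6):
            yt[i] = y[i] + dt * k3[i]
        if clamp_protein:
            yt[1] = 0.0
        rhs(yt, k, k4)
        for i in range(6):
            y[i] += dt * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) / 6.0
        if clamp_protein:
            y[1] = 0.0
        if step % store_every == 0 or step == n_steps:
            times[idx] = step * dt
            states[idx] = y
            idx += 1
    return times[:idx], states[:idx]


def max_loss_rate(y, k):
    """Largest per-species first-order loss rate at state ``y`` (s^-1).

    Used as the local stiffness estimate for the RK4 stability check:
    the step must satisfy dt * lambda_max < 2.5.
    """
    R, P, C3, C4 = y[0], y[1], y[2], y[3]
    kon3, koff3, kon4, koff4, kC3, kC4 = k
    rates = (
        (kon3 + kon4) * P,                      # loss of R
        (kon3 + kon4) * R + kon4 * C3 + kon3 * C4,  # loss of P
        koff3 + kC4 + kon4 * P,                 # loss of C3
        koff4 + kC3 + kon3 * P,                 # loss of C4
        koff3 + koff4,                          # loss of CC (and of D)
    )
    return max(rates)
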