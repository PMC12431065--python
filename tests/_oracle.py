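"""Exact joint-Gaussian conditioning oracle for the state-space smoother.

Builds the joint Gaussian of the whole latent state trajectory by forward
recursion (no Kalman recursions), reads off the signal rows, and conditions
on the observed subset by direct linear algebra. Independent of the
filter/smoother implementation it checks; only usable at small T and s.
"""

from __future__ import annotations

import numpy as np


def conditioned_signal_moments(y, system, a0, P0):
    """Posterior mean and variance of the signal at every date given the
    observed entries of ``y`` (NaN = missing), by brute-force conditioning."""
    F = system.transition
    Z = system.observation
    Q = system.state_cov
    r = system.obs_var
    T = len(y)
    m = system.state_dim

    means = [np.asarray(a0, dtype=float)]
    for _ in range(1, T):
        means.append(F @ means[-1])
    Ctt = [np.asarray(P0, dtype=float)]
    for _ in range(1, T):
        Ctt.append(F @ Ctt[-1] @ F.T + Q)

    C = np.zeros((T * m, T * m))
    for t in range(T):
        C[t * m : (t + 1) * m, t * m : (t + 1) * m] = Ctt[t]
        Fu = np.eye(m)
        for u in range(t + 1, T):
            Fu = F @ Fu
            blk = Ctt[t] @ Fu.T
            C[t * m : (t + 1) * m, u * m : (u + 1) * m] = blk
            C[u * m : (u + 1) * m, t * m : (t + 1) * m] = blk.T

    Zs = np.zeros((T, T * m))
    for t in range(T):
        Zs[t, t * m : (t + 1) * m] = Z
    mu_s = Zs @ np.concatenate(means)
    C_ss = Zs @ C @ Zs.T

    obs = np.isfinite(np.asarray(y, dtype=float))
    if not obs.any():
        return mu_s, np.diag(C_ss)
    C_oo = C_ss[np.ix_(obs, obs)] + r * np.eye(int(obs.sum()))
    C_so = C_ss[:, obs]
    K = np.linalg.solve(C_oo, C_so.T).T
    post_mean = mu_s + K @ (np.asarray(y)[obs] - mu_s[obs])
    post_var = np.diag(C_ss - K @ C_so.T)
    return post_mean, post_var
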