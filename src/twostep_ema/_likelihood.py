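"""Compiled trial-loop kernels for the hybrid RL likelihood.

The kernels operate on integer choice/state arrays and a float payoff
array; all model logic that tests exercise through the public API lives in
:mod:`twostep_ema.hybrid` — these functions are the hot inner loops only.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def nll_core(
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    r: np.ndarray,
    alpha1: float,
    alpha2: float,
    lam: float,
    beta1: float,
    beta2: float,
    omega: float,
    rep: float,
    p_common: float,
) -> float:
    """Negative log-likelihood of one subject's trial sequence.

    First-stage choice probabilities are a softmax over
    ``beta1 * (omega * q_mb + (1 - omega) * q_mf) + rep * 1[a == prev_a1]``;
    second-stage probabilities a softmax over ``beta2 * q2[s2]``. Values are
    updated in sequence by SARSA(lambda)-style prediction errors.
    """
    n = a1.shape[0]
    q_mf = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    nll = 0.0
    for t in range(n):
        # model-based first-stage values from the transition structure
        m0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        x0 = beta1 * (omega * qmb0 + (1.0 - omega) * q_mf[0])
        x1 = beta1 * (omega * qmb1 + (1.0 - omega) * q_mf[1])
        if prev == 0:
            x0 += rep
        elif prev == 1:
            x1 += rep
        m = x0 if x0 >= x1 else x1
        lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m))
        nll -= (x0 if a1[t] == 0 else x1) - lse

        s = s2[t]
        y0 = beta2 * q2[s, 0]
        y1 = beta2 * q2[s, 1]
        m = y0 if y0 >= y1 else y1
        lse = m + np.log(np.exp(y0 - m) + np.exp(y1 - m))
        nll -= (y0 if a2[t] == 0 else y1) - lse

        # SARSA(lambda) updates
        d1 = q2[s, a2[t]] - q_mf[a1[t]]
        q_mf[a1[t]] += alpha1 * d1
        d2 = r[t] - q2[s, a2[t]]
        q2[s, a2[t]] += alpha2 * d2
        q_mf[a1[t]] += alpha1 * lam * d2
        prev = a1[t]
    return nll
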