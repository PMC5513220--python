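"""Independent oracles used by the tests.

These deliberately avoid the package's own likelihood/sampling code paths:
the Kalman smoother below is a textbook Rauch-Tung-Striebel recursion for
the linear-Gaussian special case of the state-space model, written directly
from the filter equations.
"""

import numpy as np


def kalman_smoother_gompertz(
    y: np.ndarray,
    r: float,
    k: float,
    q: float,
    tau: float,
    mu0: float,
    sd0: float,
) -> np.ndarray:
    """Posterior means of the latent states for the S = 1, delta = 0 model.

    With fixed (r, k) the log-scale dynamics are linear:
    n_t = r + (1 - r/k) n_{t-1} + w_t, w_t ~ N(0, q), observed through
    y_t = n_t + v_t, v_t ~ N(0, tau^2), with n_1 ~ N(mu0, sd0^2).
    """
    T = y.size
    phi = 1.0 - r / k
    a = r
    mp = np.empty(T)
    Pp = np.empty(T)
    mf = np.empty(T)
    Pf = np.empty(T)
    for t in range(T):
        if t == 0:
            mp[t], Pp[t] = mu0, sd0**2
        else:
            mp[t] = a + phi * mf[t - 1]
            Pp[t] = phi**2 * Pf[t - 1] + q
        gain = Pp[t] / (Pp[t] + tau**2)
        mf[t] = mp[t] + gain * (y[t] - mp[t])
        Pf[t] = (1 - gain) * Pp[t]
    ms = np.empty(T)
    ms[-1] = mf[-1]
    for t in range(T - 2, -1, -1):
        J = Pf[t] * phi / Pp[t + 1]
        ms[t] = mf[t] + J * (ms[t + 1] - mp[t + 1])
    return ms
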