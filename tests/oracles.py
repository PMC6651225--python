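"""Independent straight-loop oracles, deliberately naive.

These re-derive capsule routing, prediction vectors and frame spectra with
explicit Python loops so the vectorized implementations can be checked
against something that shares no code with them.
"""

import numpy as np


def softmax_rows(b):
    out = np.empty_like(b, dtype=float)
    for i in range(b.shape[0]):
        z = b[i] - b[i].max()
        e = np.exp(z)
        out[i] = e / e.sum()
    return out


def squash_vec(s):
    n = np.linalg.norm(s)
    if n == 0:
        return np.zeros_like(s)
    return (n**2 / (1 + n**2)) * (s / n)


def prediction_vectors_loop(u, W):
    """u: (N, d_in); W: (N, J, d_out, d_in) -> u_hat (N, J, d_out)."""
    N, J = W.shape[0], W.shape[1]
    u_hat = np.zeros((N, J, W.shape[2]))
    for i in range(N):
        for j in range(J):
            u_hat[i, j] = W[i, j] @ u[i]
    return u_hat


def routing_loop(u_hat, r):
    """Literal transcription of the routing-by-agreement procedure."""
    N, J, d = u_hat.shape
    b = np.zeros((N, J))
    for _ in range(r):
        c = softmax_rows(b)
        s = np.zeros((J, d))
        for j in range(J):
            for i in range(N):
                s[j] += c[i, j] * u_hat[i, j]
        v = np.array([squash_vec(s[j]) for j in range(J)])
        for i in range(N):
            for j in range(J):
                b[i, j] += float(u_hat[i, j] @ v[j])
    return v, c


def dft_frame_magnitudes(frame, taper, n_fft):
    """One-sided magnitude spectrum of one tapered frame by direct DFT sum."""
    x = frame * taper
    n_bins = n_fft // 2 + 1
    mags = np.zeros(n_bins)
    for k in range(n_bins):
        re = sum(x[t] * np.cos(2 * np.pi * k * t / n_fft) for t in range(len(x)))
        im = sum(-x[t] * np.sin(2 * np.pi * k * t / n_fft) for t in range(len(x)))
        mags[k] = np.hypot(re, im)
    return mags
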