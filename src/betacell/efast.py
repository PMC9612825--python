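"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis: each factor is assigned a
drive frequency and swept along a space-filling search curve; the
variance of the model output carried by the factor's frequency (and its
harmonics up to the interference factor M) measures first-order
sensitivity, while everything *below* the factor's frequency band
measures the complementary set, giving the total-order index

    S_T(i) = 1 - V_complement(i) / V.

The implementation follows the standard resampling scheme (random phase
shift per resample curve).  Factors are swept on [0, 1]; callers map to
parameter space (the calibration layer uses a log10 map spanning two
orders of magnitude above and below each baseline value).
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def _search_curve(n_samples: int, omega: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Sample matrix in [0,1]^d along the FAST search curve."""
    s = 2.0 * np.pi / n_samples * np.arange(n_samples)
    return 0.5 + np.arcsin(np.sin(np.outer(s, omega) + phase)) / np.pi


def efast_indices(func: Callable[[np.ndarray], np.ndarray], n_factors: int,
                  n_samples: int = 65, M: int = 4, resamples: int = 2,
                  seed: int | np.random.Generator = 0) -> dict[str, np.ndarray]:
    """Total- and first-order eFAST indices for a vector-valued model.

    Parameters
    ----------
    func : callable
        Maps an ``(n, d)`` sample matrix in ``[0, 1]^d`` to an
        ``(n, k)`` output matrix (``k`` model outputs).
    n_factors : int
        Number of input factors ``d``.
    n_samples : int
        Points per search curve; must satisfy the Nyquist-type bound
        ``n_samples >= 4 M^2 + 1``.
    M : int
        Interference factor (harmonics attributed to a factor).
    resamples : int
        Independent random-phase curves averaged per factor.

    Returns
    -------
    dict with ``"total"`` and ``"first"`` arrays of shape (d, k).
    """
    if n_samples < 4 * M ** 2 + 1:
        raise ValueError(
            f"n_samples={n_samples} below the eFAST minimum {4 * M ** 2 + 1} for M={M}"
        )
    rng = np.random.default_rng(seed)
    omega_i = (n_samples - 1) // (2 * M)  # drive frequency of the factor of interest
    omega_max_c = max(1, omega_i // (2 * M))  # ceiling for complementary frequencies

    ST = np.zeros((n_factors, 0))
    S1 = np.zeros((n_factors, 0))
    st_rows, s1_rows = [], []
    for i in range(n_factors):
        omega = np.empty(n_factors)
        # complementary factors cycle through 1..omega_max_c
        comp = (np.arange(n_factors - 1) % omega_max_c) + 1
        omega[np.arange(n_factors) != i] = comp
        omega[i] = omega_i
        st_acc = None
        s1_acc = None
        for _ in range(resamples):
            phase = rng.uniform(0, 2 * np.pi, n_factors)
            X = _search_curve(n_samples, omega, phase)
            Y = np.atleast_2d(np.asarray(func(X), dtype=float))
            if Y.shape[0] != n_samples:
                Y = Y.T
            Y = Y - Y.mean(axis=0)
            spec = np.fft.rfft(Y, axis=0)
            power = (np.abs(spec) ** 2) / n_samples ** 2
            # one-sided variance contributions (skip the DC term)
            power[0] = 0.0
            V = 2.0 * power[1: (n_samples + 1) // 2].sum(axis=0)
            V = np.where(V <= 0, np.finfo(float).tiny, V)
            harmonics = np.arange(1, M + 1) * omega_i
            V1 = 2.0 * power[harmonics].sum(axis=0)
            Vc = 2.0 * power[1: omega_i // 2 + 1].sum(axis=0)
            st = 1.0 - Vc / V
            s1 = V1 / V
            st_acc = st if st_acc is None else st_acc + st
            s1_acc = s1 if s1_acc is None else s1_acc + s1
        st_rows.append(st_acc / resamples)
        s1_rows.append(s1_acc / resamples)
    return {"total": np.vstack(st_rows), "first": np.vstack(s1_rows)}
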