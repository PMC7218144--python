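"""Step 3: autoregressive spectral features via reflection coefficients.

A block of signal x[n] is modelled as an order-p autoregression

    x[n] = - sum_{k=1..p} a_p[k] x[n-k] + w[n],

with w[n] zero-mean white noise of variance rho. Note the minus sign: this
package uses that convention everywhere (``to_plus_convention`` converts for
interop with libraries that put the sum on the right with a plus sign).

The coefficients are estimated with Burg's method — the canonical
reflection-coefficient (lattice) estimator — which minimizes the summed
forward and backward prediction error at each order and guarantees
|k_m| <= 1, hence a stable model, and converts reflection coefficients to
AR coefficients through the Levinson–Durbin recursion. The fitted vector
a_1..a_p (optionally with rho appended) is the frequency-domain feature of
one 30 s block; the innovation variance is non-increasing in p on a fixed
signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .signal_io import BlockAnnotation

DEFAULT_AR_ORDER = 20


@dataclass
class ARModel:
    """Fitted autoregression: order, coefficients, innovation variance.

    ``a[k-1]`` is a_p[k] in the minus-sign convention above; ``reflection``
    holds the lattice coefficients k_1..k_p, each in [-1, 1]; ``rho`` is the
    final prediction-error power (>= 0).
    """

    p: int
    a: np.ndarray
    rho: float
    reflection: np.ndarray
    rho_path: np.ndarray  # prediction-error power after each order, length p+1

    def __post_init__(self):
        assert len(self.a) == len(self.reflection) == self.p


def _burg(x: np.ndarray, p: int):
    """Burg recursion; returns (a, reflection, rho_path)."""
    n = len(x)
    f = x[1:].astype(np.float64, copy=True)   # forward prediction errors
    b = x[:-1].astype(np.float64, copy=True)  # backward prediction errors
    a = np.zeros(p)
    k = np.zeros(p)
    rho_path = np.empty(p + 1)
    rho_path[0] = float(np.dot(x, x)) / n
    for m in range(p):
        denom = np.dot(f, f) + np.dot(b, b)
        km = 0.0 if denom == 0 else -2.0 * np.dot(f, b) / denom
        k[m] = km
        prev = a[:m].copy()
        a[:m] = prev + km * prev[::-1]  # Levinson-Durbin order update
        a[m] = km
        rho_path[m + 1] = rho_path[m] * (1.0 - km * km)
        if m < p - 1:
            f_upd = f + km * b
            b_upd = b + km * f
            f = f_upd[1:]
            b = b_upd[:-1]
    return a, k, rho_path


def fit_ar_reflection(x: Sequence[float], p: int) -> ARModel:
    """Fit an order-p AR model to one block with Burg's method."""
    x = np.asarray(x, dtype=np.float64)
    if p < 1:
        raise ValidationError(f"AR order must be >= 1, got {p}")
    if len(x) <= 2 * p:
        raise ValidationError(
            f"signal of length {len(x)} too short for AR order {p} (need > {2 * p})"
        )
    x = x - x.mean()
    if np.dot(x, x) == 0.0:
        raise DegenerateInputError("zero-variance signal has no AR representation")
    a, k, rho_path = _burg(x, p)
    return ARModel(p=p, a=a, rho=float(rho_path[-1]), reflection=k, rho_path=rho_path)


def to_plus_convention(a: np.ndarray) -> np.ndarray:
    """Coefficients phi for x[n] = sum phi_k x[n-k] + w[n] (e.g. Yule-Walker)."""
    return -np.asarray(a)


def ar_psd(model: ARModel, freqs: Sequence[float], fs: float) -> np.ndarray:
    """Two-sided AR power spectral density at the given frequencies (Hz).

    Integrating over (-fs/2, fs/2) — or twice the integral over (0, fs/2) —
    recovers the modelled signal variance.
    """
    from scipy.signal import freqz

    w = 2 * np.pi * np.asarray(freqs) / fs
    _, h = freqz([1.0], np.concatenate([[1.0], model.a]), worN=w)
    return model.rho / fs * np.abs(h) ** 2


def select_ar_order(
    x: Sequence[float],
    candidate_orders: Sequence[int],
    criterion: str = "aic",
    fixed_order: int = DEFAULT_AR_ORDER,
) -> int:
    """Choose the AR order by AIC or final prediction error, or return a fixed one.

    Both criteria are computed from the Burg prediction-error power rho(p)
    and the sample count n: AIC = n ln rho + 2p, FPE = rho (n+p+1)/(n-p-1).
    """
    if len(candidate_orders) == 0:
        raise ConfigurationError("candidate_orders must be non-empty")
    if criterion == "fixed":
        return fixed_order
    if criterion not in ("aic", "fpe"):
        raise ConfigurationError(f"unknown order-selection criterion {criterion!r}")
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    pmax = max(candidate_orders)
    model = fit_ar_reflection(x, pmax)
    rho = model.rho_path
    best, best_score = None, np.inf
    for p in sorted(candidate_orders):
        if criterion == "aic":
            score = n * np.log(rho[p]) + 2 * p
        else:
            score = rho[p] * (n + p + 1) / (n - p - 1)
        if score < best_score:
            best, best_score = p, score
    return best


@dataclass
class ARFeatureVector:
    """Frequency-domain feature of one block: the AR coefficient vector."""

    channel_id: str
    block: Optional[BlockAnnotation]
    p: int
    values: np.ndarray  # length p, or p+1 with rho appended


def ar_feature_vector(
    block_samples: Sequence[float],
    p: int = DEFAULT_AR_ORDER,
    include_rho: bool = False,
    channel_id: str = "",
    block: BlockAnnotation | None = None,
) -> ARFeatureVector:
    """Fit the block's AR model and expose its coefficients as features."""
    model = fit_ar_reflection(block_samples, p)
    values = np.concatenate([model.a, [model.rho]]) if include_rho else model.a
    return ARFeatureVector(channel_id=channel_id, block=block, p=p, values=values)
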