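"""Step 2 feature extraction: per-window statistics and Hjorth parameters.

Seven hand-crafted descriptors are computed per 0.5 s window: mean, skewness,
excess kurtosis, peak-to-peak amplitude, and the three Hjorth parameters —
activity (variance), mobility (a mean-frequency proxy) and complexity (a
bandwidth proxy). Conventions, fixed for reproducibility:

* moments use the population (1/N) form; skewness is the third standardized
  moment, kurtosis the fourth minus 3 (excess), both defined as 0 on a
  zero-variance window;
* the derivative in the Hjorth parameters is the first difference, without
  scaling by the sampling rate — the constant cancels in complexity and
  mobility is used as a relative discriminative feature only.

Useful identities exercised in the tests: activity scales with the square of
an amplitude gain, mobility and complexity are gain- and offset-invariant,
and the mobility of a pure sinusoid at frequency f sampled at fs is
``2 sin(pi f / fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .segmentation import WindowSet
from .signal_io import BlockAnnotation

#: canonical feature order
FEATURE_NAMES = ("mean", "skew", "kurtosis", "p2p", "activity", "mobility", "complexity")


def _moments(w: np.ndarray):
    """Population moments per row of a (n_windows, width) matrix."""
    mean = w.mean(axis=1)
    centered = w - mean[:, None]
    var = np.mean(centered**2, axis=1)
    ok = var > 0
    std = np.sqrt(var, where=ok, out=np.ones_like(var))
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(ok, np.mean(centered**3, axis=1) / std**3, 0.0)
        kurt = np.where(ok, np.mean(centered**4, axis=1) / np.where(ok, var**2, 1.0) - 3.0, 0.0)
    return mean, var, skew, kurt


def window_stats(w: Sequence[float]) -> tuple[float, float, float, float]:
    """(mean, skew, excess kurtosis, peak-to-peak) of one window."""
    w = np.asarray(w, dtype=np.float64)
    if w.size < 2:
        raise ValidationError(f"window too short for statistics: {w.size} samples")
    mean, _, skew, kurt = _moments(w[None, :])
    return float(mean[0]), float(skew[0]), float(kurt[0]), float(np.ptp(w))


def hjorth_parameters(w: Sequence[float]) -> tuple[float, float, float]:
    """Hjorth (activity, mobility, complexity) of one window.

    activity = var(w); mobility = sqrt(var(dw)/var(w));
    complexity = mobility(dw)/mobility(w), with d the first difference.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.size < 3:
        raise ValidationError(f"window too short for Hjorth parameters: {w.size}")
    var0 = float(np.var(w))
    if var0 <= 0:
        raise DegenerateInputError("zero-variance window has undefined mobility")
    d1 = np.diff(w)
    d2 = np.diff(d1)
    var1 = float(np.var(d1))
    var2 = float(np.var(d2))
    mobility = np.sqrt(var1 / var0)
    if var1 <= 0:
        raise DegenerateInputError("zero-variance first difference")
    complexity = np.sqrt(var2 / var1) / mobility
    return var0, float(mobility), float(complexity)


def feature_matrix(windows: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    """Selected features for every row of a (n_windows, width) matrix.

    Zero-variance rows get skew = kurtosis = 0 and NaN Hjorth mobility /
    complexity; callers decide whether to drop or fill such rows.
    """
    unknown = set(feature_names) - set(FEATURE_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown feature name(s): {sorted(unknown)}")
    if not feature_names:
        raise ConfigurationError("feature_names must be non-empty")
    windows = np.asarray(windows, dtype=np.float64)

    cols: dict[str, np.ndarray] = {}
    need = set(feature_names)
    if need & {"mean", "skew", "kurtosis", "activity", "mobility", "complexity"}:
        mean, var, skew, kurt = _moments(windows)
        cols["mean"], cols["skew"], cols["kurtosis"] = mean, skew, kurt
        cols["activity"] = var
    if need & {"mobility", "complexity"}:
        d1 = np.diff(windows, axis=1)
        var1 = np.var(d1, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mob = np.sqrt(var1 / cols["activity"])
            mob = np.where(cols["activity"] > 0, mob, np.nan)
            if "complexity" in need:
                var2 = np.var(np.diff(d1, axis=1), axis=1)
                comp = np.where(var1 > 0, np.sqrt(var2 / var1) / mob, np.nan)
                cols["complexity"] = comp
        cols["mobility"] = mob
    if "p2p" in need:
        cols["p2p"] = np.ptp(windows, axis=1)
    return np.column_stack([cols[name] for name in feature_names])


@dataclass
class FeatureSequence:
    """Ordered per-window feature vectors for one block of one channel."""

    channel_id: str
    block: Optional[BlockAnnotation]
    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_windows, n_features), finite

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        """The feature matrix as a DataFrame (for TSV export / inspection)."""
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.feature_names))


def build_feature_sequence(
    ws: WindowSet,
    feature_names: Sequence[str],
    channel_id: str = "",
    block: BlockAnnotation | None = None,
    on_degenerate: str = "skip",
) -> FeatureSequence:
    """Assemble the per-window feature matrix for one block.

    Row i holds the features of window i, columns in ``feature_names`` order.
    Windows whose Hjorth parameters are undefined (zero variance — absent in
    any physiological or generated signal, but possible in clipped data) are
    dropped (``on_degenerate="skip"``) or zero-filled (``"fill"``).
    """
    values = feature_matrix(ws.windows, feature_names)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        if on_degenerate == "skip":
            values = values[~bad]
        elif on_degenerate == "fill":
            values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
        else:
            raise ConfigurationError(f"unknown degenerate-window policy {on_degenerate!r}")
    return FeatureSequence(
        channel_id=channel_id,
        block=block,
        feature_names=tuple(feature_names),
        values=values,
    )
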