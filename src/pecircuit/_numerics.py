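"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def softplus(v: np.ndarray | float) -> np.ndarray | float:
    """Softplus s+(v) = ln(1 + e^v), numerically stable for large |v|."""
    return np.logaddexp(0.0, v)


def softplus_inverse(w: np.ndarray | float) -> np.ndarray | float:
    """Inverse of the softplus, v = ln(e^w - 1).

    Only defined for w > 0.  Stable form: w + log(1 - e^{-w}).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("softplus_inverse requires strictly positive weights")
    return w + np.log1p(-np.exp(-w))


def logistic(v: np.ndarray | float) -> np.ndarray | float:
    """Derivative of the softplus (the logistic function)."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    np.exp(-np.abs(v), out=out)
    return np.where(v >= 0, 1.0 / (1.0 + out), out / (1.0 + out))


def relu(x: np.ndarray | float) -> np.ndarray | float:
    """Rectifier [x]_+ = max(x, 0)."""
    return np.maximum(x, 0.0)
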