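"""Robustness weight functions on standardized average log-intensities.

Weighted likelihood downgrades observations with small intensities: a
log-ratio computed from two dim spots is noisier than the same log-ratio
from two bright ones. Weights are functions of the standardized average
log-intensity u and lie in [0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "standardize_intensity",
    "huber_lower_weight",
    "huber_upper_weight",
    "huber_two_tailed_weight",
    "tukey_lower_weight",
    "tukey_upper_weight",
    "tukey_two_tailed_weight",
    "compute_weights",
    "HUBER_C",
    "TUKEY_TAPER",
]

HUBER_C = 1.345
TUKEY_TAPER = 4.685


def standardize_intensity(u) -> np.ndarray:
    """Center and scale to sample mean 0 and sample sd 1 (ddof=1)."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("u must be a 1-d array of length >= 2")
    sd = u.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize constant intensities (sd = 0)")
    return (u - u.mean()) / sd


def huber_lower_weight(u, c: float = HUBER_C) -> np.ndarray:
    """Lower-half Huber weight: 1 for u > -c, else c/|u|."""
    if c <= 0:
        raise ValueError("c must be positive")
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        return np.where(u > -c, 1.0, c / np.abs(u))


def huber_upper_weight(u, c: float = HUBER_C) -> np.ndarray:
    """Mirror image of the lower-half weight (downweights large u)."""
    return huber_lower_weight(-np.asarray(u, dtype=float), c)


def huber_two_tailed_weight(u, c: float = HUBER_C) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.minimum(huber_lower_weight(u, c), huber_upper_weight(u, c))


def tukey_lower_weight(
    u, c: float = HUBER_C, taper: float = TUKEY_TAPER
) -> np.ndarray:
    """Lower-half bisquare-style weight with a smooth taper.

    1 for u > -c; ``(1 - ((u + c)/taper)^2)^2`` on [-c - taper, -c];
    0 below. The taper width defaults to the usual bisquare tuning
    constant 4.685.
    """
    if c <= 0 or taper <= 0:
        raise ValueError("c and taper must be positive")
    u = np.asarray(u, dtype=float)
    t = np.clip((u + c) / taper, -1.0, 0.0)
    w = (1.0 - t * t) ** 2
    return np.where(u > -c, 1.0, w)


def tukey_upper_weight(
    u, c: float = HUBER_C, taper: float = TUKEY_TAPER
) -> np.ndarray:
    return tukey_lower_weight(-np.asarray(u, dtype=float), c, taper)


def tukey_two_tailed_weight(
    u, c: float = HUBER_C, taper: float = TUKEY_TAPER
) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.minimum(
        tukey_lower_weight(u, c, taper), tukey_upper_weight(u, c, taper)
    )


_WEIGHT_FNS = {
    ("huber", "lower"): huber_lower_weight,
    ("huber", "upper"): huber_upper_weight,
    ("huber", "two_tailed"): huber_two_tailed_weight,
    ("tukey", "lower"): tukey_lower_weight,
    ("tukey", "upper"): tukey_upper_weight,
    ("tukey", "two_tailed"): tukey_two_tailed_weight,
}


def compute_weights(
    u,
    family: str = "huber",
    tail: str = "lower",
    c: float = HUBER_C,
    taper: float = TUKEY_TAPER,
) -> np.ndarray:
    """Standardize ``u`` and apply the chosen weight function.

    ``family='none'`` returns unit weights.
    """
    u = np.asarray(u, dtype=float)
    if family == "none":
        return np.ones_like(u)
    try:
        fn = _WEIGHT_FNS[(family, tail)]
    except KeyError:
        raise ValueError(f"unknown weight function {family!r}/{tail!r}")
    z = standardize_intensity(u)
    if family == "tukey":
        return fn(z, c, taper)
    return fn(z, c)
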