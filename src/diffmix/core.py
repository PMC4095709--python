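"""Domain types and density computations for the ensemble mixture classes.

Three classes of two-level finite mixtures are supported, all of the form

    f(y) = (1 - pi) * f0(y) + pi * f1(y),

where ``f0`` is a (mixture of) normal(s) capturing the centrally located,
nondifferential-leaning observations, and ``f1`` captures overdispersed,
differential observations:

* ``NUDGE``  -- one normal + a uniform ``f1`` (K forced to 1);
* ``iNUDGE`` -- K normals + a uniform ``f1``;
* ``GNG``    -- K normals + a pair of shifted exponentials for the two tails.

The uniform bounds ``a, b`` and the exponential offsets ``xi1, xi2`` are
fixed from the data at fit time and are not free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "MODEL_CLASSES",
    "Dataset",
    "NormalComponent",
    "UniformComponent",
    "ExponentialPair",
    "MixtureModel",
    "density",
    "component_densities",
    "component_weights",
    "cdf",
    "estimate_xi",
    "count_params",
    "VARIANCE_FLOOR_FACTOR",
]

MODEL_CLASSES = ("NUDGE", "iNUDGE", "GNG")

#: sigma_k^2 is clamped at this multiple of var(y) during fitting; hitting
#: the floor is reported as a potential likelihood singularity.
VARIANCE_FLOOR_FACTOR = 1e-6

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class Dataset:
    """Per-unit difference scores with optional intensities and weights.

    Parameters
    ----------
    ids : sequence
        Unit identifiers (gene / probe / region names).
    y : array-like of float
        Normalized difference scores, typically log-ratios between two
        conditions. Must be finite.
    u : array-like of float, optional
        Average log-intensities used to derive robustness weights.
    w : array-like of float, optional
        Robustness weights in [0, 1]. Defaults to all ones.
    """

    ids: np.ndarray
    y: np.ndarray
    u: Optional[np.ndarray] = None
    w: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.y = _as_1d_float(self.y, "y")
        n = self.y.shape[0]
        if n < 2:
            raise ValueError("Dataset needs at least two observations")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.ids.shape[0] != n:
            raise ValueError("ids and y have different lengths")
        if self.u is not None:
            self.u = _as_1d_float(self.u, "u")
            if self.u.shape[0] != n:
                raise ValueError("u and y have different lengths")
        if self.w is None:
            self.w = np.ones(n)
        else:
            self.w = _as_1d_float(self.w, "w")
            if self.w.shape[0] != n:
                raise ValueError("w and y have different lengths")
            if np.any((self.w < 0) | (self.w > 1)) or not np.all(
                np.isfinite(self.w)
            ):
                raise ValueError("weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @classmethod
    def from_arrays(
        cls,
        y,
        u=None,
        w=None,
        ids=None,
    ) -> "Dataset":
        y = _as_1d_float(y, "y")
        if ids is None:
            ids = np.arange(y.shape[0])
        return cls(ids=np.asarray(ids), y=y, u=u, w=w)


@dataclass
class NormalComponent:
    """One normal component: location ``mu``, variance ``sigma2``, and
    mixing proportion ``gamma`` within the normal sub-mixture."""

    mu: float
    sigma2: float
    gamma: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


@dataclass
class UniformComponent:
    """Uniform ``f1`` on [a, b]; bounds are fixed at the data range."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError("uniform bounds require a < b")


@dataclass
class ExponentialPair:
    """Two shifted exponentials for the negative and positive tails.

    The negative-side density is ``(1/beta1) * exp(-(-y - xi1)/beta1)``
    for ``y < -xi1`` and the positive side ``(1/beta2) *
    exp(-(y - xi2)/beta2)`` for ``y > xi2``; both vanish in between.
    ``rho`` is the mixing proportion of the negative side; ``beta1``,
    ``beta2`` are scale (mean excess) parameters.
    """

    rho: float
    beta1: float
    beta2: float
    xi1: float
    xi2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("exponential scales must be positive")
        if self.xi1 <= 0 or self.xi2 <= 0:
            raise ValueError("offsets xi1, xi2 must be positive")


@dataclass
class MixtureModel:
    """Parameters of one fitted (or hand-built) mixture model.

    ``model_class`` is one of ``NUDGE``, ``iNUDGE``, ``GNG``; ``pi`` is the
    first-level weight of the differential family ``f1``; ``normals`` holds
    the K normal components and ``f1`` the uniform / exponential-pair part.
    """

    model_class: str
    pi: float
    normals: list  # list[NormalComponent]
    f1: Union[UniformComponent, ExponentialPair]

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if len(self.normals) < 1:
            raise ValueError("at least one normal component is required")
        if self.model_class == "NUDGE" and len(self.normals) != 1:
            raise ValueError("NUDGE has exactly one normal component")
        if self.model_class in ("NUDGE", "iNUDGE") and not isinstance(
            self.f1, UniformComponent
        ):
            raise ValueError(f"{self.model_class} requires a uniform f1")
        if self.model_class == "GNG" and not isinstance(
            self.f1, ExponentialPair
        ):
            raise ValueError("GNG requires an exponential-pair f1")
        gam = sum(c.gamma for c in self.normals)
        if abs(gam - 1.0) > 1e-8:
            raise ValueError(
                f"normal mixing proportions sum to {gam!r}, expected 1"
            )

    @property
    def K(self) -> int:
        return len(self.normals)

    @property
    def mus(self) -> np.ndarray:
        return np.array([c.mu for c in self.normals])

    @property
    def sigma2s(self) -> np.ndarray:
        return np.array([c.sigma2 for c in self.normals])

    @property
    def gammas(self) -> np.ndarray:
        return np.array([c.gamma for c in self.normals])

    @property
    def n_f1_parts(self) -> int:
        return 2 if isinstance(self.f1, ExponentialPair) else 1


def count_params(model: MixtureModel) -> int:
    """Number of free parameters: pi, the K-1 free gammas, K means and
    K variances, plus (rho, beta1, beta2) for GNG. The fixed uniform
    bounds and exponential offsets are not counted."""
    k = model.K
    p = 1 + (k - 1) + 2 * k
    if isinstance(model.f1, ExponentialPair):
        p += 3
    return p


def _normal_pdf_matrix(y: np.ndarray, mus, sigma2s) -> np.ndarray:
    mus = np.asarray(mus, dtype=float)
    sig = np.sqrt(np.asarray(sigma2s, dtype=float))
    z = (y[:, None] - mus[None, :]) / sig[None, :]
    return np.exp(-0.5 * z * z) / (sig[None, :] * _SQRT_2PI)


def _f1_pdf_columns(model: MixtureModel, y: np.ndarray) -> np.ndarray:
    f1 = model.f1
    if isinstance(f1, UniformComponent):
        col = np.where((y >= f1.a) & (y <= f1.b), 1.0 / (f1.b - f1.a), 0.0)
        return col[:, None]
    neg = np.zeros_like(y)
    pos = np.zeros_like(y)
    left = y < -f1.xi1
    right = y > f1.xi2
    neg[left] = np.exp(-((-y[left]) - f1.xi1) / f1.beta1) / f1.beta1
    pos[right] = np.exp((-(y[right] - f1.xi2)) / f1.beta2) / f1.beta2
    return np.column_stack([neg, pos])


def component_densities(model: MixtureModel, y) -> np.ndarray:
    """Unweighted per-component densities, shape (n, K + f1 parts).

    Columns 0..K-1 are the normal components; the remaining column(s)
    hold the uniform density or the negative / positive shifted
    exponentials. Weighting column k by ``(1-pi)*gamma_k`` and the f1
    column(s) by ``pi`` (times ``rho`` / ``1-rho`` for GNG) and summing
    rows reproduces :func:`density`.
    """
    y = _as_1d_float(y, "y")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    norm_cols = _normal_pdf_matrix(y, model.mus, model.sigma2s)
    return np.column_stack([norm_cols, _f1_pdf_columns(model, y)])


def component_weights(model: MixtureModel) -> np.ndarray:
    """Mixture weights matching the columns of :func:`component_densities`."""
    w0 = (1.0 - model.pi) * model.gammas
    if isinstance(model.f1, ExponentialPair):
        w1 = np.array(
            [model.pi * model.f1.rho, model.pi * (1.0 - model.f1.rho)]
        )
    else:
        w1 = np.array([model.pi])
    return np.concatenate([w0, w1])


def density(model: MixtureModel, y) -> np.ndarray:
    """Total mixture density f(y) = (1-pi) f0(y) + pi f1(y)."""
    return component_densities(model, y) @ component_weights(model)


def cdf(model: MixtureModel, y) -> np.ndarray:
    """Cumulative distribution function of the fitted mixture."""
    from scipy.stats import norm

    y = _as_1d_float(y, "y")
    sig = np.sqrt(model.sigma2s)
    f0 = norm.cdf((y[:, None] - model.mus[None, :]) / sig[None, :])
    out = (1.0 - model.pi) * (f0 @ model.gammas)
    f1 = model.f1
    if isinstance(f1, UniformComponent):
        u = np.clip((y - f1.a) / (f1.b - f1.a), 0.0, 1.0)
        out += model.pi * u
    else:
        c = np.full_like(y, f1.rho)
        left = y < -f1.xi1
        right = y > f1.xi2
        c[left] = f1.rho * np.exp(-((-y[left]) - f1.xi1) / f1.beta1)
        c[right] = f1.rho + (1.0 - f1.rho) * (
            1.0 - np.exp(-(y[right] - f1.xi2) / f1.beta2)
        )
        out += model.pi * c
    return out


def estimate_xi(y) -> tuple:
    """Offsets for the GNG tails: ``xi1 = |max of the negative values|``
    and ``xi2 = min of the positive values``.

    Raises
    ------
    ValueError
        If ``y`` has no negative or no positive values; the exponential
        tails are then undefined and GNG is inapplicable.
    """
    y = _as_1d_float(y, "y")
    neg = y[y < 0]
    pos = y[y > 0]
    if neg.size == 0 or pos.size == 0:
        raise ValueError(
            "GNG is inapplicable: data must contain both negative and "
            "positive values to place the exponential tails"
        )
    return float(-neg.max()), float(pos.min())
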