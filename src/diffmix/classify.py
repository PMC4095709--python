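"""Differential-component labeling and weighted local-fdr classification.

A fitted model partitions into a "differential" part (f1 plus any normal
component whose tail reaches past the bulk of the data) and a
"nondifferential" part. The local false discovery rate of observation
y_i is the share of the total density contributed by the
nondifferential part,

    fdr(y_i) = f_nd(y_i) / f(y_i),

and y_i is called differential when fdr(y_i)/w_i <= z0, so downweighted
observations need stronger evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Set

import numpy as np

from .core import Dataset, MixtureModel, component_densities, density

__all__ = [
    "ComponentLabels",
    "ClassificationResult",
    "label_components",
    "local_fdr",
    "call_differential",
    "evaluate",
    "classify",
]

#: a normal component is differential when |mu| + TAIL_SD*sigma exceeds
#: IQR_MULT * IQR(y) -- i.e. when one of its 2-sigma tails reaches the
#: outlier region of the overall distribution.
TAIL_SD = 2.0
IQR_MULT = 1.5


@dataclass
class ComponentLabels:
    differential_normals: Set[int]
    iqr: float


@dataclass
class ClassificationResult:
    fdr: np.ndarray
    calls: np.ndarray
    z0: float
    labels: Optional[ComponentLabels] = None


def label_components(
    model: MixtureModel,
    data: Dataset,
    tail_sd: float = TAIL_SD,
    iqr_mult: float = IQR_MULT,
) -> ComponentLabels:
    """Mark normal component k differential iff |mu_k| + tail_sd*sigma_k
    strictly exceeds iqr_mult * IQR of the (unweighted) data."""
    if data.n < 4:
        raise ValueError("need n >= 4 for a meaningful IQR")
    q1, q3 = np.percentile(data.y, [25.0, 75.0])  # linear interpolation
    iqr = float(q3 - q1)
    if iqr == 0:
        raise ValueError("IQR of the data is zero; labeling is undefined")
    diff = {
        k
        for k, c in enumerate(model.normals)
        if abs(c.mu) + tail_sd * c.sigma > iqr_mult * iqr
    }
    return ComponentLabels(differential_normals=diff, iqr=iqr)


def local_fdr(
    model: MixtureModel, labels: ComponentLabels, y
) -> np.ndarray:
    """Nondifferential density share at each y; in [0, 1].

    The numerator sums (1-pi)*gamma_k*N(y; mu_k, sigma_k^2) over the
    normal components NOT labeled differential; f1 is always counted as
    differential. With no nondifferential component the fdr is
    identically zero.
    """
    y = np.asarray(y, dtype=float)
    nd = [k for k in range(model.K) if k not in labels.differential_normals]
    if not nd:
        return np.zeros_like(y)
    dens = density(model, y)
    if np.any(dens <= 0):
        idx = int(np.argmin(dens))
        raise ValueError(f"zero total density at y={y[idx]!r}")
    cols = component_densities(model, y)[:, nd]
    gam = model.gammas[nd]
    num = (1.0 - model.pi) * (cols @ gam)
    return np.clip(num / dens, 0.0, 1.0)


def call_differential(fdr, w, z0: float = 0.1) -> np.ndarray:
    """Call unit i differential when fdr_i / w_i <= z0; zero-weight units
    are never called."""
    if not 0.0 < z0 <= 1.0:
        raise ValueError("z0 must lie in (0, 1]")
    fdr = np.asarray(fdr, dtype=float)
    w = np.asarray(w, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w > 0, fdr / np.where(w > 0, w, 1.0), np.inf)
    return ratio <= z0


def evaluate(calls, truth):
    """True and false positive rates of calls against ground truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth have different lengths")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both positives and negatives")
    tp = int((calls & truth).sum())
    fp = int((calls & ~truth).sum())
    return tp / n_pos, fp / n_neg


def classify(
    model: MixtureModel,
    data: Dataset,
    z0: float = 0.1,
    tail_sd: float = TAIL_SD,
    iqr_mult: float = IQR_MULT,
) -> ClassificationResult:
    """Label components, compute the weighted local fdr, and call units."""
    labels = label_components(model, data, tail_sd, iqr_mult)
    fdr = local_fdr(model, labels, data.y)
    calls = call_differential(fdr, data.w, z0)
    return ClassificationResult(fdr=fdr, calls=calls, z0=z0, labels=labels)
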