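"""Model selection: BIC chooses the order K within each class, AIC
chooses the winning class.

BIC's stronger parameter penalty guards against overly rich normal
sub-mixtures (and the attendant singularity risk); AIC across classes
avoids settling on a model that is too simple. Both criteria are on a
maximize-is-better scale and use the weighted log-likelihood with the
number of observations n as sample size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .core import Dataset, MixtureModel
from .core import count_params as _count_params
from .em import FitConfig, FitResult, fit

__all__ = [
    "SelectionReport",
    "count_params",
    "bic",
    "aic",
    "scan_K",
    "select_overall",
    "fit_ensemble",
    "CLASS_PRIORITY",
]

#: tie-break order across classes: richer differential family first
CLASS_PRIORITY = ("GNG", "iNUDGE", "NUDGE")


def count_params(model: MixtureModel) -> int:
    return _count_params(model)


def bic(fit_result: FitResult, n: int) -> float:
    """2*loglik - p*log(n); larger is better."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(fit_result.loglik):
        raise ValueError("log-likelihood is not finite")
    return 2.0 * fit_result.loglik - fit_result.n_params * np.log(n)


def aic(fit_result: FitResult) -> float:
    """2*loglik - 2*p; larger is better."""
    if not np.isfinite(fit_result.loglik):
        raise ValueError("log-likelihood is not finite")
    return 2.0 * fit_result.loglik - 2.0 * fit_result.n_params


def scan_K(
    model_class: str,
    data: Dataset,
    config: Optional[FitConfig] = None,
    K_max: int = 6,
):
    """Fit K = 1..K_max (NUDGE: K = 1 only) and pick the BIC maximizer.

    Returns ``(fits, best)``. Ties in BIC break toward smaller K. A K
    whose fit raises is skipped; if every K fails the per-K diagnostics
    are collected into the raised error.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if config is None:
        config = FitConfig()
    ks = [1] if model_class == "NUDGE" else list(range(1, K_max + 1))
    fits: List[FitResult] = []
    failures: Dict[int, str] = {}
    for k in ks:
        try:
            fits.append(fit(model_class, k, data, config))
        except Exception as exc:  # noqa: BLE001 - diagnostics per K
            failures[k] = str(exc)
    if not fits:
        raise RuntimeError(
            f"all {model_class} fits failed: "
            + "; ".join(f"K={k}: {msg}" for k, msg in failures.items())
        )
    best = fits[0]
    for fr in fits[1:]:
        if fr.bic > best.bic:  # strict: ties keep the smaller K
            best = fr
    return fits, best


def select_overall(best_within: Dict[str, FitResult]) -> FitResult:
    """AIC maximizer among the per-class winners; exact ties break by
    class order GNG > iNUDGE > NUDGE."""
    if not best_within:
        raise ValueError("no fitted classes to select from")
    best = None
    for cls in CLASS_PRIORITY:
        fr = best_within.get(cls)
        if fr is None:
            continue
        if best is None or fr.aic > best.aic:
            best = fr
    if best is None:
        raise ValueError(
            f"no recognised model class in {sorted(best_within)!r}"
        )
    return best


@dataclass
class SelectionReport:
    """All fits of the two-stage selection, plus the winners."""

    per_class: Dict[str, List[FitResult]]
    best_within: Dict[str, FitResult]
    best_overall: FitResult
    skipped: Dict[str, str] = field(default_factory=dict)

    @property
    def best_class(self) -> str:
        return self.best_overall.model.model_class

    def to_dict(self) -> dict:
        def row(fr: FitResult, chosen_within: bool) -> dict:
            return {
                "class": fr.model.model_class,
                "K": fr.model.K,
                "loglik": fr.loglik,
                "n_params": fr.n_params,
                "bic": fr.bic,
                "aic": fr.aic,
                "converged": fr.converged,
                "n_iter": fr.n_iter,
                "warnings": list(fr.warnings),
                "chosen_within_class": chosen_within,
                "chosen_overall": fr is self.best_overall,
            }

        fits = []
        for cls, frs in self.per_class.items():
            for fr in frs:
                fits.append(row(fr, fr is self.best_within.get(cls)))
        return {
            "best_class": self.best_class,
            "best_K": self.best_overall.model.K,
            "skipped": dict(self.skipped),
            "fits": fits,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def fit_ensemble(
    data: Dataset,
    config: Optional[FitConfig] = None,
    K_max: int = 6,
    classes=("NUDGE", "iNUDGE", "GNG"),
) -> SelectionReport:
    """Run the full two-stage selection over the requested classes.

    GNG is skipped (with a note in ``skipped``) when the data are
    one-sided and the exponential offsets cannot be placed.
    """
    if config is None:
        config = FitConfig()
    per_class: Dict[str, List[FitResult]] = {}
    best_within: Dict[str, FitResult] = {}
    skipped: Dict[str, str] = {}
    for cls in classes:
        try:
            fits, best = scan_K(cls, data, config, K_max)
        except (ValueError, RuntimeError) as exc:
            skipped[cls] = str(exc)
            continue
        per_class[cls] = fits
        best_within[cls] = best
    overall = select_overall(best_within)
    return SelectionReport(per_class, best_within, overall, skipped)
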