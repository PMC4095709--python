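"""Model / Results interface for the ensemble differential analysis.

:class:`DifferentialMixture` wraps a vector of difference scores (plus
optional intensities used for robustness weighting); its :meth:`fit`
runs the full ensemble -- BIC order selection within each mixture
class, AIC selection across classes, differential-component labeling
and weighted local-fdr calls -- and returns
:class:`EnsembleResults`, which carries the winning model, per-unit
fdr and calls, approximate standard errors, and a text ``summary()``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import IQR_MULT, TAIL_SD, ClassificationResult
from .classify import classify as _classify_units
from .core import (
    Dataset,
    ExponentialPair,
    MixtureModel,
    UniformComponent,
    cdf,
    density,
)
from .em import FitConfig, FitResult, fit as _fit_single
from .selection import SelectionReport, fit_ensemble
from .weights import compute_weights

__all__ = ["DifferentialMixture", "EnsembleResults"]


class DifferentialMixture:
    """Ensemble mixture model for two-condition difference scores.

    Parameters
    ----------
    y : array-like
        Per-unit normalized difference scores (e.g. log-ratios).
    intensity : array-like, optional
        Average log-intensities; when given, robustness weights are
        derived from them with the chosen weight function.
    weights : array-like, optional
        Explicit weights in [0, 1]; overrides ``intensity``-derived ones.
    weight_family : {"huber", "tukey", "none"}
    tail : {"lower", "upper", "two_tailed"}
    c, taper : float
        Tuning constants of the weight functions.
    """

    def __init__(
        self,
        y,
        intensity=None,
        ids=None,
        weights=None,
        weight_family: str = "huber",
        tail: str = "lower",
        c: float = 1.345,
        taper: float = 4.685,
    ) -> None:
        y = np.asarray(y, dtype=float)
        if weights is not None:
            w = np.asarray(weights, dtype=float)
        elif intensity is not None:
            w = compute_weights(
                intensity, family=weight_family, tail=tail, c=c, taper=taper
            )
        else:
            w = None
        self.data = Dataset.from_arrays(y, u=intensity, w=w, ids=ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        y: str = "y",
        intensity: Optional[str] = None,
        ids: Optional[str] = None,
        **kwargs,
    ) -> "DifferentialMixture":
        """Build from a DataFrame, naming the score / intensity columns."""
        if y not in df.columns:
            raise KeyError(f"column {y!r} not found")
        if intensity is None and "u" in df.columns:
            intensity = "u"
        return cls(
            df[y].to_numpy(dtype=float),
            intensity=(
                df[intensity].to_numpy(dtype=float) if intensity else None
            ),
            ids=df[ids].to_numpy() if ids else None,
            **kwargs,
        )

    @property
    def nobs(self) -> int:
        return self.data.n

    def fit(
        self,
        k_max: int = 6,
        z0: float = 0.1,
        classes: Sequence[str] = ("NUDGE", "iNUDGE", "GNG"),
        tol: float = 1e-5,
        max_iter: int = 2000,
        n_restarts: int = 5,
        seed: int = 0,
        init_method: str = "kmeans",
        tail_sd: float = TAIL_SD,
        iqr_mult: float = IQR_MULT,
    ) -> "EnsembleResults":
        """Fit the ensemble and classify every unit."""
        config = FitConfig(
            tol=tol,
            max_iter=max_iter,
            n_restarts=n_restarts,
            seed=seed,
            init_method=init_method,
        )
        report = fit_ensemble(self.data, config, k_max, classes)
        cls_res = _classify_units(
            report.best_overall.model,
            self.data,
            z0=z0,
            tail_sd=tail_sd,
            iqr_mult=iqr_mult,
        )
        return EnsembleResults(self, report, cls_res)

    def fit_class(
        self, model_class: str, K: int, **config_kwargs
    ) -> FitResult:
        """Fit a single class at a fixed order (no selection)."""
        return _fit_single(
            model_class, K, self.data, FitConfig(**config_kwargs)
        )


def _free_param_info(model: MixtureModel):
    """Names and (get, set) access for the free parameters."""
    names = ["pi"]
    for k in range(model.K - 1):
        names.append(f"gamma[{k}]")
    for k in range(model.K):
        names.append(f"mu[{k}]")
    for k in range(model.K):
        names.append(f"sigma2[{k}]")
    if isinstance(model.f1, ExponentialPair):
        names += ["rho", "beta1", "beta2"]
    return names


def _pack(model: MixtureModel) -> np.ndarray:
    parts = [
        [model.pi],
        model.gammas[:-1],
        model.mus,
        model.sigma2s,
    ]
    if isinstance(model.f1, ExponentialPair):
        parts.append([model.f1.rho, model.f1.beta1, model.f1.beta2])
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


def _unpack(theta: np.ndarray, template: MixtureModel) -> MixtureModel:
    from .core import NormalComponent

    K = template.K
    i = 0
    pi = float(theta[i])
    i += 1
    g = list(theta[i : i + K - 1])
    i += K - 1
    g.append(1.0 - float(np.sum(g)))
    mus = theta[i : i + K]
    i += K
    s2s = theta[i : i + K]
    i += K
    normals = [
        NormalComponent(float(m), float(s), float(gg))
        for m, s, gg in zip(mus, s2s, g)
    ]
    if isinstance(template.f1, ExponentialPair):
        rho, b1, b2 = theta[i : i + 3]
        f1 = ExponentialPair(
            float(rho), float(b1), float(b2),
            template.f1.xi1, template.f1.xi2,
        )
    else:
        f1 = template.f1
    return MixtureModel(template.model_class, pi, normals, f1)


def _sandwich_se(model: MixtureModel, data: Dataset) -> np.ndarray:
    """Sandwich standard errors from numerically differentiated
    per-observation weighted scores; NaN where the information matrix is
    numerically singular (e.g. boundary or frozen parameters)."""
    theta = _pack(model)
    p = theta.size
    y, w = data.y, data.w
    h = 1e-5 * np.maximum(np.abs(theta), 1e-2)

    def obs_loglik(t: np.ndarray) -> np.ndarray:
        m = _unpack(t, model)
        return np.log(np.maximum(density(m, y), 1e-300))

    scores = np.empty((y.size, p))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        try:
            scores[:, j] = (obs_loglik(tp) - obs_loglik(tm)) / (2 * h[j])
        except ValueError:  # perturbed parameter left its domain
            scores[:, j] = np.nan

    psi = scores * w[:, None]

    def total(t: np.ndarray) -> float:
        return float(
            (np.log(np.maximum(density(_unpack(t, model), y), 1e-300)) * w).sum()
        )

    def total_grad(t: np.ndarray) -> np.ndarray:
        g = np.empty(p)
        for l in range(p):
            tp, tm = t.copy(), t.copy()
            tp[l] += h[l]
            tm[l] -= h[l]
            g[l] = (total(tp) - total(tm)) / (2 * h[l])
        return g

    bread = np.empty((p, p))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        try:
            bread[:, j] = (total_grad(tp) - total_grad(tm)) / (2 * h[j])
        except ValueError:
            bread[:, j] = np.nan
    with np.errstate(all="ignore"):
        try:
            a_inv = np.linalg.pinv(bread)
            meat = psi.T @ psi
            cov = a_inv @ meat @ a_inv.T
            se = np.sqrt(np.abs(np.diag(cov)))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    se[~np.isfinite(se)] = np.nan
    return se


class EnsembleResults:
    """Results of an ensemble fit: winning model, fdr, calls, summary."""

    def __init__(
        self,
        model: DifferentialMixture,
        selection: SelectionReport,
        classification: ClassificationResult,
    ) -> None:
        self.model = model
        self.selection = selection
        self.classification = classification
        self.best: FitResult = selection.best_overall
        self._bse: Optional[pd.Series] = None

    # -- basic accessors ------------------------------------------------
    @property
    def model_class(self) -> str:
        return self.best.model.model_class

    @property
    def K(self) -> int:
        return self.best.model.K

    @property
    def mixture(self) -> MixtureModel:
        return self.best.model

    @property
    def llf(self) -> float:
        return self.best.loglik

    @property
    def fdr(self) -> np.ndarray:
        return self.classification.fdr

    @property
    def calls(self) -> np.ndarray:
        return self.classification.calls

    @property
    def n_called(self) -> int:
        return int(self.classification.calls.sum())

    @property
    def param_names(self):
        return _free_param_info(self.best.model)

    @property
    def params(self) -> pd.Series:
        return pd.Series(_pack(self.best.model), index=self.param_names)

    @property
    def bse(self) -> pd.Series:
        """Approximate sandwich standard errors (lazy, numeric)."""
        if self._bse is None:
            se = _sandwich_se(self.best.model, self.model.data)
            self._bse = pd.Series(se, index=self.param_names)
        return self._bse

    # -- tables ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-unit output: id, y, w, fdr, fdr/w, call."""
        d = self.model.data
        with np.errstate(divide="ignore"):
            ratio = np.where(d.w > 0, self.fdr / np.where(d.w > 0, d.w, 1), np.inf)
        return pd.DataFrame(
            {
                "id": d.ids,
                "y": d.y,
                "w": d.w,
                "fdr": self.fdr,
                "fdr_over_w": ratio,
                "call": self.calls.astype(int),
            }
        )

    def criteria_table(self) -> pd.DataFrame:
        rows = []
        for cls, fits in self.selection.per_class.items():
            for fr in fits:
                rows.append(
                    {
                        "class": cls,
                        "K": fr.model.K,
                        "loglik": fr.loglik,
                        "n_params": fr.n_params,
                        "bic": fr.bic,
                        "aic": fr.aic,
                        "converged": fr.converged,
                        "best_within": fr is self.selection.best_within[cls],
                        "best_overall": fr is self.best,
                    }
                )
        return pd.DataFrame(rows)

    def qq_table(self, n_grid: int = 4097) -> pd.DataFrame:
        """Data quantiles vs fitted-model quantiles (for QQ plotting)."""
        d = self.model.data
        ys = np.sort(d.y)
        probs = (np.arange(1, ys.size + 1) - 0.5) / ys.size
        span = ys[-1] - ys[0]
        grid = np.linspace(ys[0] - 0.5 * span, ys[-1] + 0.5 * span, n_grid)
        cg = cdf(self.best.model, grid)
        cg, idx = np.unique(cg, return_index=True)
        model_q = np.interp(probs, cg, grid[idx])
        return pd.DataFrame(
            {"prob": probs, "data_quantile": ys, "model_quantile": model_q}
        )

    # -- simulation / plotting ------------------------------------------
    def simulate(self, nsim: int, seed: int = 0) -> np.ndarray:
        """Draw difference scores from the fitted mixture."""
        m = self.best.model
        rng = np.random.default_rng(seed)
        from .core import component_weights

        cw = component_weights(m)
        comp = rng.choice(cw.size, size=nsim, p=cw / cw.sum())
        out = np.empty(nsim)
        for k in range(m.K):
            mask = comp == k
            out[mask] = rng.normal(
                m.normals[k].mu, m.normals[k].sigma, mask.sum()
            )
        if isinstance(m.f1, ExponentialPair):
            mask = comp == m.K
            out[mask] = -(m.f1.xi1 + rng.exponential(m.f1.beta1, mask.sum()))
            mask = comp == m.K + 1
            out[mask] = m.f1.xi2 + rng.exponential(m.f1.beta2, mask.sum())
        else:
            mask = comp == m.K
            out[mask] = rng.uniform(m.f1.a, m.f1.b, mask.sum())
        return out

    def plot_density(self, ax=None, bins: int = 80):
        """Histogram of the data with the fitted density overlaid."""
        import matplotlib.pyplot as plt

        from .core import component_densities, component_weights

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.data.y
        ax.hist(y, bins=bins, density=True, alpha=0.35, color="gray",
                label="data")
        grid = np.linspace(y.min(), y.max(), 512)
        ax.plot(grid, density(self.best.model, grid), lw=2,
                label=f"{self.model_class} (K={self.K})")
        cols = component_densities(self.best.model, grid)
        cw = component_weights(self.best.model)
        labeled = self.classification.labels
        for j in range(cols.shape[1]):
            is_diff = j >= self.K or (
                labeled is not None and j in labeled.differential_normals
            )
            ax.plot(grid, cw[j] * cols[:, j], lw=1,
                    ls="--" if is_diff else ":",
                    label=("differential" if is_diff else "nondifferential")
                    + f" comp {j}")
        ax.set_xlabel("difference score y")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        return ax

    # -- summary --------------------------------------------------------
    def summary(self) -> str:
        m = self.best.model
        lines = []
        add = lines.append
        add("Ensemble mixture model results")
        add("=" * 64)
        add(f"best class:          {self.model_class}   (K = {self.K})")
        add(f"n observations:      {self.model.nobs}")
        add(f"weighted loglik:     {self.llf:.4f}")
        add(f"BIC / AIC:           {self.best.bic:.2f} / {self.best.aic:.2f}")
        add(f"converged:           {self.best.converged} "
            f"({self.best.n_iter} iterations)")
        labels = self.classification.labels
        if labels is not None:
            add(f"differential normals: {sorted(labels.differential_normals)}"
                f"   (IQR = {labels.iqr:.4f})")
        add(f"calls at z0={self.classification.z0}: {self.n_called} of "
            f"{self.model.nobs}")
        if self.best.warnings:
            add("warnings: " + "; ".join(self.best.warnings))
        add("-" * 64)
        add(f"{'parameter':<12}{'estimate':>14}{'std err':>14}")
        bse = self._bse  # do not trigger the slow path implicitly
        for j, name in enumerate(self.param_names):
            est = self.params.iloc[j]
            se = "" if bse is None else (
                f"{bse.iloc[j]:.4f}" if np.isfinite(bse.iloc[j]) else "nan"
            )
            add(f"{name:<12}{est:>14.5f}{se:>14}")
        f1 = m.f1
        if isinstance(f1, UniformComponent):
            add(f"fixed: a = {f1.a:.4f}, b = {f1.b:.4f}")
        else:
            add(f"fixed: xi1 = {f1.xi1:.4g}, xi2 = {f1.xi2:.4g}")
        add("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EnsembleResults {self.model_class} K={self.K} "
            f"n={self.model.nobs} calls={self.n_called}>"
        )
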