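"""Synthetic two-condition expression data with known differential truth.

The generator emulates a two-color microarray comparison. Control
log-expression x1 is uniform on (15, 30). For differential genes the
treatment value is

    x2 = x1 + Z + (2B - 1) * G,

with Z ~ N(0, 0.7 - 0.02*x1) (variance decreasing in expression, so dim
genes are noisier), B ~ Bernoulli(1/2) choosing over- vs
under-expression, and the effect size G drawn from one of three laws:
shifted exponential (scale 1.4286, offset 1), uniform(1, 4), or
normal(2.5, 0.75^2). Nondifferential genes get x2 = x1 + d with d drawn
either from a user-supplied pool of real null log-ratios (all |d| <= 1)
or from a truncated-normal stand-in N(0, 0.25^2) restricted to [-1, 1].
Defaults: 10,000 genes, 10% differential.

The analysis input is y = x2 - x1 with average intensity u = (x1+x2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .classify import classify, evaluate
from .core import Dataset
from .em import FitConfig
from .selection import fit_ensemble
from .weights import compute_weights

__all__ = [
    "G_LAWS",
    "SimConfig",
    "SimDataset",
    "simulate_differential",
    "simulate_null",
    "simulate_dataset",
    "run_replicates",
]

G_LAWS = ("exponential", "uniform", "normal")

_DEFAULT_G_PARAMS = {
    "exponential": {"scale": 1.4286, "offset": 1.0},
    "uniform": {"low": 1.0, "high": 4.0},
    "normal": {"mean": 2.5, "sd": 0.75},
}

_NULL_SD = 0.25  # scale of the parametric truncated-normal null
_NULL_BOUND = 1.0  # |log-ratio| cap for nondifferential genes


@dataclass
class SimConfig:
    n: int = 10_000
    p_diff: float = 0.10
    g_law: str = "exponential"
    g_params: Optional[dict] = None
    null_source: str = "parametric"  # or "pool_file"
    pool_file: Optional[str] = None
    var_is_sd: bool = False  # interpret 0.7 - 0.02*x1 as sd instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_law not in G_LAWS:
            raise ValueError(f"unknown G law {self.g_law!r}")
        if not 0.0 < self.p_diff < 1.0:
            raise ValueError("p_diff must lie in (0, 1)")
        if self.null_source not in ("parametric", "pool_file"):
            raise ValueError(f"unknown null source {self.null_source!r}")
        if self.g_params is None:
            self.g_params = dict(_DEFAULT_G_PARAMS[self.g_law])


@dataclass
class SimDataset:
    x1: np.ndarray
    x2: np.ndarray
    truth: np.ndarray
    ids: np.ndarray

    @property
    def y(self) -> np.ndarray:
        return self.x2 - self.x1

    @property
    def u(self) -> np.ndarray:
        return 0.5 * (self.x1 + self.x2)

    @property
    def n(self) -> int:
        return self.x1.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x1": self.x1,
                "x2": self.x2,
                "y": self.y,
                "u": self.u,
                "truth": self.truth.astype(int),
            }
        )

    def to_dataset(
        self,
        weight_family: str = "huber",
        tail: str = "lower",
    ) -> Dataset:
        w = compute_weights(self.u, family=weight_family, tail=tail)
        return Dataset(ids=self.ids, y=self.y, u=self.u, w=w)


def _draw_g(rng: np.random.Generator, m: int, law: str, params: dict):
    if law == "exponential":
        return rng.exponential(params["scale"], m) + params["offset"]
    if law == "uniform":
        return rng.uniform(params["low"], params["high"], m)
    if law == "normal":
        return rng.normal(params["mean"], params["sd"], m)
    raise ValueError(f"unknown G law {law!r}")


def simulate_differential(
    m: int,
    g_law: str = "exponential",
    g_params: Optional[dict] = None,
    seed=0,
    var_is_sd: bool = False,
):
    """Control/treatment log-expression pairs for m differential genes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if g_law not in G_LAWS:
        raise ValueError(f"unknown G law {g_law!r}")
    if g_params is None:
        g_params = dict(_DEFAULT_G_PARAMS[g_law])
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(15.0, 30.0, m)
    spread = 0.7 - 0.02 * x1  # in (0.1, 0.4) for x1 in (15, 30)
    sd = spread if var_is_sd else np.sqrt(spread)
    z = rng.normal(0.0, 1.0, m) * sd
    b = rng.integers(0, 2, m)
    g = _draw_g(rng, m, g_law, g_params)
    x2 = x1 + z + (2.0 * b - 1.0) * g
    return x1, x2


def _load_pool(pool_file: str) -> np.ndarray:
    pool = np.loadtxt(pool_file, dtype=float, ndmin=1)
    if pool.size == 0:
        raise ValueError("empty null pool file")
    if np.any(np.abs(pool) > _NULL_BOUND):
        raise ValueError("null pool contains |log-ratio| > 1")
    return pool


def simulate_null(
    m: int,
    null_source: str = "parametric",
    seed=0,
    pool_file: Optional[str] = None,
):
    """Nondifferential pairs: x2 - x1 bounded by 1 in absolute value."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(15.0, 30.0, m)
    if null_source == "pool_file":
        if pool_file is None:
            raise ValueError("null_source='pool_file' needs a pool_file")
        d = rng.choice(_load_pool(pool_file), size=m, replace=True)
    elif null_source == "parametric":
        lim = _NULL_BOUND / _NULL_SD
        d = truncnorm.rvs(
            -lim, lim, scale=_NULL_SD, size=m, random_state=rng
        )
    else:
        raise ValueError(f"unknown null source {null_source!r}")
    return x1, x1 + d


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full dataset: round(n*p_diff) differential genes plus nulls,
    shuffled; bit-identical for a given config."""
    n_pos = int(round(config.n * config.p_diff))
    if n_pos < 1:
        raise ValueError("round(n * p_diff) must be at least 1")
    n_neg = config.n - n_pos
    if n_neg < 1:
        raise ValueError("need at least one nondifferential gene")
    ss = np.random.SeedSequence(config.seed)
    s_diff, s_null, s_perm = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    x1d, x2d = simulate_differential(
        n_pos, config.g_law, config.g_params, s_diff, config.var_is_sd
    )
    x1n, x2n = simulate_null(
        n_neg, config.null_source, s_null, config.pool_file
    )
    x1 = np.concatenate([x1d, x1n])
    x2 = np.concatenate([x2d, x2n])
    truth = np.concatenate(
        [np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)]
    )
    perm = np.random.default_rng(s_perm).permutation(config.n)
    ids = np.array([f"gene_{i + 1}" for i in range(config.n)])
    return SimDataset(x1=x1[perm], x2=x2[perm], truth=truth[perm], ids=ids)


def run_replicates(
    config: SimConfig,
    n_reps: int = 10,
    z0: float = 0.1,
    K_max: int = 6,
    fit_config: Optional[FitConfig] = None,
    weight_family: str = "huber",
    tail: str = "lower",
    classes=("NUDGE", "iNUDGE", "GNG"),
    progress=None,
) -> pd.DataFrame:
    """Replicate study: simulate, weight, fit all classes, select,
    classify, and score against the truth.

    Returns one row per (replicate, model class) plus the ensemble pick,
    with columns rep, class, K, tpr, fpr, chosen. Deterministic given
    ``config.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if fit_config is None:
        fit_config = FitConfig()
    children = np.random.SeedSequence(config.seed).spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % 2**31)
        sim = simulate_dataset(replace(config, seed=seed))
        data = sim.to_dataset(weight_family=weight_family, tail=tail)
        try:
            report = fit_ensemble(
                data, replace(fit_config, seed=seed), K_max, classes
            )
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} failed: {exc}") from exc
        for cls, fr in report.best_within.items():
            res = classify(fr.model, data, z0=z0)
            tpr, fpr = evaluate(res.calls, sim.truth)
            rows.append(
                {
                    "rep": rep,
                    "class": cls,
                    "K": fr.model.K,
                    "tpr": tpr,
                    "fpr": fpr,
                    "chosen": fr is report.best_overall,
                }
            )
        if progress is not None:
            progress(rep)
    return pd.DataFrame(rows)
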