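"""Weighted-likelihood EM fitting of a single mixture model.

The objective is l(Psi) = sum_i w_i log f(y_i; Psi) with prespecified
weights w_i in [0, 1]. The E-step computes responsibilities from the
weighted component densities; the M-step updates pi, the normal
parameters, and (for GNG) rho, beta1, beta2 in closed form, keeping the
uniform bounds and exponential offsets fixed. Iteration stops when the
largest absolute change over the free parameters drops below ``tol`` or
after ``max_iter`` iterations; several restarts from different starting
values are run and the best weighted log-likelihood wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import (
    Dataset,
    ExponentialPair,
    MixtureModel,
    NormalComponent,
    UniformComponent,
    VARIANCE_FLOOR_FACTOR,
    component_densities,
    component_weights,
    count_params,
    estimate_xi,
)

__all__ = ["FitConfig", "FitResult", "fit", "e_step", "m_step", "initialize"]

_FROZEN_RESP = 1e-10  # below this total responsibility a component freezes
_BETA_FLOOR = 1e-8


@dataclass
class FitConfig:
    """EM control parameters.

    tol : stop when the max absolute parameter change falls below this.
    max_iter : iteration cap per EM run.
    n_restarts : EM runs per fit; the first uses ``init_method``, the
        rest use random starts under derived seeds.
    """

    tol: float = 1e-5
    max_iter: int = 2000
    n_restarts: int = 5
    seed: int = 0
    init_method: str = "kmeans"
    #: iteration cap for the exploratory short runs (one per restart);
    #: the short run with the best weighted log-likelihood is continued
    #: to convergence ("em-EM" style restarts). Set >= max_iter to run
    #: every restart to full convergence.
    short_run_iters: int = 100

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")
        if self.init_method not in ("kmeans", "quantile", "random"):
            raise ValueError(f"unknown init method {self.init_method!r}")


@dataclass
class FitResult:
    """One fitted model with its weighted log-likelihood and criteria."""

    model: MixtureModel
    loglik: float
    n_params: int
    bic: float
    aic: float
    n_iter: int
    converged: bool
    warnings: List[str] = field(default_factory=list)
    n_obs: int = 0


def _resp_and_loglik(model: MixtureModel, data: Dataset):
    dens = component_densities(model, data.y)
    cw = component_weights(model)
    weighted = dens * cw[None, :]
    fy = weighted.sum(axis=1)
    bad = fy <= 0
    if np.any(bad):
        idx = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"zero mixture density at unit index {idx} (y={data.y[idx]!r}); "
            "check uniform bounds / exponential offsets"
        )
    resp = weighted / fy[:, None]
    loglik = float(np.dot(data.w, np.log(fy)))
    return resp, loglik


def e_step(model: MixtureModel, data: Dataset) -> np.ndarray:
    """Responsibility matrix, shape (n, K + f1 parts); rows sum to 1."""
    resp, _ = _resp_and_loglik(model, data)
    return resp


def weighted_loglik(model: MixtureModel, data: Dataset) -> float:
    _, ll = _resp_and_loglik(model, data)
    return ll


def m_step(
    resp: np.ndarray,
    data: Dataset,
    model: MixtureModel,
    warnings: Optional[List[str]] = None,
) -> MixtureModel:
    """Closed-form weighted updates given responsibilities.

    All sums are weighted by w_i * resp_ij, so the update is invariant to
    rescaling the weights. A component whose total weighted responsibility
    falls below 1e-10 keeps its previous parameters (frozen) and a warning
    is recorded. Variances are clamped at the singularity floor.
    """
    if warnings is None:
        warnings = []
    y, w = data.y, data.w
    K = model.K
    wr = resp * w[:, None]
    sw = w.sum()
    if sw <= 0:
        raise ValueError("all observation weights are zero")
    var_floor = VARIANCE_FLOOR_FACTOR * float(np.var(y))

    col_mass = wr.sum(axis=0)
    norm_mass = col_mass[:K]
    f1_mass = col_mass[K:].sum()

    pi = float(f1_mass / sw)
    pi = min(max(pi, 0.0), 1.0)

    normals = []
    total_norm = norm_mass.sum()
    for k in range(K):
        old = model.normals[k]
        gamma = (
            float(norm_mass[k] / total_norm) if total_norm > 0 else old.gamma
        )
        if norm_mass[k] < _FROZEN_RESP:
            warnings.append(
                f"normal component {k} lost all responsibility; frozen"
            )
            normals.append(NormalComponent(old.mu, old.sigma2, gamma))
            continue
        mu = float(wr[:, k] @ y / norm_mass[k])
        s2 = float(wr[:, k] @ (y - mu) ** 2 / norm_mass[k])
        if s2 < var_floor:
            warnings.append(
                f"potential singularity: variance of component {k} hit the "
                f"floor {var_floor:.3g}"
            )
            s2 = var_floor
        normals.append(NormalComponent(mu, s2, gamma))
    if total_norm > 0:  # renormalize against floating drift
        g = np.array([c.gamma for c in normals])
        g = g / g.sum()
        normals = [
            NormalComponent(c.mu, c.sigma2, float(gk))
            for c, gk in zip(normals, g)
        ]

    f1 = model.f1
    if isinstance(f1, ExponentialPair):
        m1, m2 = float(col_mass[K]), float(col_mass[K + 1])
        rho = f1.rho if (m1 + m2) <= 0 else m1 / (m1 + m2)
        beta1, beta2 = f1.beta1, f1.beta2
        if m1 >= _FROZEN_RESP:
            beta1 = float(wr[:, K] @ (-y - f1.xi1) / m1)
            beta1 = max(beta1, _BETA_FLOOR)
        elif m1 > 0 or m2 > 0:
            warnings.append("negative exponential lost responsibility; frozen")
        if m2 >= _FROZEN_RESP:
            beta2 = float(wr[:, K + 1] @ (y - f1.xi2) / m2)
            beta2 = max(beta2, _BETA_FLOOR)
        elif m1 > 0 or m2 > 0:
            warnings.append("positive exponential lost responsibility; frozen")
        new_f1 = ExponentialPair(float(rho), beta1, beta2, f1.xi1, f1.xi2)
    else:
        new_f1 = UniformComponent(f1.a, f1.b)

    return MixtureModel(model.model_class, pi, normals, new_f1)


def _make_f1(model_class: str, y: np.ndarray):
    if model_class == "GNG":
        xi1, xi2 = estimate_xi(y)
        return ExponentialPair(0.5, 1.0, 1.0, xi1, xi2)
    return UniformComponent(float(y.min()), float(y.max()))


def initialize(
    model_class: str,
    K: int,
    data: Dataset,
    method: str = "kmeans",
    seed: int = 0,
) -> MixtureModel:
    """Starting parameters: pi=0.1, rho=0.5, beta=1, and normal
    components placed by K-means clusters, evenly spaced quantiles, or
    uniform random draws over the data range."""
    y = data.y
    if model_class == "NUDGE" and K != 1:
        raise ValueError("NUDGE is restricted to K = 1")
    if data.n < K:
        raise ValueError("need n >= K observations")
    if np.unique(y).size < K:
        raise ValueError("K exceeds the number of distinct y values")

    var_floor = max(VARIANCE_FLOOR_FACTOR * float(np.var(y)), 1e-12)
    vy = max(float(np.var(y)), var_floor)

    if K == 1:
        mus = np.array([float(y.mean())])
        s2s = np.array([vy])
        gammas = np.array([1.0])
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=1, random_state=seed % (2**31))
        lab = km.fit_predict(y[:, None])
        mus, s2s, gammas = [], [], []
        for k in range(K):
            yk = y[lab == k]
            mus.append(float(yk.mean()) if yk.size else float(y.mean()))
            s2s.append(max(float(np.var(yk)) if yk.size > 1 else vy, var_floor))
            gammas.append(max(yk.size / y.size, 1e-3))
        order = np.argsort(mus)
        mus = np.asarray(mus)[order]
        s2s = np.asarray(s2s)[order]
        gammas = np.asarray(gammas)[order]
        gammas = gammas / gammas.sum()
    elif method == "quantile":
        q = np.arange(1, K + 1) / (K + 1)
        mus = np.quantile(y, q)
        s2s = np.full(K, vy / K)
        gammas = np.full(K, 1.0 / K)
    elif method == "random":
        rng = np.random.default_rng(seed)
        mus = np.sort(rng.uniform(y.min(), y.max(), size=K))
        s2s = np.full(K, vy)
        gammas = np.full(K, 1.0 / K)
    else:
        raise ValueError(f"unknown init method {method!r}")

    normals = [
        NormalComponent(float(m), float(s), float(g))
        for m, s, g in zip(mus, s2s, gammas)
    ]
    return MixtureModel(model_class, 0.1, normals, _make_f1(model_class, y))


def _param_vector(model: MixtureModel) -> np.ndarray:
    parts = [
        np.array([model.pi]),
        model.gammas,
        model.mus,
        model.sigma2s,
    ]
    if isinstance(model.f1, ExponentialPair):
        parts.append(
            np.array([model.f1.rho, model.f1.beta1, model.f1.beta2])
        )
    return np.concatenate(parts)


def _run_em_fast(
    model: MixtureModel,
    data: Dataset,
    config: FitConfig,
    iter_cap: Optional[int] = None,
):
    """Array-based EM loop; identical updates to e_step/m_step but
    without per-iteration object construction. Returns the same tuple
    as :func:`_run_em`. ``iter_cap`` overrides ``config.max_iter``."""
    y, w = data.y, data.w
    n = y.size
    sw = float(w.sum())
    if sw <= 0:
        raise ValueError("all observation weights are zero")
    var_floor = VARIANCE_FLOOR_FACTOR * float(np.var(y))
    y2 = y * y

    K = model.K
    mu = model.mus.astype(float)
    s2 = model.sigma2s.astype(float)
    gam = model.gammas.astype(float)
    pi = float(model.pi)
    f1 = model.f1
    is_gng = isinstance(f1, ExponentialPair)
    if is_gng:
        rho, b1, b2 = float(f1.rho), float(f1.beta1), float(f1.beta2)
        idx1 = np.nonzero(y < -f1.xi1)[0]
        idx2 = np.nonzero(y > f1.xi2)[0]
        t1 = -y[idx1] - f1.xi1
        t2 = y[idx2] - f1.xi2
    else:
        ucol = 1.0 / (f1.b - f1.a)
        rho = b1 = b2 = 0.0

    warn_frozen = [False] * K
    warn_floor = [False] * K
    warn_e1 = warn_e2 = False
    sqrt2pi = np.sqrt(2.0 * np.pi)

    def param_vec():
        parts = [[pi], gam, mu, s2]
        if is_gng:
            parts.append([rho, b1, b2])
        return np.concatenate([np.atleast_1d(np.asarray(p)) for p in parts])

    y3 = np.column_stack([np.ones_like(y), y, y2])
    ry3 = np.empty_like(y3)
    prev = param_vec()
    converged = False
    n_iter = 0
    max_iter = config.max_iter if iter_cap is None else iter_cap
    for n_iter in range(1, max_iter + 1):
        z = y[:, None] - mu[None, :]
        wn = np.exp(z * z * (-0.5 / s2)[None, :])
        wn *= ((1.0 - pi) * gam / (np.sqrt(s2) * sqrt2pi))[None, :]
        fy = wn.sum(axis=1)
        if is_gng:
            e1 = (pi * rho / b1) * np.exp(-t1 / b1)
            e2 = (pi * (1.0 - rho) / b2) * np.exp(-t2 / b2)
            fy[idx1] += e1
            fy[idx2] += e2
        else:
            fy += pi * ucol
        if not np.all(fy > 0):
            idx = int(np.argmin(fy))
            raise ValueError(
                f"zero mixture density at unit index {idx} "
                f"(y={y[idx]!r}); check uniform bounds / exponential offsets"
            )
        r = w / fy
        np.multiply(y3, r[:, None], out=ry3)
        moments = wn.T @ ry3  # K x 3: mass, sum(w r y), sum(w r y^2)
        mass = moments[:, 0]
        swy = moments[:, 1]
        swy2 = moments[:, 2]
        if is_gng:
            r1 = r[idx1]
            r2 = r[idx2]
            m1 = float(e1 @ r1)
            m2 = float(e2 @ r2)
            f1_mass = m1 + m2
        else:
            f1_mass = pi * ucol * float(r.sum())

        pi = min(max(f1_mass / sw, 0.0), 1.0)
        total_norm = float(mass.sum())
        if total_norm > 0:
            gam = mass / total_norm
        for k in range(K):
            if mass[k] < _FROZEN_RESP:
                warn_frozen[k] = True
                continue
            mu_k = swy[k] / mass[k]
            s2_k = swy2[k] / mass[k] - mu_k * mu_k
            if s2_k < var_floor:
                warn_floor[k] = True
                s2_k = var_floor
            mu[k] = mu_k
            s2[k] = s2_k
        if is_gng:
            if m1 + m2 > 0:
                rho = m1 / (m1 + m2)
            if m1 >= _FROZEN_RESP:
                b1 = max(float((e1 * t1) @ r1) / m1, _BETA_FLOOR)
            elif m1 + m2 > 0:
                warn_e1 = True
            if m2 >= _FROZEN_RESP:
                b2 = max(float((e2 * t2) @ r2) / m2, _BETA_FLOOR)
            elif m1 + m2 > 0:
                warn_e2 = True

        cur = param_vec()
        if np.max(np.abs(cur - prev)) < config.tol:
            converged = True
            break
        prev = cur

    normals = [
        NormalComponent(float(m), float(max(s, var_floor)), float(g))
        for m, s, g in zip(mu, s2, gam / gam.sum())
    ]
    if is_gng:
        new_f1 = ExponentialPair(rho, b1, b2, f1.xi1, f1.xi2)
    else:
        new_f1 = UniformComponent(f1.a, f1.b)
    out = MixtureModel(model.model_class, pi, normals, new_f1)
    loglik = weighted_loglik(out, data)
    warnings = []
    for k in range(K):
        if warn_frozen[k]:
            warnings.append(
                f"normal component {k} lost all responsibility; frozen"
            )
        if warn_floor[k]:
            warnings.append(
                f"potential singularity: variance of component {k} hit the "
                f"floor {var_floor:.3g}"
            )
    if warn_e1:
        warnings.append("negative exponential lost responsibility; frozen")
    if warn_e2:
        warnings.append("positive exponential lost responsibility; frozen")
    return out, loglik, n_iter, converged, warnings


def _run_em(model: MixtureModel, data: Dataset, config: FitConfig):
    warnings: List[str] = []
    prev = _param_vector(model)
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        resp, _ = _resp_and_loglik(model, data)
        model = m_step(resp, data, model, warnings)
        cur = _param_vector(model)
        if np.max(np.abs(cur - prev)) < config.tol:
            converged = True
            break
        prev = cur
    loglik = weighted_loglik(model, data)
    # keep each distinct warning once
    seen = list(dict.fromkeys(warnings))
    return model, loglik, n_iter, converged, seen


def fit(
    model_class: str,
    K: int,
    data: Dataset,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit one model class at a given order K.

    Runs ``config.n_restarts`` EM runs (first from ``config.init_method``,
    the rest from random starts under seeds derived from ``config.seed``)
    and returns the run with the highest weighted log-likelihood; ties go
    to the earliest restart.
    """
    if config is None:
        config = FitConfig()
    n = data.n
    probe = initialize(model_class, K, data, "quantile", config.seed)
    p = count_params(probe)
    if n < p:
        raise ValueError(
            f"n={n} observations cannot identify {p} free parameters"
        )

    ss = np.random.SeedSequence(config.seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.n_restarts)]
    cap = min(config.short_run_iters, config.max_iter)
    best = None
    for r in range(config.n_restarts):
        method = config.init_method if r == 0 else "random"
        start = initialize(model_class, K, data, method, sub[r])
        model, ll, n_iter, conv, warns = _run_em_fast(
            start, data, config, iter_cap=cap
        )
        if best is None or ll > best[1] + 1e-12:
            best = (model, ll, n_iter, conv, warns)

    model, ll, n_iter, conv, warns = best
    if not conv:  # continue the winning short run to convergence
        remaining = config.max_iter - n_iter
        if remaining > 0:
            model, ll, it2, conv, w2 = _run_em_fast(
                model, data, config, iter_cap=remaining
            )
            n_iter += it2
            warns = list(dict.fromkeys(warns + w2))
    logn = np.log(n)
    return FitResult(
        model=model,
        loglik=ll,
        n_params=p,
        bic=2.0 * ll - p * logn,
        aic=2.0 * ll - 2.0 * p,
        n_iter=n_iter,
        converged=conv,
        warnings=warns,
        n_obs=n,
    )
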