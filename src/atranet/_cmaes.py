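"""Covariance matrix adaptation evolution strategy with box constraints.

Minimal (mu/mu_w, lambda)-CMA-ES for low-dimensional, seeded, derivative-free
minimization.  The search runs in coordinates scaled to the unit box; bounds
are enforced by reflection before evaluation.  Every strictly improving
evaluation is reported through ``archive_callback`` (downhill archiving).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["CMAResult", "cma_es_minimize"]


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    n_iterations: int


def _reflect(z: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [0, 1] (period-2 triangular map)."""
    z = np.mod(z, 2.0)
    return np.where(z > 1.0, 2.0 - z, z)


def cma_es_minimize(
    fn: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    *,
    seed: int | None = None,
    max_iter: int = 100,
    popsize: int | None = None,
    sigma0: float = 0.25,
    x0: np.ndarray | None = None,
    archive_callback: Callable[[np.ndarray, float], None] | None = None,
    f_tol: float = 0.0,
) -> CMAResult:
    """Minimize ``fn`` over a box via CMA-ES.

    ``bounds`` is a sequence of (lo, hi) pairs; ``x0`` (original units)
    defaults to a uniform random point in the box.  ``sigma0`` is the initial
    step as a fraction of the box width.  Deterministic given ``seed``.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    width = hi - lo
    if np.any(width <= 0):
        raise ValueError("every bound must satisfy lo < hi")
    d = lo.size
    rng = np.random.default_rng(seed)

    lam = popsize if popsize is not None else 4 + int(3 * np.log(d))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)

    # standard adaptation constants (Hansen's defaults)
    c_sigma = (mu_eff + 2.0) / (d + mu_eff + 5.0)
    d_sigma = 1.0 + 2.0 * max(0.0, np.sqrt((mu_eff - 1.0) / (d + 1.0)) - 1.0) + c_sigma
    c_c = (4.0 + mu_eff / d) / (d + 4.0 + 2.0 * mu_eff / d)
    c_1 = 2.0 / ((d + 1.3) ** 2 + mu_eff)
    c_mu = min(1.0 - c_1, 2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((d + 2.0) ** 2 + mu_eff))
    chi_d = np.sqrt(d) * (1.0 - 1.0 / (4.0 * d) + 1.0 / (21.0 * d ** 2))

    mean = ((np.asarray(x0, float) - lo) / width) if x0 is not None \
        else rng.uniform(0.0, 1.0, d)
    sigma = sigma0
    C = np.eye(d)
    p_sigma = np.zeros(d)
    p_c = np.zeros(d)

    best_x = lo + _reflect(mean) * width
    best_f = fn(best_x)
    n_eval = 1
    if archive_callback is not None:
        archive_callback(best_x.copy(), best_f)

    for it in range(max_iter):
        # eigendecomposition for sampling (d is small; recompute each step)
        evals, B = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        D = np.sqrt(evals)

        zs = rng.standard_normal((lam, d))
        ys = zs @ (B * D).T          # y ~ N(0, C)
        xs_unit = mean + sigma * ys
        xs = lo + _reflect(xs_unit) * width

        fs = np.empty(lam)
        for k in range(lam):
            fs[k] = fn(xs[k])
            n_eval += 1
            if fs[k] < best_f:
                best_f = fs[k]
                best_x = xs[k].copy()
                if archive_callback is not None:
                    archive_callback(best_x.copy(), best_f)

        order = np.argsort(fs, kind="stable")
        y_sel = ys[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        # step-size control
        C_inv_sqrt = (B / D) @ B.T
        p_sigma = (1.0 - c_sigma) * p_sigma + \
            np.sqrt(c_sigma * (2.0 - c_sigma) * mu_eff) * (C_inv_sqrt @ y_w)
        sigma *= np.exp((c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_d - 1.0))
        sigma = min(sigma, 1.0)

        # covariance adaptation
        h_sigma = float(np.linalg.norm(p_sigma) /
                        np.sqrt(1.0 - (1.0 - c_sigma) ** (2 * (it + 1))) <
                        (1.4 + 2.0 / (d + 1.0)) * chi_d)
        p_c = (1.0 - c_c) * p_c + h_sigma * np.sqrt(c_c * (2.0 - c_c) * mu_eff) * y_w
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (1.0 - c_1 - c_mu) * C + \
            c_1 * (np.outer(p_c, p_c) + (1.0 - h_sigma) * c_c * (2.0 - c_c) * C) + \
            c_mu * rank_mu
        C = (C + C.T) / 2.0

        if f_tol > 0.0 and best_f <= f_tol:
            break

    return CMAResult(x=best_x, fun=best_f, n_evaluations=n_eval, n_iterations=it + 1)
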