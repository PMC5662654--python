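"""Black-box polynomial model of ATRA-induced G0 cell-cycle arrest.

The arrested fraction is expanded in polynomial basis functions of the
combined coordinate t/T + p21/E2F evaluated along a simulated trajectory:
A(t) ~ a0 + sum_i a_i (t/T + p21/E2F)^(i-1), i = 1..N-1, with N = 4 by
default.  p21 is taken directly, and E2F inversely, proportional to arrest.
Coefficients are estimated from cell-cycle measurements by ordinary least
squares; predictions are clamped to [0, 1] since the output is a population
fraction.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["basis", "ArrestModel", "fit_arrest", "predict_arrest"]

#: design-matrix condition number above which a warning is issued
CONDITION_WARN = 1e8


def basis(t, p21, e2f, T: float, i: int):
    """Basis function phi_i = (t/T + p21/E2F)^(i-1).

    ``i`` ranges over 1..N-1 (i = 1 is the constant 1); ``T`` is the horizon
    normalizing time so t/T is dimensionless.
    """
    if T <= 0:
        raise ValueError("horizon T must be > 0")
    if i < 1:
        raise ValueError("basis index i must be >= 1")
    e2f = np.asarray(e2f, float)
    if np.any(e2f <= 0):
        raise ValueError("E2F level must be > 0 (ratio guard)")
    x = np.asarray(t, float) / T + np.asarray(p21, float) / e2f
    return x ** (i - 1)


def _design_matrix(t, p21, e2f, T: float, order: int) -> np.ndarray:
    # a0 multiplies the constant basis (i = 1); the remaining coefficients
    # multiply successive powers, giving the third-order polynomial
    # 1, x, x^2, x^3 for the default N = 4
    cols = [basis(t, p21, e2f, T, i) for i in range(1, order + 1)]
    return np.column_stack(cols)


class ArrestModel:
    """Least-squares arrest-fraction model over the p21/E2F trajectory.

    Parameters
    ----------
    order : int
        Number of coefficients N (a0..a_{N-1}); default 4 (third-order
        polynomial).
    horizon : float or None
        Basis normalization time T (hr). ``None`` uses the final
        measurement time passed to :meth:`fit`.

    Fitted attributes: ``coefficients_``, ``horizon_``, ``residual_``
    (sum of squared residuals), ``condition_number_``.
    """

    def __init__(self, order: int = 4, horizon: float | None = None):
        if order < 1:
            raise ValueError("order must be >= 1")
        self.order = order
        self.horizon = horizon

    def get_params(self) -> dict:
        return {"order": self.order, "horizon": self.horizon}

    def set_params(self, **kwargs) -> "ArrestModel":
        for k, v in kwargs.items():
            if k not in ("order", "horizon"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, t, arrest_fraction, p21, e2f) -> "ArrestModel":
        t = np.asarray(t, float)
        y = np.asarray(arrest_fraction, float)
        if t.size < self.order:
            raise ValueError(
                f"need at least {self.order} data points, got {t.size}")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("arrest fractions must lie in [0, 1]")
        self.horizon_ = float(self.horizon) if self.horizon is not None else float(t.max())
        X = _design_matrix(t, p21, e2f, self.horizon_, self.order)
        sv = np.linalg.svd(X, compute_uv=False)
        rank = int(np.sum(sv > sv[0] * max(X.shape) * np.finfo(float).eps))
        if rank < X.shape[1]:
            # identify which basis columns are linearly dependent on earlier ones
            bad = []
            for j in range(1, X.shape[1]):
                sub = X[:, :j + 1]
                if np.linalg.matrix_rank(sub) <= np.linalg.matrix_rank(X[:, :j]):
                    bad.append(f"phi_{j}")
            raise np.linalg.LinAlgError(
                f"rank-deficient arrest design matrix; collinear columns: {bad}")
        self.condition_number_ = float(sv[0] / sv[-1])
        if self.condition_number_ > CONDITION_WARN:
            warnings.warn(
                f"arrest design matrix condition number {self.condition_number_:.2e} "
                f"exceeds {CONDITION_WARN:.0e}", RuntimeWarning, stacklevel=2)
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.coefficients_ = coef
        self.residual_ = float(res[0]) if res.size else float(
            np.sum((X @ coef - y) ** 2))
        return self

    def _check_fitted(self):
        if not hasattr(self, "coefficients_"):
            raise RuntimeError("ArrestModel is not fitted")

    def predict_raw(self, t, p21, e2f) -> np.ndarray:
        """Unclamped polynomial value (the OLS fitted value at training points)."""
        self._check_fitted()
        X = _design_matrix(t, p21, e2f, self.horizon_, self.order)
        return X @ self.coefficients_

    def predict(self, t, p21, e2f) -> np.ndarray:
        """Predicted arrested fraction, clamped to [0, 1]."""
        return np.clip(self.predict_raw(t, p21, e2f), 0.0, 1.0)


def fit_arrest(arrest_points, p21_series, e2f_series, N: int = 4,
               T: float | None = None) -> ArrestModel:
    """Fit an :class:`ArrestModel` to (time, fraction) points.

    ``arrest_points`` is a sequence of (t, fraction) pairs (replicates enter
    as independent rows); ``p21_series``/``e2f_series`` give the protein
    levels at the same times.
    """
    pts = np.asarray(arrest_points, float)
    return ArrestModel(order=N, horizon=T).fit(
        pts[:, 0], pts[:, 1], p21_series, e2f_series)


def predict_arrest(model: ArrestModel, t, p21, e2f):
    """Clamped arrest-fraction prediction (functional wrapper)."""
    return model.predict(t, p21, e2f)
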