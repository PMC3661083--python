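"""Per-channel VAR estimation by ordinary least squares.

Each target channel ``x_k`` is regressed on lags ``1..p`` of itself and of
the channels in its extrinsic channel set ``L_k`` (the reduced model); the
full VAR is recovered as ``K`` independent single-equation fits with
``L_k`` equal to all other channels, which is row-wise equivalent to joint
multivariate OLS. Regression rows are ``n = p+1..N_win`` (conditional /
"covariance-method" least squares — the first ``p`` samples condition the
regression, no pre-sample padding is invented). Windows are demeaned per
channel before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import DataError, EiprError, VarModelSpec

__all__ = [
    "FitSingularError",
    "WindowConfig",
    "EquationFit",
    "fit_equation",
    "partial_contribution",
    "check_stability",
    "fit_full_var",
]

#: Condition-number ceiling for the lagged design matrix; beyond this the
#: normal equations are declared ill-posed and the caller should shrink
#: the channel set.
MAX_CONDITION = 1e12


class FitSingularError(EiprError):
    """Singular or ill-conditioned regression; reduce the channel set."""


@dataclass(frozen=True)
class WindowConfig:
    """Analysis-window geometry: length in seconds, model order, sampling rate."""

    window_seconds: float
    order: int
    sampling_rate: float

    def __post_init__(self):
        if self.order < 1:
            raise DataError("model order must be >= 1")
        if self.window_seconds <= 0 or self.sampling_rate <= 0:
            raise DataError("window_seconds and sampling_rate must be positive")
        n = self.window_seconds * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise DataError(
                f"window of {self.window_seconds}s at {self.sampling_rate}Hz "
                "does not contain an integer number of samples"
            )

    @property
    def n_win(self) -> int:
        return int(round(self.window_seconds * self.sampling_rate))

    def check_identifiable(self, n_channels: int) -> None:
        need = (self.order + 1) * (n_channels + 1)
        if self.n_win < need:
            raise DataError(
                f"window of {self.n_win} samples too short for K={n_channels}, "
                f"p={self.order} (need >= {need})"
            )


@dataclass(frozen=True)
class EquationFit:
    """One target channel's fitted (reduced) regression.

    ``sources`` lists the regressor channels — the target first, then the
    extrinsic set in ascending order; ``coeffs[i, j-1]`` is the estimated
    coefficient of ``x_{sources[i]}[n-j]``. Coefficients of channels
    outside the fitted set are implicitly zero.
    """

    target: int
    extrinsic_set: tuple[int, ...]
    order: int
    sources: tuple[int, ...]
    coeffs: np.ndarray            # (len(sources), p)
    residuals: np.ndarray         # (n_rows,)
    rss: float
    n_rows: int
    channel_means: np.ndarray = field(repr=False, default=None)

    def coefficients_for(self, source: int) -> np.ndarray:
        """Lag-coefficient vector A_hat_{k,source}[1..p] (zeros if unselected)."""
        if source in self.sources:
            return self.coeffs[self.sources.index(source)]
        return np.zeros(self.order)


def _demean(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    window = np.atleast_2d(np.asarray(window, dtype=float))
    means = window.mean(axis=1)
    return window - means[:, None], means


def _design(window: np.ndarray, sources: tuple[int, ...], p: int) -> np.ndarray:
    """Lagged design matrix: rows n = p..N-1, columns grouped by source."""
    N = window.shape[1]
    rows = N - p
    X = np.empty((rows, len(sources) * p))
    for i, l in enumerate(sources):
        for j in range(p):  # lag j+1
            X[:, i * p + j] = window[l, p - 1 - j:N - 1 - j]
    return X


def fit_equation(
    window: np.ndarray,
    target: int,
    extrinsic_set,
    order: int,
) -> EquationFit:
    """OLS fit of one channel on lags 1..p of itself and its extrinsic set.

    The window (channels x samples) is demeaned per channel first. The
    returned residuals and ``rss`` are exact for the returned coefficients.

    Raises
    ------
    FitSingularError
        If the design matrix is rank deficient or its condition number
        exceeds :data:`MAX_CONDITION`.
    """
    window, means = _demean(window)
    K, N = window.shape
    p = int(order)
    if p < 1:
        raise DataError("order must be >= 1")
    if not 0 <= target < K:
        raise DataError(f"target {target} out of range for K={K}")
    L = tuple(sorted(set(int(l) for l in extrinsic_set)))
    if target in L:
        raise DataError("target channel cannot be in its own extrinsic set")
    if any(not 0 <= l < K for l in L):
        raise DataError(f"extrinsic set {L} out of range for K={K}")
    sources = (target,) + L
    n_params = len(sources) * p
    if N - p <= n_params:
        raise DataError(
            f"window too short: {N - p} regression rows for {n_params} parameters"
        )

    X = _design(window, sources, p)
    y = window[target, p:]
    coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_params or (sv[-1] > 0 and sv[0] / sv[-1] > MAX_CONDITION):
        cond = np.inf if sv[-1] == 0 else sv[0] / sv[-1]
        raise FitSingularError(
            f"ill-conditioned regression for target {target} "
            f"(condition number {cond:.3g}); reduce the extrinsic channel set"
        )
    residuals = y - X @ coef
    rss = float(residuals @ residuals)
    return EquationFit(
        target=target,
        extrinsic_set=L,
        order=p,
        sources=sources,
        coeffs=coef.reshape(len(sources), p),
        residuals=residuals,
        rss=rss,
        n_rows=N - p,
        channel_means=means,
    )


def partial_contribution(fit: EquationFit, window: np.ndarray, source: int) -> np.ndarray:
    """Realized partial contribution mu_{k,l}[n] on the regression rows.

    ``mu_{k,l}[n] = sum_j A_hat_{k,l}[j] x_l[n-j]`` evaluated on the same
    (demeaned) rows as the fit, so that the demeaned target equals
    ``sum_{l in sources} mu_{k,l} + residuals`` exactly.
    """
    if source not in fit.sources:
        raise DataError(
            f"channel {source} was not in the fitted set {fit.sources}; "
            "its partial contribution is identically zero by construction"
        )
    window, _ = _demean(window)
    N = window.shape[1]
    p = fit.order
    a = fit.coefficients_for(source)
    mu = np.zeros(N - p)
    for j in range(p):
        mu += a[j] * window[source, p - 1 - j:N - 1 - j]
    return mu


def check_stability(model) -> tuple[bool, float]:
    """Stability of a VAR coefficient stack: companion spectral radius < 1.

    Accepts a :class:`VarModelSpec` or a bare ``(p, K, K)`` coefficient
    array. Returns ``(is_stable, spectral_radius)``.
    """
    if isinstance(model, VarModelSpec):
        spec = model
    else:
        coeffs = np.asarray(model, dtype=float)
        if coeffs.ndim == 2:
            coeffs = coeffs[None]
        spec = VarModelSpec(coeffs=coeffs, noise_cov=np.eye(coeffs.shape[1]))
    rho = spec.spectral_radius()
    return rho < 1.0, rho


def fit_full_var(window: np.ndarray, order: int) -> list[EquationFit]:
    """Fit the full VAR (every channel with all others extrinsic).

    Equivalent, row by row, to joint multivariate OLS.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    K = window.shape[0]
    return [
        fit_equation(window, k, [l for l in range(K) if l != k], order)
        for k in range(K)
    ]
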