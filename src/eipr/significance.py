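"""Surrogate significance thresholds for EIPR.

No finite-sample distribution of EIPR is available, so significance is
assessed against a numerically generated null. Two families of null are
provided:

* ``loom_bootstrap`` (default) — a per-pair *leave-one-channel-out
  residual bootstrap*: to test source ``l`` into target ``k``, the target
  equation is refitted without channel ``l``, the response is regenerated
  as reduced-model fitted values plus resampled residuals (the null of no
  ``l → k`` coupling, with every other dependency and the full regressor
  collinearity preserved), and the full equation is refitted to yield one
  surrogate EIPR value. This is the sharpest null: it holds everything
  fixed except the coupling under test.
* ``circular_shift`` / ``block_permute`` — window surrogates in which
  every channel is independently resampled (a random circular time shift,
  or a permutation of blocks), preserving each channel's marginal
  autocorrelation while destroying all cross-channel alignment — the
  global null of complete inter-channel independence.

From the ``N`` surrogate values of each pair, the threshold is a
one-sided bound at level ``alpha``. The default rule is a Student
prediction bound on the log scale,

    thr = exp( mean(ln eta~^2) + q * sd(ln eta~^2) * sqrt(1 + 1/N) ),

with ``q = -t_{N-1;alpha}``: EIPR is a positive power ratio whose null is
close to lognormal, and the log-scale bound tracks its right tail. The
classical rule ``thr = mean + q * sd / sqrt(N)`` (a confidence bound on
the null mean rather than on a null draw) is available as
``threshold_rule="mean_ci"``, along with a raw-scale prediction bound and
an empirical quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .coupling import CouplingMatrix, eipr_matrix, selected_sets
from .simulate import DataError
from .var_core import WindowConfig

logger = logging.getLogger("eipr")

__all__ = [
    "SignificanceConfig",
    "SurrogateDistribution",
    "make_surrogates",
    "surrogate_eiprs",
    "loom_bootstrap_eiprs",
    "significance_thresholds",
    "significant_coupling",
]

_METHODS = ("loom_bootstrap", "circular_shift", "block_permute")
_RULES = ("log_prediction", "prediction", "mean_ci", "quantile")


@dataclass(frozen=True)
class SignificanceConfig:
    """Surrogate-test parameters.

    ``n_surrogates`` null samples per pair (default 100), one-sided level
    ``alpha`` (default 0.01, i.e. 99% thresholds), null-generation
    ``method`` and ``threshold_rule`` as described in the module
    docstring, and the RNG ``seed``. ``reselect_on_surrogates`` re-runs
    channel selection on every window surrogate instead of reusing the
    original sets; off by default — the null should probe the fitted
    regression structure, and re-selection mostly adds variance.
    """

    n_surrogates: int = 100
    alpha: float = 0.01
    method: str = "loom_bootstrap"
    threshold_rule: str = "log_prediction"
    seed: int = 0
    reselect_on_surrogates: bool = False
    n_blocks: int = 8

    def __post_init__(self):
        if self.n_surrogates < 2:
            raise DataError("n_surrogates must be >= 2")
        if not 0 < self.alpha < 0.5:
            raise DataError("alpha must be in (0, 0.5)")
        if self.method not in _METHODS:
            raise DataError(f"unknown surrogate method {self.method!r}")
        if self.threshold_rule not in _RULES:
            raise DataError(f"unknown threshold rule {self.threshold_rule!r}")

    @property
    def t_quantile(self) -> float:
        """q = -t_{N-1;alpha} > 0 (e.g. 2.3646 for N=100, alpha=0.01)."""
        return float(-stats.t.ppf(self.alpha, self.n_surrogates - 1))


@dataclass(frozen=True)
class SurrogateDistribution:
    """Null sample of EIPR: ``values[i]`` is surrogate i's K x K matrix.

    Entries that were never resampled (diagonal; unselected pairs under
    per-pair nulls) are NaN.
    """

    values: np.ndarray       # (N, K, K)

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1)


def _threshold_from_null(vals: np.ndarray, config: SignificanceConfig) -> float:
    """One-sided threshold at level alpha from N null draws of one pair."""
    q = config.t_quantile
    N = config.n_surrogates
    sd = vals.std(ddof=1)
    if sd <= 1e-12 * max(abs(float(vals.mean())), 1e-300):
        logger.warning(
            "zero surrogate variance; threshold degenerates to the "
            "surrogate mean %.3g", vals.mean()
        )
        return float(vals.mean())
    rule = config.threshold_rule
    if rule == "log_prediction":
        lv = np.log(np.maximum(vals, 1e-300))
        return float(np.exp(lv.mean() + q * lv.std(ddof=1) * np.sqrt(1 + 1 / N)))
    if rule == "prediction":
        return float(vals.mean() + q * sd * np.sqrt(1 + 1 / N))
    if rule == "mean_ci":
        return float(vals.mean() + q * sd / np.sqrt(N))
    return float(np.quantile(vals, 1 - config.alpha))


# ---------------------------------------------------------------------------
# Window surrogates (global-independence null)
# ---------------------------------------------------------------------------

def _surrogate_window(
    window: np.ndarray, rng: np.random.Generator, config: SignificanceConfig
) -> np.ndarray:
    K, N = window.shape
    out = np.empty_like(window)
    if config.method == "block_permute":
        bounds = np.linspace(0, N, config.n_blocks + 1).astype(int)
        for k in range(K):
            order = rng.permutation(config.n_blocks)
            out[k] = np.concatenate(
                [window[k, bounds[b]:bounds[b + 1]] for b in order]
            )
    else:  # circular_shift
        lo, hi = N // 8, 7 * N // 8
        # pairwise-separated shifts: channels that happen to draw nearly
        # equal offsets would keep their mutual alignment intact
        margin = min(N // 16, max(1, N // (4 * K)))
        shifts: list[int] = []
        for _ in range(K):
            for _attempt in range(200):
                s = int(rng.integers(lo, hi + 1))
                if all(
                    margin <= (s - other) % N <= N - margin for other in shifts
                ):
                    break
            shifts.append(s)
        for k in range(K):
            out[k] = np.roll(window[k], shifts[k])
    return out


def make_surrogates(
    window: np.ndarray, config: SignificanceConfig
) -> list[np.ndarray]:
    """Windows with every channel independently resampled.

    The default transform here is a circular time shift with a uniform
    offset in ``[N/8, 7N/8]``: it leaves each channel's circular
    autocorrelation bit-exact while destroying cross-channel alignment.
    Block permutation also breaks marginal structure beyond the block
    length. A single master seed spawns one independent stream per
    surrogate, so the set is reproducible and order-independent.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] < 8:
        raise DataError("window too short for surrogate resampling")
    cfg = config
    if cfg.method == "loom_bootstrap":
        # window resampling needs an explicit transform; shift is the default
        cfg = SignificanceConfig(
            n_surrogates=config.n_surrogates, alpha=config.alpha,
            method="circular_shift", threshold_rule=config.threshold_rule,
            seed=config.seed, n_blocks=config.n_blocks,
        )
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_surrogates)
    return [
        _surrogate_window(window, np.random.default_rng(s), cfg)
        for s in streams
    ]


def surrogate_eiprs(
    window: np.ndarray,
    config_w: WindowConfig | int,
    config_s: SignificanceConfig,
    use_selection: bool = True,
    sets: Optional[tuple[tuple[int, ...], ...]] = None,
) -> SurrogateDistribution:
    """EIPR matrices over the window-surrogate ensemble.

    The regression structure (order and extrinsic sets) of the original
    analysis is held fixed across surrogates unless
    ``config_s.reselect_on_surrogates`` is set.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    order = config_w.order if isinstance(config_w, WindowConfig) else int(config_w)
    K = window.shape[0]
    if sets is None:
        if use_selection:
            sets = selected_sets(window, order)
        else:
            sets = tuple(tuple(l for l in range(K) if l != k) for k in range(K))
    values = np.empty((config_s.n_surrogates, K, K))
    for i, surr in enumerate(make_surrogates(window, config_s)):
        if config_s.reselect_on_surrogates:
            m = eipr_matrix(surr, order, use_selection=use_selection)
        else:
            m = eipr_matrix(surr, order, sets=sets)
        values[i] = m.values
    return SurrogateDistribution(values=values)


# ---------------------------------------------------------------------------
# Leave-one-channel-out residual bootstrap (per-pair null)
# ---------------------------------------------------------------------------

def loom_bootstrap_eiprs(
    window: np.ndarray,
    order: int,
    config: SignificanceConfig,
    sets: Optional[tuple[tuple[int, ...], ...]] = None,
) -> SurrogateDistribution:
    """Per-pair null EIPR samples from the leave-one-channel-out bootstrap.

    For each target ``k`` and each source ``l`` in its extrinsic set: the
    reduced equation (``l`` left out) is fitted; ``N`` bootstrap responses
    ``y* = fitted + resampled centered residuals`` are regressed on the
    *full* fixed design, and the surrogate EIPR is the ratio of the
    refitted ``l`` and intrinsic partial powers. Because the reduced
    fitted values lie in the span of the full design, the refitted ``l``
    coefficients have exactly zero mean under this null while retaining
    the full collinearity-driven covariance. Residuals are rescaled by
    ``sqrt(n/(n - m))`` (``m`` reduced-model parameters) to undo the
    downward bias of OLS residual variance.

    Entries for the diagonal and for pairs outside the fitted sets are
    NaN.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    x = x - x.mean(axis=1, keepdims=True)
    K, Nw = x.shape
    p = int(order)
    n_rows = Nw - p
    N = config.n_surrogates
    if sets is None:
        sets = tuple(tuple(l for l in range(K) if l != k) for k in range(K))
    values = np.full((N, K, K), np.nan)

    for k in range(K):
        srcs = (k,) + tuple(sorted(sets[k]))
        if len(srcs) == 1:
            continue
        nsrc = len(srcs)
        X = np.empty((n_rows, nsrc * p))
        for i, l in enumerate(srcs):
            for j in range(p):
                X[:, i * p + j] = x[l, p - 1 - j:Nw - 1 - j]
        y = x[k, p:]
        P = np.linalg.pinv(X)
        grams = {}
        col_means = {}
        for i, l in enumerate(srcs):
            cols = X[:, i * p:(i + 1) * p]
            grams[l] = cols.T @ cols / n_rows
            col_means[l] = cols.mean(axis=0)
        for l in sets[k]:
            i_l = srcs.index(l)
            keep = np.r_[0:i_l * p, (i_l + 1) * p:nsrc * p]
            Xr = X[:, keep]
            beta_r, *_ = np.linalg.lstsq(Xr, y, rcond=None)
            fitted = Xr @ beta_r
            resid = y - fitted
            resid = (resid - resid.mean()) * np.sqrt(
                n_rows / (n_rows - Xr.shape[1])
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, k, l])
            )
            idx = rng.integers(0, n_rows, size=(N, n_rows))
            y_star = fitted[None, :] + resid[idx]
            B = y_star @ P.T                           # (N, nsrc*p)
            b_l = B[:, i_l * p:(i_l + 1) * p]
            b_k = B[:, 0:p]
            v_l = (
                np.einsum("ij,jk,ik->i", b_l, grams[l], b_l)
                - (b_l @ col_means[l]) ** 2
            )
            v_k = (
                np.einsum("ij,jk,ik->i", b_k, grams[k], b_k)
                - (b_k @ col_means[k]) ** 2
            )
            values[:, k, l] = v_l / v_k
    return SurrogateDistribution(values=values)


# ---------------------------------------------------------------------------
# Thresholds and the full test
# ---------------------------------------------------------------------------

def significance_thresholds(
    window: np.ndarray,
    config_w: WindowConfig | int,
    config_s: SignificanceConfig,
    use_selection: bool = True,
    sets: Optional[tuple[tuple[int, ...], ...]] = None,
    distribution: Optional[SurrogateDistribution] = None,
) -> np.ndarray:
    """K x K matrix of one-sided surrogate thresholds.

    Diagonal entries (and, under per-pair nulls, unselected pairs) are
    NaN; EIPR there is structurally 1 and 0 respectively. A pair with
    zero surrogate spread degenerates to its surrogate mean (logged).
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    order = config_w.order if isinstance(config_w, WindowConfig) else int(config_w)
    K = window.shape[0]
    if sets is None and not use_selection:
        sets = tuple(tuple(l for l in range(K) if l != k) for k in range(K))
    if distribution is None:
        if config_s.method == "loom_bootstrap":
            if sets is None:
                sets = selected_sets(window, order)
            distribution = loom_bootstrap_eiprs(window, order, config_s, sets=sets)
        else:
            distribution = surrogate_eiprs(
                window, order, config_s, use_selection=use_selection, sets=sets
            )
    thr = np.full((K, K), np.nan)
    for k in range(K):
        for l in range(K):
            if k == l:
                continue
            vals = distribution.values[:, k, l]
            if np.isnan(vals).all():
                continue
            thr[k, l] = _threshold_from_null(vals, config_s)
    return thr


def significant_coupling(
    window: np.ndarray,
    config_w: WindowConfig | int,
    config_s: SignificanceConfig,
    use_selection: bool = True,
    method: str = "empirical",
    window_index: int = 0,
    channel_labels: Optional[list[str]] = None,
) -> CouplingMatrix:
    """EIPR matrix with surrogate thresholds and significance mask attached.

    Runs channel selection once on the original window, computes EIPR,
    then tests every fitted off-diagonal entry against its surrogate
    threshold (strict exceedance). Pairs without a defined threshold
    (unselected under a per-pair null) are not significant.
    """
    order = config_w.order if isinstance(config_w, WindowConfig) else int(config_w)
    cm = eipr_matrix(
        window, order, use_selection=use_selection, method=method,
        window_index=window_index, channel_labels=channel_labels,
    )
    thr = significance_thresholds(
        window, order, config_s, sets=cm.extrinsic_sets
    )
    mask = np.zeros_like(cm.values, dtype=bool)
    off = ~np.eye(cm.n_channels, dtype=bool)
    defined = off & np.isfinite(thr)
    mask[defined] = cm.values[defined] > thr[defined]
    cm.thresholds = thr
    cm.significant = mask
    return cm
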