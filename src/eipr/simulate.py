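"""Signal models, simulators and analytic oracles.

This module holds the linear-stochastic ground truth used throughout the
package: vector-autoregressive (VAR) model specifications, a benchmark
4-channel VAR(5) with a known directed-coupling structure, a Gaussian VAR
simulator, the exact stationary autocovariance sequence obtained from the
companion-form discrete Lyapunov equation, the population value of the
extrinsic-to-intrinsic power ratio (EIPR), and an ECoG-like fixture in
which a designated "focus" channel starts driving its neighbours at a
configurable onset time — the situation the analysis pipeline is meant to
detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

logger = logging.getLogger("eipr")

__all__ = [
    "EiprError",
    "UnstableModelError",
    "DataError",
    "VarModelSpec",
    "Recording",
    "AutocovarianceSet",
    "winterhalder_model",
    "simulate_var",
    "stationary_autocovariance",
    "true_partial_powers",
    "true_eipr",
    "synth_ecog",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EiprError(Exception):
    """Base class for all errors raised by this package."""


class UnstableModelError(EiprError):
    """A VAR model whose companion matrix has spectral radius >= 1."""

    def __init__(self, spectral_radius: float, msg: str | None = None):
        self.spectral_radius = float(spectral_radius)
        super().__init__(
            msg or f"VAR model is not stable: companion spectral radius "
                   f"{self.spectral_radius:.6g} >= 1"
        )


class DataError(EiprError):
    """Malformed or degenerate input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarModelSpec:
    """A multivariate autoregressive model x[n] = sum_j A[j] x[n-j] + eps[n].

    Parameters
    ----------
    coeffs
        Array of shape ``(p, K, K)``; ``coeffs[j-1]`` is the lag-``j``
        coefficient matrix ``A[j]``.
    noise_cov
        Innovation covariance ``Sigma_eps``, shape ``(K, K)``, symmetric
        positive definite.

    Notes
    -----
    The spec itself may be unstable (useful for negative tests); stability
    is enforced where it matters (simulation, Lyapunov solve) via
    :func:`check_stability` in :mod:`eipr.var_core`.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        noise_cov = np.asarray(self.noise_cov, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise DataError(f"coeffs must have shape (p, K, K), got {coeffs.shape}")
        if coeffs.shape[0] < 1:
            raise DataError("model order p must be >= 1")
        K = coeffs.shape[1]
        if noise_cov.shape != (K, K):
            raise DataError(
                f"noise_cov shape {noise_cov.shape} does not match K={K}"
            )
        if not np.allclose(noise_cov, noise_cov.T, atol=1e-12):
            raise DataError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(noise_cov).min() <= 0:
            raise DataError("noise_cov must be positive definite")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", noise_cov)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion(self) -> np.ndarray:
        """Companion matrix of shape ``(K*p, K*p)``."""
        K, p = self.n_channels, self.order
        C = np.zeros((K * p, K * p))
        for j in range(p):
            C[:K, j * K:(j + 1) * K] = self.coeffs[j]
        if p > 1:
            C[K:, :K * (p - 1)] = np.eye(K * (p - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class Recording:
    """A multichannel signal: ``data`` is channels x samples."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: Optional[float] = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        K = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{k}" for k in range(K)]
        if len(self.channel_labels) != K:
            raise DataError(
                f"{len(self.channel_labels)} labels for {K} channels"
            )
        if len(set(self.channel_labels)) != K:
            raise DataError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class AutocovarianceSet:
    """Stationary autocovariances Gamma(s) = E{x[n+s] x[n]^T}, s = 0..s_max.

    Only non-negative lags are stored; ``Gamma(-s) = Gamma(s)^T``.
    """

    lags: np.ndarray
    values: np.ndarray  # (s_max+1, K, K)

    def gamma(self, s: int) -> np.ndarray:
        if abs(s) >= self.values.shape[0]:
            raise IndexError(f"lag {s} beyond stored maximum {self.values.shape[0] - 1}")
        return self.values[s] if s >= 0 else self.values[-s].T

    def autocorr(self, channel: int, s: int) -> float:
        """Scalar autocovariance r_{x_l}[s] of one channel (even in s)."""
        return float(self.values[abs(s)][channel, channel])


# ---------------------------------------------------------------------------
# Benchmark model
# ---------------------------------------------------------------------------

def winterhalder_model() -> VarModelSpec:
    """The 4-channel VAR(5) benchmark system of Winterhalder et al.

    The directed-coupling structure is x2 -> x1 (lag 4), x4 -> x2 (lag 5),
    x1 -> x3 (lag 1), x2 -> x3 (lag 4); channel 4 is purely autonomous
    (AR(2) with a resonance). Innovation covariance is the identity.
    """
    K, p = 4, 5
    A = np.zeros((p, K, K))
    A[0, 0, 0] = 0.8    # x1 <- x1, lag 1
    A[3, 0, 1] = 0.65   # x1 <- x2, lag 4
    A[0, 1, 1] = 0.6    # x2 <- x2, lag 1
    A[4, 1, 3] = 0.6    # x2 <- x4, lag 5
    A[2, 2, 2] = 0.5    # x3 <- x3, lag 3
    A[0, 2, 0] = -0.6   # x3 <- x1, lag 1
    A[3, 2, 1] = 0.4    # x3 <- x2, lag 4
    A[0, 3, 3] = 1.2    # x4 <- x4, lag 1
    A[1, 3, 3] = -0.7   # x4 <- x4, lag 2
    return VarModelSpec(coeffs=A, noise_cov=np.eye(K))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_var(
    spec: VarModelSpec,
    n_samples: int,
    seed: int | np.random.SeedSequence = 0,
    burn_in: int = 1000,
    sampling_rate: float = 128.0,
    noise_sampler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
) -> Recording:
    """Simulate a stable VAR model.

    The process is iterated from zero initial conditions; the first
    ``burn_in`` samples are discarded so that the retained segment is
    effectively stationary. Noise is Gaussian with covariance
    ``spec.noise_cov`` unless ``noise_sampler(rng, n, K)`` is supplied
    (it must return an ``(n, K)`` array of white innovations with unit
    marginal structure; the covariance factor is applied on top).

    Raises
    ------
    UnstableModelError
        If the companion spectral radius is >= 1.
    """
    if n_samples < 1:
        raise DataError("n_samples must be >= 1")
    rho = spec.spectral_radius()
    if rho >= 1.0:
        raise UnstableModelError(rho)
    K, p = spec.n_channels, spec.order
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    if noise_sampler is None:
        z = rng.standard_normal((total, K))
    else:
        z = np.asarray(noise_sampler(rng, total, K), dtype=float)
        if z.shape != (total, K):
            raise DataError(f"noise sampler returned shape {z.shape}, "
                            f"expected {(total, K)}")
    chol = np.linalg.cholesky(spec.noise_cov)
    eps = z @ chol.T

    x = np.zeros((total + p, K))
    # one matmul per step: coefficients flattened against the stacked
    # lag vector (x[n-1], ..., x[n-p])
    A_flat = np.concatenate(list(spec.coeffs), axis=1)
    for n in range(p, total + p):
        x[n] = A_flat @ x[n - p:n][::-1].reshape(-1) + eps[n - p]
    data = x[p + burn_in:].T.copy()
    return Recording(data=data, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# Analytic oracles
# ---------------------------------------------------------------------------

def stationary_autocovariance(spec: VarModelSpec, max_lag: int) -> AutocovarianceSet:
    """Exact stationary autocovariances via the companion-form Lyapunov equation.

    Writing the VAR(p) in companion form X[n] = C X[n-1] + E[n], the
    stationary state covariance solves the discrete Lyapunov equation
    P = C P C^T + Q.  Block row one of P yields Gamma(0)..Gamma(p-1);
    higher lags follow from the Yule-Walker recursion
    Gamma(s) = sum_j A[j] Gamma(s-j).
    """
    rho = spec.spectral_radius()
    if rho >= 1.0:
        raise UnstableModelError(
            rho, f"Lyapunov solve requires a stable model "
                 f"(spectral radius {rho:.6g})"
        )
    if max_lag < 0:
        raise DataError("max_lag must be >= 0")
    K, p = spec.n_channels, spec.order
    C = spec.companion()
    Q = np.zeros((K * p, K * p))
    Q[:K, :K] = spec.noise_cov
    P = solve_discrete_lyapunov(C, Q)
    P = 0.5 * (P + P.T)  # symmetrize against round-off

    gammas = [P[:K, s * K:(s + 1) * K].copy() for s in range(min(p, max_lag + 1))]
    gammas[0] = 0.5 * (gammas[0] + gammas[0].T)
    A = spec.coeffs
    for s in range(len(gammas), max_lag + 1):
        g = np.zeros((K, K))
        for j in range(p):
            lag = s - 1 - j
            gj = gammas[lag] if lag >= 0 else gammas[-lag].T
            g += A[j] @ gj
        gammas.append(g)
    return AutocovarianceSet(
        lags=np.arange(max_lag + 1), values=np.array(gammas)
    )


def true_partial_powers(spec: VarModelSpec) -> np.ndarray:
    """Population variance of every partial contribution term.

    Entry ``(k, l)`` is ``V{mu_{k,l}} = sum_{j,j'} A_{k,l}[j] r_{x_l}[j-j']
    A_{k,l}[j']`` where ``r_{x_l}`` is the stationary autocovariance of
    channel ``l`` from the Lyapunov oracle.
    """
    K, p = spec.n_channels, spec.order
    acov = stationary_autocovariance(spec, max_lag=p)
    # r[l, s] for s = 0..p-1 (even in s)
    r = np.array([[acov.autocorr(l, s) for s in range(p)] for l in range(K)])
    # Toeplitz matrix R_l[j, j'] = r_l[|j - j'|]
    idx = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    V = np.zeros((K, K))
    for k in range(K):
        for l in range(K):
            a = spec.coeffs[:, k, l]
            V[k, l] = a @ r[l][idx] @ a
    return V


def true_eipr(spec: VarModelSpec) -> np.ndarray:
    """Population EIPR matrix eta^2_{k,l} = V{mu_{k,l}} / V{mu_{k,k}}.

    Diagonal entries are exactly 1; entries whose coefficient vector
    A_{k,l}[.] is identically zero are exactly 0 (Granger non-causality).

    Raises
    ------
    EiprError
        If some intrinsic power V{mu_{k,k}} is zero (the measure assumes
        it is bounded below by a positive constant).
    """
    V = true_partial_powers(spec)
    intrinsic = np.diag(V).copy()
    if np.any(intrinsic <= 0):
        bad = np.where(intrinsic <= 0)[0]
        raise EiprError(
            f"intrinsic power is zero for channel(s) {bad.tolist()}; "
            "EIPR requires intrinsic variance bounded below by a positive constant"
        )
    eta = V / intrinsic[:, None]
    np.fill_diagonal(eta, 1.0)
    return eta


# ---------------------------------------------------------------------------
# ECoG-like fixture
# ---------------------------------------------------------------------------

def _ar2_coeffs(freq_hz: float, modulus: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients with a spectral resonance at freq_hz."""
    theta = 2.0 * np.pi * freq_hz / fs
    return 2.0 * modulus * np.cos(theta), -modulus ** 2


def synth_ecog(
    n_channels: int,
    focus_channel: int,
    onset_sample: int,
    n_samples: int,
    sampling_rate: float = 128.0,
    seed: int | np.random.SeedSequence = 0,
    neighbors: Sequence[int] | None = None,
    gain: float = 0.5,
    coupling_lag: int = 2,
    background_freq_hz: float = 10.0,
    background_modulus: float = 0.85,
    focus_freq_hz: float = 6.0,
    focus_modulus: float = 0.95,
) -> Recording:
    """Generate an ECoG-like recording with a seizure-onset-style coupling change.

    Before ``onset_sample`` every channel is an independent stable AR(2)
    with a background resonance (``background_freq_hz``). From the onset
    on, the focus channel switches to a sharper, slower oscillation
    (``focus_freq_hz``, modulus ``focus_modulus``) — mimicking rhythmic
    ictal activity — and drives each neighbour through a lagged linear
    term ``gain * x_focus[n - coupling_lag]``. The construction is
    block-triangular (focus feeds neighbours, never the reverse), so
    stability reduces to stability of the individual AR(2) blocks; it is
    verified explicitly and violations are rejected.

    Identical ``seed`` gives bit-identical output.
    """
    if not 0 <= focus_channel < n_channels:
        raise DataError(f"focus_channel {focus_channel} out of range")
    if not 0 <= onset_sample < n_samples:
        raise DataError("onset_sample must lie inside the recording")
    if neighbors is None:
        neighbors = [k for k in range(n_channels) if k != focus_channel]
    neighbors = sorted(set(int(k) for k in neighbors) - {focus_channel})
    if coupling_lag < 1:
        raise DataError("coupling_lag must be >= 1")

    a1_bg, a2_bg = _ar2_coeffs(background_freq_hz, background_modulus, sampling_rate)
    a1_fc, a2_fc = _ar2_coeffs(focus_freq_hz, focus_modulus, sampling_rate)
    for mod, name in ((background_modulus, "background"), (focus_modulus, "focus")):
        if not 0 < mod < 1:
            raise UnstableModelError(
                mod, f"{name} AR(2) pole modulus {mod} must be in (0, 1)"
            )

    p = max(2, coupling_lag)
    K = n_channels
    # Post-onset coefficient stack, used for the stability diagnostic.
    A_post = np.zeros((p, K, K))
    for k in range(K):
        if k == focus_channel:
            A_post[0, k, k], A_post[1, k, k] = a1_fc, a2_fc
        else:
            A_post[0, k, k], A_post[1, k, k] = a1_bg, a2_bg
    for k in neighbors:
        A_post[coupling_lag - 1, k, focus_channel] += gain
    post_spec = VarModelSpec(coeffs=A_post, noise_cov=np.eye(K))
    if not post_spec.is_stable():
        raise UnstableModelError(
            post_spec.spectral_radius(),
            "post-onset coupling parameters yield an unstable system "
            f"(spectral radius {post_spec.spectral_radius():.4g})",
        )

    rng = np.random.default_rng(seed)
    burn = 1000
    total = n_samples + burn
    eps = rng.standard_normal((total, K))
    x = np.zeros((total + p, K))
    onset = onset_sample + burn
    for n in range(p, total + p):
        t = n - p  # sample index in the padded series
        post = t >= onset
        for k in range(K):
            if k == focus_channel and post:
                a1, a2 = a1_fc, a2_fc
            else:
                a1, a2 = a1_bg, a2_bg
            v = a1 * x[n - 1, k] + a2 * x[n - 2, k] + eps[t, k]
            if post and k in neighbors:
                v += gain * x[n - coupling_lag, focus_channel]
            x[n, k] = v
    data = x[p + burn:].T.copy()
    labels = [f"E{k}" for k in range(K)]
    return Recording(data=data, sampling_rate=sampling_rate, channel_labels=labels)
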