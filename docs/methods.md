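# Methods

## Model and estimation

The analysis substrate is a K-channel recording treated, within each
analysis window, as a zero-mean stationary VAR(p) process
x[n] = Σ_j A[j] x[n−j] + ε[n] with white innovations of regular
covariance Σ_ε. Estimation is single-equation ordinary least squares:
each target channel is regressed on lags 1..p of itself and of the
channels in its extrinsic set, using regression rows n = p+1..N_win
(conditional "covariance-method" least squares — the first p samples
condition the regression; no pre-sample values are invented). Windows
are demeaned per channel before fitting, since real recordings are not
zero-mean. The normal equations are solved by an SVD-based least-squares
factorization rather than explicit inversion; a design condition number
above 1e12 raises an error advising a smaller channel set. Fitting the
full model (selection disabled) is implemented as K independent
single-equation fits with all other channels extrinsic, which is
row-wise identical to joint multivariate OLS — the test suite verifies
agreement with statsmodels' VAR estimator to machine precision.

## Channel selection

The extrinsic set of each target grows greedily from empty: every step
scores each remaining candidate by
BIC = ln(S_err/n_rows) + M·ln(N_win)/N_win with M = (|L_k|+1)·p, adds
the argmin if it strictly lowers the current value, and stops otherwise.
Two conventions were genuinely open and are fixed here as follows.
First, the residual sum of squares is normalized by the number of
regression rows inside the logarithm. The argmin is unchanged (the
shift is constant across candidate sets of equal size... and across
sizes the penalty term carries the size dependence), and only this
convention puts the criterion on the scale of the log innovation
variance — an intrinsic-only fit of a unit-variance channel scores
≈ 0.01, not ≈ 9.5. Second, the stopping rule applies to the full
penalized criterion, the only reading consistent with stopping "when it
cannot be decreased any more". Exact ties break toward the lowest
channel index for determinism.

## EIPR and PDC

The partial contribution μ_{k,l}[n] = Σ_j Â_{k,l}[j] x_l[n−j] is
materialized on the regression rows, so the identity
x_k = Σ_l μ_{k,l} + residual holds exactly. Its variance is estimated by
default as the population-form (1/n) variance of the realized series;
a plug-in alternative — the quadratic form of the fitted lag
coefficients with the sample autocovariance of the source — is exposed
as a flag and agrees within O(p/N). EIPR is the ratio of a source's
partial power to the target's intrinsic power; the diagonal is exactly 1
and unselected pairs are exactly 0. The intrinsic power is assumed
bounded away from zero; a floor of 1e−12 times the channel variance
raises an error rather than returning an unstable ratio.

Squared PDC is computed from Ã(f) = I − Σ_j A[j]e^{−2πifj} on a uniform
normalized-frequency grid in [0, 0.5] (512 points by default), with the
column normalization that makes Σ_k π²_{k,l}(f) = 1 identically. The
spectral cross-check verifies three identities on a stable model: the
quadrature of |A_{k,l}(f)|² S_{x_l}(f) against the time-domain partial
power, the ratio form of EIPR built from those integrals, and PDC
rebuilt from partial-contribution spectral densities. Off-diagonal
entries of Ã and A differ only in sign, so both spellings give the same
modulus; the intrinsic (diagonal) terms use A_{k,k}. The time-domain
reference is exact: stationary autocovariances come from the
companion-form discrete Lyapunov equation (machine precision, no
quadrature), with higher lags by the Yule–Walker recursion. With a
4096-point trapezoidal grid the spectral forms agree with the Lyapunov
oracle to better than 1e−3 relative; the two PDC routes are
algebraically identical and agree to 1e−10.

## Significance

Observed EIPR values are never exactly zero, so each directed pair is
tested against a numerically generated null. The default null is a
per-pair **leave-one-channel-out residual bootstrap**: for pair (k, l),
the target equation is refitted with channel l's lag block removed; N
(default 100) bootstrap responses are formed as reduced-model fitted
values plus resampled centered residuals (rescaled by √(n/(n−m)) to
undo the downward bias of OLS residual variance); each response is
regressed on the *full fixed design*, and the surrogate EIPR is the
ratio of the refitted source and intrinsic partial powers. Because the
reduced fitted values lie in the span of the full design, the refitted
source coefficients have exactly zero mean under this null while
retaining the collinearity-driven covariance of the real design — the
dominant inflation of spurious coupling estimates when channels are
mutually correlated, which window-shuffling surrogates cannot
reproduce. The threshold is a one-sided Student prediction bound at
α = 0.01 on the *log* of the null values,
thr = exp(mean(ln η̃²) + q·sd(ln η̃²)·√(1+1/N)) with q = −t_{N−1;α}
≈ 2.3646: EIPR is a positive ratio whose null is close to lognormal,
and the log-scale bound tracks its right tail where a raw-scale
Gaussian bound is anticonservative. An entry is significant if it
strictly exceeds its threshold. No multiple-testing correction is
applied across the K² pairs — deliberately, matching common practice
for these tables; users scanning many channels should account for this.

Alternative nulls are provided: window surrogates in which every
channel is independently circularly shifted (offsets uniform in
[N/8, 7N/8], with a pairwise-separation guard so two channels cannot
draw nearly equal offsets and keep their mutual alignment) or
block-permuted; and alternative threshold rules, including the
classical mean + q·sd/√N (a confidence bound on the null mean,
`threshold_rule="mean_ci"`) and an empirical quantile. The mean-CI rule
is retained for reference but is not the default: a bound on the null
*mean* sits near the null's 60th–70th percentile, so against any null
that matches the observed sampling distribution it flags 20–40% of
truly non-coupled pairs. The default combination was chosen by measured
operating characteristics: on the benchmark system all eight non-causal
pairs stay below threshold in 19/20 seeds with all four true couplings
detected in 20/20, and on fully independent white-noise channels the
per-pair false-positive rate is ≈1.5% at nominal α = 0.01 (1050 pair
tests).

## Pipeline

Preprocessing for clinical-style recordings: a 2nd-order IIR notch at
50 Hz (quality factor 35) and an 8th-order Butterworth low-pass at
64 Hz, both applied forward-backward for zero phase, then integer-factor
decimation to 128 Hz. The low-pass must not exceed the target Nyquist
rate (64 Hz at 128 Hz is the boundary case and is allowed — the filter
runs at the input rate before decimation). Analysis windows default to
4 s with model order p = 7 — long enough to estimate the correlation
structure, short enough that ictal signals are approximately stationary
within a window; p = 7 accommodates about three spectral peaks plus a
slow component. Windows do not overlap by default (`step_seconds`
exposes overlap). Per window, the pipeline runs channel selection, EIPR,
and the surrogate test, then emits a directed graph: an arrow l → k
appears when η²_{k,l} exceeds its threshold ("significant" rule), or —
mirroring displays restricted to the strongest couplings — only the top
fraction (default 0.1) of significant edges by EIPR value
("top_fraction" rule; at least one edge is kept when any is
significant, ties break by channel index). Windows with singular fits
(flat or duplicated electrodes) are skipped with a logged diagnostic
rather than aborting the run. Per-window surrogate seeds derive from the
master seed and the window index, so runs are reproducible and windows
independent.

## Synthetic data

Two generators define the study conditions. `winterhalder_model()` is
the 4-channel VAR(5) benchmark (couplings x2→x1 at lag 4, x4→x2 at
lag 5, x1→x3 at lag 1, x2→x3 at lag 4; x4 autonomous AR(2); identity
noise covariance), simulated by default for 12800 samples ≙ 100 s at
128 Hz in a single window. `synth_ecog()` emulates the seizure-onset
situation: independent stable AR(2) channels with a 10 Hz background
resonance (pole modulus 0.85); from the onset sample the focus channel
switches to a sharper 6 Hz oscillation (modulus 0.95) — rhythmic ictal
activity — and drives each neighbour with gain 0.5 at lag 2. The
coupling is feed-forward, so the post-onset system is block-triangular
and stability reduces to the AR(2) blocks; it is nevertheless verified
and violations rejected. Innovations are Gaussian throughout (the
lightest-tailed reading of "white noise", and the one under which the
OLS machinery and Student-based thresholds are exact); a pluggable
noise sampler allows heavier tails. Simulations start from zeros and
discard a 1000-sample burn-in — companion spectral radii here are
≤ 0.95, so transients decay well below noise within that span.

What the generators do *not* emulate: nonstationary background rhythms,
1/f spectra, volume conduction and common reference effects, artifacts,
spike-wave complexes, or nonlinear coupling. Passing tests therefore
show that the estimation chain is correct and well calibrated for
linear-stochastic signals of clinical dimensions, not that the method's
clinical conclusions transfer to any particular recording.

## Problem sizes and numerical choices

Tests and the acceptance script run the benchmark at its native size
(4 × 12800, 20–100 seeds), the null calibration at 6 × 512 × 35
replicates (1050 pair tests), and the fixture pipeline at 4 × 2048
(four 4 s windows, 20 seeds); the long-run autocovariance convergence
check uses a single 10⁶-sample simulation. Variance estimators use the
1/n population convention throughout. Frequency-domain checks use
trapezoidal quadrature (512-point grids in routine use, 4096 for the
oracle-equivalence test). Random numbers come from numpy Generators
seeded via `SeedSequence`; every stochastic stage spawns independent
child streams from one master seed, making results independent of
evaluation order.

## Known limitations

Constant lag order across channels and windows (a data-driven order
with adaptive window length is a natural extension); greedy forward
selection explores a single path through the subset lattice and offers
no optimality guarantee beyond the demonstrated recovery behavior;
EIPR is not bounded above by 1, so values are not directly comparable
across systems with different intrinsic dynamics; the significance
machinery assumes within-window stationarity and light-tailed
innovations; and EDF input support depends on the optional `mne`
dependency.
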