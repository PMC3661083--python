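# eipr — directed coupling in multichannel biosignals

`eipr` identifies directed synchronization effects in multichannel
time-series recordings — the motivating application is intracranial EEG
(ECoG) from epilepsy patients, where the goal is to localize the seizure
onset zone from the pattern of couplings between electrodes shortly after
seizure onset. It is a library plus a small command-line tool for
neurophysiologists and time-series analysts who want a scalar,
physically interpretable alternative to frequency-domain coupling
measures.

## The measure

Each channel of a zero-mean multivariate signal **x**[n] is modelled
autoregressively,

    x_k[n] = μ_{k,k}[n] + Σ_{l ∈ L_k} μ_{k,l}[n] + ε_k[n],
    μ_{k,l}[n] = Σ_{j=1..p} A_{k,l}[j] x_l[n−j],

where `μ_{k,k}` is the *intrinsic contribution* (the channel's own past),
each `μ_{k,l}` is a *partial extrinsic contribution* (the lag-filtered
influence of source channel l), and `L_k` is the *extrinsic channel set*
selected per target by greedy bottom-up minimization of the Bayesian
information criterion

    BIC(L_k) = ln(S_err / n_rows) + M ln(N_win) / N_win,   M = (|L_k|+1)·p.

The **extrinsic-to-intrinsic power ratio (EIPR)**

    η²_{k,l} = V{μ_{k,l}} / V{μ_{k,k}}

condenses the directed coupling l → k into one non-negative scalar: the
power a source injects into a target, in units of the target's intrinsic
power (an SNR-like ratio). Unlike partial directed coherence (PDC),
whose column normalization makes every entry depend on all channels
driven by the same source, the EIPR of a pair depends on that pair
alone; both measures vanish exactly under Granger non-causality. PDC is
included as the frequency-domain comparator, together with spectral-
domain identities that cross-check both measures against an exact
companion-form Lyapunov oracle.

Significance is assessed per directed pair with a leave-one-channel-out
residual bootstrap: the target equation is refitted without the source
under test, responses are regenerated from that null fit, and the
observed EIPR is compared against a one-sided 99% bound of the resulting
null distribution (see `docs/methods.md` for the construction and its
calibration).

## Worked example

The package ships a 4-channel VAR(5) benchmark system with known
couplings x2→x1, x4→x2, x1→x3, x2→x3 and an autonomous channel x4:

```python
import eipr

spec = eipr.winterhalder_model()
rec = eipr.simulate_var(spec, 12800, seed=1)          # 100 s at 128 Hz
cm = eipr.significant_coupling(
    rec.data, 5, eipr.SignificanceConfig(seed=1),
    use_selection=False, channel_labels=["x1", "x2", "x3", "x4"],
)
print(eipr.io.coupling_table(cm, with_thresholds=True).to_string())
```

prints (row = target, column = source, threshold in brackets):

```
                   x1                 x2                 x3                 x4
x1            1.00000  0.19223 (0.00046)  0.00006 (0.00073)  0.00005 (0.00017)
x2  0.00070 (0.00427)            1.00000  0.00053 (0.00525)  0.73889 (0.00134)
x3  2.01019 (0.00146)  0.26383 (0.00144)            1.00000  0.00009 (0.00064)
x4  0.00063 (0.00340)  0.00025 (0.00125)  0.00019 (0.00251)            1.00000
```

The four imposed couplings stand out by two to four orders of magnitude
and exceed their thresholds; the eight non-causal pairs sit below
theirs. The strongest entry, η²₃,₁ ≈ 2.0, says channel 1 injects about
twice the power into channel 3 that channel 3 generates intrinsically.
Channel selection (`eipr.select_channels`) recovers the extrinsic sets
L₁={x2}, L₂={x4}, L₃={x1, x2} (x1 chosen first, then x2) and L₄={}.

The same pipeline runs from the shell:

```
eipr simulate winterhalder --n-samples 12800 --seed 1 --out bench.txt
eipr eipr bench.txt --order 5 --no-selection --surrogates 100 --out table.tsv
eipr analyze recording.txt --config analysis.yaml --seed 1 --out-dir results/
```

`analyze` preprocesses (50 Hz notch, 64 Hz low-pass, downsample to
128 Hz), slides 4-second windows, runs selection + EIPR + significance
per window, and writes coupling tables, GraphML/DOT graphs of the
significant edges, and a run manifest.

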