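"""Greedy bottom-up extrinsic-channel selection by BIC.

For each target channel the extrinsic set starts empty and grows one
channel per step: every remaining candidate is scored by the Bayesian
information criterion of the extended regression, the argmin is added if
it strictly lowers the current BIC, and the procedure stops otherwise.
Coefficients of unselected channels are zero by construction.

The criterion is ``BIC(L_k) = ln(S_err / n_rows) + M ln(N_win) / N_win``
with ``M = (|L_k| + 1) * p`` the parameter count. The residual sum of
squares is normalized by the number of regression rows inside the
logarithm (a mean-squared-residual convention); the normalization shifts
every candidate's value by the same constant, so the selected sets are
unchanged, and it keeps the criterion's magnitude on the scale of the
log innovation variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .var_core import fit_equation

__all__ = ["BicValue", "SelectionStep", "SelectionTrace", "bic", "select_channels"]


@dataclass(frozen=True)
class BicValue:
    """BIC of one candidate regression."""

    value: float
    n_params: int   # M = (|L_k| + 1) * p
    rss: float      # raw residual sum of squares S_err
    n: int          # window length N_win used in the penalty


@dataclass(frozen=True)
class SelectionStep:
    """One step of the greedy search.

    ``candidates`` maps each evaluated channel to the BIC of the regression
    extended by that channel; ``chosen`` is the accepted channel or ``None``
    on the stopping step; ``bic_after`` is the running BIC after the step.
    """

    candidates: dict[int, float]
    chosen: int | None
    bic_after: float


@dataclass(frozen=True)
class SelectionTrace:
    """Full record of the bottom-up selection for one target channel.

    ``final_set`` preserves selection order (first-chosen first).
    """

    target: int
    steps: tuple[SelectionStep, ...]
    final_set: tuple[int, ...]
    initial_bic: float

    @property
    def final_bic(self) -> float:
        return self.steps[-1].bic_after if self.steps else self.initial_bic


def bic(window: np.ndarray, target: int, extrinsic_set, order: int) -> BicValue:
    """BIC of the regression of ``target`` on itself plus ``extrinsic_set``."""
    fit = fit_equation(window, target, extrinsic_set, order)
    n_win = np.atleast_2d(window).shape[1]
    M = (len(fit.extrinsic_set) + 1) * fit.order
    value = float(np.log(fit.rss / fit.n_rows) + M * np.log(n_win) / n_win)
    return BicValue(value=value, n_params=M, rss=fit.rss, n=n_win)


def select_channels(
    window: np.ndarray,
    target: int,
    order: int,
    max_set_size: int | None = None,
) -> SelectionTrace:
    """Grow the extrinsic channel set for ``target`` greedily by BIC.

    Each step evaluates every remaining channel, picks the argmin (exact
    ties broken toward the lowest channel index), and accepts it only if
    it strictly decreases the running BIC. The accepted-step BIC sequence
    is therefore strictly decreasing. Worst case returns the empty set.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    K = window.shape[0]
    if max_set_size is None:
        max_set_size = K - 1
    current = bic(window, target, (), order).value
    initial = current
    selected: list[int] = []
    steps: list[SelectionStep] = []
    remaining = [l for l in range(K) if l != target]

    while remaining and len(selected) < max_set_size:
        scores: dict[int, float] = {}
        for l in remaining:
            scores[l] = bic(window, target, selected + [l], order).value
        best = min(scores, key=lambda l: (scores[l], l))
        if scores[best] < current:
            selected.append(best)
            remaining.remove(best)
            current = scores[best]
            steps.append(SelectionStep(candidates=scores, chosen=best,
                                       bic_after=current))
        else:
            steps.append(SelectionStep(candidates=scores, chosen=None,
                                       bic_after=current))
            break

    return SelectionTrace(
        target=target,
        steps=tuple(steps),
        final_set=tuple(selected),
        initial_bic=initial,
    )
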