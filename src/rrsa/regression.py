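"""Per-time-sample OLS decomposition of similarity series (rRSA).

At every time sample the pairwise similarity values are modelled as

    r  ~=  b0 + b_WS * word_specific + b_Sem * semantic + b_Form * form + e

fitted independently per participant.  From the betas four predicted
condition signals are read off by plugging in predictor configurations:

    Unrelated     = b0
    Semantic      = b0 + b_Sem
    Form          = b0 + b_Form
    WordSpecific  = b0 + b_WS + b_Sem + b_Form

(identical words carry the maximal value 1 on all three predictors, hence
the Word-Specific configuration sets all three to 1).  By construction
``WordSpecific - Unrelated = b_WS + b_Sem + b_Form`` at every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .predictors import PredictorTable
from .rsa import PairSimilaritySeries

__all__ = [
    "CONDITIONS",
    "BetaSeries",
    "ConditionSignals",
    "fit_rrsa",
    "predicted_condition_signals",
    "grand_average",
    "condition_design",
]

CONDITIONS = ("word_specific", "semantic", "form", "unrelated")

#: predictor configuration (word_specific, semantic, form) per condition
_CONFIG = {
    "word_specific": (1.0, 1.0, 1.0),
    "semantic": (0.0, 1.0, 0.0),
    "form": (0.0, 0.0, 1.0),
    "unrelated": (0.0, 0.0, 0.0),
}

MIN_PAIRS_PER_SAMPLE = 5


@dataclass
class BetaSeries:
    """OLS coefficients per time sample for one participant.

    ``beta`` rows are (intercept, word_specific, semantic, form); samples
    where the fit was impossible (rank-deficient design or fewer than
    ``MIN_PAIRS_PER_SAMPLE`` surviving pairs) are NaN.
    """

    participant_id: str
    beta: np.ndarray  # (4, n_samples)
    resid_var: np.ndarray  # (n_samples,)
    times: np.ndarray
    n_pairs: np.ndarray  # pairs actually used per sample

    @property
    def intercept(self) -> np.ndarray:
        return self.beta[0]


@dataclass
class ConditionSignals:
    """Predicted rRSA value per condition and time sample."""

    participant_id: str
    data: np.ndarray  # (4, n_samples), row order = CONDITIONS
    times: np.ndarray

    def __getitem__(self, condition: str) -> np.ndarray:
        return self.data[CONDITIONS.index(condition)]


def condition_design() -> np.ndarray:
    """(4, 4) matrix mapping betas to the four predicted conditions."""
    return np.array([[1.0, *cfg] for cfg in (_CONFIG[c] for c in CONDITIONS)])


def _solve_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of every column of Y on X; returns (betas, residual variance)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = X.shape[0] - X.shape[1]
    var = (resid**2).sum(axis=0) / dof if dof > 0 else np.full(Y.shape[1], np.nan)
    return coef, var


def fit_rrsa(
    series: PairSimilaritySeries, table: PredictorTable, fisher_z: bool = False
) -> BetaSeries:
    """Fit the rRSA model at every time sample of one participant.

    Pairs carrying a missing correlation at a sample are dropped for that
    sample only; a sample whose surviving design is rank-deficient or has
    fewer than ``MIN_PAIRS_PER_SAMPLE`` pairs is flagged missing (NaN).
    With ``fisher_z=True`` the correlations are arctanh-transformed before
    the regression (default off: raw similarity is regressed, and the
    condition signals stay on the correlation scale).
    """
    values = series.values
    if fisher_z:
        with np.errstate(invalid="ignore"):
            values = np.arctanh(np.clip(values, -1 + 1e-12, 1 - 1e-12))
    X_full = table.design_matrix(series.pairs)
    n_samples = values.shape[1]
    beta = np.full((4, n_samples), np.nan)
    resid_var = np.full(n_samples, np.nan)
    n_pairs_used = np.zeros(n_samples, dtype=int)

    valid = np.isfinite(values)  # (n_pairs, n_samples)
    all_valid = valid.all(axis=0)

    # fast path: samples with the complete pair set share one design
    if all_valid.any():
        if np.linalg.matrix_rank(X_full) == X_full.shape[1] and X_full.shape[0] >= MIN_PAIRS_PER_SAMPLE:
            coef, var = _solve_ols(X_full, values[:, all_valid])
            beta[:, all_valid] = coef
            resid_var[all_valid] = var
            n_pairs_used[all_valid] = X_full.shape[0]

    # per-sample path for incomplete samples, grouped by identical masks
    rest = np.nonzero(~all_valid)[0]
    if rest.size:
        masks: dict[bytes, list[int]] = {}
        for s in rest:
            masks.setdefault(valid[:, s].tobytes(), []).append(s)
        for key, samples in masks.items():
            mask = np.frombuffer(key, dtype=bool)
            if mask.sum() < MIN_PAIRS_PER_SAMPLE:
                continue
            X = X_full[mask]
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            cols = np.asarray(samples)
            coef, var = _solve_ols(X, values[mask][:, cols])
            beta[:, cols] = coef
            resid_var[cols] = var
            n_pairs_used[cols] = int(mask.sum())

    return BetaSeries(series.participant_id, beta, resid_var, series.times.copy(), n_pairs_used)


def predicted_condition_signals(betas: BetaSeries) -> ConditionSignals:
    """Read the four predicted condition signals off the fitted betas."""
    data = condition_design() @ betas.beta
    return ConditionSignals(betas.participant_id, data, betas.times.copy())


def grand_average(signals: list[ConditionSignals]) -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise across-participant mean of condition signals.

    Returns ``(mean (4, n_samples), times, n_participants)``; samples
    missing for a participant are excluded from that sample's mean.
    """
    if not signals:
        raise ValueError("no condition signals to average")
    times = signals[0].times
    for s in signals[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("condition signals have mismatched time axes")
    stack = np.stack([s.data for s in signals])  # (n, 4, samples)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return mean, times.copy(), len(signals)
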