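"""Cross-temporal similarity (temporal generalization) and its decomposition.

Correlating sentence i's spatial pattern at time t_k with sentence j's
pattern at every time sample t_l diagnoses whether a neural code is
sustained (a square of generalization) or transient (similarity confined
to the diagonal).  Because the matrices grow with the square of the
sample count, epochs are first downsampled (1,000 -> 300 Hz turns an
800-sample epoch into 240 samples, i.e. 240 x 240 matrices) and pair
matrices are streamed in batches so the full stack never has to be
resident at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import resample_poly

from .predictors import PredictorTable
from .regression import CONDITIONS, condition_design
from .rsa import EpochsTensor, _zscore_patterns

__all__ = [
    "CTSMatrix",
    "ConditionCTS",
    "downsample_epochs",
    "cts_matrix",
    "iter_cts_batches",
    "fit_rcts",
]


@dataclass
class CTSMatrix:
    """Cross-temporal Pearson correlations for one sentence pair.

    Cell (k, l) correlates the spatial pattern of sentence i at time k
    with sentence j at time l.  Only the unordered pair is stored; its
    orientation is fixed by sentence-id order, and cell (k, l) of pair
    (i, j) equals cell (l, k) of pair (j, i).
    """

    pair: tuple[str, str]
    matrix: np.ndarray  # (n_samples, n_samples)
    times: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("CTS matrix must be square")
        finite = self.matrix[np.isfinite(self.matrix)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class ConditionCTS:
    """Predicted cross-temporal matrices per condition (cell-wise algebra
    identical to the time-resolved condition signals)."""

    participant_id: str
    data: np.ndarray  # (4, n_samples, n_samples), row order = CONDITIONS
    beta: np.ndarray  # (4, n_samples, n_samples): b0, b_WS, b_Sem, b_Form
    times: np.ndarray

    def __getitem__(self, condition: str) -> np.ndarray:
        return self.data[CONDITIONS.index(condition)]


def downsample_epochs(
    epochs: EpochsTensor, target_rate: float, method: str = "poly"
) -> EpochsTensor:
    """Resample an epoch tensor to *target_rate* Hz.

    ``method="poly"`` applies anti-alias filtered polyphase resampling
    (sample count = floor(duration * target_rate)); ``method="decimate"``
    keeps every k-th sample without filtering and requires an integer
    factor — exactness tests use it because kept samples are untouched.
    """
    if target_rate > epochs.sfreq:
        raise ValueError("target rate must not exceed the source rate")
    if target_rate == epochs.sfreq:
        return replace(epochs, data=epochs.data.copy(), times=epochs.times.copy())
    if method == "decimate":
        ratio = epochs.sfreq / target_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("decimate mode needs an integer downsampling factor")
        step = int(round(ratio))
        data = epochs.data[:, :, ::step].copy()
        times = epochs.times[::step].copy()
    elif method == "poly":
        frac = Fraction(target_rate / epochs.sfreq).limit_denominator(10_000)
        up, down = frac.numerator, frac.denominator
        data = resample_poly(epochs.data, up, down, axis=-1)
        n = data.shape[-1]
        step_ms = 1_000.0 / target_rate
        times = epochs.times[0] + step_ms * np.arange(n)
    else:
        raise ValueError(f"unknown downsampling method {method!r}")
    return replace(epochs, data=data, times=times, sfreq=float(target_rate))


def cts_matrix(
    trial_i: np.ndarray,
    trial_j: np.ndarray,
    pair: tuple[str, str] = ("i", "j"),
    times: np.ndarray | None = None,
    sfreq: float = float("nan"),
) -> CTSMatrix:
    """Cross-temporal correlation matrix for one pair of trials.

    ``trial_i`` and ``trial_j`` are channels x samples arrays over the
    same channel set; cell (k, l) is the Pearson correlation of the two
    channel vectors at times k (trial i) and l (trial j).
    """
    trial_i = np.asarray(trial_i, dtype=float)
    trial_j = np.asarray(trial_j, dtype=float)
    if trial_i.shape != trial_j.shape or trial_i.ndim != 2:
        raise ValueError("trials must share channel set and sample count")
    n_ch = trial_i.shape[0]
    z = _zscore_patterns(np.stack([trial_i, trial_j]))
    zi, zj = np.nan_to_num(z[0], nan=0.0), np.nan_to_num(z[1], nan=0.0)
    m = (zi.T @ zj) / n_ch
    bad_i = np.isnan(z[0]).any(axis=0)
    bad_j = np.isnan(z[1]).any(axis=0)
    m[bad_i, :] = np.nan
    m[:, bad_j] = np.nan
    if times is None:
        times = np.arange(trial_i.shape[1], dtype=float)
    return CTSMatrix(pair, np.clip(m, -1.0, 1.0), np.asarray(times, float), sfreq)


def iter_cts_batches(
    epochs: EpochsTensor,
    pairs: Sequence[tuple[str, str]] | None = None,
    batch_size: int = 128,
) -> Iterator[tuple[list[tuple[str, str]], np.ndarray]]:
    """Yield (pair keys, (batch, S, S) matrices) in streamed batches.

    Pairs default to all unordered trial pairs in lexicographic order,
    oriented by sentence-id sort so orientation is deterministic.
    """
    ids = sorted(epochs.trials)
    if pairs is None:
        iu, ju = np.triu_indices(len(ids), k=1)
        pairs = [(ids[i], ids[j]) for i, j in zip(iu, ju)]
    index = {sid: k for k, sid in enumerate(epochs.trials)}
    z = _zscore_patterns(epochs.data)
    bad = np.isnan(z).any(axis=1)  # (trials, samples)
    zf = np.nan_to_num(z, nan=0.0)
    n_ch = epochs.n_channels
    for start in range(0, len(pairs), batch_size):
        chunk = list(pairs[start : start + batch_size])
        ii = np.array([index[a] for a, _ in chunk])
        jj = np.array([index[b] for _, b in chunk])
        mats = np.einsum("pcs,pct->pst", zf[ii], zf[jj], optimize=True) / n_ch
        mats[bad[ii][:, :, None] & np.ones_like(mats, bool)] = np.nan
        mats[np.ones_like(mats, bool) & bad[jj][:, None, :]] = np.nan
        yield chunk, np.clip(mats, -1.0, 1.0)


def fit_rcts(
    epochs_or_batches: EpochsTensor | Iterator[tuple[list, np.ndarray]],
    table: PredictorTable,
    participant_id: str | None = None,
    batch_size: int = 128,
) -> ConditionCTS:
    """Per-cell OLS of the cross-temporal matrices on the three regressors.

    Accepts either a (downsampled) epoch tensor — batches are generated
    internally — or an explicit batch iterator as produced by
    :func:`iter_cts_batches`.  Normal equations are accumulated batch by
    batch, so memory stays at one batch of matrices; cells with missing
    correlations are re-solved individually over their valid pairs, and
    rank-deficient cells are flagged NaN.
    """
    if isinstance(epochs_or_batches, EpochsTensor):
        epochs = epochs_or_batches
        participant_id = participant_id or epochs.participant_id
        times = epochs.times.copy()
        batches = iter_cts_batches(epochs, batch_size=batch_size)
    else:
        if participant_id is None:
            participant_id = "unknown"
        times = None
        batches = epochs_or_batches

    xtx = np.zeros((4, 4))
    xty: np.ndarray | None = None
    shape: tuple[int, int] | None = None
    # design rows of pairs missing at specific cells, for per-cell downdating
    nan_records: list[tuple[np.ndarray, np.ndarray]] = []  # (x_row (4,), cell indices)
    n_pairs = 0

    for pair_keys, mats in batches:
        X = table.design_matrix(pair_keys)
        if shape is None:
            shape = mats.shape[1:]
            xty = np.zeros((4, shape[0] * shape[1]))
        flat = mats.reshape(len(pair_keys), -1)
        bad = ~np.isfinite(flat)
        if bad.any():
            for p in np.nonzero(bad.any(axis=1))[0]:
                nan_records.append((X[p].copy(), np.nonzero(bad[p])[0]))
            flat = np.where(bad, 0.0, flat)
        xtx += X.T @ X
        xty += X.T @ flat
        n_pairs += len(pair_keys)

    if xty is None or shape is None:
        raise ValueError("no cross-temporal batches to fit")

    beta_flat = np.full((4, shape[0] * shape[1]), np.nan)
    if np.linalg.matrix_rank(xtx) == 4:
        beta_flat = np.linalg.solve(xtx, xty)

    # cells touched by missing correlations: re-solve normal equations with
    # the offending pairs' contributions removed (their y was zero-filled,
    # so xty already sums only valid pairs)
    if nan_records:
        cell_rows: dict[int, list[np.ndarray]] = {}
        for x_row, cells in nan_records:
            for cell in cells:
                cell_rows.setdefault(int(cell), []).append(x_row)
        for cell, rows in cell_rows.items():
            A = xtx - sum(np.outer(x, x) for x in rows)
            if n_pairs - len(rows) < 5 or np.linalg.matrix_rank(A) < 4:
                beta_flat[:, cell] = np.nan
                continue
            beta_flat[:, cell] = np.linalg.solve(A, xty[:, cell])

    beta = beta_flat.reshape(4, *shape)
    data = np.einsum("cb,bkl->ckl", condition_design(), beta)
    if times is None:
        times = np.arange(shape[0], dtype=float)
    return ConditionCTS(participant_id, data, beta, times)
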