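"""Time-resolved pairwise representational similarity from epoch tensors.

The neural input is one epoch per sentence: channels x time samples of
cleaned EEG, time in ms relative to the expected onset of the final word
(the package consumes already-preprocessed epochs; filtering, ICA and
artifact handling happen upstream).  At every time sample the spatial
pattern (the vector of channel amplitudes) of each trial is correlated
with the pattern of every other trial using Pearson's r, yielding one
similarity time series per unordered sentence pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EpochsTensor",
    "PairSimilaritySeries",
    "spatial_pattern_correlation",
    "pairwise_rsa_series",
    "crop_window",
]


@dataclass
class EpochsTensor:
    """Per-participant trials x channels x samples array with a ms time axis.

    ``times`` must be strictly increasing and uniformly spaced; epochs are
    stored half-open, e.g. -800..0 ms at 1,000 Hz is the 800 samples
    -800, -799, ..., -1.
    """

    participant_id: str
    trials: list[str]  # sentence ids, one per trial
    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    times: np.ndarray  # ms
    sfreq: float  # Hz
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.trials) != n_trials:
            raise ValueError("trial id list does not match data")
        if len(self.trials) != len(set(self.trials)):
            raise ValueError("duplicate trial (sentence) ids")
        if n_channels < 2:
            raise ValueError("need at least two channels for spatial patterns")
        if self.times.shape != (n_samples,):
            raise ValueError("times length does not match data")
        steps = np.diff(self.times)
        if n_samples > 1 and (steps <= 0).any():
            raise ValueError("times must be strictly increasing")
        if n_samples > 2 and not np.allclose(steps, steps[0]):
            raise ValueError("times must be uniformly spaced")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        if not self.channels:
            self.channels = [f"ch{k:02d}" for k in range(n_channels)]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def pick_channels(self, names: Sequence[str]) -> "EpochsTensor":
        """Restrict to a channel-selection list (e.g. scalp channels only)."""
        idx = [self.channels.index(n) for n in names]
        return replace(
            self, data=self.data[:, idx, :].copy(), channels=list(names)
        )

    def trial(self, sentence_id: str) -> np.ndarray:
        return self.data[self.trials.index(sentence_id)]


@dataclass
class PairSimilaritySeries:
    """Pearson correlations of spatial patterns: pairs x time samples."""

    participant_id: str
    pairs: list[tuple[str, str]]
    values: np.ndarray  # (n_pairs, n_samples), NaN = missing
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs), len(self.times)):
            raise ValueError("values shape does not match pairs/times")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlations outside [-1, 1]")


def _zscore_patterns(data: np.ndarray) -> np.ndarray:
    """Z-score each (trial, sample) channel vector; zero variance -> NaN."""
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    sd = centered.std(axis=1, keepdims=True)  # population sd, ddof=0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / sd, np.nan)
    return z


def spatial_pattern_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two channel vectors at a single time sample.

    Returns NaN (a missing marker, not 0) if either vector has zero
    variance across channels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        logger.debug("zero-variance pattern vector; correlation undefined")
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def pairwise_rsa_series(epochs: EpochsTensor) -> PairSimilaritySeries:
    """Similarity time series for every unordered trial pair.

    For each pair of trials and each time sample, the Pearson correlation
    across channels of the two spatial patterns.  Pairs are ordered
    lexicographically by sentence id; each pair key is stored sorted, so
    trial order in the tensor is irrelevant.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials to form pairs")
    order = np.argsort(np.asarray(epochs.trials, dtype=object))
    ids = [epochs.trials[k] for k in order]
    data = epochs.data[order]

    z = _zscore_patterns(data)  # (trials, channels, samples)
    n_ch = epochs.n_channels
    zs = np.nan_to_num(z, nan=0.0).transpose(2, 0, 1)  # (samples, trials, channels)
    corr = np.matmul(zs, zs.transpose(0, 2, 1)) / n_ch  # (samples, trials, trials)
    corr = np.moveaxis(corr, 0, -1)  # (trials, trials, samples)

    # re-mark zero-variance patterns as missing (they were zero-filled above)
    invalid = np.isnan(z).any(axis=1)  # (trials, samples)
    corr[invalid[:, None, :] | invalid[None, :, :]] = np.nan

    iu, ju = np.triu_indices(len(ids), k=1)
    values = np.clip(corr[iu, ju, :], -1.0, 1.0)
    pairs = [(ids[i], ids[j]) for i, j in zip(iu, ju)]
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info(
            "participant %s: %d pair-sample correlations undefined (zero variance)",
            epochs.participant_id,
            n_missing,
        )
    return PairSimilaritySeries(epochs.participant_id, pairs, values, epochs.times.copy())


def crop_window(epochs: EpochsTensor, start_ms: float, end_ms: float) -> EpochsTensor:
    """Retain samples with ``start_ms <= t <= end_ms`` (both ends inclusive)."""
    if start_ms >= end_ms:
        raise ValueError("start_ms must be before end_ms")
    mask = (epochs.times >= start_ms) & (epochs.times <= end_ms)
    if not mask.any():
        raise ValueError(f"no samples in [{start_ms}, {end_ms}] ms")
    return replace(
        epochs, data=epochs.data[:, :, mask].copy(), times=epochs.times[mask].copy()
    )
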