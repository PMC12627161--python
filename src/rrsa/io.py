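"""On-disk containers for epochs, similarity series and derived signals.

The epoch container is a directory holding one ``.npz`` per participant
(``data`` trials x channels x samples, ``trials`` sentence ids) plus a
JSON manifest with the shared time axis, sampling rate and channel names.
Derived series are exported as long-format TSV; statistics reports as
JSON.  Optional import from standard EEG epoch formats goes through
:func:`from_mne_epochs` and never touches the core pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .regression import CONDITIONS, BetaSeries, ConditionSignals
from .rsa import EpochsTensor, PairSimilaritySeries

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_similarity_tsv",
    "save_condition_signals_tsv",
    "load_condition_signals_tsv",
    "save_beta_tsv",
    "from_mne_epochs",
]

MANIFEST = "manifest.json"


def save_epochs(tensors: list[EpochsTensor], directory: str | Path) -> Path:
    """Write an epoch container directory; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref = tensors[0]
    manifest = {
        "participants": [t.participant_id for t in tensors],
        "times_ms": ref.times.tolist(),
        "sfreq": ref.sfreq,
        "channels": ref.channels,
    }
    (directory / MANIFEST).write_text(json.dumps(manifest, indent=2))
    for t in tensors:
        if t.times.shape != ref.times.shape or not np.allclose(t.times, ref.times):
            raise ValueError("all participants must share one time axis")
        np.savez_compressed(
            directory / f"{t.participant_id}.npz",
            data=t.data,
            trials=np.asarray(t.trials, dtype=str),
        )
    return directory


def load_epochs(
    directory: str | Path, participants: list[str] | None = None
) -> list[EpochsTensor]:
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST).read_text())
    times = np.asarray(manifest["times_ms"], dtype=float)
    out = []
    for pid in participants or manifest["participants"]:
        with np.load(directory / f"{pid}.npz") as payload:
            out.append(
                EpochsTensor(
                    participant_id=pid,
                    trials=[str(t) for t in payload["trials"]],
                    data=payload["data"],
                    times=times.copy(),
                    sfreq=float(manifest["sfreq"]),
                    channels=list(manifest["channels"]),
                )
            )
    return out


def save_similarity_tsv(series: PairSimilaritySeries, path: str | Path) -> None:
    """Long-format export: pair_id, time_ms, r."""
    n_pairs, n_samples = series.values.shape
    frame = pd.DataFrame(
        {
            "pair_id": np.repeat([f"{a}~{b}" for a, b in series.pairs], n_samples),
            "time_ms": np.tile(series.times, n_pairs),
            "r": series.values.ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def save_condition_signals_tsv(
    signals: list[ConditionSignals], path: str | Path
) -> None:
    rows = []
    for s in signals:
        for c, name in enumerate(CONDITIONS):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": s.participant_id,
                        "condition": name,
                        "time_ms": s.times,
                        "value": s.data[c],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_condition_signals_tsv(path: str | Path) -> list[ConditionSignals]:
    frame = pd.read_csv(
        path, sep="\t", dtype={"participant": str}, float_precision="round_trip"
    )
    out = []
    for pid, sub in frame.groupby("participant", sort=True):
        wide = sub.pivot(index="condition", columns="time_ms", values="value")
        times = wide.columns.to_numpy(float)
        data = np.stack([wide.loc[name].to_numpy(float) for name in CONDITIONS])
        out.append(ConditionSignals(pid, data, times))
    return out


def save_beta_tsv(betas: list[BetaSeries], path: str | Path) -> None:
    names = ("intercept", "word_specific", "semantic", "form")
    rows = []
    for b in betas:
        for k, name in enumerate(names):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": b.participant_id,
                        "coefficient": name,
                        "time_ms": b.times,
                        "value": b.beta[k],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")


def from_mne_epochs(epochs, participant_id: str, trial_ids: list[str]) -> EpochsTensor:
    """Adapter from an ``mne.Epochs`` object (any format MNE reads).

    *trial_ids* assigns a sentence id to each epoch, in order.  Times are
    converted from seconds to ms.  MNE is imported lazily; the core
    pipeline never requires it.
    """
    data = epochs.get_data(copy=True) * 1e6  # volts -> microvolts
    return EpochsTensor(
        participant_id=participant_id,
        trials=list(trial_ids),
        data=data,
        times=np.asarray(epochs.times) * 1000.0,
        sfreq=float(epochs.info["sfreq"]),
        channels=list(epochs.ch_names),
    )
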