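"""Synthetic lexicons and EEG epochs with planted representational structure.

The generator emulates the structure regression-RSA assumes: every word
owns a word-unique spatial pattern (a channels-vector), words in the same
taxonomy branch share a semantic component, words with the same stem share
a form component, and each component is switched on inside a configurable
latency window with a raised-cosine envelope (so the peak-t latency of a
planted effect sits at the window centre).  White Gaussian sensor noise is
added on top, and every participant sees the same similarity structure
through a private orthogonal rotation of the pattern space — spatial
topographies differ across participants while pattern correlations do
not.  (Pearson correlation across channels centers each pattern, so the
rotations are constrained to fix the channel-mean direction; only then is
the similarity structure exactly preserved.)  Everything is reproducible
from seeds.

Defaults follow the experimental design the package targets: 47 target
words x 2 highly constraining sentences (94 epochs, 4,371 pairs), 34 scalp
channels at 1,000 Hz, epochs -800..0 ms relative to expected word onset,
and effect windows at the latencies where semantic, form and word-specific
similarity increases are observed (semantic -672..-657, form -650..-644,
word-specific -650..-614 ms), i.e. a planted semantic -> form ->
word-specific latency ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .predictors import Lexicon, Taxonomy
from .rsa import EpochsTensor

__all__ = [
    "EffectWindow",
    "EffectSchedule",
    "GroundTruth",
    "default_schedule",
    "make_lexicon",
    "make_ground_truth",
    "simulate_epochs",
    "planted_truth_report",
    "load_truth_report",
]

_VOWELS = "aeiou"
_CONSONANTS = "bcdfglmnprst"


@dataclass(frozen=True)
class EffectWindow:
    """One planted effect: active latency window and pattern-share amplitude.

    ``amplitude`` is the convex share of the shared component mixed into
    the word's pattern while the effect is on (1 = pattern fully shared,
    0 = no effect), which makes the expected pairwise correlation of the
    planted signal analytically accessible.
    """

    start_ms: float
    end_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("effect window start must precede its end")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude is a pattern-share fraction in [0, 1]")

    def envelope(self, times: np.ndarray) -> np.ndarray:
        """Raised-cosine bump: 0 at the window edges, 1 at its centre."""
        frac = (times - self.start_ms) / (self.end_ms - self.start_ms)
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(frac, 0.0, 1.0)))
        return np.where((frac >= 0) & (frac <= 1), env, 0.0)

    @property
    def center_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)


@dataclass(frozen=True)
class EffectSchedule:
    """Which effects are planted, where, and how strongly."""

    semantic: EffectWindow | None = None
    form: EffectWindow | None = None
    word_specific: EffectWindow | None = None

    def active(self) -> dict[str, EffectWindow]:
        return {
            name: w
            for name, w in (
                ("semantic", self.semantic),
                ("form", self.form),
                ("word_specific", self.word_specific),
            )
            if w is not None
        }

    def check_within(self, tmin: float, tmax: float) -> None:
        for name, w in self.active().items():
            if w.start_ms < tmin or w.end_ms > tmax:
                raise ValueError(f"{name} window outside the epoch [{tmin}, {tmax}] ms")


def default_schedule() -> EffectSchedule:
    """Semantic before form before word-specific, at the observed latencies."""
    return EffectSchedule(
        semantic=EffectWindow(-672.0, -657.0, 0.5),
        form=EffectWindow(-650.0, -644.0, 0.5),
        word_specific=EffectWindow(-650.0, -614.0, 1.0),
    )


@dataclass
class GroundTruth:
    """Everything needed to regenerate the planted signal, minus noise.

    ``semantic_groups`` / ``form_groups`` label which words share the
    semantic and form components; patterns themselves are drawn inside
    :func:`simulate_epochs` from ``seed`` so the truth file stays small
    and text-only.
    """

    schedule: EffectSchedule
    semantic_groups: dict[str, str]
    form_groups: dict[str, str]
    noise_sd: float = 1.0
    signal_gain: float = 2.0
    seed: int = 0
    noise_model: str = "white"  # "white" (default, analytic oracles) or "pink"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.signal_gain < 0:
            raise ValueError("signal_gain must be nonnegative")
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")


def make_lexicon(
    n_words: int = 47,
    n_sentences_per_word: int = 2,
    form_family_size: int = 4,
    seed: int = 0,
    stem_length: int = 3,
) -> tuple[Lexicon, Taxonomy]:
    """Generate a lexicon of word-predicting sentences and a toy taxonomy.

    Words are grouped into *form families* (shared stems, hence high edit
    similarity) and, by an independent seeded shuffle, into taxonomy
    branches (shared parent, hence high Lin similarity), so the semantic
    and form predictors decorrelate.  Each leaf carries a random corpus
    count, spreading information content across words.  Deterministic for
    a given seed.
    """
    if n_words < 2:
        raise ValueError("need at least two words")
    if n_sentences_per_word < 1 or form_family_size < 1:
        raise ValueError("degenerate lexicon sizes")
    rng = np.random.default_rng(seed)

    # pronounceable CV(C)V words: family k shares a stem, members differ in suffix
    n_families = -(-n_words // form_family_size)
    stems = []
    for k in range(n_families):
        c1 = _CONSONANTS[k % len(_CONSONANTS)]
        v1 = _VOWELS[(k // len(_CONSONANTS)) % len(_VOWELS)]
        c2 = _CONSONANTS[(k * 7 + 3) % len(_CONSONANTS)]
        stems.append((c1 + v1 + c2)[:stem_length])
    words: list[str] = []
    form_groups: dict[str, str] = {}
    for w in range(n_words):
        fam, member = divmod(w, form_family_size)
        suffix = _VOWELS[member % len(_VOWELS)] + _CONSONANTS[(member // len(_VOWELS) + fam) % len(_CONSONANTS)]
        word = stems[fam] + suffix
        if word in words:  # extremely defensive; construction avoids clashes
            word += _VOWELS[fam % len(_VOWELS)]
        words.append(word)
        form_groups[word] = f"fam{fam:02d}"

    # independent semantic grouping: shuffled chunks become taxonomy branches
    shuffled = [words[k] for k in rng.permutation(n_words)]
    branch_size = form_family_size
    parents: dict[str, tuple[str, ...]] = {"entity": ()}
    counts: dict[str, float] = {"entity": 0.0}
    word_to_node: dict[str, str] = {}
    semantic_groups: dict[str, str] = {}
    for b in range(-(-n_words // branch_size)):
        branch = f"branch{b:02d}"
        parents[branch] = ("entity",)
        counts[branch] = 0.0
        for word in shuffled[b * branch_size : (b + 1) * branch_size]:
            parents[word] = (branch,)
            counts[word] = float(rng.integers(1, 7))
            word_to_node[word] = word
            semantic_groups[word] = branch

    sentences = []
    k = 0
    for word in words:
        for _ in range(n_sentences_per_word):
            sentences.append((f"s{k:03d}", word))
            k += 1
    lexicon = Lexicon(tuple(sentences))
    taxonomy = Taxonomy(parents, counts, word_to_node)
    return lexicon, taxonomy


def make_ground_truth(
    lexicon: Lexicon,
    taxonomy: Taxonomy,
    schedule: EffectSchedule | None = None,
    noise_sd: float = 1.0,
    signal_gain: float = 2.0,
    seed: int = 0,
) -> GroundTruth:
    """Assemble a :class:`GroundTruth` from a lexicon and its taxonomy.

    Semantic groups are the words' parent branches in the taxonomy; form
    groups collect words sharing their three-character stem.
    """
    semantic_groups = {
        w: taxonomy.parents[taxonomy.node_for(w)][0] for w in lexicon.words
    }
    form_groups = {w: w[:3] for w in lexicon.words}
    return GroundTruth(
        schedule or default_schedule(),
        semantic_groups,
        form_groups,
        noise_sd=noise_sd,
        signal_gain=signal_gain,
        seed=seed,
    )


def _pink(white: np.ndarray) -> np.ndarray:
    """Shape white noise to a 1/f amplitude spectrum along the last axis,
    renormalized to unit variance."""
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(white.shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=white.shape[-1], axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def _unit_patterns(labels: list[str], n_channels: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for lab in sorted(labels):
        v = rng.normal(size=n_channels)
        out[lab] = v / np.linalg.norm(v)
    return out


def simulate_epochs(
    lexicon: Lexicon,
    truth: GroundTruth,
    n_participants: int = 24,
    n_channels: int = 34,
    sfreq: float = 1000.0,
    seed: int = 0,
    tmin: float = -800.0,
    tmax: float = 0.0,
) -> list[EpochsTensor]:
    """Simulate one epoch tensor per participant with the planted effects.

    The epoch grid is half-open: ``[tmin, tmax)`` at *sfreq*, e.g.
    -800..0 ms at 1,000 Hz gives the 800 samples -800..-1.  At time t the
    clean pattern of a trial expecting word w is

        gain * sum over active effects e of
            env_e(t) * [ sqrt(a_e) * shared_e(group(w)) + sqrt(1 - a_e) * unique(w) ]

    (for the word-specific effect the "shared" component *is* the unique
    pattern), rotated by the participant's private orthogonal matrix, plus
    N(0, noise_sd**2) white noise per channel and sample.
    """
    truth.schedule.check_within(tmin, tmax)
    step = 1000.0 / sfreq
    times = np.arange(tmin, tmax - 1e-9, step)
    n_samples = times.size
    if n_samples < 2:
        raise ValueError("epoch too short")

    words = sorted(lexicon.words)
    pat_rng = np.random.default_rng(truth.seed)
    unique = _unit_patterns(words, n_channels, pat_rng)
    sem_shared = _unit_patterns(sorted(set(truth.semantic_groups.values())), n_channels, pat_rng)
    form_shared = _unit_patterns(sorted(set(truth.form_groups.values())), n_channels, pat_rng)

    # per-word clean signal (channels x samples), shared across participants
    effects = truth.schedule.active()
    signal: dict[str, np.ndarray] = {}
    for w in words:
        acc = np.zeros((n_channels, n_samples))
        for name, window in effects.items():
            env = window.envelope(times)
            a = window.amplitude
            if name == "semantic":
                shared = sem_shared[truth.semantic_groups[w]]
            elif name == "form":
                shared = form_shared[truth.form_groups[w]]
            else:
                shared = unique[w]
            pattern = np.sqrt(a) * shared + np.sqrt(1.0 - a) * unique[w]
            acc += np.outer(pattern, env)
        signal[w] = truth.signal_gain * acc
    if not all(np.isfinite(s).all() for s in signal.values()):
        raise ValueError("planted amplitudes produced non-finite signal")

    # orthonormal basis of the subspace orthogonal to the channel-mean
    # direction: participant rotations act there, leaving Pearson pattern
    # correlations (which center across channels) exactly invariant
    u = np.full(n_channels, 1.0 / np.sqrt(n_channels))
    basis = np.linalg.svd(np.eye(n_channels) - np.outer(u, u))[0][:, : n_channels - 1]

    tensors = []
    for p in range(n_participants):
        rng = np.random.default_rng([seed, p])
        block, _ = np.linalg.qr(rng.normal(size=(n_channels - 1, n_channels - 1)))
        rot = np.outer(u, u) + basis @ block @ basis.T
        data = np.empty((len(lexicon.sentences), n_channels, n_samples))
        for k, (_, word) in enumerate(lexicon.sentences):
            data[k] = rot @ signal[word]
        if truth.noise_sd > 0:
            noise = rng.normal(size=data.shape)
            if truth.noise_model == "pink":
                noise = _pink(noise)
            data += truth.noise_sd * noise
        tensors.append(
            EpochsTensor(
                participant_id=f"sub-{p:02d}",
                trials=[sid for sid, _ in lexicon.sentences],
                data=data,
                times=times.copy(),
                sfreq=sfreq,
            )
        )
    return tensors


# ---------------------------------------------------------------------------
# ground-truth report
# ---------------------------------------------------------------------------

def planted_truth_report(truth: GroundTruth, path: str | Path | None = None) -> dict:
    """Machine-readable record of the planted structure (for assertions)."""
    report = {
        "schedule": {
            name: {"start_ms": w.start_ms, "end_ms": w.end_ms, "amplitude": w.amplitude,
                   "expected_peak_ms": w.center_ms}
            for name, w in truth.schedule.active().items()
        },
        "noise_sd": truth.noise_sd,
        "signal_gain": truth.signal_gain,
        "noise_model": truth.noise_model,
        "seed": truth.seed,
        "semantic_groups": dict(sorted(truth.semantic_groups.items())),
        "form_groups": dict(sorted(truth.form_groups.items())),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def load_truth_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
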