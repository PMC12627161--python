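"""Pairwise predictors for regression-RSA.

For every unordered pair of sentences the design matrix carries three
regressors describing the relation between the two *expected* final words:

``word_specific``
    Dummy-coded identity: 1 if both sentences predict the same word
    (a within-word pair), 0 otherwise.
``semantic``
    Lin similarity in a concept taxonomy,
    ``2 * IC(lcs) / (IC(a) + IC(b))``, with information content
    ``IC = -log p`` estimated from corpus counts attached to the taxonomy.
``form``
    Normalized orthographic (edit) similarity,
    ``1 - 2 d / (|a| + |b| + d)`` with ``d`` the unit-cost Levenshtein
    distance.

All three live in [0, 1] and equal 1 for identical words.  The semantic
source is pluggable: either a :class:`Taxonomy` (Lin similarity computed
here) or a precomputed symmetric word-by-word similarity matrix, so no
corpus download is ever required.
"""

from __future__ import annotations

import itertools
import math
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "Lexicon",
    "Taxonomy",
    "PredictorTable",
    "levenshtein_distance",
    "normalized_edit_similarity",
    "information_content",
    "lin_similarity",
    "build_predictor_table",
    "variance_inflation_factors",
]


def normalize_word(word: str) -> str:
    """Canonical form used for identity matching: NFC + lowercase.

    Accents are preserved deliberately — in Spanish orthography they are
    contrastive (``papa`` vs ``papá``).
    """
    return unicodedata.normalize("NFC", word).lower()


# ---------------------------------------------------------------------------
# string similarity
# ---------------------------------------------------------------------------

def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two strings.

    Minimum number of single-character substitutions, insertions and
    deletions transforming *a* into *b*.  Empty strings are legal.
    """
    if a == b:
        return 0
    if not a or not b:
        return len(a) + len(b)
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def normalized_edit_similarity(a: str, b: str) -> float:
    """Length-normalized edit similarity in [0, 1].

    With ``d = levenshtein_distance(a, b)`` and unit edit weights this is
    ``1 - 2 d / ((|a| + |b|) + d)``, i.e. the complement of the normalized
    (metric-preserving) Levenshtein distance.  Equals 1 iff the strings are
    identical; two strings with no characters in common score 0.  The
    degenerate both-empty case falls under the identity clause and is 1.
    """
    if a == b:
        return 1.0
    d = levenshtein_distance(a, b)
    return 1.0 - 2.0 * d / (len(a) + len(b) + d)


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lexicon:
    """Sentence frames and the single word each one predicts."""

    sentences: tuple[tuple[str, str], ...]  # (sentence_id, expected_word)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.sentences]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sentence ids in lexicon")
        for sid, word in self.sentences:
            if not word:
                raise ValueError(f"sentence {sid!r} has an empty expected word")

    @property
    def words(self) -> set[str]:
        return {w for _, w in self.sentences}

    @property
    def sentence_ids(self) -> list[str]:
        return [sid for sid, _ in self.sentences]

    def expected_word(self, sentence_id: str) -> str:
        for sid, word in self.sentences:
            if sid == sentence_id:
                return word
        raise KeyError(sentence_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sentence_id", "expected_word"}
        if not required.issubset(frame.columns):
            raise ValueError(f"lexicon TSV needs columns {sorted(required)}")
        return cls(tuple(zip(frame["sentence_id"], frame["expected_word"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.sentences, columns=["sentence_id", "expected_word"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# taxonomy / Lin similarity
# ---------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Rooted concept taxonomy with corpus counts, for Lin similarity.

    ``parents`` maps every node to its parent nodes (empty tuple for the
    root; multiple parents are allowed, i.e. a rooted DAG).  ``counts``
    holds each node's *own* nonnegative corpus frequency; cumulative counts
    (own + all distinct descendants') define occurrence probabilities and
    hence information content.
    """

    parents: Mapping[str, tuple[str, ...]]
    counts: Mapping[str, float]
    word_to_node: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, ps in self.parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for node, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {node!r} is not a node")
        for node, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {node!r}")
        self._check_acyclic()
        self._cumulative: dict[str, float] = {}
        self._ancestors_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if state.get(node) == 2:
                return
            if node in stack:
                raise ValueError(f"cycle through {node!r}")
            for p in self.parents[node]:
                visit(p, stack + (node,))
            state[node] = 2

        for node in self.parents:
            visit(node, ())

    def children(self, node: str) -> list[str]:
        return [n for n, ps in self.parents.items() if node in ps]

    def ancestors(self, node: str) -> frozenset[str]:
        """All ancestors of *node*, including the node itself."""
        cached = self._ancestors_cache.get(node)
        if cached is not None:
            return cached
        out = {node}
        for p in self.parents[node]:
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestors_cache[node] = result
        return result

    def _descendants(self, node: str) -> set[str]:
        out = {node}
        for child in self.children(node):
            out |= self._descendants(child)
        return out

    def cumulative_count(self, node: str) -> float:
        """Own count plus own counts of every distinct descendant."""
        if node not in self._cumulative:
            self._cumulative[node] = float(
                sum(self.counts.get(n, 0.0) for n in self._descendants(node))
            )
        return self._cumulative[node]

    def node_for(self, word: str) -> str:
        key = normalize_word(word)
        mapping = {normalize_word(w): n for w, n in self.word_to_node.items()}
        if key in mapping:
            return mapping[key]
        if key in self.parents:
            return key
        raise KeyError(f"word {word!r} not mapped to any taxonomy node")

    @classmethod
    def from_tsv(cls, edges_path: str | Path, wordmap_path: str | Path | None = None) -> "Taxonomy":
        """Read an edge list ``child  parent  own_count`` (+ optional word map).

        The root appears with an empty parent field.  A word map TSV has
        columns ``word`` and ``node``.
        """
        frame = pd.read_csv(edges_path, sep="\t", dtype={"child": str, "parent": str})
        parents: dict[str, list[str]] = {}
        counts: dict[str, float] = {}
        for _, row in frame.iterrows():
            child = row["child"]
            parent = row["parent"] if isinstance(row["parent"], str) and row["parent"] else None
            parents.setdefault(child, [])
            if parent is not None:
                parents.setdefault(parent, [])
                parents[child].append(parent)
            counts[child] = counts.get(child, 0.0) + float(row.get("own_count", 0.0) or 0.0)
        word_to_node: dict[str, str] = {}
        if wordmap_path is not None:
            wm = pd.read_csv(wordmap_path, sep="\t", dtype=str)
            word_to_node = dict(zip(wm["word"], wm["node"]))
        return cls({k: tuple(v) for k, v in parents.items()}, counts, word_to_node)

    def to_tsv(self, edges_path: str | Path, wordmap_path: str | Path | None = None) -> None:
        rows = [
            {"child": n, "parent": (ps[0] if ps else ""), "own_count": self.counts.get(n, 0.0)}
            for n, ps in self.parents.items()
        ]
        pd.DataFrame(rows).to_csv(edges_path, sep="\t", index=False)
        if wordmap_path is not None:
            pd.DataFrame(
                [{"word": w, "node": n} for w, n in self.word_to_node.items()]
            ).to_csv(wordmap_path, sep="\t", index=False)


def information_content(node: str, taxonomy: Taxonomy) -> float:
    """IC(node) = -ln( cumulative(node) / cumulative(root) ).

    Zero at the root, weakly increasing toward the leaves.  Natural log;
    Lin similarity is invariant to the base.
    """
    total = taxonomy.cumulative_count(taxonomy.root)
    if total <= 0:
        raise ValueError("taxonomy has zero total corpus count")
    cum = taxonomy.cumulative_count(node)
    if cum <= 0:
        raise ValueError(f"node {node!r} has zero cumulative count; IC undefined")
    return -math.log(cum / total)


def least_common_subsumer(a_node: str, b_node: str, taxonomy: Taxonomy) -> str:
    """Most specific (maximum-IC) common ancestor of the two nodes."""
    common = taxonomy.ancestors(a_node) & taxonomy.ancestors(b_node)
    if not common:  # unreachable in a single-rooted taxonomy
        raise ValueError("nodes share no ancestor")
    # ties broken lexicographically for determinism
    return max(sorted(common), key=lambda n: information_content(n, taxonomy))


def lin_similarity(a: str, b: str, taxonomy: Taxonomy) -> float:
    """Lin similarity ``2 IC(lcs) / (IC(a) + IC(b))`` between two words."""
    na, nb = taxonomy.node_for(a), taxonomy.node_for(b)
    if na == nb:
        return 1.0
    ic_a = information_content(na, taxonomy)
    ic_b = information_content(nb, taxonomy)
    lcs = least_common_subsumer(na, nb, taxonomy)
    ic_lcs = information_content(lcs, taxonomy)
    if ic_a + ic_b == 0:
        return 0.0
    return 2.0 * ic_lcs / (ic_a + ic_b) + 0.0  # + 0.0 canonicalizes -0.0


# ---------------------------------------------------------------------------
# predictor table
# ---------------------------------------------------------------------------

@dataclass
class PredictorTable:
    """One row per unordered sentence pair with the three regressors.

    Rows are keyed ``(sent_i, sent_j)`` with ``sent_i < sent_j`` in the
    lexicon's sentence order, so the table is symmetric by construction and
    holds exactly ``n (n - 1) / 2`` rows for *n* sentences.
    """

    frame: pd.DataFrame  # columns: pair_id, sent_i, sent_j, word_specific, semantic, form

    COLUMNS = ("pair_id", "sent_i", "sent_j", "word_specific", "semantic", "form")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"predictor table missing columns {sorted(missing)}")
        for col in ("semantic", "form"):
            vals = self.frame[col].to_numpy(float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} values outside [0, 1]")
        if not self.frame["word_specific"].isin([0, 1]).all():
            raise ValueError("word_specific must be dummy-coded 0/1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["sent_i"], self.frame["sent_j"]))

    def design_matrix(
        self, pairs: Sequence[tuple[str, str]] | None = None
    ) -> np.ndarray:
        """(n_pairs, 4) design ``[1, word_specific, semantic, form]``.

        With *pairs* given, rows are returned in that order (orientation of
        each pair is ignored); missing pairs raise ``KeyError``.
        """
        if pairs is None:
            sub = self.frame
            return np.column_stack(
                [
                    np.ones(len(sub)),
                    sub["word_specific"].to_numpy(float),
                    sub["semantic"].to_numpy(float),
                    sub["form"].to_numpy(float),
                ]
            )
        index = {
            frozenset(p): k for k, p in enumerate(self.pairs)
        }
        rows = []
        full = self.design_matrix()
        for p in pairs:
            k = index.get(frozenset(p))
            if k is None:
                raise KeyError(f"pair {p} not in predictor table")
            rows.append(full[k])
        return np.asarray(rows)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        for col in ("semantic", "form"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictorTable":
        frame = pd.read_csv(
            path,
            sep="\t",
            dtype={"pair_id": str, "sent_i": str, "sent_j": str},
        )
        return cls(frame)


def build_predictor_table(
    lexicon: Lexicon,
    semantic_source: Taxonomy | pd.DataFrame | Mapping[frozenset, float],
) -> PredictorTable:
    """Build the full pairwise predictor table for a lexicon.

    *semantic_source* is either a :class:`Taxonomy` (Lin similarity is
    computed here) or a precomputed symmetric similarity matrix: a pandas
    DataFrame indexed and columned by word, or a mapping keyed by
    ``frozenset({word_a, word_b})``.  Word identity uses NFC-normalized,
    lowercased exact string equality.
    """
    sentences = list(lexicon.sentences)
    if len(sentences) < 2:
        raise ValueError("need at least two sentences to form pairs")

    def semantic(a: str, b: str) -> float:
        if normalize_word(a) == normalize_word(b):
            return 1.0
        if isinstance(semantic_source, Taxonomy):
            return lin_similarity(a, b, semantic_source)
        if isinstance(semantic_source, pd.DataFrame):
            try:
                return float(semantic_source.loc[a, b])
            except KeyError as exc:
                raise KeyError(f"word pair ({a!r}, {b!r}) missing from matrix") from exc
        val = semantic_source.get(frozenset({a, b}))
        if val is None:
            raise KeyError(f"word pair ({a!r}, {b!r}) missing from mapping")
        return float(val)

    # cache on unordered word pairs: 47 words -> 1,081 similarities feed 4,371 rows
    sem_cache: dict[frozenset, float] = {}
    form_cache: dict[frozenset, float] = {}
    rows = []
    for (sid_i, w_i), (sid_j, w_j) in itertools.combinations(sentences, 2):
        wkey = frozenset({normalize_word(w_i), normalize_word(w_j)})
        same = normalize_word(w_i) == normalize_word(w_j)
        if wkey not in sem_cache:
            sem_cache[wkey] = semantic(w_i, w_j)
            form_cache[wkey] = normalized_edit_similarity(
                normalize_word(w_i), normalize_word(w_j)
            )
        rows.append(
            {
                "pair_id": f"{sid_i}~{sid_j}",
                "sent_i": sid_i,
                "sent_j": sid_j,
                "word_specific": int(same),
                "semantic": sem_cache[wkey],
                "form": form_cache[wkey],
            }
        )
    return PredictorTable(pd.DataFrame(rows))


def variance_inflation_factors(table: PredictorTable) -> dict[str, float]:
    """VIF of each regressor on the other two (with intercept).

    ``VIF_k = 1 / (1 - R²_k)``; perfect collinearity is reported as
    ``inf`` rather than silently capped.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = table.design_matrix()
    if X.shape[0] < 4:
        raise ValueError("need at least 4 rows for a VIF analysis")
    names = ("word_specific", "semantic", "form")
    for k, name in enumerate(names, start=1):
        if np.isclose(np.var(X[:, k]), 0.0):
            raise ValueError(f"predictor {name} has zero variance")
    out: dict[str, float] = {}
    with np.errstate(divide="ignore"):
        for k, name in enumerate(names, start=1):
            vif = float(variance_inflation_factor(X, k))
            out[name] = math.inf if not np.isfinite(vif) or vif > 1e12 else vif
    return out
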