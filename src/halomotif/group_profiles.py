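"""Per-group positional probability profiles and sequence classification.

Six substrate groups of flavin-dependent halogenases are modelled
(5-, 6- and 7-Trp halogenases, indole, phenolic and pyrrole halogenases).
Each group contributes a positional residue-probability matrix over its seed
alignment's match columns.  A query is aligned to every group's profile HMM;
the probability of the query residue at each match column, concatenated over
the six groups in a fixed order, forms its feature vector.  Queries are then
embedded in 2-D with t-SNE for inspection, and classified by 1-nearest
neighbour against labelled reference vectors.

The default classification path is 1-NN on the raw feature vectors: the
neighbour structure is identical to the embedded space but reproducible and
metric.  1-NN on the 2-D embedding is available for parity with
embedding-based workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .profile_hmm import ProfileHMM, build_phmm, viterbi_align
from .seqio import AMINO_ACIDS, MultipleAlignment, SequenceRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Fixed concatenation order of group segments in feature vectors.
GROUP_ORDER = ("5-Trp", "6-Trp", "7-Trp", "indole", "phenolic", "pyrrole")

#: Probability assigned to match columns with no aligned query residue
#: (deletion, or outside the local alignment), and to 'X' residues.
GAP_FILL = 0.05


class ProfileSetError(ValueError):
    """Profile set incomplete or inconsistent with the query/feature space."""


class FeatureError(ValueError):
    """A query could not be embedded (e.g. aligns to no group profile)."""


@dataclass
class GroupProfile:
    """Positional residue probabilities for one halogenase group."""

    group: str
    probabilities: np.ndarray  # (L_g, 20), rows sum to 1
    column_map: np.ndarray  # 1-based seed-MSA columns of the match states
    model: ProfileHMM  # the aligner for this group's match columns

    @property
    def n_columns(self) -> int:
        return self.probabilities.shape[0]


def build_group_profile(
    msa: MultipleAlignment,
    group: str,
    pseudocount: float = 1.0,
    gap_threshold: float = 0.5,
) -> GroupProfile:
    """Column probability profile for one group's seed alignment.

    Shares the match-column rule and pseudocount scheme with the scan model:
    P(a | column) = (count_a + pseudocount) / (n_observed + 20 * pseudocount).
    """
    if msa.n_rows < 2:
        raise ProfileSetError(f"group {group!r}: need at least 2 seed rows")
    model = build_phmm(msa, gap_threshold=gap_threshold, pseudocount=pseudocount)
    return GroupProfile(
        group=group,
        probabilities=model.match_emissions.copy(),
        column_map=model.column_map.copy(),
        model=model,
    )


@dataclass
class FeatureVector:
    query_id: str
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EmbeddingPoint:
    query_id: str
    x: float
    y: float
    assigned_class: str = "unassigned"


def feature_vector(
    query: SequenceRecord,
    profiles: dict[str, GroupProfile],
    min_coverage: float = 0.1,
    gap_fill: float = GAP_FILL,
) -> FeatureVector:
    """Positional-probability features of a query against all six groups.

    For each group, each match column contributes the column's probability of
    the query residue aligned there (Viterbi alignment); columns with no
    aligned residue contribute ``gap_fill``.  Segments are concatenated in
    :data:`GROUP_ORDER`.
    """
    missing = [g for g in GROUP_ORDER if g not in profiles]
    if missing:
        raise ProfileSetError(f"profile set incomplete; missing groups {missing}")
    x = query.residues
    segments = []
    best_cov = 0.0
    for g in GROUP_ORDER:
        prof = profiles[g]
        aln = viterbi_align(prof.model, query)
        best_cov = max(best_cov, aln.model_coverage)
        seg = np.full(prof.n_columns, gap_fill)
        for node, qpos in aln.match_map.items():
            ch = x[qpos - 1]
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                seg[node - 1] = prof.probabilities[node - 1, idx]
        segments.append(seg)
    if best_cov < min_coverage:
        raise FeatureError(
            f"query {query.id!r} is not FDH-like: best profile coverage "
            f"{best_cov:.3f} < {min_coverage}"
        )
    return FeatureVector(query.id, np.concatenate(segments))


def embed_tsne(
    features: list[FeatureVector],
    perplexity: float = 10.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> list[EmbeddingPoint]:
    """2-D t-SNE embedding of feature vectors; deterministic given the seed."""
    n = len(features)
    if n < 3 * perplexity:
        raise FeatureError(
            f"t-SNE needs at least {int(3 * perplexity)} points for perplexity "
            f"{perplexity} (got {n}); classify on raw feature vectors instead"
        )
    X = np.vstack([f.values for f in features])
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        random_state=seed,
        init="pca",
    ).fit_transform(X)
    return [
        EmbeddingPoint(f.query_id, float(cx), float(cy))
        for f, (cx, cy) in zip(features, coords)
    ]


@dataclass(frozen=True)
class Reference:
    """A labelled reference point for nearest-neighbour classification."""

    id: str
    label: str
    values: tuple[float, ...]


def knn_classify(
    query_values: np.ndarray,
    references: list[Reference],
    k: int = 1,
) -> tuple[str, float]:
    """Nearest-neighbour class label and distance (Euclidean metric).

    Distance ties are broken by the lexicographically lowest reference id; for
    k > 1 the majority label among the k nearest wins, with ties going to the
    label whose members are cumulatively closest.
    """
    if not references:
        raise ValueError("no reference points")
    q = np.asarray(query_values, dtype=float)
    dims = {len(r.values) for r in references}
    if dims != {q.shape[0]}:
        raise ValueError(f"dimension mismatch: query {q.shape[0]}, references {sorted(dims)}")
    order = sorted(references, key=lambda r: (float(np.linalg.norm(np.asarray(r.values) - q)), r.id))
    if k == 1:
        best = order[0]
        return best.label, float(np.linalg.norm(np.asarray(best.values) - q))
    top = order[:k]
    tally: dict[str, list[float]] = {}
    for r in top:
        tally.setdefault(r.label, []).append(float(np.linalg.norm(np.asarray(r.values) - q)))
    label = min(tally, key=lambda lb: (-len(tally[lb]), sum(tally[lb]), lb))
    return label, min(tally[label])
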