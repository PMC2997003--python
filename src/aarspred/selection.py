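"""SVM-weight feature ranking with recursive elimination.

Repeatedly fit a linear soft-margin SVM, score each surviving feature by
its squared weight, and eliminate the lowest-scoring batch until no
features remain; a feature's rank is its reverse elimination order (the
last survivor gets rank 1). This reproduces the attribute-ranking role of
SVM-based recursive feature elimination used to pick the discriminative
dipeptide subsets for each classification stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from aarspred.errors import ComputationError, InputError

#: Below this many surviving features, eliminate one per round.
_ONE_BY_ONE_LIMIT = 50


@dataclass(frozen=True)
class FeatureRanking:
    """(name, rank, score-at-elimination) triples; ranks permute 1..n."""

    entries: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        ranks = sorted(r for _, r, _ in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ComputationError("ranks are not a permutation of 1..n")

    def names_by_rank(self) -> list[str]:
        return [n for n, _, _ in sorted(self.entries, key=lambda e: e[1])]

    def rank_of(self, name: str) -> int:
        for n, r, _ in self.entries:
            if n == name:
                return r
        raise InputError(f"unknown feature {name!r}")

    def to_tsv(self) -> str:
        lines = ["name\trank\tscore"]
        for n, r, s in sorted(self.entries, key=lambda e: e[1]):
            lines.append(f"{n}\t{r}\t{s:.6g}")
        return "\n".join(lines) + "\n"


def rank_features(
    X: np.ndarray,
    y: Sequence[int],
    feature_names: Sequence[str],
    batch_fraction: float = 0.1,
    C: float = 1.0,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by recursive linear-SVM weight elimination.

    Each round drops the surviving features with the smallest squared
    weights: one per round once at most 50 survive, otherwise
    ``batch_fraction`` of the survivors. Ties break by feature-name
    lexicographic order, so the procedure is deterministic for fixed
    inputs; ``seed`` is recorded for provenance but no randomness is
    drawn.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise InputError(
            f"X has {X.shape} columns but {len(feature_names)} names given"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("feature ranking needs both classes present")
    if counts.min() < 2:
        raise InputError("feature ranking needs >= 2 samples per class")
    n = len(feature_names)
    surviving = list(range(n))
    eliminated: list[tuple[int, float]] = []  # feature index, score when dropped
    round_no = 0
    while surviving:
        round_no += 1
        if len(surviving) == 1:
            eliminated.append((surviving[0], float("inf")))
            break
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(X[:, surviving], y)
        scores = np.asarray(clf.coef_).ravel() ** 2
        n_drop = (
            1
            if len(surviving) <= _ONE_BY_ONE_LIMIT
            else max(1, int(batch_fraction * len(surviving)))
        )
        order = sorted(
            range(len(surviving)),
            key=lambda i: (scores[i], feature_names[surviving[i]]),
        )
        for i in order[:n_drop]:
            eliminated.append((surviving[i], float(scores[i])))
        dropped = {surviving[i] for i in order[:n_drop]}
        surviving = [f for f in surviving if f not in dropped]
    entries = []
    for pos, (feat_idx, score) in enumerate(eliminated):
        rank = len(eliminated) - pos  # first eliminated -> worst rank
        entries.append((feature_names[feat_idx], rank, score))
    return FeatureRanking(tuple(entries))


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """The k best-ranked feature names, in rank order."""
    if not 1 <= k <= len(ranking.entries):
        raise InputError(
            f"k must be in 1..{len(ranking.entries)}, got {k}"
        )
    return ranking.names_by_rank()[:k]
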