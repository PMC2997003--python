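"""Similarity-search baseline: classify by top local-alignment hit.

Each held-out query is assigned the label of its highest-scoring database
sequence (Smith-Waterman local alignment, affine gaps, BLOSUM62 by
default), provided the score reaches the hit threshold. The historical
hit accounting counts a no-hit positive as a false negative and a no-hit
negative as a false *positive*; a corrected accounting (no-hit negative ->
true negative) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from aarspred.errors import InputError, ValidationError
from aarspred.evaluation import (
    ConfusionCounts,
    CVSplit,
    EvaluationReport,
    metrics,
    _mean_or_none,
)
from aarspred.sequence_io import LabeledDataset, ProteinSequence

import numpy as np


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for local alignment and the hit-call threshold.

    Either a substitution matrix name (``matrix``) or simple
    ``match``/``mismatch`` scores; a gap of length k costs
    ``gap_open + k * gap_extend``. A top hit below ``threshold`` counts
    as no-hit.
    """

    matrix: str | None = "BLOSUM62"
    match: float | None = None
    mismatch: float | None = None
    gap_open: float = 10.0
    gap_extend: float = 1.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties are costs and must be >= 0")
        if self.threshold < 0:
            raise ValidationError("hit threshold must be >= 0")
        simple = self.match is not None and self.mismatch is not None
        if not simple and self.matrix is None:
            raise ValidationError(
                "need either a matrix name or match/mismatch scores"
            )


def _make_aligner(p: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if p.match is not None and p.mismatch is not None:
        aligner.match_score = p.match
        aligner.mismatch_score = p.mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load(p.matrix)
    # first gapped position costs open+extend, each further one extend
    aligner.open_gap_score = -(p.gap_open + p.gap_extend)
    aligner.extend_gap_score = -p.gap_extend
    return aligner


def local_align_score(
    a: str | ProteinSequence,
    b: str | ProteinSequence,
    p: AlignmentParams = AlignmentParams(),
) -> float:
    """Maximal Smith-Waterman local alignment score; 0 if nothing aligns."""
    sa = a.residues if isinstance(a, ProteinSequence) else a
    sb = b.residues if isinstance(b, ProteinSequence) else b
    if not sa or not sb:
        return 0.0
    return max(0.0, float(_make_aligner(p).score(sa, sb)))


def top_hit_classify(
    query: ProteinSequence,
    db: LabeledDataset,
    p: AlignmentParams = AlignmentParams(),
) -> int | None:
    """Label of the best-scoring database sequence, or None for no-hit.

    Ties break by database order (first maximum wins). Scores strictly
    below the threshold do not count as hits.
    """
    if not db.records:
        raise InputError("similarity database is empty")
    aligner = _make_aligner(p)
    best_score, best_label = -1.0, None
    for seq, label in db.records:
        score = max(0.0, float(aligner.score(query.residues, seq.residues)))
        if score > best_score:
            best_score, best_label = score, label
    if best_score < p.threshold:
        return None
    return best_label


def cv_similarity_eval(
    ds: LabeledDataset,
    split: CVSplit,
    p: AlignmentParams = AlignmentParams(),
    corrected_accounting: bool = False,
) -> EvaluationReport:
    """Cross-validated top-hit classification.

    Per fold, the database is the other k-1 folds and the test fold
    supplies queries. Historical accounting: no-hit positives count as FN
    and no-hit negatives as FP; with ``corrected_accounting`` a no-hit
    negative counts as TN instead.
    """
    fold_reports: list[EvaluationReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in range(1, split.k + 1):
        db = ds.subset(split.ids_not_in_fold(fold))
        queries = ds.subset(split.ids_in_fold(fold))
        tp = tn = fp = fn = 0
        for seq, label in queries.records:
            hit = top_hit_classify(seq, db, p)
            if hit is None:
                if label == 1:
                    fn += 1
                elif corrected_accounting:
                    tn += 1
                else:
                    fp += 1
            elif hit == label:
                tp += label == 1
                tn += label == 0
            else:
                fn += label == 1
                fp += label == 0
        c = ConfusionCounts(tp, tn, fp, fn)
        fold_reports.append(metrics(c))
        pooled = pooled + c
    return EvaluationReport(
        sensitivity=_mean_or_none([r.sensitivity for r in fold_reports]),
        specificity=_mean_or_none([r.specificity for r in fold_reports]),
        accuracy=_mean_or_none([r.accuracy for r in fold_reports]),
        mcc=float(np.mean([r.mcc for r in fold_reports])),
        per_fold=fold_reports,
        pooled=metrics(pooled),
    )
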