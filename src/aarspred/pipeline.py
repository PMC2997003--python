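"""Feature-extraction pipelines and trainable SVM pipelines.

Six feature modes mirror the approaches compared for each stage:

=============  ============================================  dims (stage1/stage2)
``domain``     binary PROSITE-domain bits only               4 / 5
``aac``        amino-acid composition                        20 / 20
``dpc``        full dipeptide composition                    400 / 400
``dpc-selected`` stage's selected dipeptide subset           18 / 14
``hybrid1``    aac + domain bits                             24 / 25
``hybrid2``    selected dipeptides + domain bits             22 / 19
=============  ============================================  =====================

A :class:`FeaturePipeline` maps (sequence, domain annotation) to a feature
vector with a fixed spec; :class:`SVMPipeline` wraps a pipeline plus SVM
hyperparameters into the fit/score object consumed by cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from aarspred.classifier import SVMModel, train
from aarspred.composition import (
    FeatureSpec,
    FeatureVector,
    STAGE1_DIPEPTIDES,
    STAGE2_DIPEPTIDES,
    aa_composition,
    assemble_hybrid,
    dipeptide_composition,
    subset_features,
)
from aarspred.domains import (
    DomainAnnotation,
    STAGE1_DOMAINS,
    STAGE2_DOMAINS,
    encode_domains,
)
from aarspred.errors import InputError
from aarspred.sequence_io import LabeledDataset, ProteinSequence

FEATURE_MODES = ("domain", "aac", "dpc", "dpc-selected", "hybrid1", "hybrid2")


@dataclass(frozen=True)
class FeaturePipeline:
    """Deterministic (sequence, annotation) -> feature-vector map."""

    mode: str
    dipeptide_list: tuple[str, ...]
    domain_list: tuple[str, ...]

    @property
    def spec(self) -> FeatureSpec:
        names: tuple[str, ...]
        if self.mode == "domain":
            names = self.domain_list
        elif self.mode == "aac":
            names = tuple("ACDEFGHIKLMNPQRSTVWY")
        elif self.mode == "dpc":
            from aarspred.composition import DIPEPTIDES

            names = DIPEPTIDES
        elif self.mode == "dpc-selected":
            names = self.dipeptide_list
        elif self.mode == "hybrid1":
            names = tuple("ACDEFGHIKLMNPQRSTVWY") + self.domain_list
        else:  # hybrid2
            names = self.dipeptide_list + self.domain_list
        return FeatureSpec(names)

    def __call__(
        self, seq: ProteinSequence, ann: DomainAnnotation
    ) -> FeatureVector:
        if self.mode == "domain":
            return encode_domains(ann, seq.id, self.domain_list)
        if self.mode == "aac":
            return aa_composition(seq)
        if self.mode == "dpc":
            return dipeptide_composition(seq)
        if self.mode == "dpc-selected":
            return subset_features(dipeptide_composition(seq), self.dipeptide_list)
        if self.mode == "hybrid1":
            return assemble_hybrid(
                [aa_composition(seq), encode_domains(ann, seq.id, self.domain_list)]
            )
        # hybrid2
        return assemble_hybrid(
            [
                subset_features(dipeptide_composition(seq), self.dipeptide_list),
                encode_domains(ann, seq.id, self.domain_list),
            ]
        )


def build_pipeline(
    mode: str,
    stage: int = 1,
    domain_list: Sequence[str] | None = None,
    dipeptide_list: Sequence[str] | None = None,
) -> FeaturePipeline:
    """Construct a feature pipeline for a stage, with optional overrides.

    Stage 1 defaults to the 4-domain list and the 18 selected dipeptides;
    stage 2 to the 5-domain list and the 14 selected dipeptides.
    """
    if mode not in FEATURE_MODES:
        raise InputError(f"unknown feature mode {mode!r}; expected {FEATURE_MODES}")
    if stage not in (1, 2):
        raise InputError(f"stage must be 1 or 2, got {stage}")
    dips = tuple(
        dipeptide_list
        if dipeptide_list is not None
        else (STAGE1_DIPEPTIDES if stage == 1 else STAGE2_DIPEPTIDES)
    )
    doms = tuple(
        domain_list
        if domain_list is not None
        else (STAGE1_DOMAINS if stage == 1 else STAGE2_DOMAINS)
    )
    return FeaturePipeline(mode, dips, doms)


def feature_matrix(
    pipeline: FeaturePipeline,
    seqs: Sequence[ProteinSequence],
    ann: DomainAnnotation | None = None,
) -> tuple[np.ndarray, FeatureSpec, list[str]]:
    """Stack per-sequence feature vectors into an (n, d) matrix."""
    ann = ann or DomainAnnotation()
    vectors = [pipeline(s, ann) for s in seqs]
    X = (
        np.stack([v.values for v in vectors])
        if vectors
        else np.zeros((0, len(pipeline.spec)))
    )
    return X, pipeline.spec, [s.id for s in seqs]


def matrix_to_tsv(
    X: np.ndarray, spec: FeatureSpec, ids: Sequence[str]
) -> str:
    """Feature matrix as TSV: first column id, one column per feature."""
    lines = ["id\t" + "\t".join(spec.names)]
    for sid, row in zip(ids, X):
        lines.append(sid + "\t" + "\t".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"


@dataclass
class SVMPipeline:
    """Feature pipeline + SVM hyperparameters; fit/score for CV.

    The domain annotation is fixed at construction: it is an input table,
    not something learned, so sharing it across folds leaks nothing.
    """

    featurize: FeaturePipeline
    ann: DomainAnnotation = field(default_factory=DomainAnnotation)
    kernel: str = "rbf"
    C: float = 10.0
    gamma: float = 0.05
    seed: int = 0
    model: SVMModel | None = None

    def fit(self, ds: LabeledDataset) -> "SVMPipeline":
        X, spec, _ = feature_matrix(self.featurize, ds.sequences, self.ann)
        self.model = train(
            X, ds.labels, kernel=self.kernel, C=self.C, gamma=self.gamma,
            seed=self.seed, feature_spec=spec,
        )
        return self

    def decision_values(self, seqs: Sequence[ProteinSequence]) -> np.ndarray:
        if self.model is None:
            raise InputError("pipeline is not fitted")
        X, _, _ = feature_matrix(self.featurize, seqs, self.ann)
        return self.model.decision_function(X)
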