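"""Amino-acid and dipeptide composition features.

Composition is expressed in percent (0-100): the amino-acid vector has 20
entries (one per residue, alphabetical), the dipeptide vector has 400
entries (the 20x20 grid of ordered residue pairs, first letter major). Over-
lapping length-2 windows are counted, so a sequence of length L contributes
L-1 dipeptide observations. The two fixed dipeptide subsets found most
discriminative for each classification stage are shipped as constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from aarspred.errors import ValidationError
from aarspred.sequence_io import ALPHABET, ProteinSequence

AMINO_ACIDS: tuple[str, ...] = tuple(ALPHABET)

#: The 400 ordered dipeptides in grid order (first letter major, alphabetical).
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a, b in product(ALPHABET, ALPHABET))

#: 18 dipeptides discriminating aaRS from non-aaRS proteins (stage 1).
STAGE1_DIPEPTIDES: tuple[str, ...] = (
    "CL", "DR", "FY", "GM", "GR", "GS", "IN", "MV", "ND",
    "PL", "QI", "QR", "RD", "RF", "ST", "WF", "YD", "YV",
)

#: 14 dipeptides discriminating class-1 from class-2 aaRSs (stage 2).
STAGE2_DIPEPTIDES: tuple[str, ...] = (
    "AY", "DP", "DW", "EN", "EV", "GH", "IG",
    "KM", "PW", "QW", "SG", "WD", "YA", "YV",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered, named feature axes; serialized alongside any trained model."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            seen: set[str] = set()
            dup = next(n for n in self.names if n in seen or seen.add(n))
            raise ValidationError(f"duplicate feature name {dup!r}")
        if not self.names:
            raise ValidationError("feature spec must not be empty")

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown feature name {name!r}") from None


AA_SPEC = FeatureSpec(AMINO_ACIDS)
DIPEPTIDE_SPEC = FeatureSpec(DIPEPTIDES)


@dataclass(frozen=True)
class FeatureVector:
    """Real-valued features tied to a :class:`FeatureSpec`."""

    spec: FeatureSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) != len(self.spec):
            raise ValidationError(
                f"values length {vals.shape} does not match spec length "
                f"{len(self.spec)}"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.spec.index_of(name)])


def aa_composition(seq: ProteinSequence) -> FeatureVector:
    """Percent composition of each of the 20 amino acids.

    Entry for residue r is 100 * count(r) / len(seq); the 20 values sum
    to 100.
    """
    counts = np.zeros(20)
    for idx in map(ALPHABET.index, seq.residues):
        counts[idx] += 1
    return FeatureVector(AA_SPEC, 100.0 * counts / len(seq))


def dipeptide_composition(seq: ProteinSequence) -> FeatureVector:
    """Percent composition of the 400 ordered dipeptides.

    Overlapping windows: entry for dipeptide d is 100 * count(d) / (L-1).
    Requires L >= 2.
    """
    L = len(seq)
    if L < 2:
        raise ValidationError(
            f"sequence {seq.id!r} has length {L}; dipeptide composition "
            "requires length >= 2"
        )
    counts = np.zeros(400)
    r = seq.residues
    for i in range(L - 1):
        counts[ALPHABET.index(r[i]) * 20 + ALPHABET.index(r[i + 1])] += 1
    return FeatureVector(DIPEPTIDE_SPEC, 100.0 * counts / (L - 1))


def subset_features(v: FeatureVector, names: Sequence[str]) -> FeatureVector:
    """Extract named features in the requested order, without renormalizing."""
    idx = [v.spec.index_of(n) for n in names]
    return FeatureVector(FeatureSpec(tuple(names)), v.values[idx])


def assemble_hybrid(parts: Iterable[FeatureVector]) -> FeatureVector:
    """Concatenate feature vectors into one hybrid vector.

    Specs must be disjoint; the result's dimension is the sum of the part
    dimensions (e.g. 18 selected dipeptides + 4 domain bits -> 22).
    """
    parts = list(parts)
    if not parts:
        raise ValidationError("assemble_hybrid needs at least one part")
    names: list[str] = []
    for p in parts:
        names.extend(p.spec.names)
    spec = FeatureSpec(tuple(names))  # raises on duplicates across parts
    return FeatureVector(spec, np.concatenate([p.values for p in parts]))
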