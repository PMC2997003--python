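"""Reading, validating and writing protein sequences and labeled datasets.

Sequences are plain strings over the 20 standard one-letter amino-acid
codes. Non-standard residue codes (B, Z, X, U, O, J and anything else) are
either rejected (``strict``) or dropped with a warning
(``drop_nonstandard``, the default), so that downstream composition vectors
live exactly in the 20- and 400-dimensional spaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from aarspred.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes, alphabetical.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

CleanPolicy = Literal["strict", "drop_nonstandard"]


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence: identifier plus residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-standard residues "
                f"{sorted(bad)}; run clean_sequence first"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Binary-labeled sequence collection (1 = positive, 0 = negative)."""

    records: list[tuple[ProteinSequence, int]]
    positive_name: str = "positive"
    negative_name: str = "negative"

    def __post_init__(self) -> None:
        ids = [seq.id for seq, _ in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate sequence id {dup!r} in dataset")
        for _, lab in self.records:
            if lab not in (0, 1):
                raise ValidationError(f"labels must be 0/1, got {lab!r}")

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> list[int]:
        return [lab for _, lab in self.records]

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self.records) - self.n_positive

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        """Records whose id is in ``ids``, original order preserved."""
        wanted = set(ids)
        return LabeledDataset(
            [(s, l) for s, l in self.records if s.id in wanted],
            self.positive_name,
            self.negative_name,
        )


def clean_sequence(raw: str, policy: CleanPolicy = "drop_nonstandard") -> str:
    """Case-fold and validate a raw residue string.

    ``strict`` raises on any character outside the 20-letter alphabet;
    ``drop_nonstandard`` removes offenders with a logged warning. Both
    policies are idempotent on their own output.
    """
    if not raw:
        raise ValidationError("empty sequence")
    upper = raw.upper()
    offending = [(i + 1, c) for i, c in enumerate(upper) if c not in _ALPHABET_SET]
    if not offending:
        return upper
    if policy == "strict":
        shown = ", ".join(f"{c!r}@{i}" for i, c in offending[:10])
        raise ValidationError(
            f"{len(offending)} non-standard residue(s): {shown}"
        )
    if policy != "drop_nonstandard":
        raise ValueError(f"unknown cleaning policy {policy!r}")
    cleaned = "".join(c for c in upper if c in _ALPHABET_SET)
    logger.warning(
        "dropped %d non-standard residue(s) (%s)",
        len(offending),
        "".join(sorted({c for _, c in offending})),
    )
    if not cleaned:
        raise ValidationError("sequence empty after dropping non-standard residues")
    return cleaned


def read_fasta(
    path: str | Path, policy: CleanPolicy = "drop_nonstandard"
) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into validated protein sequences.

    The header token up to the first whitespace becomes the id. Records are
    returned in file order; residues are cleaned per ``policy``.
    """
    path = Path(path)
    out: list[ProteinSequence] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises ValueError on gross malformation
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    # SeqIO silently skips leading junk before the first '>'; reject it.
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: sequence data before first header")
                break
    for rec in records:
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        raw = str(rec.seq)
        if not raw:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            out.append(ProteinSequence(rec.id, clean_sequence(raw, policy)))
        except ValidationError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(
    seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences to FASTA with fixed line wrapping."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def load_labeled_tsv(
    fasta_path: str | Path,
    labels_path: str | Path,
    policy: CleanPolicy = "drop_nonstandard",
) -> LabeledDataset:
    """Load sequences from FASTA and 0/1 labels from a two-column TSV.

    The TSV has columns (id, label); every sequence must be labeled and
    every labeled id must exist in the FASTA.
    """
    seqs = read_fasta(fasta_path, policy)
    labels: dict[str, int] = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{labels_path}:{lineno}: expected 2 columns")
            sid, lab = parts[0].strip(), parts[1].strip()
            if lineno == 1 and lab not in ("0", "1"):
                continue  # header row
            if lab not in ("0", "1"):
                raise FormatError(
                    f"{labels_path}:{lineno}: label must be 0 or 1, got {lab!r}"
                )
            if sid in labels:
                raise ValidationError(f"{labels_path}:{lineno}: duplicate id {sid!r}")
            labels[sid] = int(lab)
    missing = [s.id for s in seqs if s.id not in labels]
    if missing:
        raise ValidationError(f"no label for sequence(s) {missing[:5]}")
    return LabeledDataset([(s, labels[s.id]) for s in seqs])


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    positive_name: str = "positive",
    negative_name: str = "negative",
    policy: CleanPolicy = "drop_nonstandard",
) -> LabeledDataset:
    """Load a positive/negative FASTA pair into one labeled dataset.

    Positives get label 1, negatives 0. Ids must be unique across both
    files; either file being empty is an error.
    """
    pos = read_fasta(pos_path, policy)
    neg = read_fasta(neg_path, policy)
    if not pos:
        raise FormatError(f"{pos_path}: positive set is empty")
    if not neg:
        raise FormatError(f"{neg_path}: negative set is empty")
    collisions = {s.id for s in pos} & {s.id for s in neg}
    if collisions:
        raise ValidationError(
            f"id(s) present in both files: {sorted(collisions)[:5]}"
        )
    records = [(s, 1) for s in pos] + [(s, 0) for s in neg]
    return LabeledDataset(records, positive_name, negative_name)
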