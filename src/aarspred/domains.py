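"""PROSITE domain presence features.

Domain presence is a binary feature: 1 if the scanner reported the
accession for the sequence, else 0. Presence normally comes from an
ingested scan-result table (ProfileScan / InterProScan reformatted to a
two-column TSV); pattern-type signatures can additionally be detected with
the built-in PROSITE-pattern matcher. Generalized-profile (weight-matrix)
scoring is deliberately not re-implemented: profile-type accessions are
only ever ingested from hit tables or emitted by the synthetic generator.

Domain sets used by the two classification stages:

* stage 1 (aaRS vs non-aaRS): PS50862, PS00178, PS50860, PS50861
* stage 2 (class-1 vs class-2): the four above plus PS50889

with PS00178 and PS50889 preferred by class-1 enzymes and PS50862,
PS50860, PS50861 by class-2.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from aarspred.errors import FormatError, ValidationError
from aarspred.sequence_io import ALPHABET, ProteinSequence
from aarspred.composition import FeatureSpec, FeatureVector

_ACCESSION_RE = re.compile(r"^PS\d{5}$")

#: Domains used as stage-1 features, fixed order.
STAGE1_DOMAINS: tuple[str, ...] = ("PS50862", "PS00178", "PS50860", "PS50861")

#: Domains used as stage-2 features, fixed order.
STAGE2_DOMAINS: tuple[str, ...] = (
    "PS50862", "PS00178", "PS50860", "PS50861", "PS50889",
)

#: Domains preferentially found in class-1 aaRSs.
CLASS1_PREFERRED_DOMAINS: frozenset[str] = frozenset({"PS00178", "PS50889"})

#: Domains preferentially found in class-2 aaRSs.
CLASS2_PREFERRED_DOMAINS: frozenset[str] = frozenset(
    {"PS50862", "PS50860", "PS50861"}
)

#: Pattern-type signatures detectable by the internal matcher. PS00178
#: carries the class-1 'HIGH' adenylate-binding signature.
BUILTIN_PATTERNS: Mapping[str, str] = {"PS00178": "H-I-G-H."}

#: Synthetic exact-motif stand-ins, one per accession, used by the data
#: generator so that emitted sequences and hit tables agree. The strings
#: for the four profile-type domains are invented peptides, not real
#: PROSITE consensus sequences; only PS00178's corresponds to a genuine
#: signature (HIGH).
SYNTHETIC_SIGNATURES: Mapping[str, str] = {
    "PS00178": "HIGH",
    "PS50889": "RLDKWLWAAR",
    "PS50862": "GFGLERLLMI",
    "PS50860": "DTAYMGRFEH",
    "PS50861": "WQMVHPNCMA",
}


def _check_accession(acc: str) -> str:
    if not _ACCESSION_RE.match(acc):
        raise ValidationError(
            f"{acc!r} is not a PROSITE accession (expected PS + 5 digits)"
        )
    return acc


@dataclass
class DomainAnnotation:
    """Per-sequence sets of PROSITE accessions reported present."""

    hits: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hits = {
            sid: frozenset(_check_accession(a) for a in accs)
            for sid, accs in self.hits.items()
        }

    def domains_of(self, seq_id: str) -> frozenset[str]:
        return self.hits.get(seq_id, frozenset())

    def merged_with(self, other: "DomainAnnotation") -> "DomainAnnotation":
        """Union of hits; useful to combine table and matcher sources."""
        out = {sid: set(accs) for sid, accs in self.hits.items()}
        for sid, accs in other.hits.items():
            out.setdefault(sid, set()).update(accs)
        return DomainAnnotation({k: frozenset(v) for k, v in out.items()})


@dataclass(frozen=True)
class PatternElement:
    """One hyphen-separated element of a PROSITE pattern."""

    kind: str  # literal | any | set | excluded
    residues: frozenset[str]  # empty for 'any'
    min_repeat: int = 1
    max_repeat: int = 1


@dataclass(frozen=True)
class PrositePattern:
    """Parsed PROSITE pattern: ordered elements plus optional anchors."""

    accession: str
    elements: tuple[PatternElement, ...]
    n_anchor: bool = False
    c_anchor: bool = False


def _parse_repeat(token: str, base_end: int, pos0: int) -> tuple[int, int]:
    """Parse a trailing ``(n)`` / ``(n,m)`` repeat; returns (min, max)."""
    rest = token[base_end:]
    if not rest:
        return 1, 1
    if not (rest.startswith("(") and rest.endswith(")")):
        raise FormatError(
            f"bad repeat specifier {rest!r} at position {pos0 + base_end + 1}"
        )
    body = rest[1:-1]
    m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
    if not m:
        raise FormatError(
            f"bad repeat range {body!r} at position {pos0 + base_end + 2}"
        )
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    if lo > hi:
        raise FormatError(f"repeat range ({lo},{hi}) has min > max")
    return lo, hi


def _parse_element(token: str, pos0: int) -> PatternElement:
    if not token:
        raise FormatError(f"empty pattern element at position {pos0 + 1}")
    first = token[0].upper()
    if token[0] in "[{":
        closer = "]" if token[0] == "[" else "}"
        end = token.find(closer)
        if end < 0:
            raise FormatError(
                f"unbalanced {token[0]!r} at position {pos0 + 1}"
            )
        body = token[1:end].upper()
        if not body:
            raise FormatError(f"empty residue set at position {pos0 + 1}")
        bad = set(body) - set(ALPHABET)
        if bad:
            raise FormatError(
                f"non-residue character(s) {sorted(bad)} in set at "
                f"position {pos0 + 1}"
            )
        lo, hi = _parse_repeat(token, end + 1, pos0)
        kind = "set" if token[0] == "[" else "excluded"
        return PatternElement(kind, frozenset(body), lo, hi)
    if first == "X":
        lo, hi = _parse_repeat(token, 1, pos0)
        return PatternElement("any", frozenset(), lo, hi)
    if first in ALPHABET:
        lo, hi = _parse_repeat(token, 1, pos0)
        return PatternElement("literal", frozenset({first}), lo, hi)
    raise FormatError(
        f"unknown pattern character {token[0]!r} at position {pos0 + 1}"
    )


def parse_prosite_pattern(text: str, accession: str = "PS00000") -> PrositePattern:
    """Parse PROSITE pattern syntax (``H-I-G-H.``, ``[AC]-x(2)-D.`` ...).

    Hyphen-separated elements; literal residues, ``x`` wildcards, ``[..]``
    residue sets, ``{..}`` exclusion sets, ``(n)``/``(n,m)`` repeats;
    optional ``<``/``>`` terminal anchors and trailing period.
    Case-insensitive. Raises :class:`FormatError` with the offending
    position on malformed input.
    """
    raw = text.strip()
    if not raw:
        raise FormatError("empty pattern")
    if raw.endswith("."):
        raw = raw[:-1]
    n_anchor = raw.startswith("<")
    if n_anchor:
        raw = raw[1:]
    c_anchor = raw.endswith(">")
    if c_anchor:
        raw = raw[:-1]
    if not raw:
        raise FormatError("pattern has anchors but no elements")
    elements: list[PatternElement] = []
    pos = 0
    for token in raw.split("-"):
        elements.append(_parse_element(token, pos))
        pos += len(token) + 1
    return PrositePattern(accession, tuple(elements), n_anchor, c_anchor)


def _element_regex(el: PatternElement) -> str:
    if el.kind == "literal":
        cls = next(iter(el.residues))
    elif el.kind == "any":
        cls = f"[{ALPHABET}]"
    elif el.kind == "set":
        cls = "[" + "".join(sorted(el.residues)) + "]"
    else:  # excluded
        cls = "[^" + "".join(sorted(el.residues)) + "]"
    if (el.min_repeat, el.max_repeat) == (1, 1):
        return cls
    if el.min_repeat == el.max_repeat:
        return f"{cls}{{{el.min_repeat}}}"
    return f"{cls}{{{el.min_repeat},{el.max_repeat}}}"


def match_pattern(p: PrositePattern, seq: ProteinSequence | str) -> list[int]:
    """All 1-based start positions where the pattern matches the sequence.

    Matches may overlap; anchored patterns only match at the respective
    terminus. An empty result means no match.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    body = "".join(_element_regex(el) for el in p.elements)
    if p.c_anchor:
        body += "$"
    compiled = re.compile(body)
    starts = range(1) if p.n_anchor else range(len(residues))
    return [i + 1 for i in starts if compiled.match(residues, i)]


def scan_sequences(
    seqs: Iterable[ProteinSequence],
    patterns: Mapping[str, str] = BUILTIN_PATTERNS,
) -> DomainAnnotation:
    """Annotate sequences with the internal matcher over pattern signatures."""
    parsed = {acc: parse_prosite_pattern(txt, acc) for acc, txt in patterns.items()}
    hits: dict[str, frozenset[str]] = {}
    for seq in seqs:
        found = {acc for acc, pat in parsed.items() if match_pattern(pat, seq)}
        if found:
            hits[seq.id] = frozenset(found)
    return DomainAnnotation(hits)


def load_domain_hits(path: str | Path) -> DomainAnnotation:
    """Load a two-column (seq_id, accession) TSV of domain hits.

    A header row is tolerated; duplicate rows collapse via set semantics;
    extra columns are ignored. Malformed rows raise with their line number.
    """
    path = Path(path)
    hits: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            sid, acc = row[0].strip(), row[1].strip()
            if lineno == 1 and not _ACCESSION_RE.match(acc):
                continue  # header row
            if not sid:
                raise FormatError(f"{path}:{lineno}: empty sequence id")
            if not _ACCESSION_RE.match(acc):
                raise FormatError(
                    f"{path}:{lineno}: {acc!r} is not a PROSITE accession"
                )
            hits.setdefault(sid, set()).add(acc)
    return DomainAnnotation({k: frozenset(v) for k, v in hits.items()})


def save_domain_hits(ann: DomainAnnotation, path: str | Path) -> None:
    """Write hits as a headered two-column TSV, sorted for reproducibility."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["seq_id", "accession"])
        for sid in sorted(ann.hits):
            for acc in sorted(ann.hits[sid]):
                writer.writerow([sid, acc])


def encode_domains(
    ann: DomainAnnotation, seq_id: str, domain_list: Sequence[str]
) -> FeatureVector:
    """Binary presence vector over ``domain_list`` for one sequence.

    Bit i is 1 iff domain_list[i] was reported for ``seq_id``; ids absent
    from the annotation yield the all-zero vector. Only set membership
    matters, never multiplicity or order of hits.
    """
    if not domain_list:
        raise ValidationError("domain_list must be non-empty")
    present = ann.domains_of(seq_id)
    values = np.array([1.0 if d in present else 0.0 for d in domain_list])
    return FeatureVector(FeatureSpec(tuple(domain_list)), values)
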