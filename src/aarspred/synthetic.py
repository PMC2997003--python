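"""Synthetic labeled protein datasets with controlled, recoverable signal.

The generator emulates the contrasts a composition-plus-domain classifier
exploits in real aaRS data: class-biased dipeptide composition (extra
copies of target dipeptides inserted at random positions), planted
signature motifs (HIGH and KMSKS for class-1-like sequences), and a
domain-hit table consistent with the planted content (a coupled domain,
e.g. the HIGH-carrying pattern PS00178, is only ever reported for
sequences that actually contain its motif). Every draw comes from one
seeded generator stream, so datasets are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from aarspred.composition import DIPEPTIDES
from aarspred.domains import DomainAnnotation
from aarspred.errors import InputError, ValidationError
from aarspred.sequence_io import ALPHABET, LabeledDataset, ProteinSequence

#: Class-1 aaRS signature peptides planted by the aaRS-like presets.
CLASS1_MOTIFS: tuple[str, ...] = ("HIGH", "KMSKS")


@dataclass(frozen=True)
class DomainPlanEntry:
    """One domain emission rule for a class.

    ``coupled_motif`` ties the hit to sequence content: the accession is
    reported (with probability ``probability``) only when the motif occurs
    in the final sequence. Uncoupled entries model profile-type domains
    whose signal the sequence text does not carry.
    """

    accession: str
    probability: float
    coupled_motif: str | None = None


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for a two-class synthetic dataset.

    ``biased_dipeptides`` maps label -> list of (dipeptide, excess percent
    points of composition); ``motif_plan`` maps label -> list of
    (motif, insertion probability); ``domain_plan`` maps label -> list of
    :class:`DomainPlanEntry`.
    """

    n_per_class: tuple[int, int] = (200, 200)  # (positives, negatives)
    length_range: tuple[int, int] = (300, 600)
    background: tuple[float, ...] = tuple([1.0 / 20] * 20)
    biased_dipeptides: Mapping[int, tuple[tuple[str, float], ...]] = field(
        default_factory=dict
    )
    motif_plan: Mapping[int, tuple[tuple[str, float], ...]] = field(
        default_factory=dict
    )
    domain_plan: Mapping[int, tuple[DomainPlanEntry, ...]] = field(
        default_factory=dict
    )
    seed: int = 0
    positive_name: str = "positive"
    negative_name: str = "negative"

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise ValidationError("n_per_class entries must be >= 1")
        lo, hi = self.length_range
        if not 2 <= lo <= hi:
            raise ValidationError(f"bad length range ({lo}, {hi})")
        if len(self.background) != 20 or abs(sum(self.background) - 1.0) > 1e-9:
            raise ValidationError("background must be 20 probabilities summing to 1")
        if any(p < 0 for p in self.background):
            raise ValidationError("background frequencies must be >= 0")
        for label, pairs in self.biased_dipeptides.items():
            total = 0.0
            for dip, excess in pairs:
                if dip not in DIPEPTIDES:
                    raise ValidationError(f"{dip!r} is not a dipeptide")
                if excess < 0:
                    raise ValidationError("dipeptide excess must be >= 0")
                total += excess
            if total >= 40.0:
                raise InputError(
                    f"label {label}: total requested excess {total:.1f} "
                    "percent exceeds sequence capacity"
                )
        for plan in self.motif_plan.values():
            for motif, prob in plan:
                if not set(motif) <= set(ALPHABET):
                    raise ValidationError(f"motif {motif!r} has non-standard residues")
                if not 0.0 <= prob <= 1.0:
                    raise ValidationError("motif probability must be in [0, 1]")
        for plan in self.domain_plan.values():
            for entry in plan:
                if not 0.0 <= entry.probability <= 1.0:
                    raise ValidationError("domain probability must be in [0, 1]")


@dataclass
class SequenceTruth:
    """What was planted in one sequence."""

    label: int
    motifs: list[tuple[str, int]]  # (motif, 1-based start in final sequence)
    dipeptide_insertions: dict[str, int]
    domains: list[str]


def _insert(residues: list[str], pos: int, fragment: str,
            planted: list[tuple[str, int]]) -> None:
    """Insert fragment at 0-based pos, shifting recorded motif positions."""
    residues[pos:pos] = list(fragment)
    for i, (motif, start) in enumerate(planted):
        if start - 1 >= pos:
            planted[i] = (motif, start + len(fragment))


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[LabeledDataset, DomainAnnotation, dict[str, SequenceTruth]]:
    """Draw a labeled dataset, its domain-hit table and the truth record.

    Sequences are i.i.d. draws from the background frequencies; class
    signal is added by inserting extra dipeptide copies (enough that the
    expected composition excess over background matches the request) and
    signature motifs at uniform random interior positions. The truth
    record stores every planted motif position, per-dipeptide insertion
    counts and emitted domains.
    """
    rng = np.random.default_rng(cfg.seed)
    bg = np.asarray(cfg.background)
    records: list[tuple[ProteinSequence, int]] = []
    hits: dict[str, frozenset[str]] = {}
    truth: dict[str, SequenceTruth] = {}
    for label, n, prefix in (
        (1, cfg.n_per_class[0], "pos"),
        (0, cfg.n_per_class[1], "neg"),
    ):
        biases = cfg.biased_dipeptides.get(label, ())
        motifs = cfg.motif_plan.get(label, ())
        dplan = cfg.domain_plan.get(label, ())
        for i in range(n):
            sid = f"{prefix}_{i + 1:04d}"
            L0 = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            residues = list(rng.choice(list(ALPHABET), size=L0, p=bg))
            planted: list[tuple[str, int]] = []
            # dipeptide enrichment: n_d insertions give ~n_d extra windows
            # of d in a final length of about L0 + 2 * sum(n_d)
            total_excess = sum(e for _, e in biases)
            denom = 1.0 - 2.0 * total_excess / 100.0
            ins_counts: dict[str, int] = {}
            for dip, excess in biases:
                n_ins = int(round((excess / 100.0) * (L0 - 1) / denom))
                if 2 * n_ins >= L0:
                    raise InputError(
                        f"excess {excess} for {dip} exceeds capacity at length {L0}"
                    )
                ins_counts[dip] = n_ins
                for _ in range(n_ins):
                    pos = int(rng.integers(1, len(residues)))
                    _insert(residues, pos, dip, planted)
            for motif, prob in motifs:
                if rng.random() < prob:
                    pos = int(rng.integers(1, len(residues)))
                    _insert(residues, pos, motif, planted)
                    planted.append((motif, pos + 1))
            seq_str = "".join(residues)
            seq = ProteinSequence(sid, seq_str)
            emitted: list[str] = []
            for entry in dplan:
                if entry.coupled_motif is not None and entry.coupled_motif not in seq_str:
                    continue
                if rng.random() < entry.probability:
                    emitted.append(entry.accession)
            if emitted:
                hits[sid] = frozenset(emitted)
            records.append((seq, label))
            truth[sid] = SequenceTruth(label, planted, ins_counts, emitted)
    ds = LabeledDataset(records, cfg.positive_name, cfg.negative_name)
    return ds, DomainAnnotation(hits), truth


def truth_to_json(truth: dict[str, SequenceTruth]) -> str:
    """Serialize the truth record as stable, human-readable JSON."""
    return json.dumps(
        {sid: asdict(t) for sid, t in sorted(truth.items())}, indent=1
    )


def presets() -> dict[str, GeneratorConfig]:
    """Named generator configurations for the two stages plus a null.

    * ``stage1`` — aaRS-like positives vs background negatives: positives
      carry the HIGH and KMSKS peptides with probability 0.9, mild
      enrichment of six of the 18 stage-1 dipeptides, and domain hits at
      rates giving roughly 60-70% of positives at least one of the four
      stage-1 domains versus ~10% of negatives.
    * ``stage2`` — class-1-like (positive) vs class-2-like sequences:
      each side carries only its preferred domain accessions and its own
      dipeptide enrichment; class-1 additionally carries HIGH and KMSKS.
    * ``null`` — no planted signal of any kind, for chance-level checks.
    """
    stage1 = GeneratorConfig(
        n_per_class=(200, 200),
        length_range=(300, 600),
        biased_dipeptides={
            1: tuple((d, 1.0) for d in ("GR", "GS", "ND", "ST", "RD", "PL")),
        },
        motif_plan={1: (("HIGH", 0.9), ("KMSKS", 0.9))},
        domain_plan={
            1: (
                DomainPlanEntry("PS00178", 0.50, coupled_motif="HIGH"),
                DomainPlanEntry("PS50862", 0.30),
                DomainPlanEntry("PS50860", 0.12),
                DomainPlanEntry("PS50861", 0.12),
            ),
            0: tuple(
                DomainPlanEntry(acc, 0.025)
                for acc in ("PS50862", "PS00178", "PS50860", "PS50861")
            ),
        },
        positive_name="aaRS",
        negative_name="non-aaRS",
    )
    # both stage-2 classes are aaRSs, so they share the stage-1 aaRS
    # dipeptide enrichment on top of their class-specific signal
    aars_bias = tuple((d, 1.0) for d in ("GR", "GS", "ND", "ST", "RD", "PL"))
    stage2 = GeneratorConfig(
        n_per_class=(150, 150),
        length_range=(300, 600),
        biased_dipeptides={
            1: aars_bias + tuple((d, 1.0) for d in ("EV", "IG", "KM")),
            0: aars_bias + tuple((d, 1.0) for d in ("SG", "GH", "DP")),
        },
        motif_plan={1: (("HIGH", 0.9), ("KMSKS", 0.9))},
        domain_plan={
            1: (
                DomainPlanEntry("PS00178", 0.60, coupled_motif="HIGH"),
                DomainPlanEntry("PS50889", 0.50),
            ),
            0: (
                DomainPlanEntry("PS50862", 0.60),
                DomainPlanEntry("PS50860", 0.25),
                DomainPlanEntry("PS50861", 0.25),
            ),
        },
        positive_name="class-1",
        negative_name="class-2",
    )
    null = GeneratorConfig(
        n_per_class=(100, 100),
        length_range=(300, 600),
        positive_name="null-positive",
        negative_name="null-negative",
    )
    return {"stage1": stage1, "stage2": stage2, "null": null}


def get_preset(name: str, seed: int | None = None) -> GeneratorConfig:
    """Fetch a preset by name, optionally re-seeded."""
    catalog = presets()
    if name not in catalog:
        raise InputError(
            f"unknown preset {name!r}; available: {sorted(catalog)}"
        )
    cfg = catalog[name]
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict_config(cfg), "seed": seed})
    return cfg


def asdict_config(cfg: GeneratorConfig) -> dict:
    """Plain-dict view of a config (domain plans kept as dataclasses)."""
    return {
        "n_per_class": cfg.n_per_class,
        "length_range": cfg.length_range,
        "background": cfg.background,
        "biased_dipeptides": cfg.biased_dipeptides,
        "motif_plan": cfg.motif_plan,
        "domain_plan": cfg.domain_plan,
        "seed": cfg.seed,
        "positive_name": cfg.positive_name,
        "negative_name": cfg.negative_name,
    }
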