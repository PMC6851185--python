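"""Gene-model data structures for genes with mutually exclusive exon clusters.

A :class:`GeneModel` describes a gene as an ordered list of exon *slots*.
Each slot is constitutive (always spliced in), optional (included or
skipped), a *cluster* of mutually exclusive variants (exactly one variant
retained per mature transcript), or a placeholder for an exon whose
sequence could not be determined.  Splice constraints (implication /
exclusion between exon identities) and terminators (an intron-retention
stop or alternative stop-carrying variants) complete the description.

Coordinates follow the GFF3 convention: 1-based, closed intervals.
Exon identities are strings ``"slot.variant"`` for cluster members
(e.g. ``"6.47"``) and plain ``"slot"`` for single-exon slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ExonVariant",
    "SlotSpec",
    "SpliceConstraint",
    "Terminator",
    "GeneModel",
    "Violation",
    "ExonCensus",
    "validate_model",
    "exon_census",
    "InvalidModelError",
]

SLOT_KINDS = ("constitutive", "optional", "cluster", "placeholder")
CONSTRAINT_KINDS = ("implies", "forbids")
TERMINATOR_KINDS = ("retained_intron", "stop_variant")
REGION_TAGS = ("extracellular", "tail")


class InvalidModelError(ValueError):
    """Raised when an operation refuses to run on an invalid model."""


@dataclass(frozen=True)
class ExonVariant:
    """One exon record: a genomic interval plus its extracted sequence.

    ``sequence`` is ``None`` when unknown (placeholder exons).
    ``frame_offset`` (0..2) records the reading-frame shift relative to the
    slot's canonical frame; it is non-zero only for overlapping cluster
    variants read in a different frame (e.g. a terminal variant entirely
    contained within its sibling's span).
    """

    id: str
    slot: int
    start: int
    end: int
    strand: str = "+"
    sequence: Optional[str] = None
    frame_offset: int = 0
    peptide: Optional[str] = None  # curated amino-acid sequence, if any
    synthetic: bool = False  # True for stand-in (not curated) nucleotides

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SlotSpec:
    """One position in the exon order and the variants that may fill it."""

    slot: int
    kind: str
    variants: list[str] = field(default_factory=list)
    region_tag: str = "extracellular"


@dataclass(frozen=True)
class SpliceConstraint:
    """A pairwise splicing rule between exon identities.

    ``implies``: whenever the antecedent exon is present in a transcript,
    the consequent exon must be present too.  ``forbids``: the two exons
    never co-occur.
    """

    kind: str
    antecedent: str
    consequent: str


@dataclass(frozen=True)
class Terminator:
    """A way for translation/transcription to end.

    ``retained_intron``: the intron after ``after_slot`` is retained; it
    carries its own stop codon and poly(A) signal, producing a truncated
    (tail-less, secreted) protein.  ``stop_variant``: the stop codon lies
    in the cluster variant ``variant_id``.
    """

    kind: str
    after_slot: Optional[int] = None
    variant_id: Optional[str] = None
    sequence: Optional[str] = None  # retained-intron nucleotides, if known


@dataclass
class GeneModel:
    name: str
    slots: list[SlotSpec] = field(default_factory=list)
    exons: dict[str, ExonVariant] = field(default_factory=dict)
    constraints: list[SpliceConstraint] = field(default_factory=list)
    terminators: list[Terminator] = field(default_factory=list)
    genome: Optional[str] = None
    genome_sequence_ref: Optional[str] = None

    # -- convenience accessors -------------------------------------------------

    def slot_spec(self, slot: int) -> SlotSpec:
        for s in self.slots:
            if s.slot == slot:
                return s
        raise KeyError(f"no slot {slot}")

    def slot_of(self, exon_id: str) -> int:
        return self.exons[exon_id].slot

    def cluster_slots(self) -> list[SlotSpec]:
        return [s for s in self.slots if s.kind == "cluster"]

    def optional_slots(self) -> list[SlotSpec]:
        return [s for s in self.slots if s.kind == "optional"]

    def retained_intron(self) -> Optional[Terminator]:
        for t in self.terminators:
            if t.kind == "retained_intron":
                return t
        return None

    def subset(self, slots: Iterable[int], name: Optional[str] = None) -> "GeneModel":
        """A new model restricted to the given slots.

        Constraints referencing dropped slots and terminators anchored
        outside the kept range are dropped as well.
        """
        keep = set(slots)
        new_slots = [replace_slot(s) for s in self.slots if s.slot in keep]
        exons = {eid: ev for eid, ev in self.exons.items() if ev.slot in keep}
        constraints = [
            c
            for c in self.constraints
            if _ref_slot(self, c.antecedent) in keep
            and _ref_slot(self, c.consequent) in keep
        ]
        terminators = []
        for t in self.terminators:
            if t.kind == "retained_intron" and t.after_slot in keep:
                terminators.append(t)
            elif t.kind == "stop_variant" and t.variant_id in exons:
                terminators.append(t)
        return GeneModel(
            name=name or f"{self.name}[subset]",
            slots=new_slots,
            exons=exons,
            constraints=constraints,
            terminators=terminators,
            genome=self.genome,
            genome_sequence_ref=self.genome_sequence_ref,
        )


def replace_slot(s: SlotSpec) -> SlotSpec:
    return SlotSpec(slot=s.slot, kind=s.kind, variants=list(s.variants),
                    region_tag=s.region_tag)


def _ref_slot(model: GeneModel, exon_id: str) -> Optional[int]:
    if exon_id in model.exons:
        return model.exons[exon_id].slot
    return None


# -- validation ----------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.subject}: {self.message}"


def validate_model(model: GeneModel) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions."""
    out: list[Violation] = []
    seen_slots: set[int] = []  # type: ignore[assignment]
    seen_slots = set()
    prev = None
    for s in model.slots:
        subj = f"slot {s.slot}"
        if s.kind not in SLOT_KINDS:
            out.append(Violation("slot kind", subj, f"unknown kind {s.kind!r}"))
        if s.region_tag not in REGION_TAGS:
            out.append(Violation("region tag", subj, f"unknown tag {s.region_tag!r}"))
        if s.slot in seen_slots:
            out.append(Violation("slot order", subj, "duplicate slot number"))
        if prev is not None and s.slot <= prev:
            out.append(Violation("slot order", subj, "slots not strictly increasing"))
        prev = s.slot
        seen_slots.add(s.slot)
        if s.kind == "cluster" and len(s.variants) < 2:
            out.append(Violation("cluster arity<2", subj,
                                 f"cluster has {len(s.variants)} variant(s)"))
        if s.kind != "cluster" and len(s.variants) > 1:
            out.append(Violation("slot arity", subj,
                                 "non-cluster slot lists multiple variants"))
        for vid in s.variants:
            if vid not in model.exons:
                out.append(Violation("unknown id", subj,
                                     f"variant {vid!r} has no exon record"))
            elif model.exons[vid].slot != s.slot:
                out.append(Violation("slot mismatch", subj,
                                     f"exon {vid!r} claims slot {model.exons[vid].slot}"))
    for eid, ev in model.exons.items():
        subj = f"exon {eid}"
        if ev.id != eid:
            out.append(Violation("id mismatch", subj, f"record id {ev.id!r}"))
        if ev.start > ev.end:
            out.append(Violation("interval", subj, f"start {ev.start} > end {ev.end}"))
        if ev.strand not in ("+", "-"):
            out.append(Violation("strand", subj, f"bad strand {ev.strand!r}"))
        if ev.sequence is not None and len(ev.sequence) != ev.length:
            out.append(Violation("sequence length", subj,
                                 f"sequence {len(ev.sequence)} nt for a "
                                 f"{ev.length} nt interval"))
        if not 0 <= ev.frame_offset <= 2:
            out.append(Violation("frame offset", subj,
                                 f"frame_offset {ev.frame_offset} outside 0..2"))
        if ev.slot not in seen_slots:
            out.append(Violation("unknown slot", subj,
                                 f"references undeclared slot {ev.slot}"))
    for c in model.constraints:
        subj = f"constraint {c.antecedent} {c.kind} {c.consequent}"
        if c.kind not in CONSTRAINT_KINDS:
            out.append(Violation("constraint kind", subj, f"unknown kind {c.kind!r}"))
        for ref in (c.antecedent, c.consequent):
            if ref not in model.exons:
                out.append(Violation("unknown id", subj, f"unknown id {ref!r}"))
    boundary = None
    for t in model.terminators:
        subj = f"terminator {t.kind}"
        if t.kind not in TERMINATOR_KINDS:
            out.append(Violation("terminator kind", subj, f"unknown kind {t.kind!r}"))
        elif t.kind == "retained_intron":
            if t.after_slot is None or t.after_slot not in seen_slots:
                out.append(Violation("unknown slot", subj,
                                     f"after_slot {t.after_slot!r} not in model"))
            else:
                boundary = t.after_slot
        elif t.kind == "stop_variant":
            if t.variant_id not in model.exons:
                out.append(Violation("unknown id", subj,
                                     f"variant {t.variant_id!r} not in model"))
    if boundary is not None:
        for c in model.constraints:
            sa = _ref_slot(model, c.antecedent)
            sb = _ref_slot(model, c.consequent)
            if sa is not None and sb is not None:
                if (sa <= boundary) != (sb <= boundary):
                    out.append(Violation(
                        "constraint spans terminator boundary",
                        f"constraint {c.antecedent} {c.kind} {c.consequent}",
                        f"crosses the retained intron after slot {boundary}"))
    return out


# -- census --------------------------------------------------------------------


@dataclass(frozen=True)
class ExonCensus:
    n_slots: int
    n_constitutive: int
    n_optional: int
    n_cluster_slots: int
    n_variant_records: int
    n_exon_records: int

    def as_dict(self) -> dict:
        return {
            "n_slots": self.n_slots,
            "n_constitutive": self.n_constitutive,
            "n_optional": self.n_optional,
            "n_cluster_slots": self.n_cluster_slots,
            "n_variant_records": self.n_variant_records,
            "n_exon_records": self.n_exon_records,
        }


def exon_census(model: GeneModel) -> ExonCensus:
    """Count slots and exon records by kind.

    Placeholder slots count toward ``n_slots`` only, so for a gene with one
    unidentified exon the record total is smaller than the slot total.
    """
    violations = validate_model(model)
    if violations:
        raise InvalidModelError(
            "refusing census of invalid model: " + "; ".join(map(str, violations))
        )
    n_con = sum(1 for s in model.slots if s.kind == "constitutive")
    n_opt = sum(1 for s in model.slots if s.kind == "optional")
    clusters = model.cluster_slots()
    n_var = sum(len(s.variants) for s in clusters)
    return ExonCensus(
        n_slots=len(model.slots),
        n_constitutive=n_con,
        n_optional=n_opt,
        n_cluster_slots=len(clusters),
        n_variant_records=n_var,
        n_exon_records=n_con + n_opt + n_var,
    )
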