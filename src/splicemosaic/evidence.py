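"""Infer exon types and splice constraints from observed transcript chains.

Each cDNA contig contributes an ordered *exon chain*.  A chain only votes
on slots within its span, so partial contigs (e.g. tail-only transcripts)
never misclassify uncovered exons as skipped.  Classification rules:

* constitutive — the slot's single exon appears in every spanning chain;
* optional — it appears in some spanning chains and is absent from others;
* cluster — several variant identities are observed, they never co-occur
  within one chain, and every spanning chain carries exactly one of them;
* unobserved — no chain spans the slot;
* ambiguous — observations fit none of the above (e.g. co-occurring
  variants, or a multi-variant slot sometimes skipped entirely).

Implication constraints ("A present forces B present") are emitted when B
occurs in 100% of the chains containing A, with the number of supporting
chains attached, mirroring how a handful of contigs can pin down rules
such as an optional exon always being followed by one specific terminal
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import SpliceConstraint

__all__ = [
    "TranscriptChain",
    "ExonClassification",
    "InferredConstraint",
    "classify_exons",
    "infer_implications",
    "ChainOrderError",
    "read_chains_tsv",
    "write_chains_tsv",
]


class ChainOrderError(ValueError):
    """A chain's exons are not in increasing slot order."""


@dataclass(frozen=True)
class TranscriptChain:
    id: str
    exon_ids: tuple[str, ...]

    def span(self, slot_map: Mapping[str, int]) -> tuple[int, int]:
        slots = [slot_map[e] for e in self.exon_ids if e in slot_map]
        if not slots:
            raise ValueError(f"chain {self.id}: no exon maps to a known slot")
        return min(slots), max(slots)


@dataclass
class SlotCall:
    slot: int
    call: str  # constitutive | optional | cluster | unobserved | ambiguous
    members: frozenset[str] = frozenset()
    n_spanning: int = 0


@dataclass
class ExonClassification:
    calls: dict[int, SlotCall] = field(default_factory=dict)
    novel_ids: frozenset[str] = frozenset()

    def of(self, slot: int) -> str:
        return self.calls[slot].call

    def members(self, slot: int) -> frozenset[str]:
        return self.calls[slot].members


def _check_order(chain: TranscriptChain, slot_map: Mapping[str, int]) -> None:
    slots = [slot_map[e] for e in chain.exon_ids if e in slot_map]
    # equal slots are allowed: a contig showing two variants of one slot is
    # evidence of co-occurrence, which classification must see (ambiguous)
    for a, b in zip(slots, slots[1:]):
        if b < a:
            raise ChainOrderError(
                f"chain {chain.id}: slot {b} follows slot {a} "
                f"(exon order inconsistent with gene order)")


def classify_exons(chains: Sequence[TranscriptChain],
                   slot_map: Mapping[str, int]) -> ExonClassification:
    """Deterministic per-slot classification from transcript evidence."""
    if not chains:
        raise ValueError("need at least one chain")
    novel = frozenset(
        e for c in chains for e in c.exon_ids if e not in slot_map)
    for c in chains:
        _check_order(c, slot_map)
    all_slots = sorted(set(slot_map.values()))
    result = ExonClassification(novel_ids=novel)
    for slot in all_slots:
        ids_here = {e for e, s in slot_map.items() if s == slot}
        spanning = [c for c in chains
                    if c.span(slot_map)[0] <= slot <= c.span(slot_map)[1]]
        if not spanning:
            result.calls[slot] = SlotCall(slot, "unobserved")
            continue
        observed: set[str] = set()
        per_chain_counts: list[int] = []
        co_occur = False
        for c in spanning:
            present = [e for e in c.exon_ids if e in ids_here]
            observed.update(present)
            per_chain_counts.append(len(present))
            if len(present) > 1:
                co_occur = True
        members = frozenset(observed)
        n = len(spanning)
        if co_occur:
            call = "ambiguous"
        elif len(observed) >= 2:
            # multiple variants, never co-occurring
            call = "cluster" if all(k == 1 for k in per_chain_counts) else "ambiguous"
        elif len(observed) == 1:
            if all(k == 1 for k in per_chain_counts):
                call = "constitutive"
            elif any(k == 1 for k in per_chain_counts):
                call = "optional"  # >=1 presence and >=1 absence
            else:  # pragma: no cover - unreachable (observed nonempty)
                call = "ambiguous"
        else:
            # slot spanned but none of its exons ever seen; an optional call
            # would need at least one presence, so flag instead
            call = "ambiguous" if ids_here else "unobserved"
            members = frozenset(ids_here)
        result.calls[slot] = SlotCall(slot, call, members, n)
    return result


@dataclass(frozen=True)
class InferredConstraint:
    constraint: SpliceConstraint
    support: int


def infer_implications(chains: Sequence[TranscriptChain],
                       slot_map: Mapping[str, int],
                       min_support: int = 3,
                       classification: Optional[ExonClassification] = None,
                       ) -> list[InferredConstraint]:
    """Emit ``A implies B`` whenever B is present in every chain containing A.

    Only non-constitutive antecedents and consequents are reported (a rule
    whose consequent is constitutive is vacuous), and rules supported by
    fewer than ``min_support`` chains are withheld — a small-sample guard
    motivated by surveys of only a few dozen contigs.
    """
    if classification is None:
        classification = classify_exons(chains, slot_map)
    variable_ids: set[str] = set()
    for slot, call in classification.calls.items():
        if call.call in ("optional", "cluster"):
            variable_ids.update(call.members)
    out: list[InferredConstraint] = []
    for a in sorted(variable_ids):
        carriers = [c for c in chains if a in c.exon_ids]
        if not carriers:
            continue
        for b in sorted(variable_ids):
            if b == a or slot_map[b] == slot_map[a]:
                continue
            # only judge chains that actually span B's slot
            sb = slot_map[b]
            judged = [c for c in carriers
                      if c.span(slot_map)[0] <= sb <= c.span(slot_map)[1]]
            if not judged or len(judged) < min_support:
                continue
            if all(b in c.exon_ids for c in judged):
                out.append(InferredConstraint(
                    SpliceConstraint("implies", a, b), support=len(judged)))
    return out


# -- plain-text chain format ---------------------------------------------------


def read_chains_tsv(path) -> list[TranscriptChain]:
    """TSV with columns: transcript_id, comma-separated exon ids."""
    chains = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("transcript_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            chains.append(TranscriptChain(parts[0], tuple(parts[1].split(","))))
    return chains


def write_chains_tsv(chains: Sequence[TranscriptChain], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\texon_ids\n")
        for c in chains:
            fh.write(f"{c.id}\t{','.join(c.exon_ids)}\n")
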