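"""Exact isoform counting and enumeration under splice constraints.

The isoform space of a :class:`~splicemosaic.model.GeneModel` is the set of
valid selections: one variant per mutually exclusive cluster, an
include/skip decision per optional exon, and a terminator.  Counting is
exact (Python integers): constraint-free slots contribute closed-form
factors (cluster arity, 2 per optional exon) and constraint-connected slot
groups are enumerated exhaustively, so the count stays fast even for
genes with tens of millions of isoforms.

A retained-intron terminator splits the gene at its ``after_slot`` into an
upstream ("extracellular") part and a downstream ("tail") part: membrane
bound isoforms combine one configuration from each, while intron-retained
isoforms are truncated after the boundary slot and carry no tail choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Optional

from .model import (
    GeneModel,
    InvalidModelError,
    SlotSpec,
    Terminator,
    validate_model,
)

__all__ = [
    "IsoformSpec",
    "IsoformCount",
    "count_isoforms",
    "enumerate_isoforms",
    "classify_isoform",
    "EnumerationTruncated",
]


class EnumerationTruncated(RuntimeError):
    """Raised when enumeration would exceed the caller's limit."""


@dataclass(frozen=True)
class IsoformSpec:
    """One valid isoform selection.

    ``cluster_choices`` maps cluster slot -> chosen variant id;
    ``optional_included`` is the set of included optional slots.  For a
    ``tail_less`` spec both cover only slots up to the retained intron.
    """

    cluster_choices: tuple[tuple[int, str], ...]
    optional_included: frozenset[int]
    terminator: Terminator
    tail_less: bool = False

    @property
    def choices(self) -> dict[int, str]:
        return dict(self.cluster_choices)

    def exon_ids(self, model: GeneModel) -> list[str]:
        """Ordered exon identities of the mature transcript."""
        boundary = _boundary(model)
        chosen = self.choices
        out: list[str] = []
        for s in model.slots:
            if self.tail_less and boundary is not None and s.slot > boundary:
                break
            if s.kind == "constitutive" or s.kind == "placeholder":
                out.append(s.variants[0] if s.variants else str(s.slot))
            elif s.kind == "optional":
                if s.slot in self.optional_included:
                    out.append(s.variants[0] if s.variants else str(s.slot))
            elif s.kind == "cluster":
                out.append(chosen[s.slot])
        return out


@dataclass(frozen=True)
class IsoformCount:
    n_extracellular: int
    n_tail: int
    n_membrane_bound: int
    n_tail_less: int
    n_total: int
    diagnostic: Optional[str] = None


# -- helpers -------------------------------------------------------------------


def _boundary(model: GeneModel) -> Optional[int]:
    """Slot number after which the gene splits into extracellular vs tail."""
    ri = model.retained_intron()
    if ri is not None:
        return ri.after_slot
    tails = [s.slot for s in model.slots if s.region_tag == "tail"]
    if tails:
        return min(tails) - 1
    return None


def _variable_slots(model: GeneModel) -> list[SlotSpec]:
    return [s for s in model.slots if s.kind in ("cluster", "optional")]


def _presence(model: GeneModel, exon_id: str, assignment: dict[int, Optional[str]],
              active_slots: set[int]) -> Optional[bool]:
    """Is `exon_id` present, given a (partial) assignment over variable slots?

    Returns None when the identity's slot is variable but unassigned.
    Identities in slots outside `active_slots` (e.g. tail exons of a
    truncated isoform) are absent.  Constitutive exons are always present.
    """
    ev = model.exons.get(exon_id)
    if ev is None:
        return False
    if ev.slot not in active_slots:
        return False
    spec = model.slot_spec(ev.slot)
    if spec.kind == "constitutive":
        return True
    if spec.kind == "placeholder":
        return False
    if ev.slot not in assignment:
        return None
    chosen = assignment[ev.slot]
    if spec.kind == "optional":
        return chosen is not None
    return chosen == exon_id


def _constraints_ok(model: GeneModel, assignment: dict[int, Optional[str]],
                    active_slots: set[int]) -> bool:
    for c in model.constraints:
        a = _presence(model, c.antecedent, assignment, active_slots)
        b = _presence(model, c.consequent, assignment, active_slots)
        if a is None or b is None:
            continue  # not yet decidable (partial assignment)
        if c.kind == "implies" and a and not b:
            return False
        if c.kind == "forbids" and a and b:
            return False
    return True


def _slot_options(s: SlotSpec) -> list[Optional[str]]:
    """Deterministic option order: skip-before-include, variants as listed."""
    if s.kind == "optional":
        return [None, s.variants[0] if s.variants else str(s.slot)]
    return list(s.variants)


def _components(model: GeneModel, slots: list[SlotSpec]) -> list[list[SlotSpec]]:
    """Group variable slots connected by constraints (union-find)."""
    idx = {s.slot: i for i, s in enumerate(slots)}
    parent = list(range(len(slots)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for c in model.constraints:
        sa = model.exons[c.antecedent].slot if c.antecedent in model.exons else None
        sb = model.exons[c.consequent].slot if c.consequent in model.exons else None
        if sa in idx and sb in idx:
            union(idx[sa], idx[sb])
    groups: dict[int, list[SlotSpec]] = {}
    for i, s in enumerate(slots):
        groups.setdefault(find(i), []).append(s)
    return [sorted(g, key=lambda s: s.slot) for g in groups.values()]


def _count_region(model: GeneModel, slots: list[SlotSpec],
                  active_slots: set[int]) -> int:
    """Exact count of valid configurations over the given variable slots."""
    total = 1
    constrained_slots = set()
    for c in model.constraints:
        for ref in (c.antecedent, c.consequent):
            if ref in model.exons:
                constrained_slots.add(model.exons[ref].slot)
    for group in _components(model, slots):
        if len(group) == 1 and group[0].slot not in constrained_slots:
            s = group[0]
            total *= 2 if s.kind == "optional" else len(s.variants)
            continue
        # brute-force the constrained group
        n = 0
        options = [_slot_options(s) for s in group]
        for combo in product(*options):
            assignment = {s.slot: ch for s, ch in zip(group, combo)}
            if _constraints_ok(model, assignment, active_slots):
                n += 1
        total *= n
    return total


def _require_valid(model: GeneModel) -> None:
    violations = validate_model(model)
    if violations:
        raise InvalidModelError("; ".join(map(str, violations)))


# -- public operations ---------------------------------------------------------


def count_isoforms(model: GeneModel) -> IsoformCount:
    """Exact isoform count, split by terminator class.

    ``n_membrane_bound = n_extracellular * n_tail``; intron-retained
    (tail-less) isoforms contribute one per extracellular configuration
    when the model declares a retained-intron terminator.
    """
    _require_valid(model)
    boundary = _boundary(model)
    var = _variable_slots(model)
    all_slots = {s.slot for s in model.slots}
    if boundary is None:
        ext_slots, tail_slots = var, []
        ext_active, tail_active = all_slots, set()
    else:
        ext_slots = [s for s in var if s.slot <= boundary]
        tail_slots = [s for s in var if s.slot > boundary]
        ext_active = {s for s in all_slots if s <= boundary}
        tail_active = all_slots
    n_ext = _count_region(model, ext_slots, ext_active)
    n_tail = _count_region(model, tail_slots, tail_active) if tail_slots else 1
    n_mb = n_ext * n_tail
    n_tl = n_ext if model.retained_intron() is not None else 0
    diag = None
    if n_mb == 0 and n_tl == 0:
        diag = "unsatisfiable constraints: no valid isoform"
    return IsoformCount(
        n_extracellular=n_ext,
        n_tail=n_tail,
        n_membrane_bound=n_mb,
        n_tail_less=n_tl,
        n_total=n_mb + n_tl,
        diagnostic=diag,
    )


def _enumerate_region(model: GeneModel, slots: list[SlotSpec],
                      active_slots: set[int]) -> Iterator[dict[int, Optional[str]]]:
    """Slot-major enumeration of valid assignments over `slots`."""
    options = [_slot_options(s) for s in slots]
    for combo in product(*options):
        assignment = {s.slot: ch for s, ch in zip(slots, combo)}
        if _constraints_ok(model, assignment, active_slots):
            yield assignment


def _spec_from(assignment: dict[int, Optional[str]], model: GeneModel,
               terminator: Terminator, tail_less: bool) -> IsoformSpec:
    choices = tuple(
        (slot, vid) for slot, vid in sorted(assignment.items()) if vid is not None
        and model.slot_spec(slot).kind == "cluster"
    )
    included = frozenset(
        slot for slot, vid in assignment.items()
        if vid is not None and model.slot_spec(slot).kind == "optional"
    )
    return IsoformSpec(cluster_choices=choices, optional_included=included,
                       terminator=terminator, tail_less=tail_less)


def enumerate_isoforms(model: GeneModel, limit: Optional[int] = None,
                       include_tail_less: bool = True) -> Iterator[IsoformSpec]:
    """Yield every valid isoform exactly once, in deterministic slot-major
    order (membrane-bound first, then intron-retained forms).

    Raises :class:`EnumerationTruncated` as soon as `limit` would be
    exceeded — truncation is never silent.
    """
    _require_valid(model)
    boundary = _boundary(model)
    var = _variable_slots(model)
    all_slots = {s.slot for s in model.slots}
    stop_terms = [t for t in model.terminators if t.kind == "stop_variant"]
    ri = model.retained_intron()

    def pick_stop_terminator(assignment: dict[int, Optional[str]]) -> Terminator:
        chosen = {v for v in assignment.values() if v is not None}
        for t in stop_terms:
            if t.variant_id in chosen:
                return t
        if stop_terms:
            return stop_terms[0]
        return Terminator(kind="stop_variant", variant_id=None)

    n = 0
    for assignment in _enumerate_region(model, var, all_slots):
        n += 1
        if limit is not None and n > limit:
            raise EnumerationTruncated(f"more than {limit} isoforms")
        yield _spec_from(assignment, model, pick_stop_terminator(assignment), False)
    if include_tail_less and ri is not None and boundary is not None:
        ext = [s for s in var if s.slot <= boundary]
        ext_active = {s for s in all_slots if s <= boundary}
        for assignment in _enumerate_region(model, ext, ext_active):
            n += 1
            if limit is not None and n > limit:
                raise EnumerationTruncated(f"more than {limit} isoforms")
            yield _spec_from(assignment, model, ri, True)


def classify_isoform(spec: IsoformSpec) -> str:
    """'tail_less' for intron-retained isoforms, else 'membrane_bound'."""
    if spec.tail_less or spec.terminator.kind == "retained_intron":
        return "tail_less"
    return "membrane_bound"
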