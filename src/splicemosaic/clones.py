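"""Assignment of amplicon clone sequences to exon variants and per-tissue
presence/absence tallies.

An amplicon spanning one or more mutually exclusive clusters carries
exactly one variant of each covered cluster.  Each clone is compared
against every variant of each cluster by infix alignment identity
(the variant must align within the clone, since the amplicon includes
primer-bounded constitutive context); a cluster vote requires a unique
best hit at or above an identity threshold, otherwise the clone is
ambiguous (tie) or unassigned (low identity) for that cluster.
The tally aggregates assigned votes into a variants x tissues detection
matrix and reports variants never detected per tissue and overall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import pandas as pd

from .model import GeneModel

__all__ = [
    "ClusterVote",
    "CloneAssignment",
    "DetectionMatrix",
    "assign_clone",
    "tally_matrix",
]


@dataclass(frozen=True)
class ClusterVote:
    slot: int
    variant_id: Optional[str]
    identity: float
    status: str  # assigned | ambiguous | unassigned


@dataclass(frozen=True)
class CloneAssignment:
    clone_id: str
    tissue: str
    votes: tuple[ClusterVote, ...]

    def vote(self, slot: int) -> ClusterVote:
        for v in self.votes:
            if v.slot == slot:
                return v
        raise KeyError(f"no vote for cluster slot {slot}")


def _infix_identity(variant_seq: str, clone_seq: str) -> float:
    """Identity of the variant aligned as an infix of the clone."""
    d = edlib.align(variant_seq.upper(), clone_seq.upper(),
                    mode="HW", task="distance")["editDistance"]
    return 1.0 - d / len(variant_seq)


def assign_clone(clone_id: str, clone_seq: str, model: GeneModel,
                 tissue: str = "", threshold: float = 0.95,
                 clusters: Optional[Sequence[int]] = None) -> CloneAssignment:
    """Vote on each (covered) cluster by best infix alignment identity."""
    if not clone_seq:
        raise ValueError(f"clone {clone_id}: empty sequence")
    slots = list(clusters) if clusters is not None else \
        [s.slot for s in model.cluster_slots()]
    votes: list[ClusterVote] = []
    for slot in slots:
        spec = model.slot_spec(slot)
        scored: list[tuple[float, str]] = []
        for vid in spec.variants:
            seq = model.exons[vid].sequence
            if seq is None:
                continue
            scored.append((_infix_identity(seq, clone_seq), vid))
        if not scored:
            votes.append(ClusterVote(slot, None, 0.0, "unassigned"))
            continue
        scored.sort(key=lambda t: (-t[0], t[1]))
        best_id, best_vid = scored[0]
        tie = len(scored) > 1 and scored[1][0] == best_id
        if best_id < threshold:
            votes.append(ClusterVote(slot, None, best_id, "unassigned"))
        elif tie:
            votes.append(ClusterVote(slot, None, best_id, "ambiguous"))
        else:
            votes.append(ClusterVote(slot, best_vid, best_id, "assigned"))
    return CloneAssignment(clone_id, tissue, tuple(votes))


@dataclass
class DetectionMatrix:
    """Per-cluster variant x tissue detection counts.

    ``counts`` has one row per variant id and one column per tissue;
    ``undetected`` maps tissue -> sorted variant ids with zero count, and
    ``undetected_overall`` lists variants detected in no tissue at all.
    Ambiguous/unassigned votes are excluded from counts and reported in
    ``n_ambiguous`` / ``n_unassigned``.
    """

    slot: int
    counts: pd.DataFrame
    undetected: dict[str, list[str]] = field(default_factory=dict)
    undetected_overall: list[str] = field(default_factory=list)
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0

    def long_format(self) -> pd.DataFrame:
        """Heat-map-ready long table: variant, tissue, count, detected."""
        df = self.counts.reset_index().melt(
            id_vars="variant", var_name="tissue", value_name="count")
        df["detected"] = df["count"] > 0
        return df


def tally_matrix(assignments: Sequence[CloneAssignment], model: GeneModel,
                 slot: int) -> DetectionMatrix:
    """Detection matrix for one cluster from a set of clone assignments."""
    if not assignments:
        raise ValueError("need at least one assignment")
    spec = model.slot_spec(slot)
    tissues = sorted({a.tissue for a in assignments})
    counts = pd.DataFrame(0, index=pd.Index(spec.variants, name="variant"),
                          columns=tissues, dtype=int)
    n_as = n_am = n_un = 0
    for a in assignments:
        try:
            v = a.vote(slot)
        except KeyError:
            continue
        if v.status == "assigned":
            counts.loc[v.variant_id, a.tissue] += 1
            n_as += 1
        elif v.status == "ambiguous":
            n_am += 1
        else:
            n_un += 1
    undetected = {t: [vid for vid in spec.variants if counts.loc[vid, t] == 0]
                  for t in tissues}
    overall = [vid for vid in spec.variants
               if int(counts.loc[vid].sum()) == 0]
    return DetectionMatrix(slot=slot, counts=counts, undetected=undetected,
                           undetected_overall=overall, n_assigned=n_as,
                           n_ambiguous=n_am, n_unassigned=n_un)
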