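"""Seeded synthetic instances for every analysis stage.

The generator emulates a variant-survey design around a Dscam-like gene: a
genome carrying tandem arrays of near-duplicate exon variants with
canonical GT-AG intron boundaries, a gene model with mutually exclusive
clusters / optional exons / splice constraints, transcript exon chains
sampled from the model, and an amplicon clone survey (individuals x
clones x tissues, substitution errors only).  Every output comes with a
truth record and is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .evidence import TranscriptChain
from .isoforms import IsoformSpec, enumerate_isoforms
from .model import (
    ExonVariant,
    GeneModel,
    SlotSpec,
    SpliceConstraint,
)
from .translation import CODON_TABLE

__all__ = [
    "SimConfig",
    "SimulatedGene",
    "simulate_gene",
    "simulate_transcripts",
    "simulate_clone_survey",
    "reverse_translate",
    "encode_dual_frame",
    "mutate_peptide",
    "CloneRecord",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codon options per residue, deterministic order
_CODONS: dict[str, list[str]] = {}
for _c, _aa in sorted(CODON_TABLE.items()):
    _CODONS.setdefault(_aa, []).append(_c)
# non-stop codons for random coding filler
_CODING = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Survey-design parameters for one synthetic instance.

    Defaults mirror the reference gene's architecture: three extracellular clusters of
    26, 81 and 26 variants, ~60-residue variants at ~0.7 pairwise
    identity, and a 10 individuals x 20 clones x 2 tissues survey with a
    small substitution error rate typical of amplicon cloning.
    """

    seed: int = 0
    cluster_sizes: tuple[int, ...] = (26, 81, 26)
    variant_length_aa: int = 60
    length_jitter_aa: int = 0
    identity: float = 0.7
    n_optional: int = 0
    constraints: tuple[SpliceConstraint, ...] = ()
    intron_length: int = 120
    n_individuals: int = 10
    clones_per_sample: int = 20
    tissues: tuple[str, ...] = ("hemocyte", "nerve")
    clone_error_rate: float = 0.002
    usage_weights: Optional[dict] = None  # tissue -> {slot -> {vid: w}}

    def validate(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ConfigError(f"identity {self.identity} outside [0,1]")
        if not 0.0 <= self.clone_error_rate <= 1.0:
            raise ConfigError(f"error rate {self.clone_error_rate} outside [0,1]")
        if self.variant_length_aa < 4:
            raise ConfigError("variant_length_aa must be >= 4")
        if self.length_jitter_aa >= self.variant_length_aa:
            raise ConfigError("length jitter as large as the variant length")


def reverse_translate(peptide: str, rng: Optional[np.random.Generator] = None,
                      stop: bool = False) -> str:
    """Peptide -> nucleotides; fixed (first) codon per residue unless an
    rng is given, in which case codons are drawn uniformly."""
    parts = []
    for aa in peptide + ("*" if stop else ""):
        opts = _CODONS[aa]
        parts.append(opts[0] if rng is None else opts[int(rng.integers(len(opts)))])
    return "".join(parts)


def mutate_peptide(peptide: str, identity: float,
                   rng: np.random.Generator,
                   frozen: Sequence[int] = ()) -> str:
    """Substitute residues so the result has ~`identity` to the input.

    ``frozen`` lists 0-based positions never touched (conserved anchors).
    """
    pep = list(peptide)
    mutable = [i for i in range(len(pep)) if i not in set(frozen)]
    n_mut = int(round((1.0 - identity) * len(pep)))
    n_mut = min(n_mut, len(mutable))
    for i in rng.choice(len(mutable), size=n_mut, replace=False):
        pos = mutable[int(i)]
        choices = AA20.replace(pep[pos], "")
        pep[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(pep)


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[int(i)] for i in rng.integers(0, 20, size=n))


def _random_intron(rng: np.random.Generator, n: int) -> str:
    """GT ... AG canonical intron; interior avoids AG/GT only by chance."""
    n = max(n, 6)
    interior = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=n - 4))
    return "GT" + interior + "AG"


@dataclass
class SimulatedGene:
    genome: str
    model: GeneModel
    truth: dict


def simulate_gene(config: SimConfig) -> SimulatedGene:
    """Build a genome + gene model with planted variant arrays.

    Cluster ancestors are random peptides; members are substitution
    mutants at the target identity, reverse-translated with random
    codons, planted in tandem with canonical GT-AG intron boundaries.
    The truth record holds every planted coordinate, peptide and realized
    identity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    slots: list[SlotSpec] = []
    exons: dict[str, ExonVariant] = {}
    genome_parts: list[str] = []
    pos = 0  # 0-based cursor
    truth: dict = {"clusters": {}, "optional": [], "constitutive": []}

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        genome_parts.append(seq)
        pos += len(seq)
        return start, pos

    def emit_intron() -> None:
        emit(_random_intron(rng, config.intron_length))

    slot_no = 0

    def add_single(kind: str) -> None:
        nonlocal slot_no
        slot_no += 1
        pep = _random_peptide(rng, max(4, config.variant_length_aa // 3))
        seq = reverse_translate(pep, rng)
        emit_intron() if slot_no > 1 else emit(
            "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=50)))
        s, e = emit(seq)
        eid = str(slot_no)
        exons[eid] = ExonVariant(eid, slot_no, s, e, "+", seq, synthetic=True,
                                 peptide=pep)
        slots.append(SlotSpec(slot_no, kind, [eid]))
        truth["optional" if kind == "optional" else "constitutive"].append(
            {"slot": slot_no, "start": s, "end": e})

    # leading constitutive exon, then each cluster separated by constitutive
    # exons, then optional exons
    add_single("constitutive")
    for size in config.cluster_sizes:
        slot_no += 1
        cluster_slot = slot_no
        L = config.variant_length_aa
        ancestor = _random_peptide(rng, L)
        members: list[str] = []
        crec = []
        truth.setdefault("ancestors", {})[cluster_slot] = ancestor
        for v in range(1, size + 1):
            jit = int(rng.integers(-config.length_jitter_aa,
                                   config.length_jitter_aa + 1)) \
                if config.length_jitter_aa else 0
            pep = mutate_peptide(ancestor, config.identity, rng)
            if jit > 0:
                pep = pep + _random_peptide(rng, jit)
            elif jit < 0:
                pep = pep[:jit]
            seq = reverse_translate(pep, rng)
            emit_intron()
            s, e = emit(seq)
            vid = f"{cluster_slot}.{v}"
            exons[vid] = ExonVariant(vid, cluster_slot, s, e, "+", seq,
                                     synthetic=True, peptide=pep)
            members.append(vid)
            crec.append({"id": vid, "start": s, "end": e, "peptide": pep})
        slots.append(SlotSpec(cluster_slot, "cluster", members))
        truth["clusters"][cluster_slot] = crec
        add_single("constitutive")
    for _ in range(config.n_optional):
        add_single("optional")
    emit("".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=50)))

    model = GeneModel(
        name=f"synthetic_gene_seed{config.seed}",
        slots=slots,
        exons=exons,
        constraints=list(config.constraints),
        terminators=[],
        genome="".join(genome_parts),
        genome_sequence_ref=f"synthetic_genome_seed{config.seed}",
    )
    return SimulatedGene(genome=model.genome, model=model, truth=truth)


def simulate_transcripts(model: GeneModel, n: int,
                         usage_weights: Optional[dict] = None,
                         seed: int = 0,
                         ) -> tuple[list[TranscriptChain], list[IsoformSpec]]:
    """Sample `n` valid isoforms and emit their exon chains + truth specs.

    ``usage_weights`` maps cluster slot -> {variant id: weight}; optional
    slots are included with probability 0.5.  Sampling is by enumeration
    weight over the valid isoform list for small models, which guarantees
    validity under any constraint set.
    """
    rng = np.random.default_rng(seed)
    specs = list(enumerate_isoforms(model, include_tail_less=False))
    if not specs:
        raise ValueError("model has no valid isoform")
    weights = np.ones(len(specs))
    if usage_weights:
        for i, sp in enumerate(specs):
            w = 1.0
            for slot, vid in sp.cluster_choices:
                w *= usage_weights.get(slot, {}).get(vid, 1.0)
            weights[i] = w
    if weights.sum() == 0:
        raise ValueError("usage weights exclude every valid isoform")
    p = weights / weights.sum()
    chains: list[TranscriptChain] = []
    sampled: list[IsoformSpec] = []
    for k in range(n):
        sp = specs[int(rng.choice(len(specs), p=p))]
        sampled.append(sp)
        chains.append(TranscriptChain(f"contig{k+1}", tuple(sp.exon_ids(model))))
    return chains, sampled


@dataclass(frozen=True)
class CloneRecord:
    id: str
    individual: int
    tissue: str
    sequence: str
    source_variants: tuple[tuple[int, str], ...]  # (cluster slot, variant id)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    hits = rng.random(len(s)) < rate
    for i in np.flatnonzero(hits):
        choices = "ACGT".replace(s[int(i)], "")
        s[int(i)] = choices[int(rng.integers(3))]
    return "".join(s)


def simulate_clone_survey(model: GeneModel, config: SimConfig,
                          ) -> tuple[list[CloneRecord], dict]:
    """Amplicon clone survey over the model's clusters.

    Each clone spans every cluster: its sequence is the concatenation of
    the chosen variant per cluster, joined by the constitutive exons lying
    between clusters (the primer-bounded amplicon backbone), with seeded
    substitution errors.  Per-tissue variant usage comes from
    ``config.usage_weights`` (tissue -> {slot -> {vid: weight}}); a zero
    weight makes a variant undetectable in that tissue, which the truth
    record tracks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    cluster_slots = [s.slot for s in model.cluster_slots()]
    if not cluster_slots:
        raise ValueError("model has no cluster slot")
    lo, hi = min(cluster_slots), max(cluster_slots)
    backbone = {
        s.slot: model.exons[s.variants[0]].sequence or ""
        for s in model.slots
        if s.kind == "constitutive" and lo < s.slot < hi
    }
    clones: list[CloneRecord] = []
    truth: dict = {"clones": [], "used_variants": {t: set() for t in config.tissues}}
    for ind in range(1, config.n_individuals + 1):
        for tissue in config.tissues:
            for k in range(1, config.clones_per_sample + 1):
                chosen: list[tuple[int, str]] = []
                parts: list[str] = []
                for s in model.slots:
                    if s.slot < lo or s.slot > hi:
                        continue
                    if s.kind == "cluster":
                        w = None
                        if config.usage_weights:
                            w = config.usage_weights.get(tissue, {}).get(s.slot)
                        if w:
                            probs = np.array([w.get(v, 1.0) for v in s.variants],
                                             dtype=float)
                        else:
                            probs = np.ones(len(s.variants))
                        probs = probs / probs.sum()
                        vid = s.variants[int(rng.choice(len(s.variants), p=probs))]
                        chosen.append((s.slot, vid))
                        parts.append(model.exons[vid].sequence or "")
                    elif s.kind == "constitutive":
                        parts.append(backbone.get(s.slot, ""))
                seq = _substitute("".join(parts), config.clone_error_rate, rng)
                cid = f"ind{ind}_{tissue}_clone{k}"
                clones.append(CloneRecord(cid, ind, tissue, seq, tuple(chosen)))
                truth["clones"].append({"id": cid, "tissue": tissue,
                                        "variants": dict(chosen)})
                truth["used_variants"][tissue].update(v for _, v in chosen)
    return clones, truth


# -- dual-frame encoding of overlapping terminal variants ---------------------


def encode_dual_frame(pep_a: str, pep_b: str,
                      offset: Optional[int] = None,
                      max_nodes: int = 50000) -> tuple[str, int]:
    """Nucleotides encoding `pep_a` (+stop) in frame 0 whose window at
    `offset` encodes `pep_b` (+stop) in a shifted frame.

    Models a terminal exon pair where the second variant's span is
    contained in (or extends into the 3'UTR of) the first: positions past
    ``pep_a``'s stop codon are unconstrained 3'UTR.  When ``offset`` is
    None the smallest feasible non-frame-0 offset is chosen by a
    deterministic, node-capped backtracking search.  Returns (sequence,
    offset); raises ``ValueError`` if no offset is feasible.
    """
    A = pep_a + "*"
    B = pep_b + "*"
    LA = 3 * len(A)

    def attempt(off: int) -> Optional[str]:
        LB = 3 * len(B)
        L = max(LA, off + LB)
        S: list[Optional[str]] = [None] * L
        nodes = 0

        def b_ok() -> bool:
            for j in range(len(B)):
                seg = S[off + 3 * j: off + 3 * j + 3]
                if all(x is None for x in seg):
                    continue
                if not any(all(x is None or x == c[k]
                               for k, x in enumerate(seg))
                           for c in _CODONS[B[j]]):
                    return False
            return True

        def rec(i: int) -> Optional[str]:
            nonlocal nodes
            nodes += 1
            if nodes > max_nodes:
                return None
            if i == len(A):
                for j in range(len(B)):
                    lo2 = off + 3 * j
                    seg = S[lo2:lo2 + 3]
                    for c in _CODONS[B[j]]:
                        if all(x is None or x == c[k]
                               for k, x in enumerate(seg)):
                            S[lo2:lo2 + 3] = list(c)
                            break
                    else:
                        return None
                return "".join(x if x is not None else "A" for x in S)
            for c in _CODONS[A[i]]:
                S[3 * i:3 * i + 3] = list(c)
                if b_ok():
                    r = rec(i + 1)
                    if r:
                        return r
            S[3 * i:3 * i + 3] = [None] * 3
            return None

        return rec(0)

    offsets = [offset] if offset is not None else \
        [d for d in range(1, LA) if d % 3 != 0]
    for off in offsets:
        s = attempt(off)
        if s is not None:
            return s, off
    raise ValueError(
        "no dual-frame encoding exists for these peptides at any offset")
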