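"""Mature-transcript assembly, translation and consensus-motif scanning.

Splicing is concatenation of the selected exon sequences in slot order;
for an intron-retained isoform the retained intron (which carries its own
stop codon) is appended after the boundary exon.  Translation uses the
standard genetic code and reports where — and in which exon — the first
stop codon arises, so that stop codons generated *across* a splice
junction (a hallmark of frame-shifting optional exons) are attributed to
the exon whose base completes the stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from Bio.Data.CodonTable import standard_dna_table

from .isoforms import IsoformSpec
from .model import GeneModel

__all__ = [
    "MotifPattern",
    "MotifHit",
    "StopInfo",
    "TranslationResult",
    "MatureTranscript",
    "splice",
    "splice_segments",
    "translate",
    "mature_transcript",
    "scan_motifs",
    "DEFAULT_MOTIFS",
    "UnknownSequenceError",
    "AmbiguousBaseError",
    "PatternSyntaxError",
]

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class UnknownSequenceError(ValueError):
    """An isoform selects an exon whose sequence is unknown."""


class AmbiguousBaseError(ValueError):
    def __init__(self, positions: list[int]):
        self.positions = positions
        super().__init__(f"non-ACGT bases at 1-based positions {positions}")


class PatternSyntaxError(ValueError):
    pass


# -- splicing ------------------------------------------------------------------


def splice_segments(model: GeneModel, spec: IsoformSpec,
                    skip_unknown: bool = False) -> list[tuple[str, int]]:
    """(exon_id, length) of each CDS segment in order.

    The retained intron of a tail-less isoform appears as a pseudo-segment
    ``"intron_after_<slot>"``.
    """
    segments: list[tuple[str, int]] = []
    for eid in spec.exon_ids(model):
        ev = model.exons[eid]
        if ev.sequence is None:
            if skip_unknown:
                continue
            raise UnknownSequenceError(
                f"exon {eid} (slot {ev.slot}) has unknown sequence")
        segments.append((eid, len(ev.sequence)))
    if spec.tail_less and spec.terminator.sequence is not None:
        segments.append(
            (f"intron_after_{spec.terminator.after_slot}",
             len(spec.terminator.sequence)))
    return segments


def splice(model: GeneModel, spec: IsoformSpec, skip_unknown: bool = False) -> str:
    """Assemble the CDS: selected exon sequences concatenated in slot order."""
    parts: list[str] = []
    for eid in spec.exon_ids(model):
        ev = model.exons[eid]
        if ev.sequence is None:
            if skip_unknown:
                continue
            raise UnknownSequenceError(
                f"exon {eid} (slot {ev.slot}) has unknown sequence")
        parts.append(ev.sequence)
    if spec.tail_less and spec.terminator.sequence is not None:
        parts.append(spec.terminator.sequence)
    return "".join(parts)


# -- translation ---------------------------------------------------------------


@dataclass(frozen=True)
class StopInfo:
    codon_index: int  # 1-based codon number of the stop
    nt_position: int  # 1-based CDS position of the stop codon's last base
    source_exon: Optional[str] = None  # exon whose base completes the stop


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    stop: Optional[StopInfo]

    @property
    def has_stop(self) -> bool:
        return self.stop is not None


def translate(cds: str) -> TranslationResult:
    """Standard-code translation from position 1 up to the first stop.

    A CDS without any in-frame stop is returned with ``stop=None``
    (flagged, not an error); trailing bases short of a codon are ignored.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS of length {len(cds)} is shorter than one codon")
    cds = cds.upper()
    bad = [i + 1 for i, b in enumerate(cds) if b not in "ACGT"]
    if bad:
        raise AmbiguousBaseError(bad)
    protein: list[str] = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i:i + 3]]
        if aa == "*":
            return TranslationResult(
                "".join(protein),
                StopInfo(codon_index=i // 3 + 1, nt_position=i + 3))
        protein.append(aa)
    return TranslationResult("".join(protein), None)


@dataclass(frozen=True)
class MatureTranscript:
    spec: IsoformSpec
    cds: str
    protein: str
    stop: Optional[StopInfo]
    annotations: tuple["MotifHit", ...] = ()


def mature_transcript(model: GeneModel, spec: IsoformSpec,
                      patterns: Optional[Sequence["MotifPattern"]] = None,
                      skip_unknown: bool = False) -> MatureTranscript:
    """Splice, translate and annotate one isoform.

    The stop codon is attributed to the segment containing its final base,
    so a stop spanning a splice junction belongs to the downstream exon.
    """
    cds = splice(model, spec, skip_unknown=skip_unknown)
    segments = splice_segments(model, spec, skip_unknown=skip_unknown)
    res = translate(cds)
    stop = res.stop
    if stop is not None:
        pos = stop.nt_position
        cum = 0
        source = None
        for eid, length in segments:
            cum += length
            if pos <= cum:
                source = eid
                break
        stop = StopInfo(stop.codon_index, stop.nt_position, source)
    hits: tuple[MotifHit, ...] = ()
    if patterns:
        hits = tuple(scan_motifs(res.protein, patterns))
    return MatureTranscript(spec=spec, cds=cds, protein=res.protein,
                            stop=stop, annotations=hits)


# -- motif scanning ------------------------------------------------------------


@dataclass(frozen=True)
class MotifPattern:
    """A consensus over residue classes: 'X' = any residue, '[...]' = any of.

    ``c_terminal`` anchors the match to the end of the sequence (PDZ-class
    ligands).  ``verbatim`` marks curated consensi, as opposed to package
    defaults.
    """

    name: str
    consensus: str
    c_terminal: bool = False
    verbatim: bool = True

    def classes(self) -> list[frozenset[str]]:
        out: list[frozenset[str]] = []
        i = 0
        s = self.consensus
        while i < len(s):
            ch = s[i]
            if ch == "[":
                j = s.find("]", i)
                if j < 0:
                    raise PatternSyntaxError(f"{self.name}: unclosed '[' in {s!r}")
                group = s[i + 1:j]
                if not group:
                    raise PatternSyntaxError(f"{self.name}: empty class in {s!r}")
                out.append(frozenset(group.upper()))
                i = j + 1
            elif ch.upper() == "X":
                out.append(frozenset(AA20))
                i += 1
            elif ch.upper() in AA20:
                out.append(frozenset(ch.upper()))
                i += 1
            else:
                raise PatternSyntaxError(f"{self.name}: bad symbol {ch!r} in {s!r}")
        if len(out) < 3:
            raise PatternSyntaxError(f"{self.name}: pattern shorter than 3 residues")
        return out


# Curated consensi: ITAM, ITIM, RGD.  The remaining interaction motifs
# have no curated consensus here; the defaults below are standard
# literature classes and are labeled non-curated in reports.
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("ITAM", "YXXL"),
    MotifPattern("ITIM", "[ISVL]XYXX[VL]"),
    MotifPattern("RGD", "RGD"),
    MotifPattern("SH2-binding", "YXX[LIV]", verbatim=False),
    MotifPattern("SH3-binding", "PXXP", verbatim=False),
    MotifPattern("polyproline", "PXXP", verbatim=False),
    MotifPattern("PDZ-ligand", "[ST]X[VLI]", c_terminal=True, verbatim=False),
)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    matched: str
    verbatim: bool = True


def _scan_one(seq_id: str, seq: str, pattern: MotifPattern) -> list[MotifHit]:
    classes = pattern.classes()
    k = len(classes)
    s = seq.upper()
    hits: list[MotifHit] = []
    starts = range(len(s) - k, len(s) - k + 1) if pattern.c_terminal \
        else range(len(s) - k + 1)
    for i in starts:
        if i < 0:
            continue
        if all(s[i + j] in classes[j] for j in range(k)):
            hits.append(MotifHit(seq_id, pattern.name, i + 1, i + k,
                                 s[i:i + k], pattern.verbatim))
    return hits


def scan_motifs(sequences: Union[str, Mapping[str, str]],
                patterns: Sequence[MotifPattern] = DEFAULT_MOTIFS) -> list[MotifHit]:
    """All (overlapping) consensus matches, 1-based spans.

    Accepts a single protein string or a mapping of id -> peptide for
    per-exon scanning.
    """
    if isinstance(sequences, str):
        sequences = {"query": sequences}
    hits: list[MotifHit] = []
    for sid, seq in sequences.items():
        for p in patterns:
            hits.extend(_scan_one(sid, seq, p))
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.motif))
    return hits
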