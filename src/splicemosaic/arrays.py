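"""Discovery of tandem arrays of near-duplicate exon variants in genomic DNA.

Hypervariable exon arrays (the source of mutually exclusive splicing
diversity) are tandem runs of paralogous exons flanked by canonical
splice sites.  The scanner enumerates candidate internal exons — windows
preceded by an AG acceptor and followed by a GT donor — whose lengths lie
within a band around the known variants' length, translates them, and
scores each against a peptide profile of known cluster members.
Overlapping candidates are resolved greedily by score and the survivors
are numbered in genomic order, matching the convention of naming exon
variants by their position in the gene.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import edlib

from .translation import CODON_TABLE

__all__ = [
    "AnchorSpec",
    "ArrayProfile",
    "ScanParams",
    "CandidateExon",
    "discover_array",
    "profile_similarity",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _translate_frame0(nt: str) -> str:
    return "".join(CODON_TABLE.get(nt[i:i + 3].upper(), "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))


@dataclass(frozen=True)
class AnchorSpec:
    """A conserved motif bounding the search region for an array."""

    name: str
    motif: str
    kind: str = "nucleotide"  # or "peptide"
    side: str = "internal"    # upstream | downstream | internal


@dataclass(frozen=True)
class ArrayProfile:
    """Peptides of known cluster members used to score candidates."""

    members: tuple[str, ...]

    def median_nt_length(self) -> int:
        return int(statistics.median(3 * len(m) for m in self.members))


@dataclass(frozen=True)
class ScanParams:
    min_similarity: float = 0.5
    length_band: float = 0.4        # +/- fraction of the profile median
    relaxed_band: float = 0.8       # abnormal-length candidates still reported
    require_splice_sites: bool = True
    anchor_pad: int = 2000          # search window around anchor hits
    strand: str = "+"


@dataclass(frozen=True)
class CandidateExon:
    start: int   # 1-based closed, on the forward strand of the input genome
    end: int
    strand: str
    acceptor: str
    donor: str
    peptide: str
    score: float
    variant_number: Optional[int] = None
    flag: Optional[str] = None  # e.g. "abnormal_length"


def profile_similarity(candidate_peptide: str, profile: ArrayProfile) -> float:
    """Best normalized alignment identity of the candidate against any
    profile member: 1 - edit_distance / max(len), in [0, 1]."""
    if not candidate_peptide:
        raise ValueError("empty candidate peptide")
    if not profile.members:
        raise ValueError("empty profile")
    best = 0.0
    for m in profile.members:
        d = edlib.align(candidate_peptide, m, task="distance")["editDistance"]
        denom = max(len(candidate_peptide), len(m))
        best = max(best, 1.0 - d / denom)
    return best


def _anchor_region(genome: str, anchors: Sequence[AnchorSpec],
                   pad: int) -> Optional[tuple[int, int]]:
    """0-based half-open envelope around all anchor hits, or None if no hit."""
    hits: list[int] = []
    for a in anchors:
        needle = a.motif.upper()
        if a.kind == "nucleotide":
            hay = genome.upper()
            i = hay.find(needle)
            while i >= 0:
                hits.extend((i, i + len(needle)))
                i = hay.find(needle, i + 1)
        else:
            # peptide anchors: scan all three frames
            for f in range(3):
                pep = _translate_frame0(genome[f:])
                j = pep.find(needle)
                while j >= 0:
                    hits.extend((f + 3 * j, f + 3 * (j + len(needle))))
                    j = pep.find(needle, j + 1)
    if not hits:
        return None
    return max(0, min(hits) - pad), min(len(genome), max(hits) + pad)


def _scan_forward(genome: str, profile: ArrayProfile, params: ScanParams,
                  region: tuple[int, int]) -> list[CandidateExon]:
    g = genome.upper()
    lo, hi = region
    med = profile.median_nt_length()
    lmin = max(3, int(round(med * (1 - params.length_band))))
    lmax = int(round(med * (1 + params.length_band)))
    rmin = max(3, int(round(med * (1 - params.relaxed_band))))
    rmax = int(round(med * (1 + params.relaxed_band)))
    # candidate exon starts: positions right after an AG acceptor
    starts = [i for i in range(max(lo, 2), hi)
              if g[i - 2:i] == "AG"] if params.require_splice_sites \
        else list(range(lo, hi))
    out: list[CandidateExon] = []
    for s in starts:
        # lengths stepped by 3 so candidates stay in frame with their start
        for L in range(rmin - rmin % 3, rmax + 1, 3):
            e = s + L  # 0-based exclusive end
            if e > hi:
                break
            if params.require_splice_sites and g[e:e + 2] != "GT":
                continue
            pep = _translate_frame0(g[s:e])
            if not pep or "*" in pep:
                continue
            score = profile_similarity(pep, profile)
            if score < params.min_similarity:
                continue
            flag = None if lmin <= L <= lmax else "abnormal_length"
            out.append(CandidateExon(
                start=s + 1, end=e, strand="+",
                acceptor=g[s - 2:s], donor=g[e:e + 2],
                peptide=pep, score=score, flag=flag))
    return out


def _resolve_overlaps(cands: list[CandidateExon],
                      median_length: int) -> list[CandidateExon]:
    """Greedy by score; ties prefer the length closest to the profile
    median (the scan's own length model), then the leftmost window."""
    kept: list[CandidateExon] = []
    for c in sorted(cands, key=lambda c: (-c.score,
                                          abs(c.end - c.start + 1 - median_length),
                                          c.start, c.end)):
        if all(c.end < k.start or c.start > k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


def discover_array(genome: str, anchors: Sequence[AnchorSpec],
                   profile: ArrayProfile,
                   params: ScanParams = ScanParams()) -> list[CandidateExon]:
    """Find a tandem exon array; candidates are numbered in genomic order.

    On the minus strand the reverse complement is scanned and coordinates
    are mapped back to the forward strand (so a mirrored genome yields
    mirrored intervals).
    """
    if not genome:
        raise ValueError("empty genome")
    work = genome if params.strand == "+" else reverse_complement(genome)
    if anchors:
        region = _anchor_region(work, anchors, params.anchor_pad)
        if region is None:
            warnings.warn("no anchor matched; returning no candidates")
            return []
    else:
        region = (0, len(work))
    cands = _resolve_overlaps(_scan_forward(work, profile, params, region),
                              profile.median_nt_length())
    if params.strand == "-":
        n = len(genome)
        cands = [replace(c, start=n - c.end + 1, end=n - c.start + 1,
                         strand="-")
                 for c in cands]
        cands.sort(key=lambda c: c.start)
    return [replace(c, variant_number=i + 1) for i, c in enumerate(cands)]
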