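"""Per-column conservation profiles and anchor-based epitope extraction.

For a protein multiple alignment, each column's conservation is measured
as information content IC = log2(20) - H, where H is the Shannon entropy
of the residue frequencies in that column (gaps excluded; the fraction of
non-gap residues is reported separately as occupancy).  This is the
quantity plotted on the y-axis of a sequence logo, in bits.

Epitope windows are defined relative to conserved *anchors*: either a
fixed alignment position with an expected residue set (e.g. an invariant
isoleucine at position 16) or a short conserved motif located by
consensus.  Position anchors count only non-empty alignment columns, so
padding the alignment with gap columns shifts extracted windows
consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ColumnProfile",
    "EpitopeRule",
    "EpitopeExtract",
    "column_profiles",
    "extract_epitopes",
    "profiles_frame",
    "AnchorResolutionError",
    "EXON4_EPITOPE_RULES",
    "EXON6_EPITOPE_RULES",
]

GAP_CHARS = {"-", "."}
LOG2_20 = math.log2(20)


class AnchorResolutionError(ValueError):
    """An epitope anchor could not be located on the alignment."""


def _as_rows(alignment: Union[Mapping[str, str], Sequence[str]]
             ) -> tuple[list[str], list[str]]:
    if isinstance(alignment, Mapping):
        ids, rows = list(alignment.keys()), list(alignment.values())
    else:
        rows = list(alignment)
        ids = [f"seq{i+1}" for i in range(len(rows))]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    L = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != L:
            raise ValueError(
                f"ragged alignment: sequence {ids[i]} has length {len(r)}, "
                f"expected {L}")
    return ids, [r.upper() for r in rows]


@dataclass(frozen=True)
class ColumnProfile:
    column: int  # 1-based alignment column
    frequencies: dict[str, float]
    entropy: float           # bits
    information_content: float  # bits: log2(20) - entropy
    occupancy: float         # non-gap fraction


def column_profiles(alignment: Union[Mapping[str, str], Sequence[str]],
                    small_sample_correction: bool = False
                    ) -> list[ColumnProfile]:
    """Residue frequencies, entropy and IC per column (20-letter alphabet).

    With ``small_sample_correction`` the usual logo correction
    (19 / (2 ln 2 n)) is subtracted from the IC, floored at 0.
    """
    _, rows = _as_rows(alignment)
    out: list[ColumnProfile] = []
    for j in range(len(rows[0])):
        residues = [r[j] for r in rows if r[j] not in GAP_CHARS]
        n = len(residues)
        occ = n / len(rows)
        if n == 0:
            out.append(ColumnProfile(j + 1, {}, LOG2_20, 0.0, 0.0))
            continue
        freqs: dict[str, float] = {}
        for a in residues:
            freqs[a] = freqs.get(a, 0.0) + 1.0
        for a in freqs:
            freqs[a] /= n
        p = np.array(list(freqs.values()))
        H = float(-(p * np.log2(p)).sum())
        ic = LOG2_20 - H
        if small_sample_correction:
            ic = max(0.0, ic - 19.0 / (2 * math.log(2) * n))
        out.append(ColumnProfile(j + 1, freqs, H, ic, occ))
    return out


def profiles_frame(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Logo-matrix layout: one row per column, one frequency column per
    residue, plus entropy/IC/occupancy."""
    alphabet = sorted({a for p in profiles for a in p.frequencies})
    rows = []
    for p in profiles:
        row = {"column": p.column, "entropy": p.entropy,
               "information_content": p.information_content,
               "occupancy": p.occupancy}
        for a in alphabet:
            row[a] = p.frequencies.get(a, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


# -- epitope extraction --------------------------------------------------------


@dataclass(frozen=True)
class EpitopeRule:
    """A window of alignment columns relative to a conserved anchor.

    ``anchor_position`` counts non-empty alignment columns (1-based); the
    residue at that column must be in ``anchor_residues`` for at least
    ``min_anchor_frac`` of the sequences.  Alternatively ``anchor_motif``
    names a short motif located where it matches the most sequences.
    ``side`` is "before" (window ends immediately before the anchor) or
    "after" (window starts immediately after it).
    """

    exon_slot: int
    epitope: str  # "I" or "II"
    window: int
    side: str
    anchor_position: Optional[int] = None
    anchor_residues: frozenset[str] = frozenset()
    anchor_motif: Optional[str] = None
    min_anchor_frac: float = 0.9

    def anchor_name(self) -> str:
        if self.anchor_motif:
            return f"motif {self.anchor_motif}"
        return f"{self.anchor_position}{'/'.join(sorted(self.anchor_residues))}"


# The hypervariable Ig2 exon-4 rules: epitope I is the ~12 residues ending
# just before the invariant 16I; epitope II the 13 residues after the
# conserved 41V.  For the Ig3 exon-6 cluster, epitope I is completed by
# the 8 residues after the conserved 9K/R and epitope II by the 8 residues
# before the conserved LLC motif.
EXON4_EPITOPE_RULES = (
    EpitopeRule(4, "I", window=12, side="before", anchor_position=16,
                anchor_residues=frozenset("I")),
    EpitopeRule(4, "II", window=13, side="after", anchor_position=41,
                anchor_residues=frozenset("V")),
)
EXON6_EPITOPE_RULES = (
    EpitopeRule(6, "I", window=8, side="after", anchor_position=9,
                anchor_residues=frozenset("KR")),
    EpitopeRule(6, "II", window=8, side="before", anchor_motif="LLC"),
)


@dataclass
class EpitopeExtract:
    rule: EpitopeRule
    columns: tuple[int, int]  # 1-based closed range of alignment columns
    sub_alignment: dict[str, str] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)  # seqs failing the anchor
    warning: Optional[str] = None


def _nonempty_columns(rows: list[str]) -> list[int]:
    """0-based indices of columns holding at least one residue."""
    return [j for j in range(len(rows[0]))
            if any(r[j] not in GAP_CHARS for r in rows)]


def _resolve_position_anchor(ids, rows, rule) -> tuple[int, list[str], Optional[str]]:
    cols = _nonempty_columns(rows)
    if rule.anchor_position > len(cols):
        raise AnchorResolutionError(
            f"anchor {rule.anchor_name()}: alignment has only "
            f"{len(cols)} non-empty columns")
    j = cols[rule.anchor_position - 1]
    hits = [ids[i] for i, r in enumerate(rows) if r[j] in rule.anchor_residues]
    flagged = [i_ for i_ in ids if i_ not in set(hits)]
    frac = len(hits) / len(rows)
    warning = None
    if frac < rule.min_anchor_frac:
        # tolerate when the stated residue set still dominates the column
        residues = [r[j] for r in rows if r[j] not in GAP_CHARS]
        modal = max(set(residues), key=residues.count) if residues else None
        if modal in rule.anchor_residues:
            warning = (f"anchor {rule.anchor_name()} present in only "
                       f"{frac:.0%} of sequences (still the modal residue)")
        else:
            raise AnchorResolutionError(
                f"anchor {rule.anchor_name()} resolved in only {frac:.0%} "
                f"of sequences (threshold {rule.min_anchor_frac:.0%})")
    return j, flagged, warning


def _resolve_motif_anchor(ids, rows, rule) -> tuple[int, list[str], Optional[str]]:
    motif = rule.anchor_motif.upper()
    k = len(motif)
    L = len(rows[0])
    best_j, best_frac = None, 0.0
    for j in range(L - k + 1):
        n = sum(1 for r in rows if r[j:j + k] == motif)
        frac = n / len(rows)
        if frac > best_frac:
            best_j, best_frac = j, frac
    if best_j is None or best_frac < rule.min_anchor_frac:
        raise AnchorResolutionError(
            f"anchor motif {motif!r} found in at most {best_frac:.0%} of "
            f"sequences (threshold {rule.min_anchor_frac:.0%})")
    flagged = [ids[i] for i, r in enumerate(rows)
               if r[best_j:best_j + k] != motif]
    return best_j, flagged, None


def extract_epitopes(alignment: Union[Mapping[str, str], Sequence[str]],
                     rules: Sequence[EpitopeRule]) -> list[EpitopeExtract]:
    """Cut the rule-defined windows out of the alignment.

    Sequences failing an anchor are listed in ``flagged`` but their window
    is still returned — nothing is silently dropped.
    """
    ids, rows = _as_rows(alignment)
    out: list[EpitopeExtract] = []
    for rule in rules:
        if rule.anchor_motif is not None:
            j, flagged, warning = _resolve_motif_anchor(ids, rows, rule)
            anchor_start, anchor_end = j, j + len(rule.anchor_motif) - 1
        else:
            j, flagged, warning = _resolve_position_anchor(ids, rows, rule)
            anchor_start = anchor_end = j
        if rule.side == "before":
            lo, hi = anchor_start - rule.window, anchor_start - 1
        elif rule.side == "after":
            lo, hi = anchor_end + 1, anchor_end + rule.window
        else:
            raise ValueError(f"bad side {rule.side!r}")
        if lo < 0 or hi >= len(rows[0]):
            raise AnchorResolutionError(
                f"epitope {rule.epitope} window [{lo + 1}, {hi + 1}] falls "
                f"outside the alignment")
        sub = {i_: r[lo:hi + 1] for i_, r in zip(ids, rows)}
        out.append(EpitopeExtract(rule=rule, columns=(lo + 1, hi + 1),
                                  sub_alignment=sub, flagged=flagged,
                                  warning=warning))
    return out
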