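"""Serialization of gene models: FASTA genome + GFF3 exons + YAML config.

The GFF3 file carries one ``exon`` feature per exon record with
attributes ``slot``, ``variant``, ``kind``, ``frame_offset`` and
``region``; placeholder exons additionally carry ``unknown_sequence=1``.
Constraints and terminators, which GFF3 cannot express, live in a YAML
sidecar.  Coordinates are 1-based closed (GFF3 convention); minus-strand
sequences are reverse-complemented on extraction.  ``save`` then ``load``
is the identity on every model field.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ExonVariant,
    GeneModel,
    SlotSpec,
    SpliceConstraint,
    Terminator,
)

__all__ = ["save_model", "load_model", "ModelParseError", "CoordinateError"]


class ModelParseError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


def _paths(directory: Union[str, Path]) -> tuple[Path, Path, Path]:
    d = Path(directory)
    return d / "model.yaml", d / "model.gff3", d / "genome.fa"


def save_model(model: GeneModel, directory: Union[str, Path]) -> None:
    """Write config YAML, exon GFF3 and genome FASTA into `directory`."""
    cfg_path, gff_path, fa_path = _paths(directory)
    os.makedirs(directory, exist_ok=True)

    if model.genome is not None:
        rec = SeqRecord(Seq(model.genome),
                        id=model.genome_sequence_ref or model.name,
                        description="")
        SeqIO.write([rec], str(fa_path), "fasta")

    seqid = model.genome_sequence_ref or model.name
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in model.slots:
            for vid in s.variants:
                ev = model.exons[vid]
                variant = vid.split(".", 1)[1] if "." in vid else "0"
                attrs = (f"ID={vid};slot={ev.slot};variant={variant};"
                         f"kind={s.kind};frame_offset={ev.frame_offset};"
                         f"region={s.region_tag}")
                if ev.sequence is None:
                    attrs += ";unknown_sequence=1"
                if ev.synthetic:
                    attrs += ";synthetic=1"
                fh.write("\t".join([
                    seqid, "splicemosaic", "exon", str(ev.start), str(ev.end),
                    ".", ev.strand, ".", attrs]) + "\n")

    cfg = {
        "name": model.name,
        "genome_sequence_ref": model.genome_sequence_ref,
        "slots": [
            {"slot": s.slot, "kind": s.kind, "variants": list(s.variants),
             "region_tag": s.region_tag}
            for s in model.slots
        ],
        "constraints": [
            {"kind": c.kind, "antecedent": c.antecedent,
             "consequent": c.consequent}
            for c in model.constraints
        ],
        "terminators": [
            {"kind": t.kind, "after_slot": t.after_slot,
             "variant_id": t.variant_id, "sequence": t.sequence}
            for t in model.terminators
        ],
        "peptides": {
            vid: ev.peptide for vid, ev in model.exons.items()
            if ev.peptide is not None
        },
    }
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_model(directory: Union[str, Path]) -> GeneModel:
    """Inverse of :func:`save_model`; extracts exon sequences from the
    genome (reverse-complemented on the minus strand)."""
    cfg_path, gff_path, fa_path = _paths(directory)
    for p in (cfg_path, gff_path, fa_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    records = list(SeqIO.parse(str(fa_path), "fasta"))
    if not records:
        raise ModelParseError(f"{fa_path}: no FASTA record")
    genome = str(records[0].seq)

    with open(gff_path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ModelParseError(
                    f"{gff_path}:{ln}: expected 9 columns, got {len(cols)}")
            try:
                s_, e_ = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ModelParseError(
                    f"{gff_path}:{ln}: non-integer coordinates") from exc
            if e_ < s_:
                raise CoordinateError(
                    f"{gff_path}:{ln}: end {e_} < start {s_}")

    try:
        db = gffutils.create_db(str(gff_path), ":memory:",
                                merge_strategy="error", keep_order=True)
    except Exception as exc:  # gffutils wraps line context in its message
        raise ModelParseError(f"{gff_path}: {exc}") from exc

    exons: dict[str, ExonVariant] = {}
    for feat in db.features_of_type("exon"):
        eid = feat.attributes["ID"][0]
        slot = int(feat.attributes["slot"][0])
        start, end = feat.start, feat.end
        if start > end:
            raise CoordinateError(f"exon {eid}: end {end} < start {start}")
        if start < 1 or end > len(genome):
            raise CoordinateError(
                f"exon {eid}: interval [{start}, {end}] outside genome of "
                f"length {len(genome)}")
        unknown = feat.attributes.get("unknown_sequence", ["0"])[0] == "1"
        if unknown:
            seq: Optional[str] = None
        else:
            seq = genome[start - 1:end]
            if feat.strand == "-":
                seq = str(Seq(seq).reverse_complement())
        exons[eid] = ExonVariant(
            id=eid, slot=slot, start=start, end=end,
            strand=feat.strand or "+", sequence=seq,
            frame_offset=int(feat.attributes.get("frame_offset", ["0"])[0]),
            peptide=cfg.get("peptides", {}).get(eid),
            synthetic=feat.attributes.get("synthetic", ["0"])[0] == "1",
        )

    slots = [SlotSpec(slot=d["slot"], kind=d["kind"],
                      variants=list(d["variants"]),
                      region_tag=d.get("region_tag", "extracellular"))
             for d in cfg.get("slots", [])]
    constraints = [SpliceConstraint(d["kind"], d["antecedent"], d["consequent"])
                   for d in cfg.get("constraints", [])]
    terminators = [Terminator(d["kind"], d.get("after_slot"),
                              d.get("variant_id"), d.get("sequence"))
                   for d in cfg.get("terminators", [])]
    return GeneModel(
        name=cfg["name"],
        slots=slots,
        exons=exons,
        constraints=constraints,
        terminators=terminators,
        genome=genome,
        genome_sequence_ref=cfg.get("genome_sequence_ref"),
    )
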