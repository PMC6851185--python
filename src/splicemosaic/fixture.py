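"""The packaged PmDscam worked example.

The shrimp (Penaeus monodon) Dscam gene is the worked example: 44 exon
slots, of which exon 1 was never identified (modeled as a placeholder),
31 exons are constitutive, 7 cytoplasmic-tail exons are optional, and 5
slots are mutually exclusive clusters — exon 4 (26 variants, N-terminal
Ig2), exon 6 (81, N-terminal Ig3), exon 15 (26, entire Ig7), exon 32 (2,
alternative transmembrane domains) and exon 44 (2, alternative stop
codons).  Including exon 43 forces terminal variant 44.1 and generates a
stop codon at 44.1's very first codon; retaining the intron after exon
31 (which carries its own stop and poly(A) signal) yields the secreted
tail-less form.

Cytoplasmic-tail amino-acid sequences are the curated ones (exons
31-44); extracellular nucleotide sequences are deterministic synthetic
stand-ins (the real sequences live in a sequence-database accession, not
in print) and are flagged ``synthetic`` on each record.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .model import (
    ExonVariant,
    GeneModel,
    SlotSpec,
    SpliceConstraint,
    Terminator,
)
from .simulate import (
    _random_intron,
    encode_dual_frame,
    mutate_peptide,
    reverse_translate,
    _random_peptide,
)

__all__ = ["TAIL_PEPTIDES", "build_pmdscam_fixture", "tail_submodel",
           "terminal_submodel", "extracellular_cluster_model"]

# Curated cytoplasmic-tail peptides (exons 31-44).  Stop codons are not
# part of the peptides: 43's stop is generated across the splice junction
# at 44.1's first codon, and 44.1/44.2 carry their own stops, all of
# which the fixture nucleotides reproduce.
TAIL_PEPTIDES: dict[str, str] = {
    "31": "VAEYEVATLTLTG",
    "32.1": "GTIAPAREVPAFGAGDLPIYLNLNLIVPVVSAVVVIVLAIVIICYLRGRNTPIK",
    "32.2": "ATLPPTVSDSRVTWLPDWWPKWLDLNVLVPVIATIVVIIVGIVVICVAVTRRKNGIENLR",
    "33": "EEVYQQYQYNASMPPPSTMDKRHPGFREELGYIPPPNRKLPPVPGSQYNTCDRIKR",
    "34": "GGGSGRGTHATWDPRRPMYEELSLHPPPGRRIPLGGPPQPLGSQDTLRS",
    "35": "GGDDEICPYATFHLLGFREEMDPQQAGNNFQTFPHQNGHGSQQHFVNSPASRSM",
    "36": "PRHGSGNYYSCVSGDYTCGHTPNEGHQ",
    "37": "PRHGSGNYYSCVAGEYGPGG",
    "38": "PPSSTYYSTVPGDMTASRMSNSTFSPTYDDPARSDEESDQYGGSTYSGGGPYARAIDSVSQSGTAKRLS",
    "39": "NGGHPPGAPVSGPQPSNHRFICK",
    "40": "RGSTSGSAGQGSPEPLPLDSSGLGSSLNDSNNSTASNQFSEAECDHDLVQRNYG",
    "41": "RHCAQTKP",
    "42": "VKATKSTEEMRKLLDK",
    "43": "KLNKT",
    "44.1": "NEAAAHIQNGGLRMVSDEMNV",
    "44.2": "EMKQLPTFKMEA",
}

EXTRACELLULAR_CLUSTERS = {4: 26, 6: 81, 15: 26}
TAIL_CLUSTERS = {32: 2, 44: 2}
OPTIONAL_SLOTS = (34, 36, 37, 39, 41, 42, 43)
TAIL_CONSTITUTIVE = (31, 33, 35, 38, 40)

_FIXTURE_SEED = 20190531  # fixed: the stand-ins are part of the fixture

# ancestor peptide lengths (aa) for the three extracellular clusters; the
# Ig7 cluster encodes a whole Ig domain, hence longer
_CLUSTER_LEN = {4: 60, 6: 60, 15: 100}
_CLUSTER_IDENTITY = 0.65


def _exon4_ancestor(rng: np.random.Generator) -> tuple[str, list[int]]:
    pep = list(_random_peptide(rng, _CLUSTER_LEN[4]))
    pep[15] = "I"   # conserved 16I (epitope I ends just before it)
    pep[40] = "V"   # conserved 41V (epitope II starts just after it)
    return "".join(pep), [15, 40]


def _exon6_ancestor(rng: np.random.Generator) -> tuple[str, list[int]]:
    pep = list(_random_peptide(rng, _CLUSTER_LEN[6]))
    pep[8] = "K"    # conserved 9K(R)
    pep[47:50] = list("LLC")  # conserved LLC motif (epitope II ends before it)
    return "".join(pep), [8, 47, 48, 49]


def _exon15_ancestor(rng: np.random.Generator) -> tuple[str, list[int]]:
    return _random_peptide(rng, _CLUSTER_LEN[15]), []


_ANCESTORS = {4: _exon4_ancestor, 6: _exon6_ancestor, 15: _exon15_ancestor}


@lru_cache(maxsize=1)
def build_pmdscam_fixture() -> GeneModel:
    """Assemble the full 44-slot gene model, genome included."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    slots: list[SlotSpec] = []
    exons: dict[str, ExonVariant] = {}
    parts: list[str] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        start = pos + 1
        pos += len(seq)
        return start, pos

    def intron() -> None:
        emit(_random_intron(rng, 100))

    # slot 1: placeholder for the unidentified exon (sequence unknown)
    s1, e1 = emit("".join("ACGT"[int(i)] for i in rng.integers(0, 4, 60)))
    exons["1"] = ExonVariant("1", 1, s1, e1, "+", None, synthetic=True)
    slots.append(SlotSpec(1, "placeholder", ["1"]))

    def add_constitutive(slot: int, peptide: str, region: str) -> None:
        seq = reverse_translate(peptide)
        intron()
        s, e = emit(seq)
        eid = str(slot)
        exons[eid] = ExonVariant(eid, slot, s, e, "+", seq, peptide=peptide,
                                 synthetic=region == "extracellular")
        slots.append(SlotSpec(slot, "constitutive", [eid], region_tag=region))

    def add_optional(slot: int, peptide: str, seq=None) -> None:
        seq = seq if seq is not None else reverse_translate(peptide)
        intron()
        s, e = emit(seq)
        eid = str(slot)
        exons[eid] = ExonVariant(eid, slot, s, e, "+", seq, peptide=peptide)
        slots.append(SlotSpec(slot, "optional", [eid], region_tag="tail"))

    def add_cluster(slot: int) -> None:
        ancestor, frozen = _ANCESTORS[slot](rng)
        members: list[str] = []
        for v in range(1, EXTRACELLULAR_CLUSTERS[slot] + 1):
            pep = mutate_peptide(ancestor, _CLUSTER_IDENTITY, rng,
                                 frozen=frozen)
            if slot == 6:
                pep = pep[:8] + ("R" if v % 3 == 0 else "K") + pep[9:]
            if slot == 15 and v == 13:
                # one Ig7 variant of abnormal length
                pep = pep + _random_peptide(rng, 25)
            seq = reverse_translate(pep, rng)
            intron()
            s, e = emit(seq)
            vid = f"{slot}.{v}"
            exons[vid] = ExonVariant(vid, slot, s, e, "+", seq, peptide=pep,
                                     synthetic=True)
            members.append(vid)
        slots.append(SlotSpec(slot, "cluster", members))

    # --- extracellular region: slots 2..31 -----------------------------------
    for slot in range(2, 31):
        if slot in EXTRACELLULAR_CLUSTERS:
            add_cluster(slot)
        else:
            pep = _random_peptide(rng, int(rng.integers(40, 90)))
            add_constitutive(slot, pep, "extracellular")
    add_constitutive(31, TAIL_PEPTIDES["31"], "tail")

    # --- retained intron after exon 31: stop + poly(A) signal ----------------
    ri_interior = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 40))
    retained = "GT" + "A" + "TAA" + ri_interior + "AATAAA" + \
        "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 30)) + "AG"
    emit(retained)

    # --- cytoplasmic tail: slots 32..44 --------------------------------------
    tm_members = []
    for v in (1, 2):
        pep = TAIL_PEPTIDES[f"32.{v}"]
        seq = reverse_translate(pep)
        if v > 1:
            intron()
        s, e = emit(seq)
        vid = f"32.{v}"
        exons[vid] = ExonVariant(vid, 32, s, e, "+", seq, peptide=pep)
        tm_members.append(vid)
    slots.append(SlotSpec(32, "cluster", tm_members, region_tag="tail"))

    for slot in range(33, 43):
        pep = TAIL_PEPTIDES[str(slot)]
        if slot in OPTIONAL_SLOTS:
            add_optional(slot, pep)
        else:
            add_constitutive(slot, pep, "tail")

    # exon 43 ends with two dangling bases; spliced onto 44.1 (whose first
    # base is A) they complete the junction stop codon TAA
    seq43 = reverse_translate(TAIL_PEPTIDES["43"]) + "TA"
    add_optional(43, TAIL_PEPTIDES["43"], seq=seq43)

    # exon 44: variant 44.2 is contained within 44.1's span, read in a
    # shifted frame (its stop falls in 44.1's 3'UTR region)
    dual, offset = encode_dual_frame(TAIL_PEPTIDES["44.1"],
                                     TAIL_PEPTIDES["44.2"], max_nodes=2000)
    intron()
    s, e = emit(dual)
    exons["44.1"] = ExonVariant("44.1", 44, s, e, "+", dual,
                                peptide=TAIL_PEPTIDES["44.1"])
    s2 = s + offset
    e2 = s2 + 3 * (len(TAIL_PEPTIDES["44.2"]) + 1) - 1
    exons["44.2"] = ExonVariant("44.2", 44, s2, e2, "+",
                                dual[offset:offset + (e2 - s2 + 1)],
                                frame_offset=offset % 3,
                                peptide=TAIL_PEPTIDES["44.2"])
    slots.append(SlotSpec(44, "cluster", ["44.1", "44.2"], region_tag="tail"))
    emit("".join("ACGT"[int(i)] for i in rng.integers(0, 4, 60)))

    model = GeneModel(
        name="PmDscam",
        slots=slots,
        exons=exons,
        constraints=[SpliceConstraint("implies", "43", "44.1")],
        terminators=[
            Terminator("retained_intron", after_slot=31, sequence=retained),
            Terminator("stop_variant", variant_id="44.1"),
            Terminator("stop_variant", variant_id="44.2"),
        ],
        genome="".join(parts),
        genome_sequence_ref="PmDscam_fixture",
    )
    return model


def tail_submodel() -> GeneModel:
    """Slots 31-44: the cytoplasmic-tail model behind the 384 count."""
    return build_pmdscam_fixture().subset(range(31, 45), name="PmDscam-tail")


def terminal_submodel() -> GeneModel:
    """Slots 43-44 only: optional 43 + terminal cluster, 3 valid configs."""
    return build_pmdscam_fixture().subset((43, 44), name="PmDscam-terminal")


def extracellular_cluster_model() -> GeneModel:
    """The three hypervariable clusters (26 x 81 x 26) and nothing else."""
    return build_pmdscam_fixture().subset((4, 6, 15),
                                          name="PmDscam-extracellular")
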