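"""Splicing, translation, junction stop codons and motif scanning."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq

from splicemosaic.fixture import TAIL_PEPTIDES, terminal_submodel
from splicemosaic.isoforms import enumerate_isoforms
from splicemosaic.translation import (
    AmbiguousBaseError,
    DEFAULT_MOTIFS,
    MotifPattern,
    PatternSyntaxError,
    UnknownSequenceError,
    mature_transcript,
    scan_motifs,
    splice,
    translate,
)
from splicemosaic.simulate import reverse_translate

from conftest import make_model


class TestTranslate:
    def test_single_codon(self):
        res = translate("ATG")
        assert res.protein == "M"
        assert res.stop is None

    def test_stop_position_is_reported_one_based(self):
        res = translate("ATGAAATGA")
        assert res.protein == "MK"
        assert res.stop.codon_index == 3
        assert res.stop.nt_position == 9

    def test_translation_matches_biopython_on_random_cds(self):
        rng = np.random.default_rng(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            pep = "".join(aas[int(i)] for i in rng.integers(0, 20, 30))
            cds = reverse_translate(pep, rng, stop=True)
            res = translate(cds)
            ref = str(Seq(cds).translate(to_stop=True))
            assert res.protein == ref == pep
            assert res.stop.codon_index == len(pep) + 1

    def test_missing_stop_is_flagged_not_fatal(self):
        res = translate("ATGAAA")
        assert res.protein == "MK"
        assert not res.has_stop

    def test_trailing_partial_codon_is_ignored(self):
        assert translate("ATGAAAC").protein == "MK"

    def test_ambiguous_bases_reported_with_positions(self):
        with pytest.raises(AmbiguousBaseError) as exc:
            translate("ATGNNAACR")
        assert exc.value.positions == [4, 5, 9]

    def test_sub_codon_cds_is_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")


class TestSplice:
    def test_splice_concatenates_in_slot_order(self):
        m = make_model(clusters={2: 2}, optionals=[3], constitutives=[1, 4])
        spec = next(iter(enumerate_isoforms(m)))
        ids = spec.exon_ids(m)
        assert splice(m, spec) == "".join(m.exons[e].sequence for e in ids)

    def test_unknown_sequence_raises_unless_skipped(self):
        from splicemosaic.model import ExonVariant, SlotSpec
        m = make_model(constitutives=[2, 3])
        m.slots.insert(0, SlotSpec(1, "placeholder", ["1"]))
        m.exons["1"] = ExonVariant("1", 1, 1, 10, "+", None)
        spec = next(iter(enumerate_isoforms(m)))
        with pytest.raises(UnknownSequenceError):
            splice(m, spec)
        assert len(splice(m, spec, skip_unknown=True)) == 18


class TestJunctionStop:
    """The terminal optional exon ends in two dangling bases; spliced onto
    its forced terminal partner they complete a stop codon, so the stop is
    attributed to the downstream exon's first codon."""

    def _specs(self):
        m = terminal_submodel()
        return m, list(enumerate_isoforms(m))

    def test_terminal_submodel_has_three_configurations(self):
        _, specs = self._specs()
        assert len(specs) == 3

    def test_including_the_penultimate_exon_stops_at_partner_first_codon(self):
        m, specs = self._specs()
        with_43 = [s for s in specs if 43 in s.optional_included]
        assert len(with_43) == 1
        mt = mature_transcript(m, with_43[0])
        assert mt.protein == TAIL_PEPTIDES["43"]
        assert mt.stop.codon_index == len(TAIL_PEPTIDES["43"]) + 1
        assert mt.stop.source_exon == "44.1"

    def test_without_it_each_terminal_variant_translates_fully(self):
        m, specs = self._specs()
        by_choice = {s.choices[44]: s for s in specs
                     if 43 not in s.optional_included}
        mt1 = mature_transcript(m, by_choice["44.1"])
        assert mt1.protein == TAIL_PEPTIDES["44.1"]
        assert mt1.stop.source_exon == "44.1"
        mt2 = mature_transcript(m, by_choice["44.2"])
        assert mt2.protein == TAIL_PEPTIDES["44.2"]
        assert mt2.stop.source_exon == "44.2"

    def test_overlapping_terminal_variants_share_genomic_span(self):
        m, _ = self._specs()
        a, b = m.exons["44.1"], m.exons["44.2"]
        assert a.start < b.start <= a.end  # second variant starts inside
        assert b.frame_offset != 0         # and is read in a shifted frame


def _naive_hits(seq, pattern):
    """Regex re-implementation of the consensus scanner (oracle)."""
    rx = ""
    i, s = 0, pattern.consensus
    while i < len(s):
        if s[i] == "[":
            j = s.index("]", i)
            rx += "[" + s[i + 1:j] + "]"
            i = j + 1
        elif s[i].upper() == "X":
            rx += "[A-Z]"
            i += 1
        else:
            rx += s[i]
            i += 1
    if pattern.c_terminal:
        rx += "$"
    return [(m.start() + 1, m.start() + len(m.group(1)))
            for m in re.finditer(f"(?=({rx}))", seq)]


class TestMotifScan:
    def test_tail_exon_34_carries_an_itam_like_site(self):
        hits = [h for h in scan_motifs(TAIL_PEPTIDES["34"]) if h.motif == "ITAM"]
        assert len(hits) >= 1
        assert hits[0].start == 19 and hits[0].matched == "YEEL"

    def test_no_itim_match_in_any_tail_peptide(self):
        hits = scan_motifs(TAIL_PEPTIDES)
        assert [h for h in hits if h.motif == "ITIM"] == []

    def test_rgd_matches_verbatim(self):
        hits = scan_motifs("AARGDAA", [MotifPattern("RGD", "RGD")])
        assert [(h.start, h.end) for h in hits] == [(3, 5)]

    def test_c_terminal_pattern_only_matches_at_the_end(self):
        pdz = MotifPattern("PDZ-ligand", "[ST]X[VLI]", c_terminal=True)
        assert scan_motifs("SAVAAA", [pdz]) == []
        hits = scan_motifs("AAASAV", [pdz])
        assert [(h.start, h.end) for h in hits] == [(4, 6)]

    def test_overlapping_matches_are_all_reported(self):
        p = MotifPattern("ITAM", "YXXL")
        hits = scan_motifs("YYALLL", [p])
        assert [(h.start, h.matched) for h in hits] == [(1, "YYAL"), (2, "YALL")]

    def test_scanner_agrees_with_regex_oracle_on_random_peptides(self):
        rng = np.random.default_rng(11)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(30):
            pep = "".join(aas[int(i)] for i in rng.integers(0, 20, 80))
            for pat in DEFAULT_MOTIFS:
                got = [(h.start, h.end) for h in scan_motifs(pep, [pat])]
                assert got == _naive_hits(pep, pat), (pat.name, pep)

    def test_default_motifs_label_non_curated_consensi(self):
        names = {p.name: p.verbatim for p in DEFAULT_MOTIFS}
        assert names["ITAM"] and names["ITIM"] and names["RGD"]
        assert not names["SH3-binding"]
        assert not names["PDZ-ligand"]

    def test_pattern_syntax_errors(self):
        with pytest.raises(PatternSyntaxError):
            MotifPattern("bad", "Y[XL").classes()
        with pytest.raises(PatternSyntaxError):
            MotifPattern("bad", "Y[]L").classes()
        with pytest.raises(PatternSyntaxError):
            MotifPattern("bad", "YX").classes()
        with pytest.raises(PatternSyntaxError):
            MotifPattern("bad", "YX7L").classes()
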