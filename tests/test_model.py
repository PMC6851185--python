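"""Gene-model structure: census, validation, serialization round trips."""

import pytest

from splicemosaic.io import (
    CoordinateError,
    ModelParseError,
    load_model,
    save_model,
)
from splicemosaic.model import (
    ExonVariant,
    GeneModel,
    InvalidModelError,
    SlotSpec,
    SpliceConstraint,
    Terminator,
    exon_census,
    validate_model,
)
from splicemosaic.simulate import SimConfig, simulate_gene

from conftest import make_model


class TestCensus:
    def test_counts_slots_and_records_by_kind(self):
        m = make_model(clusters={3: 4, 5: 2}, optionals=[4],
                       constitutives=[2, 6])
        c = exon_census(m)
        assert c.n_slots == 5
        assert c.n_constitutive == 2
        assert c.n_optional == 1
        assert c.n_cluster_slots == 2
        assert c.n_variant_records == 6
        assert c.n_exon_records == 9

    def test_placeholder_slot_counts_toward_slots_only(self):
        m = make_model(constitutives=[2, 3])
        m.slots.insert(0, SlotSpec(1, "placeholder", ["1"]))
        m.exons["1"] = ExonVariant("1", 1, 1, 10, "+", None)
        c = exon_census(m)
        assert c.n_slots == 3
        assert c.n_exon_records == 2

    def test_census_refuses_invalid_model(self):
        m = make_model(clusters={2: 2}, constitutives=[3])
        m.slots[0].variants.append("ghost")  # no exon record for it
        with pytest.raises(InvalidModelError):
            exon_census(m)


class TestValidation:
    def test_valid_model_has_no_violations(self):
        m = make_model(clusters={2: 3}, optionals=[3], constitutives=[1, 4])
        assert validate_model(m) == []

    def test_single_variant_cluster_is_flagged(self):
        m = make_model(clusters={2: 2}, constitutives=[1])
        m.slots[-1].variants.pop()
        del m.exons["2.2"]
        rules = {v.rule for v in validate_model(m)}
        assert "cluster arity<2" in rules

    def test_unknown_variant_id_is_flagged(self):
        m = make_model(constitutives=[1, 2])
        m.constraints.append(SpliceConstraint("implies", "1", "nope"))
        rules = {v.rule for v in validate_model(m)}
        assert "unknown id" in rules

    def test_duplicate_and_unordered_slots_are_flagged(self):
        m = make_model(constitutives=[1, 2])
        m.slots.append(SlotSpec(1, "constitutive", ["1"]))
        rules = {v.rule for v in validate_model(m)}
        assert "slot order" in rules

    def test_bad_interval_strand_and_frame_offset(self):
        m = make_model(constitutives=[1])
        m.exons["1"] = ExonVariant("1", 1, 10, 4, "?", "ACGTACG",
                                   frame_offset=5)
        rules = {v.rule for v in validate_model(m)}
        assert {"interval", "strand", "frame offset"} <= rules

    def test_sequence_length_must_match_interval(self):
        m = make_model(constitutives=[1])
        ev = m.exons["1"]
        m.exons["1"] = ExonVariant("1", 1, ev.start, ev.end, "+", "ACG")
        rules = {v.rule for v in validate_model(m)}
        assert "sequence length" in rules

    def test_constraint_crossing_retained_intron_boundary_is_flagged(self):
        m = make_model(optionals=[2, 4], constitutives=[1, 3, 5],
                       retained_after=3,
                       constraints=[SpliceConstraint("implies", "2", "4")])
        rules = {v.rule for v in validate_model(m)}
        assert "constraint spans terminator boundary" in rules

    def test_violations_are_data_not_exceptions(self):
        m = make_model(constitutives=[1])
        m.exons["1"] = ExonVariant("1", 1, 10, 4, "+", None)
        vs = validate_model(m)  # must not raise
        assert all(v.rule and v.subject and v.message for v in vs)


def _genome_model() -> GeneModel:
    # two plus-strand exons and one minus-strand exon on a known genome
    genome = "TTTATGGCAGCATTTAAACCCGGGTTTACGTACGTAAATTT"
    e1 = ExonVariant("1", 1, 4, 12, "+", genome[3:12])
    e2 = ExonVariant("2", 2, 19, 24, "+", genome[18:24])
    # minus strand: stored sequence is the reverse complement of the slice
    from splicemosaic.arrays import reverse_complement
    e3 = ExonVariant("3", 3, 28, 36, "-", reverse_complement(genome[27:36]))
    return GeneModel(
        name="mini", genome=genome, genome_sequence_ref="mini_ref",
        slots=[SlotSpec(1, "constitutive", ["1"]),
               SlotSpec(2, "optional", ["2"]),
               SlotSpec(3, "constitutive", ["3"])],
        exons={"1": e1, "2": e2, "3": e3},
        constraints=[], terminators=[])


class TestRoundTrip:
    def test_save_then_load_is_identity_on_small_model(self, tmp_path):
        m = _genome_model()
        save_model(m, tmp_path)
        m2 = load_model(tmp_path)
        assert m2.name == m.name
        assert m2.genome == m.genome
        assert [s.__dict__ for s in m2.slots] == [s.__dict__ for s in m.slots]
        assert m2.exons == m.exons
        assert m2.constraints == m.constraints
        assert m2.terminators == m.terminators

    def test_minus_strand_sequence_is_reverse_complemented(self, tmp_path):
        m = _genome_model()
        save_model(m, tmp_path)
        m2 = load_model(tmp_path)
        assert m2.exons["3"].sequence == m.exons["3"].sequence
        assert m2.exons["3"].strand == "-"

    def test_round_trip_on_simulated_models(self, tmp_path):
        for seed in range(3):
            cfg = SimConfig(seed=seed, cluster_sizes=(3, 2), n_optional=1,
                            variant_length_aa=20, identity=0.8)
            sim = simulate_gene(cfg)
            d = tmp_path / f"m{seed}"
            save_model(sim.model, d)
            m2 = load_model(d)
            assert m2.exons == sim.model.exons
            assert m2.genome == sim.model.genome

    def test_round_trip_on_reference_fixture(self, tmp_path, pmdscam):
        save_model(pmdscam, tmp_path)
        m2 = load_model(tmp_path)
        assert m2.exons == pmdscam.exons
        assert m2.constraints == pmdscam.constraints
        assert m2.terminators == pmdscam.terminators
        assert exon_census(m2) == exon_census(pmdscam)


class TestParseErrors:
    def _write(self, tmp_path, gff_body):
        m = _genome_model()
        save_model(m, tmp_path)
        (tmp_path / "model.gff3").write_text("##gff-version 3\n" + gff_body)

    def test_wrong_column_count_names_the_line(self, tmp_path):
        self._write(tmp_path, "mini_ref\tx\texon\t1\t5\t.\t+\n")
        with pytest.raises(ModelParseError, match="expected 9 columns"):
            load_model(tmp_path)

    def test_end_before_start_raises_coordinate_error(self, tmp_path):
        self._write(tmp_path,
                    "mini_ref\tx\texon\t9\t4\t.\t+\t.\tID=1;slot=1;kind=constitutive\n")
        with pytest.raises(CoordinateError):
            load_model(tmp_path)

    def test_interval_outside_genome_raises(self, tmp_path):
        self._write(tmp_path,
                    "mini_ref\tx\texon\t1\t99999\t.\t+\t.\tID=1;slot=1;kind=constitutive\n")
        with pytest.raises(CoordinateError, match="outside genome"):
            load_model(tmp_path)

    def test_missing_file_raises_file_not_found(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nowhere")
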