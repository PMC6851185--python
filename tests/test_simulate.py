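"""Seeded synthetic-data generators and their truth records."""

import numpy as np
import pytest
from Bio.Seq import Seq

from splicemosaic.clones import assign_clone, tally_matrix
from splicemosaic.isoforms import count_isoforms
from splicemosaic.model import validate_model
from splicemosaic.simulate import (
    SimConfig,
    encode_dual_frame,
    mutate_peptide,
    reverse_translate,
    simulate_clone_survey,
    simulate_gene,
    simulate_transcripts,
)
from splicemosaic.translation import translate


class TestPrimitives:
    def test_reverse_translate_round_trips_through_translation(self):
        rng = np.random.default_rng(0)
        pep = "MKLVNPQRSTWYACDEFGHI"
        for r in (None, rng):
            cds = reverse_translate(pep, r, stop=True)
            assert str(Seq(cds).translate(to_stop=True)) == pep

    def test_mutate_peptide_hits_the_target_identity(self):
        rng = np.random.default_rng(1)
        pep = "A" * 100
        mut = mutate_peptide(pep, 0.7, rng)
        ident = sum(a == b for a, b in zip(pep, mut)) / 100
        assert ident == pytest.approx(0.7)

    def test_frozen_positions_are_never_mutated(self):
        rng = np.random.default_rng(2)
        pep = "MKLVNPQRST" * 4
        for _ in range(20):
            mut = mutate_peptide(pep, 0.5, rng, frozen=[0, 8, 39])
            assert mut[0] == pep[0] and mut[8] == pep[8] and mut[39] == pep[39]

    def test_bad_config_is_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(identity=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(clone_error_rate=-0.1).validate()
        with pytest.raises(ValueError):
            SimConfig(variant_length_aa=2).validate()


class TestGeneGenerator:
    def test_same_seed_reproduces_everything(self):
        a = simulate_gene(SimConfig(seed=3, cluster_sizes=(4, 3)))
        b = simulate_gene(SimConfig(seed=3, cluster_sizes=(4, 3)))
        assert a.genome == b.genome
        assert a.model.exons == b.model.exons
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = simulate_gene(SimConfig(seed=4, cluster_sizes=(3,)))
        b = simulate_gene(SimConfig(seed=5, cluster_sizes=(3,)))
        assert a.genome != b.genome

    def test_generated_model_is_valid(self):
        sim = simulate_gene(SimConfig(seed=6, cluster_sizes=(4, 2),
                                      n_optional=2))
        assert validate_model(sim.model) == []

    def test_truth_coordinates_point_at_the_planted_sequences(self):
        sim = simulate_gene(SimConfig(seed=7, cluster_sizes=(3,),
                                      variant_length_aa=30))
        slot = [s.slot for s in sim.model.cluster_slots()][0]
        for rec in sim.truth["clusters"][slot]:
            nt = sim.genome[rec["start"] - 1:rec["end"]]
            assert translate(nt + "TAA").protein == rec["peptide"]

    def test_planted_introns_are_canonical(self):
        sim = simulate_gene(SimConfig(seed=8, cluster_sizes=(3,)))
        slot = [s.slot for s in sim.model.cluster_slots()][0]
        for rec in sim.truth["clusters"][slot]:
            assert sim.genome[rec["start"] - 3:rec["start"] - 1] == "AG"
            assert sim.genome[rec["end"]:rec["end"] + 2] == "GT"

    def test_survey_scale_config_reproduces_the_reference_arithmetic(self):
        sim = simulate_gene(SimConfig(seed=9, cluster_sizes=(26, 81, 26)))
        assert count_isoforms(sim.model).n_total == 26 * 81 * 26


class TestTranscriptSampling:
    def test_chains_are_valid_isoforms_of_the_model(self):
        sim = simulate_gene(SimConfig(seed=10, cluster_sizes=(3, 2),
                                      n_optional=1))
        chains, specs = simulate_transcripts(sim.model, n=25, seed=10)
        assert len(chains) == len(specs) == 25
        for chain, spec in zip(chains, specs):
            assert chain.exon_ids == tuple(spec.exon_ids(sim.model))

    def test_sampling_is_seed_deterministic(self):
        sim = simulate_gene(SimConfig(seed=11, cluster_sizes=(3,)))
        a, _ = simulate_transcripts(sim.model, n=10, seed=1)
        b, _ = simulate_transcripts(sim.model, n=10, seed=1)
        assert a == b

    def test_zero_weight_variants_are_never_sampled(self):
        sim = simulate_gene(SimConfig(seed=12, cluster_sizes=(3,)))
        slot = [s.slot for s in sim.model.cluster_slots()][0]
        weights = {slot: {f"{slot}.1": 0.0}}
        _, specs = simulate_transcripts(sim.model, n=60, seed=2,
                                        usage_weights=weights)
        assert all(sp.choices[slot] != f"{slot}.1" for sp in specs)

    def test_all_zero_weights_are_an_error(self):
        sim = simulate_gene(SimConfig(seed=13, cluster_sizes=(2,)))
        slot = [s.slot for s in sim.model.cluster_slots()][0]
        weights = {slot: {f"{slot}.1": 0.0, f"{slot}.2": 0.0}}
        with pytest.raises(ValueError, match="exclude every valid isoform"):
            simulate_transcripts(sim.model, n=5, usage_weights=weights)


class TestCloneSurvey:
    def _setup(self):
        cfg = SimConfig(seed=20, cluster_sizes=(5, 4), variant_length_aa=40,
                        identity=0.8, n_individuals=3, clones_per_sample=5,
                        usage_weights={t: {2: {"2.1": 0.0}}
                                       for t in ("hemocyte", "nerve")})
        sim = simulate_gene(cfg)
        clones, truth = simulate_clone_survey(sim.model, cfg)
        return cfg, sim, clones, truth

    def test_survey_shape_and_determinism(self):
        cfg, sim, clones, _ = self._setup()
        assert len(clones) == 3 * 5 * 2
        clones2, _ = simulate_clone_survey(sim.model, cfg)
        assert clones == clones2

    def test_truth_matches_the_emitted_sequences(self):
        cfg, sim, clones, truth = self._setup()
        assert [c.id for c in clones] == [t["id"] for t in truth["clones"]]
        for c in clones:
            assert dict(c.source_variants).keys() == {2, 4}

    def test_zero_weight_variant_is_undetectable_end_to_end(self):
        cfg, sim, clones, truth = self._setup()
        assert all("2.1" not in truth["used_variants"][t]
                   for t in cfg.tissues)
        assignments = [assign_clone(c.id, c.sequence, sim.model,
                                    tissue=c.tissue, threshold=0.9)
                       for c in clones]
        dm = tally_matrix(assignments, sim.model, 2)
        assert "2.1" in dm.undetected_overall

    def test_assignment_recovers_the_planted_variants(self):
        cfg, sim, clones, _ = self._setup()
        ok = 0
        for c in clones:
            a = assign_clone(c.id, c.sequence, sim.model, tissue=c.tissue,
                             threshold=0.9)
            want = dict(c.source_variants)
            for v in a.votes:
                if v.status == "assigned":
                    assert v.variant_id == want[v.slot]
                    ok += 1
        assert ok >= 0.95 * 2 * len(clones)  # nearly every vote lands


class TestDualFrameEncoding:
    def test_both_peptides_decode_from_one_sequence(self):
        seq, off = encode_dual_frame("MKLV", "ARN")
        assert translate(seq).protein == "MKLV"
        assert translate(seq[off:]).protein == "ARN"
        assert off % 3 != 0

    def test_explicit_offset_is_honored(self):
        _, off = encode_dual_frame("MKLVNP", "AR")
        seq, off2 = encode_dual_frame("MKLVNP", "AR", offset=off)
        assert off2 == off
        assert translate(seq).protein == "MKLVNP"
        assert translate(seq[off:]).protein == "AR"

    def test_node_cap_failure_is_an_error(self):
        with pytest.raises(ValueError):
            encode_dual_frame("MKLV", "WWW", max_nodes=0)
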