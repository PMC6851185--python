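"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from splicemosaic.model import (
    ExonVariant,
    GeneModel,
    SlotSpec,
    SpliceConstraint,
    Terminator,
)


@pytest.fixture(scope="session")
def pmdscam():
    from splicemosaic.fixture import build_pmdscam_fixture
    return build_pmdscam_fixture()


def make_model(clusters=None, optionals=(), constitutives=(),
               constraints=(), retained_after=None, seq_len=9,
               name="toy") -> GeneModel:
    """Small in-memory model; slots are given explicit numbers.

    ``clusters`` maps slot -> arity.  Every exon gets a dummy in-frame
    sequence so splicing-level code can run on these models too.
    """
    clusters = clusters or {}
    slots, exons = [], {}
    pos = 1
    all_slots = sorted(set(clusters) | set(optionals) | set(constitutives))
    for slot in all_slots:
        if slot in clusters:
            members = []
            for v in range(1, clusters[slot] + 1):
                vid = f"{slot}.{v}"
                seq = "GCA" * (seq_len // 3)
                exons[vid] = ExonVariant(vid, slot, pos, pos + len(seq) - 1,
                                         "+", seq)
                pos += len(seq) + 10
                members.append(vid)
            slots.append(SlotSpec(slot, "cluster", members))
        else:
            kind = "optional" if slot in optionals else "constitutive"
            vid = str(slot)
            seq = "GCA" * (seq_len // 3)
            exons[vid] = ExonVariant(vid, slot, pos, pos + len(seq) - 1,
                                     "+", seq)
            pos += len(seq) + 10
            slots.append(SlotSpec(slot, kind, [vid]))
    terminators = []
    if retained_after is not None:
        terminators.append(Terminator("retained_intron",
                                      after_slot=retained_after))
    return GeneModel(name=name, slots=slots, exons=exons,
                     constraints=list(constraints), terminators=terminators)


def oracle_count(model: GeneModel) -> int:
    """Exhaustive Cartesian-product-plus-filter isoform count.

    Independent of the package's counting path: enumerates the raw product
    of all per-slot options and filters by a from-scratch constraint
    evaluator.  Includes intron-retained isoforms when the model has a
    retained-intron terminator.
    """
    def count_over(slots_subset, active):
        opts = []
        for s in model.slots:
            if s.slot not in slots_subset:
                continue
            if s.kind == "cluster":
                opts.append([(s.slot, v) for v in s.variants])
            elif s.kind == "optional":
                opts.append([(s.slot, None), (s.slot, s.variants[0])])
        n = 0
        for combo in product(*opts):
            chosen = {v for _, v in combo if v is not None}

            def present(eid):
                ev = model.exons.get(eid)
                if ev is None or ev.slot not in active:
                    return False
                spec = model.slot_spec(ev.slot)
                if spec.kind == "constitutive":
                    return True
                if spec.kind == "placeholder":
                    return False
                return eid in chosen

            ok = True
            for c in model.constraints:
                a, b = present(c.antecedent), present(c.consequent)
                if c.kind == "implies" and a and not b:
                    ok = False
                if c.kind == "forbids" and a and b:
                    ok = False
            n += ok
        return n

    all_slots = {s.slot for s in model.slots}
    total = count_over(all_slots, all_slots)
    ri = model.retained_intron()
    if ri is not None:
        ext = {s for s in all_slots if s <= ri.after_slot}
        total += count_over(ext, ext)
    return total


def random_model(rng: np.random.Generator, max_isoforms=10000) -> GeneModel:
    """A random small model with clusters, optionals and constraints."""
    n_var = int(rng.integers(2, 6))
    slots = list(range(2, 2 + n_var))
    clusters, optionals = {}, []
    for s in slots:
        if rng.random() < 0.5:
            clusters[s] = int(rng.integers(2, 5))
        else:
            optionals.append(s)
    constitutives = [1, 2 + n_var]
    ids = []
    for s in slots:
        if s in clusters:
            ids.extend(f"{s}.{v}" for v in range(1, clusters[s] + 1))
        else:
            ids.append(str(s))
    constraints = []
    n_con = int(rng.integers(0, 3))
    for _ in range(n_con):
        a, b = rng.choice(len(ids), size=2, replace=False)
        kind = "implies" if rng.random() < 0.7 else "forbids"
        constraints.append(SpliceConstraint(kind, ids[int(a)], ids[int(b)]))
    return make_model(clusters=clusters, optionals=optionals,
                      constitutives=constitutives, constraints=constraints)
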