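"""Synthetic cohort generator: controlled identity, planting, dropout, truth."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fesurvey.motifs import parse_motif, scan_protein
from fesurvey.proteome import Proteome, ProteinRecord
from fesurvey.simulate import (
    CYSTEINE_FREE,
    CohortConfig,
    GroupProfile,
    SyntheticTruth,
    apply_dropout,
    default_families,
    generate_cohort,
    mutate_to_identity,
    plant_motif,
)

from conftest import noise_free_config
from oracles import column_identity


def _random_seq(seed, length=100, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


class TestMutateToIdentity:
    def test_exact_substitution_count(self):
        seed = _random_seq(0, 100)
        out = mutate_to_identity(seed, 30.0, rng_seed=7)
        assert len(out) == 100
        assert sum(a != b for a, b in zip(seed, out)) == 70
        assert column_identity(seed, out) == pytest.approx(30.0)

    def test_identity_100_unchanged(self):
        seed = _random_seq(1, 40)
        assert mutate_to_identity(seed, 100.0, rng_seed=3) == seed

    def test_rounding_contract_length_50(self):
        # 25% identity on length 50: substitutions = round(50*0.75) = 38,
        # hence identity = 12/50 = 24% by brute-force column comparison
        seed = _random_seq(2, 50)
        out = mutate_to_identity(seed, 25.0, rng_seed=1)
        assert sum(a != b for a, b in zip(seed, out)) == 38
        assert column_identity(seed, out) == pytest.approx(24.0)

    def test_deterministic(self):
        seed = _random_seq(3, 80)
        assert mutate_to_identity(seed, 40, 9) == mutate_to_identity(seed, 40, 9)

    def test_empty_and_bad_inputs(self):
        with pytest.raises(ValueError):
            mutate_to_identity("", 50, 0)
        with pytest.raises(ValueError):
            mutate_to_identity(_random_seq(0, 20), 0.0, 0)

    @given(st.integers(0, 1000), st.integers(10, 95))
    def test_identity_forced_by_construction(self, seed, ident):
        seq = _random_seq(seed, 60)
        out = mutate_to_identity(seq, ident, rng_seed=seed + 1)
        n_sub = int(np.floor(60 * (1 - ident / 100.0) + 0.5))
        assert column_identity(seq, out) == pytest.approx(100.0 * (60 - n_sub) / 60)


class TestPlantMotif:
    def test_plant_at_position(self):
        out, span = plant_motif("A" * 10, parse_motif("CXXCH"), position=3, rng_seed=0)
        assert span == (3, 7)
        assert out[:2] == "AA" and out[7:] == "AAA"
        assert [m.start for m in scan_protein(out, parse_motif("CXXCH"))] == [3]

    def test_deterministic(self):
        pat = parse_motif("CX{4,5}CXnCX{3}C")
        a = plant_motif("A" * 100, pat, "random", rng_seed=5)
        b = plant_motif("A" * 100, pat, "random", rng_seed=5)
        assert a == b

    def test_outside_span_unchanged(self):
        seq = _random_seq(4, 50, CYSTEINE_FREE)
        out, (s, e) = plant_motif(seq, parse_motif("CXXCH"), "random", rng_seed=8)
        assert out[: s - 1] == seq[: s - 1] and out[e:] == seq[e:]

    def test_pattern_longer_than_sequence(self):
        with pytest.raises(ValueError):
            plant_motif("AAAA", parse_motif("CX{4,5}CXnCX{3}C"), rng_seed=0)

    def test_100_plants_all_recovered_on_cysteine_free_background(self):
        pat = parse_motif("CXXCH")
        hits = 0
        for i in range(100):
            seq = _random_seq(i, 80, CYSTEINE_FREE)
            out, _ = plant_motif(seq, pat, "random", rng_seed=1000 + i, alphabet=CYSTEINE_FREE)
            hits += bool(scan_protein(out, pat))
        assert hits == 100


def _toy_proteome(n=100):
    return Proteome("g", [ProteinRecord(f"p{i}", "ADEFGHIKLM", i + 1) for i in range(n)])


class TestDropout:
    def test_exact_retained_count(self):
        reduced, dropped = apply_dropout(_toy_proteome(100), 0.5, rng_seed=3)
        assert len(reduced) == 50 and len(dropped) == 50

    def test_identity_case(self):
        prot = _toy_proteome(30)
        reduced, dropped = apply_dropout(prot, 1.0, rng_seed=0)
        assert reduced is prot and dropped == []

    @pytest.mark.parametrize("seed", range(10))
    def test_relative_order_preserved(self, seed):
        prot = _toy_proteome(40)
        reduced, _ = apply_dropout(prot, 0.5, rng_seed=seed)
        loci = [p.locus for p in reduced]
        assert loci == sorted(loci)


class TestGenerateCohort:
    def test_certain_carriage_planted_everywhere(self):
        fams = default_families()
        group = GroupProfile("a", {"SufB": 1.0, "SufC": 1.0})
        zero = GroupProfile("b", {"SufB": 0.0, "SufC": 0.0})
        config = CohortConfig(
            groups=[group, zero], families=fams, n_genomes_per_group=5,
            background_proteins_per_genome=10, rng_seed=2,
        )
        _, truth = generate_cohort(config)
        with_both = [
            g for g, t in truth.genomes.items()
            if {"SufB", "SufC"} <= set(t.planted_families)
        ]
        assert len(with_both) == 5
        assert all(g.startswith("a_") for g in with_both)

    def test_truth_json_round_trip_and_determinism(self):
        config = noise_free_config(n_per_group=2, rng_seed=5)
        p1, t1 = generate_cohort(config)
        p2, t2 = generate_cohort(config)
        assert t1.to_json() == t2.to_json()
        assert [
            (p.genome_id, [(r.protein_id, r.sequence, r.locus) for r in p])
            for p in p1
        ] == [
            (p.genome_id, [(r.protein_id, r.sequence, r.locus) for r in p])
            for p in p2
        ]
        assert SyntheticTruth.from_json(t1.to_json()).to_json() == t1.to_json()

    def test_truth_references_existing_proteins(self):
        config = noise_free_config(n_per_group=2, completeness=0.7, rng_seed=9)
        proteomes, truth = generate_cohort(config)
        by_id = {p.genome_id: p for p in proteomes}
        for gid, gt in truth.genomes.items():
            retained_ids = set(by_id[gid].protein_ids)
            # every planted family protein either survived or is listed dropped
            for fam, pid in gt.planted_families.items():
                assert (pid in retained_ids) != (pid in gt.dropped_protein_ids)
            n_retained = gt.n_proteins_before_dropout - len(gt.dropped_protein_ids)
            assert len(by_id[gid]) == n_retained

    def test_operon_families_adjacent(self):
        config = noise_free_config(n_per_group=3, rng_seed=4)
        proteomes, truth = generate_cohort(config)
        for prot in proteomes:
            gt = truth.genomes[prot.genome_id]
            ahb = sorted(
                gt.planted_families[f]
                for f in ("AhbA", "AhbB", "AhbC", "AhbD")
                if f in gt.planted_families
            )
            if len(ahb) == 4:
                loci = sorted(
                    next(r.locus for r in prot if r.protein_id == pid) for pid in ahb
                )
                assert loci[-1] - loci[0] == 3

    def test_unknown_family_reference_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(
                groups=[GroupProfile("a", {"NoSuchFam": 1.0})],
                families=default_families(),
            )

    def test_carriage_probability_recovered(self):
        """Bernoulli carriage at p=0.3 is recovered within binomial error
        over 200 genomes."""
        fams = default_families()
        config = CohortConfig(
            groups=[GroupProfile("a", {"SufB": 0.3})],
            families=fams,
            n_genomes_per_group=200,
            background_proteins_per_genome=3,
            rng_seed=13,
        )
        _, truth = generate_cohort(config)
        k = sum("SufB" in t.planted_families for t in truth.genomes.values())
        # 4 sigma band: 0.3 +- 4*sqrt(0.3*0.7/200) ~ +-0.13
        assert 0.17 <= k / 200 <= 0.43
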