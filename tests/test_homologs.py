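"""Hit-table parsing, the built-in aligner backend, tier classification,
synteny rescue, and family presence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fesurvey.homologs import (
    ACCEPTED,
    REJECTED,
    RESCUED,
    AcceptancePolicy,
    HitRecord,
    HomologCall,
    QueryFamily,
    SIROHEME_POLICY,
    apply_synteny,
    best_hits_per_subject,
    classify_hit,
    family_presence,
    pairwise_search,
    parse_hit_table,
    write_hit_table,
)
from fesurvey.proteome import Proteome, ProteinRecord
from fesurvey.simulate import CYSTEINE_FREE, mutate_to_identity


def _hit(e=1e-6, ident=45.0, cov=80.0, family="SufB", **kw):
    defaults = dict(
        family_name=family,
        genome_id="g",
        subject_protein_id="p1",
        e_value=e,
        bit_score=100.0,
        percent_identity=ident,
        percent_query_coverage=cov,
        query_length=100,
        subject_locus=1,
    )
    defaults.update(kw)
    return HitRecord(**defaults)


class TestParseHitTable:
    ROW = "SufB\tg1|p1|4\t95.5\t80\t3\t0\t1\t80\t10\t89\t1.5e-40\t150.2"

    def test_coverage_arithmetic(self):
        recs = parse_hit_table(self.ROW, {"SufB": 100})
        assert len(recs) == 1
        r = recs[0]
        assert r.percent_query_coverage == pytest.approx(80.0)
        assert r.genome_id == "g1" and r.subject_protein_id == "p1" and r.subject_locus == 4
        assert r.e_value == pytest.approx(1.5e-40)

    def test_full_identity_full_coverage(self):
        row = "SufB\tg1|p1|1\t100\t100\t0\t0\t1\t100\t1\t100\t0.0\t200"
        r = parse_hit_table(row, {"SufB": 100})[0]
        assert r.percent_identity == 100.0 and r.percent_query_coverage == 100.0

    def test_unknown_query_errors(self):
        with pytest.raises(ValueError, match="unknown query"):
            parse_hit_table(self.ROW, {"FeoB": 100})

    def test_malformed_rows_report_line_numbers(self):
        bad = self.ROW + "\nSufB\tg|p|1\tnot_a_number\t1\t1\t0\t1\t2\t1\t2\t0.1\t10"
        with pytest.raises(ValueError, match="line 2"):
            parse_hit_table(bad, {"SufB": 100})

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = [
            _hit(
                e=float(10.0 ** -rng.integers(5, 60)),
                ident=float(rng.integers(20, 101)),
                cov=float(rng.integers(31, 101)),
                subject_protein_id=f"p{i}",
                subject_locus=i + 1,
            )
            for i in range(20)
        ]
        path = tmp_path / "hits.tsv"
        write_hit_table(recs, path)
        back = parse_hit_table(path, {"SufB": 100})
        for a, b in zip(recs, back):
            assert a.subject_protein_id == b.subject_protein_id
            assert a.percent_identity == pytest.approx(b.percent_identity, abs=1e-3)
            assert a.percent_query_coverage == pytest.approx(b.percent_query_coverage, abs=0.6)
            assert a.e_value == pytest.approx(b.e_value, rel=1e-3)


class TestPairwiseSearch:
    def _proteome(self, seqs):
        return Proteome("g", [ProteinRecord(f"p{i}", s, i + 1) for i, s in enumerate(seqs)])

    def test_self_hit_is_perfect(self):
        rng = np.random.default_rng(1)
        seed = "".join(rng.choice(list(CYSTEINE_FREE), size=150))
        fam = QueryFamily("F", (seed,))
        hits = pairwise_search(fam, self._proteome([seed]))
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0
        assert hits[0].percent_query_coverage == 100.0

    def test_planted_identity_recovered_within_tolerance(self):
        rng = np.random.default_rng(2)
        seed = "".join(rng.choice(list(CYSTEINE_FREE), size=200))
        fam = QueryFamily("F", (seed,))
        homolog = mutate_to_identity(seed, 40.0, rng_seed=3, alphabet=CYSTEINE_FREE)
        hits = pairwise_search(fam, self._proteome([homolog]))
        assert len(hits) == 1
        # local alignment may trim noisy ends, so allow a 5-point band
        assert hits[0].percent_identity == pytest.approx(40.0, abs=5.0)

    def test_unrelated_proteins_yield_no_significant_hit(self):
        """Empirical null: no random cysteine-free protein reaches the E
        screen with real coverage over 1000 trials."""
        rng = np.random.default_rng(4)
        seed = "".join(rng.choice(list(CYSTEINE_FREE), size=200))
        fam = QueryFamily("F", (seed,))
        seqs = [
            "".join(rng.choice(list(CYSTEINE_FREE), size=int(rng.integers(120, 260))))
            for _ in range(1000)
        ]
        policy = AcceptancePolicy()
        hits = pairwise_search(fam, self._proteome(seqs))
        accepted = [
            h
            for h in hits
            if classify_hit(h, policy).status in (ACCEPTED, RESCUED)
        ]
        assert accepted == []


class TestClassifyHit:
    def test_strong_hit_accepted(self):
        call = classify_hit(_hit(e=1e-6, ident=45, cov=80), AcceptancePolicy())
        assert call.status == ACCEPTED and call.reason == "ok"

    def test_rescue_band_with_domain_evidence(self):
        call = classify_hit(
            _hit(e=1e-6, ident=25, cov=60), AcceptancePolicy(), domain_evidence=True
        )
        assert call.status == RESCUED

    def test_rescue_band_without_evidence_rejected(self):
        call = classify_hit(_hit(e=1e-6, ident=25, cov=60), AcceptancePolicy())
        assert call.status == REJECTED and call.reason == "no_domain_evidence"

    def test_evalue_screen_first(self):
        call = classify_hit(_hit(e=1e-3, ident=90, cov=95), AcceptancePolicy(), True)
        assert call.status == REJECTED and call.reason == "evalue"

    def test_siroheme_override_stringency(self):
        # a hit that easily passes the default policy fails the 1e-30 screen
        call = classify_hit(_hit(e=1e-20, ident=60, cov=70), SIROHEME_POLICY)
        assert call.status == REJECTED and call.reason == "evalue"

    @pytest.mark.parametrize(
        "e,ident,cov,domain,motif,status,reason",
        [
            # boundary conventions: E <= e_max passes, coverage strictly > min,
            # identity >= min accepts, rescue band is [20, 30)
            (1.0e-5, 30.0, 30.1, False, True, ACCEPTED, "ok"),
            (1.0e-5, 30.0, 30.0, False, True, REJECTED, "coverage"),
            (1.0001e-5, 30.0, 80.0, False, True, REJECTED, "evalue"),
            (1e-6, 29.999, 80.0, True, True, RESCUED, "ok"),
            (1e-6, 20.0, 80.0, True, True, RESCUED, "ok"),
            (1e-6, 19.999, 80.0, True, True, REJECTED, "identity"),
            (1e-6, 25.0, 80.0, False, True, REJECTED, "no_domain_evidence"),
            (1e-6, 45.0, 80.0, False, False, REJECTED, "motif_failed"),
            (1e-6, 25.0, 80.0, True, False, REJECTED, "motif_failed"),
        ],
    )
    def test_decision_table_at_boundaries(self, e, ident, cov, domain, motif, status, reason):
        call = classify_hit(_hit(e=e, ident=ident, cov=cov), AcceptancePolicy(), domain, motif)
        assert (call.status, call.reason) == (status, reason)

    @pytest.mark.parametrize(
        "e,ident,cov,status",
        [
            (1e-31, 50.0, 50.1, ACCEPTED),
            (1e-31, 50.0, 50.0, REJECTED),
            (1e-31, 49.9, 80.0, REJECTED),
            (1e-29, 60.0, 80.0, REJECTED),
        ],
    )
    def test_siroheme_boundaries(self, e, ident, cov, status):
        call = classify_hit(_hit(e=e, ident=ident, cov=cov), SIROHEME_POLICY, False, True)
        assert call.status == status

    @given(
        st.floats(1e-40, 1e-3), st.floats(0, 100), st.floats(0.1, 100),
        st.booleans(), st.booleans(),
    )
    def test_tier_exclusivity_and_monotonicity(self, e, ident, cov, domain, motif):
        policy = AcceptancePolicy()
        call = classify_hit(_hit(e=e, ident=ident, cov=cov), policy, domain, motif)
        assert call.status in (ACCEPTED, RESCUED, REJECTED)
        assert (call.status == REJECTED) == (call.reason != "ok")
        # raising identity or lowering E never demotes an accepted call
        if call.status == ACCEPTED:
            better = classify_hit(
                _hit(e=e / 10, ident=min(ident + 5, 100), cov=cov), policy, domain, motif
            )
            assert better.status == ACCEPTED

    def test_policy_invariants(self):
        with pytest.raises(ValueError):
            AcceptancePolicy(rescue_band=(35.0, 40.0))
        with pytest.raises(ValueError):
            AcceptancePolicy(e_max=0.0)
        with pytest.raises(ValueError):
            HomologCall(_hit(), REJECTED, "ok")


class TestSynteny:
    OPERONS = {"ahb": {"AhbA", "AhbB", "AhbC", "AhbD"}}

    def _call(self, family, locus, status=ACCEPTED, reason="ok"):
        return HomologCall(
            _hit(family=family, subject_locus=locus, subject_protein_id=f"p{locus}"),
            status,
            reason,
        )

    def test_partial_hit_upgraded_between_neighbours(self):
        calls = [
            self._call("AhbA", 10),
            self._call("AhbB", 11, REJECTED, "coverage"),
            self._call("AhbC", 12),
        ]
        out = apply_synteny(calls, self.OPERONS)
        upgraded = [c for c in out if c.hit.family_name == "AhbB"][0]
        assert upgraded.status == RESCUED and upgraded.synteny_support

    def test_no_neighbours_stays_rejected(self):
        calls = [self._call("AhbB", 11, REJECTED, "coverage")]
        out = apply_synteny(calls, self.OPERONS)
        assert out[0].status == REJECTED

    def test_evalue_rejections_never_upgraded(self):
        calls = [
            self._call("AhbA", 10),
            self._call("AhbB", 11, REJECTED, "evalue"),
            self._call("AhbC", 12),
        ]
        out = apply_synteny(calls, self.OPERONS)
        assert [c for c in out if c.hit.family_name == "AhbB"][0].status == REJECTED

    @pytest.mark.parametrize("distance,expect_rescue", [(1, True), (5, True), (6, False)])
    def test_window_bound(self, distance, expect_rescue):
        calls = [
            self._call("AhbA", 10),
            self._call("AhbC", 10 + 2 * distance if distance <= 5 else 30),
            self._call("AhbB", 10 + distance, REJECTED, "identity"),
        ]
        # place both neighbours within/outside the +-5 window of the partial hit
        calls[1] = self._call("AhbC", calls[2].hit.subject_locus + min(distance, 9))
        out = apply_synteny(calls, self.OPERONS, k=2, w=5)
        got = [c for c in out if c.hit.family_name == "AhbB"][0]
        assert (got.status == RESCUED) == expect_rescue


class TestFamilyPresence:
    def test_single_accepted_makes_present(self):
        calls = [HomologCall(_hit(), ACCEPTED, "ok")]
        assert family_presence(calls) == {"SufB": True}

    def test_only_rejected_absent(self):
        calls = [
            HomologCall(_hit(), REJECTED, "evalue"),
            HomologCall(_hit(subject_protein_id="p2"), REJECTED, "identity"),
        ]
        assert family_presence(calls) == {"SufB": False}

    def test_order_independent(self):
        calls = [
            HomologCall(_hit(), REJECTED, "evalue"),
            HomologCall(_hit(subject_protein_id="p2"), ACCEPTED, "ok"),
        ]
        assert family_presence(calls) == family_presence(calls[::-1])


class TestBestHitSelection:
    def test_best_bit_score_wins_with_tie_breaks(self):
        hits = [
            _hit(bit_score=50.0, e=1e-10),
            _hit(bit_score=60.0, e=1e-12),
            _hit(bit_score=60.0, e=1e-13),
        ]
        best = best_hits_per_subject(hits)
        assert len(best) == 1
        assert best[0].e_value == pytest.approx(1e-13)
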