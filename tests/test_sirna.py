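import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msapkit.sirna import (
    DmfMatch,
    Direction,
    SirnaRecord,
    benjamini_hochberg,
    de_test,
    differential_expression,
    length_stratify,
    match_to_dmfs,
    normalize,
    reverse_complement,
)

LIBS = {"A1": 1_000_000, "B1": 1_000_000}


def _record(a: int, b: int, seq="ACGTACGTACGTACGTACGTACGT") -> SirnaRecord:
    return SirnaRecord(seq, {"A1": a, "B1": b})


class TestNormalize:
    def test_cpm_basic(self):
        assert normalize(10, 1_000_000) == 10.0

    def test_zero_count(self):
        assert normalize(0, 1_000_000) == 0.0

    def test_scaling(self):
        assert normalize(5, 2_000_000) == 2.5

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            normalize(5, 0)


class TestRecordValidation:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            SirnaRecord("ACGT", {"A1": 1})
        with pytest.raises(ValueError):
            SirnaRecord("A" * 31, {"A1": 1})

    def test_u_normalized(self):
        record = SirnaRecord("ACGU" * 6, {"A1": 1})
        assert "U" not in record.sequence
        assert record.length == 24

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            _record(-1, 2)


class TestDeTest:
    def test_equal_cpm_log2fc_zero(self):
        log2fc, p = de_test(_record(50, 50), ["A1"], ["B1"], LIBS)
        assert log2fc == 0.0
        assert p == pytest.approx(1.0)

    def test_fourfold_change(self):
        log2fc, _ = de_test(_record(100, 25), ["A1"], ["B1"], LIBS, pseudocount=0.0)
        assert log2fc == pytest.approx(2.0)

    def test_pseudocount_keeps_fc_finite(self):
        log2fc, _ = de_test(_record(64, 0), ["A1"], ["B1"], LIBS, pseudocount=0.5)
        assert np.isfinite(log2fc)
        assert log2fc == pytest.approx(np.log2(64.5 / 0.5))

    def test_p_matches_binomial_oracle(self):
        from scipy.stats import binom

        log2fc, p = de_test(_record(80, 40), ["A1"], ["B1"], LIBS)
        # two-sided exact binomial: sum of point probs <= observed
        rv = binom(120, 0.5)
        p_obs = rv.pmf(80)
        oracle = sum(rv.pmf(k) for k in range(121) if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_absent_record_errors(self):
        with pytest.raises(ValueError):
            de_test(_record(0, 0), ["A1"], ["B1"], LIBS)

    def test_direction_antisymmetry(self):
        fwd, _ = de_test(_record(100, 25), ["A1"], ["B1"], LIBS)
        rev, _ = de_test(_record(100, 25), ["B1"], ["A1"], LIBS)
        assert fwd == pytest.approx(-rev)


class TestDifferentialExpression:
    def test_thresholds_applied(self):
        records = [
            _record(400, 50, "A" * 24),   # |log2FC| ~ 3, strong
            _record(52, 48, "C" * 24),    # null
        ]
        results = {r.sequence: r for r in differential_expression(records, ["A1"], ["B1"], LIBS)}
        assert results["A" * 24].direction is Direction.UP
        assert results["C" * 24].direction is Direction.NS

    def test_swap_flips_direction(self):
        records = [_record(400, 50)]
        (up,) = differential_expression(records, ["A1"], ["B1"], LIBS)
        (down,) = differential_expression(records, ["B1"], ["A1"], LIBS)
        assert up.direction is Direction.UP
        assert down.direction is Direction.DOWN
        assert up.log2_fold_change == pytest.approx(-down.log2_fold_change)

    def test_all_zero_records_excluded(self):
        results = differential_expression([_record(0, 0)], ["A1"], ["B1"], LIBS)
        assert results == []

    def test_lfc_gate_without_significance_is_ns(self):
        # big fold change but tiny counts: adjusted p stays high
        results = differential_expression([_record(4, 0)], ["A1"], ["B1"], LIBS)
        assert results[0].direction is Direction.NS


class TestBenjaminiHochberg:
    def test_monotone_rank_preserving(self):
        ps = [0.001, 0.02, 0.5, 0.04, 0.9]
        adj = benjamini_hochberg(ps)
        assert list(np.argsort(ps)) == list(np.argsort(adj, kind="stable"))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_adjusted_at_least_raw(self, ps):
        adj = benjamini_hochberg(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=50))
    def test_order_preserved(self, ps):
        adj = benjamini_hochberg(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestMatchToDmfs:
    DMF = "AACCGGTT" * 10  # 80 nt

    def test_forward_exact_match(self):
        sirna = self.DMF[10:34]
        matches = match_to_dmfs([sirna], {"d1": self.DMF})
        assert DmfMatch(sirna, "d1", 10, "+") in matches

    def test_reverse_complement_match(self):
        sub = "ACGTTGCATGCCAGTCAGTCAGTA"
        dmf = "TTTT" + sub + "GGGG"
        rc = reverse_complement(sub)
        matches = match_to_dmfs([rc], {"d1": dmf})
        assert matches == [DmfMatch(rc, "d1", 4, "-")]

    def test_random_24mer_no_match(self):
        rng = np.random.default_rng(11)
        dmf = "".join(rng.choice(list("ACGT"), size=300))
        sirna = "".join(rng.choice(list("ACGT"), size=24))
        # brute-force oracle over every offset and strand
        rc = reverse_complement(sirna)
        hits = [
            (i, s)
            for s, needle in (("+", sirna), ("-", rc))
            for i in range(len(dmf) - 23)
            if dmf[i : i + 24] == needle
        ]
        assert hits == []
        assert match_to_dmfs([sirna], {"d1": dmf}) == []

    def test_every_match_verifies_by_substring(self):
        rng = np.random.default_rng(13)
        dmf = "".join(rng.choice(list("ACGT"), size=120))
        sirnas = [dmf[i : i + 21] for i in (0, 40, 99)]
        for m in match_to_dmfs(sirnas, {"d1": dmf}):
            if m.strand == "+":
                assert dmf[m.offset : m.offset + len(m.sirna)] == m.sirna
            else:
                assert dmf[m.offset : m.offset + len(m.sirna)] == reverse_complement(m.sirna)

    def test_u_matches_t(self):
        sirna = self.DMF[0:24].replace("T", "U")
        matches = match_to_dmfs([sirna], {"d1": self.DMF})
        assert matches[0].offset == 0

    def test_mismatch_tolerance(self):
        sirna = "A" + self.DMF[1:24]
        mutated = "G" + sirna[1:]
        assert match_to_dmfs([mutated], {"d1": self.DMF}) == []
        hits = match_to_dmfs([mutated], {"d1": self.DMF}, max_mismatches=1)
        assert any(m.offset == 0 and m.strand == "+" for m in hits)

    def test_non_acgt_dmf_rejected(self):
        with pytest.raises(ValueError):
            match_to_dmfs(["A" * 24], {"d1": "ACGTN"})


class TestLengthStratify:
    def test_counts_by_length(self):
        matches = [
            DmfMatch("A" * 21, "d", 0, "+"),
            DmfMatch("C" * 24, "d", 1, "+"),
            DmfMatch("G" * 24, "d", 2, "+"),
        ]
        assert length_stratify(matches) == {21: 1, 24: 2}

    def test_empty(self):
        assert length_stratify([]) == {}

    def test_distinct_sequences_counted_once(self):
        matches = [DmfMatch("A" * 24, "d1", 0, "+"), DmfMatch("A" * 24, "d2", 5, "+")]
        assert length_stratify(matches) == {24: 1}
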