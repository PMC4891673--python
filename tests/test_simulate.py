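import numpy as np
import pytest
from scipy import stats

from msapkit.bisulfite import Call, call_clones, summarize_region
from msapkit.msap import MethylationState
from msapkit.patterns import Uniformity, identify_dmfs
from msapkit.simulate import (
    BandSimParams,
    BisulfiteSimParams,
    GenerationSimParams,
    SirnaSimParams,
    gen_band_matrices,
    gen_bisulfite_clones,
    gen_generation_panels,
    gen_sirna_counts,
)

S = MethylationState


class TestBandSim:
    def test_zero_change_rate_identity(self):
        result = gen_band_matrices(BandSimParams(n_loci=50, change_rate=0.0, seed=1))
        assert result.truth == []
        for states in result.population.values():
            assert states == result.ref
        assert identify_dmfs(result.ref, result.population) == []

    def test_truth_table_recovered_exactly(self):
        params = BandSimParams(n_loci=926, change_rate=0.08, uniform_fraction=0.42, seed=4)
        result = gen_band_matrices(params)
        dmfs = {d.locus_id: d for d in identify_dmfs(result.ref, result.population)}
        assert set(dmfs) == {t.locus_id for t in result.truth}
        for t in result.truth:
            d = dmfs[t.locus_id]
            assert d.uniformity is t.uniformity
            if t.uniformity is Uniformity.UNIFORM:
                assert d.variant_state is t.variant_state

    def test_state_frequencies_within_multinomial_ci(self):
        freqs = (0.53, 0.15, 0.31, 0.01)
        result = gen_band_matrices(BandSimParams(n_loci=926, change_rate=0.0,
                                                 state_frequencies=freqs, seed=8))
        counts = {s: 0 for s in S}
        for state in result.ref.values():
            counts[state] += 1
        for s, p in zip(S, freqs):
            lo, hi = stats.binom(926, p).ppf([0.0025, 0.9975])
            assert lo <= counts[s] <= hi

    def test_determinism(self):
        a = gen_band_matrices(BandSimParams(n_loci=80, seed=3))
        b = gen_band_matrices(BandSimParams(n_loci=80, seed=3))
        assert a.ref == b.ref and a.population == b.population

    def test_exact_counts_mode(self):
        params = BandSimParams(exact_counts=True, seed=2)
        result = gen_band_matrices(params)
        assert len(result.truth) == 76
        assert sum(t.uniformity is Uniformity.UNIFORM for t in result.truth) == 32

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            BandSimParams(n_loci=0)
        with pytest.raises(ValueError):
            BandSimParams(state_frequencies=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            BandSimParams(change_rate=1.5)


MANIFEST = [(f"u{i}", S.CG, S.UNMETHYLATED) for i in range(32)]


class TestGenerationSim:
    def test_zero_reversion_all_stable(self):
        result = gen_generation_panels(GenerationSimParams(reversion_probability=0.0, seed=1),
                                       MANIFEST)
        assert all(result.truth_stable.values())
        for panel in result.panels:
            for locus, _, variant in MANIFEST:
                assert all(s is variant for s in panel.states[locus])

    def test_full_reversion_zero_final(self):
        result = gen_generation_panels(GenerationSimParams(reversion_probability=1.0, seed=1),
                                       MANIFEST)
        final = result.panels[-1]
        for locus, ref, _ in MANIFEST:
            assert all(s is ref for s in final.states[locus])

    def test_truth_matches_panel_contents(self):
        result = gen_generation_panels(GenerationSimParams(reversion_probability=0.1, seed=9),
                                       MANIFEST)
        for locus, _, variant in MANIFEST:
            observed_stable = all(
                s is variant for panel in result.panels for s in panel.states[locus]
            )
            assert observed_stable == result.truth_stable[locus]

    def test_closed_form_stable_fraction(self):
        # P(stable) = (1 - r)^(sum of panel sizes) = 0.95^50 per locus
        r, total_indiv = 0.05, 50
        expected = (1 - r) ** total_indiv
        fractions = []
        for seed in range(200):
            result = gen_generation_panels(
                GenerationSimParams(reversion_probability=r, seed=seed), MANIFEST
            )
            fractions.append(np.mean(list(result.truth_stable.values())))
        mean = np.mean(fractions)
        se = np.sqrt(expected * (1 - expected) / (200 * 32))
        assert abs(mean - expected) < 3 * se

    def test_empty_manifest_errors(self):
        with pytest.raises(ValueError):
            gen_generation_panels(GenerationSimParams(), [])


class TestBisulfiteSim:
    def test_no_methylation_full_conversion(self):
        params = BisulfiteSimParams(p_cg=0, p_chg=0, p_chh=0, conversion_rate=1.0,
                                    n_clones=5, seed=3)
        result = gen_bisulfite_clones(params)
        ref = result.amplicon.sequence
        for _, clone in result.clones:
            assert all(clone[i] != "C" for i in range(len(ref)) if ref[i] == "C")

    def test_pcg_one_all_cg_methylated(self):
        params = BisulfiteSimParams(p_cg=1.0, p_chg=0, p_chh=0, n_clones=5, seed=3)
        result = gen_bisulfite_clones(params)
        matrix = call_clones(result.amplicon, result.clones)
        for calls in matrix.calls.values():
            for pos, call in calls.items():
                if result.amplicon.contexts[pos].value == "CG":
                    assert call is Call.METHYLATED

    def test_truth_agrees_with_calls(self):
        params = BisulfiteSimParams(conversion_rate=1.0, n_clones=10, seed=5)
        result = gen_bisulfite_clones(params)
        matrix = call_clones(result.amplicon, result.clones)
        for clone_id, calls in matrix.calls.items():
            for pos, call in calls.items():
                expected = Call.METHYLATED if pos in result.truth_methylated[clone_id] \
                    else Call.UNMETHYLATED
                assert call is expected

    def test_parameter_recovery_within_binomial_ci(self):
        params = BisulfiteSimParams(p_cg=0.8, p_chg=0.4, p_chh=0.1,
                                    conversion_rate=1.0, n_clones=50, seed=7)
        result = gen_bisulfite_clones(params)
        matrix = call_clones(result.amplicon, result.clones)
        summary = summarize_region(matrix, result.amplicon)
        for ctx, p_true in (("CG", 0.8), ("CHG", 0.4), ("CHH", 0.1)):
            ci = stats.binomtest(summary.methylated[ctx], summary.total[ctx]).proportion_ci(0.95)
            assert ci.low <= p_true <= ci.high

    def test_conversion_rate_recovery(self):
        from msapkit.bisulfite import conversion_efficiency

        params = BisulfiteSimParams(p_cg=0.8, p_chg=0.4, p_chh=0.0,
                                    conversion_rate=0.99, n_clones=50, seed=11)
        result = gen_bisulfite_clones(params)
        matrix = call_clones(result.amplicon, result.clones)
        # CHH is truly unmethylated here, so T-rate estimates conversion
        rate = conversion_efficiency(matrix, result.amplicon)
        n_chh = sum(
            1 for calls in matrix.calls.values() for pos in calls
            if result.amplicon.contexts[pos].value == "CHH"
        )
        ci = stats.binomtest(round(rate * n_chh), n_chh).proportion_ci(0.95)
        assert ci.low <= 0.99 <= ci.high

    def test_determinism(self):
        a = gen_bisulfite_clones(BisulfiteSimParams(seed=2, n_clones=3))
        b = gen_bisulfite_clones(BisulfiteSimParams(seed=2, n_clones=3))
        assert a.amplicon.sequence == b.amplicon.sequence
        assert a.clones == b.clones


class TestSirnaSim:
    def test_null_type_one_rate(self):
        from msapkit.sirna import differential_expression

        params = SirnaSimParams(n_records=2000, seed=5)
        result = gen_sirna_counts(params)
        de = differential_expression(result.records, list(params.group_a),
                                     list(params.group_b), dict(params.library_sizes))
        frac = np.mean([r.p_value < 0.05 for r in de])
        assert frac <= 0.075

    def test_spiked_records_called_up(self):
        from msapkit.sirna import Direction, differential_expression

        params = SirnaSimParams(n_records=400, n_spiked=25, spike_log2fc=3.0,
                                mean_count=200.0, seed=6)
        result = gen_sirna_counts(params)
        de = {r.sequence: r for r in differential_expression(
            result.records, list(params.group_a), list(params.group_b),
            dict(params.library_sizes))}
        assert all(de[s].direction is Direction.UP for s in result.spiked)

    def test_planted_substrings_match(self):
        rng = np.random.default_rng(3)
        dmf = "".join(rng.choice(list("ACGT"), size=300))
        params = SirnaSimParams(n_records=200, n_spiked=17, seed=9)
        result = gen_sirna_counts(params, {"d1": dmf}, n_planted=17, planted_length=24)
        assert len(result.planted_matches) == 17
        for seq, (dmf_id, offset, strand) in result.planted_matches.items():
            assert dmf[offset : offset + 24] == seq
            assert strand == "+"

    def test_lengths_in_range(self):
        result = gen_sirna_counts(SirnaSimParams(n_records=100, seed=1))
        assert all(18 <= r.length <= 30 for r in result.records)

    def test_determinism(self):
        a = gen_sirna_counts(SirnaSimParams(n_records=50, seed=4))
        b = gen_sirna_counts(SirnaSimParams(n_records=50, seed=4))
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
        assert [r.counts for r in a.records] == [r.counts for r in b.records]

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SirnaSimParams(n_records=0)
        with pytest.raises(ValueError):
            SirnaSimParams(n_spiked=10, n_records=5)
        with pytest.raises(ValueError):
            gen_sirna_counts(SirnaSimParams(n_records=5), n_planted=3)
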