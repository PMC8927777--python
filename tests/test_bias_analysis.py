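import numpy as np
import pytest

from conftest import counts_from, random_gene_counts

from cubkit.bias_analysis import (
    correlation_matrix,
    enc_plot_table,
    neutrality_fit,
    optimal_codons,
    pr2_point,
    shared_optimal_codons,
)
from cubkit.codon_stats import CompositionProfile, composition_profile, count_codons, enc
from cubkit.synthetic_data import SimConfig, generate


def profile(gene_id="g", gc3s=0.3, gc12=0.3, enc=50.0, gc3=None, **over):
    base = dict(
        gene_id=gene_id, n_codons=200, a_pct=0.3, c_pct=0.2, g_pct=0.2, t_pct=0.3,
        gc=0.4, gc1=gc12, gc2=gc12, gc3=gc3 if gc3 is not None else gc3s,
        gc12=gc12, gc3s=gc3s, a3s=0.3, t3s=0.3, c3s=0.2, g3s=0.2, enc=enc,
    )
    base.update(over)
    return CompositionProfile(**base)


class TestEncPlotTable:
    def test_ratio_against_expected_curve(self):
        tab = enc_plot_table([profile(gc3=0.5, enc=60.5), profile("h", gc3=0.5, enc=30.25)])
        assert list(tab["enc_ratio"]) == [pytest.approx(1.0), pytest.approx(0.5)]

    def test_missing_enc_rows_dropped(self):
        tab = enc_plot_table([profile(), profile("h", enc=None)])
        assert list(tab["gene_id"]) == ["g"]

    def test_mutation_only_genome_sits_on_curve(self, code6):
        recs, _ = generate(SimConfig(n_genes=150, seed=11))
        profs = [composition_profile(count_codons(r, code6), code6) for r in recs]
        ratios = enc_plot_table(profs)["enc_ratio"]
        assert 0.9 <= float(np.median(ratios)) <= 1.1


class TestPr2:
    def test_parity_center(self, code1):
        c = counts_from({"AAA": 2, "AAT": 2, "AAG": 1, "AAC": 1})
        p = pr2_point(c, code1)
        assert (p.x, p.y) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_direct_ratios(self, code1):
        # thirds: A x3, T x1, G x1, C x3
        c = counts_from({"AAA": 3, "AAT": 1, "AAG": 1, "AAC": 3})
        p = pr2_point(c, code1)
        assert (p.x, p.y) == (pytest.approx(0.25), pytest.approx(0.75))

    def test_degenerate_denominator_flags_missing(self, code1):
        p = pr2_point(counts_from({"AAA": 4}), code1)
        assert p.x is None and p.y == pytest.approx(1.0)

    def test_fourfold_site_set_ignores_twofold_families(self, code1):
        # Lys is not a fourfold box; Gly is
        c = counts_from({"AAA": 50, "GGA": 1, "GGT": 1, "GGG": 1, "GGC": 1})
        p = pr2_point(c, code1, site_set="fourfold_third")
        assert p.x == pytest.approx(0.5) and p.y == pytest.approx(0.5)

    def test_stop_codons_excluded(self, code6):
        # TGA is the only stop under table 6 and is excluded from thirds
        c = counts_from({"TGA": 5, "AAA": 1, "AAT": 1})
        p = pr2_point(c, code6)
        assert p.x is None and p.y == pytest.approx(0.5)


class TestNeutralityFit:
    def test_identity_line(self):
        profs = [profile(str(i), gc3s=x, gc12=x) for i, x in enumerate((0.1, 0.2, 0.3, 0.4))]
        fit = neutrality_fit(profs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_constant_gc12_gives_zero_slope(self):
        profs = [profile(str(i), gc3s=x, gc12=0.35) for i, x in enumerate((0.1, 0.2, 0.3))]
        assert neutrality_fit(profs).slope == pytest.approx(0.0)

    def test_zero_gc3s_variance_is_error(self):
        profs = [profile(str(i), gc3s=0.3, gc12=0.1 * i) for i in range(4)]
        with pytest.raises(ValueError, match="variance"):
            neutrality_fit(profs)

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(6)
        profs = [profile(str(i), gc3s=float(x), gc12=float(0.4 * x + 0.2 + rng.normal(0, 0.01)))
                 for i, x in enumerate(rng.uniform(0.1, 0.6, 40))]
        a = neutrality_fit(profs)
        b = neutrality_fit(list(reversed(profs)))
        c = neutrality_fit(profs + profs)
        assert a.slope == pytest.approx(b.slope) == pytest.approx(c.slope)

    def test_parameter_recovery_from_generator(self, code6):
        slopes = []
        for seed in (21, 22, 23):
            recs, _ = generate(SimConfig(n_genes=500, neutrality_slope=0.4, seed=seed))
            profs = [composition_profile(count_codons(r, code6), code6) for r in recs]
            slopes.append(neutrality_fit(profs).slope)
        assert all(0.35 <= s <= 0.45 for s in slopes)


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(7)
        profs = [profile(str(i), gc3s=float(rng.uniform(0.2, 0.5)), enc=float(rng.uniform(40, 60)))
                 for i in range(30)]
        m = correlation_matrix(profs)
        assert np.allclose(np.diag(m.r.to_numpy()), 1.0)
        assert np.allclose(m.r.to_numpy(), m.r.to_numpy().T, equal_nan=True)

    def test_functional_dependence_gives_r_one(self):
        profs = [profile(str(i), gc3s=0.1 * i + 0.1, gc12=0.1 * i + 0.1) for i in range(5)]
        m = correlation_matrix(profs, variables=("gc12", "gc3s"))
        assert m.r.loc["gc12", "gc3s"] == pytest.approx(1.0)

    def test_independent_variables_uncorrelated(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            profs = [
                profile(str(i), gc3s=float(rng.uniform()), enc=float(rng.uniform(20, 61)))
                for i in range(1000)
            ]
            m = correlation_matrix(profs, variables=("gc3s", "enc"))
            if abs(m.r.loc["gc3s", "enc"]) < 0.1 and m.p.loc["gc3s", "enc"] > 0.01:
                hits += 1
        assert hits >= 9

    def test_constant_variable_flagged_nan(self):
        profs = [profile(str(i), gc3s=0.1 * i + 0.1, enc=50.0) for i in range(5)]
        m = correlation_matrix(profs, variables=("gc3s", "enc"))
        assert np.isnan(m.r.loc["gc3s", "enc"])


class TestOptimalCodons:
    def _gene_set(self, code, n=30, skew=None, seed=0):
        """n genes; optionally the first 3 use only TTT for Phe (low ENC)."""
        rng = np.random.default_rng(seed)
        counts, encs = {}, {}
        for i in range(n):
            g = f"g{i:03d}"
            counts[g] = random_gene_counts(rng, code, 300)
            encs[g] = enc(counts[g], code)
        return counts, encs

    def test_identical_tails_give_empty_optimal(self, code1):
        c = counts_from({c: 3 for c in code1.sense_codons})
        counts = {f"g{i}": c for i in range(20)}
        encs = {f"g{i}": 30.0 + i for i in range(20)}
        rep = optimal_codons(counts, encs, code1)
        assert rep.decile_size == 2
        assert all(d == pytest.approx(0.0) for d in rep.delta_rscu.values() if d is not None)
        assert rep.optimal == set()

    def test_too_few_genes_refused(self, code1):
        counts, encs = self._gene_set(code1, n=10)
        with pytest.raises(ValueError, match=">= 20"):
            optimal_codons(counts, encs, code1)

    def test_tails_disjoint_and_sized(self, code1):
        counts, encs = self._gene_set(code1, n=53)
        rep = optimal_codons(counts, encs, code1)
        assert rep.decile_size == 6  # ceil(0.1 * 53)
        assert len(rep.high_set_ids) == len(rep.low_set_ids) == 6
        assert not set(rep.high_set_ids) & set(rep.low_set_ids)
        assert max(encs[g] for g in rep.high_set_ids) <= min(encs[g] for g in rep.low_set_ids)

    def test_input_order_invariance(self, code1):
        counts, encs = self._gene_set(code1, n=40)
        rep1 = optimal_codons(counts, encs, code1)
        rev = dict(reversed(list(counts.items())))
        rep2 = optimal_codons(rev, encs, code1)
        assert rep1.optimal == rep2.optimal
        assert rep1.high_set_ids == rep2.high_set_ids

    def test_delta_antisymmetry(self, code1):
        counts, encs = self._gene_set(code1, n=40)
        rep = optimal_codons(counts, encs, code1)
        flipped = {g: -e for g, e in encs.items()}  # reverses the ranking
        rep2 = optimal_codons(counts, flipped, code1)
        for c, d in rep.delta_rscu.items():
            if d is not None and rep2.delta_rscu[c] is not None:
                assert rep2.delta_rscu[c] == pytest.approx(-d, abs=1e-9)

    def test_injected_preference_recovered(self, code6):
        # the injected codons must be flagged and carry the two largest
        # ΔRSCU values; single-species ΔRSCU > 0.08 also admits sampling
        # noise from unrelated families, which the cross-species
        # intersection (see the nine-species scenario tests) removes
        target = {"GGA", "AGA"}
        for seed in (31, 32):
            recs, _ = generate(
                SimConfig(n_genes=300, length_codons=(300, 600), gc3_mean=0.45,
                          gc3_sd=0.03, optimal_set=tuple(sorted(target)),
                          preference_strength=3.0, seed=seed)
            )
            counts = {r.id: count_codons(r, code6) for r in recs}
            encs = {g: enc(c, code6) for g, c in counts.items()}
            rep = optimal_codons(counts, encs, code6, species="sim")
            assert rep.optimal >= target
            top2 = sorted(
                (d, c) for c, d in rep.delta_rscu.items() if d is not None
            )[-2:]
            assert {c for _, c in top2} == target


class TestSharedOptimalCodons:
    def test_intersection(self):
        reps = [type("R", (), {"optimal": opt})() for opt in ({"A", "B"}, {"B", "C"})]
        assert shared_optimal_codons(reps) == {"B"}

    def test_self_intersection_identity(self):
        rep = type("R", (), {"optimal": {"GGA", "TTT"}})()
        assert shared_optimal_codons([rep, rep]) == {"GGA", "TTT"}
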