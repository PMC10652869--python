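import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ordgwas as og
from ordgwas.genio import ValidationError
from ordgwas.simulate import (
    DEFAULT_H2_PROFILE,
    MethodReport,
    SimulationDesign,
    canonical_loci,
    distribution_stats,
    resolve_effects,
)


class TestSynthGenotypes:
    def test_deterministic_and_inbred_coded(self):
        G1 = og.synth_genotypes(n=40, m=120, seed=9)
        G2 = og.synth_genotypes(n=40, m=120, seed=9)
        np.testing.assert_array_equal(G1.dosages, G2.dosages)
        assert set(np.unique(G1.dosages)) <= {0.0, 2.0}
        assert len(set(G1.chrom)) == 5

    def test_maf_floor_after_filter(self):
        G = og.filter_maf(og.synth_genotypes(n=199, m=2000, seed=1), 0.1)
        assert (G.maf() > 0.1).all()

    def test_no_linkage_by_default(self):
        G = og.synth_genotypes(n=400, m=400, seed=2)
        D = G.dosages - G.dosages.mean(axis=0)
        r = np.array(
            [
                np.corrcoef(D[:, j], D[:, j + 1])[0, 1]
                for j in range(G.m - 1)
                if G.chrom[j] == G.chrom[j + 1]
            ]
        )
        assert abs(r.mean()) < 0.05

    def test_first_order_linkage_raises_neighbor_correlation(self):
        G = og.synth_genotypes(n=400, m=200, seed=2, rho=0.5)
        D = G.dosages - G.dosages.mean(axis=0)
        r = np.array(
            [
                np.corrcoef(D[:, j], D[:, j + 1])[0, 1]
                for j in range(G.m - 1)
                if G.chrom[j] == G.chrom[j + 1]
            ]
        )
        assert r.mean() > 0.2


class TestCanonicalLoci:
    def test_full_panel_uses_reference_indices(self):
        assert canonical_loci(10_000) == (278, 2143, 2054, 3698, 1716, 6178, 8501)

    def test_rescaled_panel_keeps_chromosomes(self):
        idx = canonical_loci(5000)
        assert len(set(idx)) == 7
        assert max(idx) < 5000
        G = og.synth_genotypes(n=10, m=5000, seed=0)
        assert [G.chrom[j] for j in idx] == ["1", "2", "2", "2", "1", "4", "5"]


class TestOData:
    def test_pure_noise_when_effects_are_zero(self):
        G = og.synth_genotypes(n=199, m=100, seed=3)
        d = SimulationDesign(
            qtn_indices=tuple(range(7)), qtn_effects=(0.0,) * 7,
            residual_variance=1.0,
        )
        rng = np.random.default_rng(0)
        od = og.simulate_odata(G, d, rng)
        se = np.sqrt(2.0 / G.n)
        assert abs(od.values.var(ddof=1) - 1.0) < 3 * se

    def test_heritability_realized_within_band(self):
        """Realized variance ratio of a single h2=0.25 QTN stays near target."""
        G = og.synth_genotypes(n=199, m=100, seed=4)
        d = SimulationDesign(
            qtn_indices=(50,), qtn_h2=(0.25,), residual_variance=1.0
        )
        b = resolve_effects(G, d)
        x = G.dosages[:, 50]
        inside = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            od = og.simulate_odata(G, d, rng, effects=b)
            g = (x - x.mean()) * b[0]
            h2 = g.var() / od.values.var()
            inside += 0.20 <= h2 <= 0.30
        assert inside >= 0.9 * n_seeds

    def test_infeasible_heritability_total(self):
        G = og.synth_genotypes(n=20, m=20, seed=5)
        d = SimulationDesign(qtn_indices=(0, 1), qtn_h2=(0.6, 0.5))
        with pytest.raises(ValidationError, match="heritability"):
            resolve_effects(G, d)

    def test_default_profile_sums_below_one(self):
        assert sum(DEFAULT_H2_PROFILE) < 1.0


class TestDiscretize:
    @pytest.mark.parametrize(
        "n,props,expected",
        [
            (8, (1, 2, 1), [2, 4, 2]),
            (4, (1, 1), [2, 2]),
            (10, (1, 2, 4, 2, 1), [1, 2, 4, 2, 1]),
        ],
    )
    def test_level_counts_follow_proportions(self, n, props, expected):
        rng = np.random.default_rng(n)
        values = rng.permutation(n).astype(float)
        h = og.discretize(og.ContinuousPhenotype(values), props)
        assert np.bincount(h.codes(), minlength=len(props) + 1)[1:].tolist() == expected

    def test_level_one_is_the_lowest_block(self):
        values = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.0])
        h = og.discretize(og.ContinuousPhenotype(values), (1, 1))
        assert h.codes().tolist() == [2, 1, 2, 1, 2, 1]

    def test_fewer_samples_than_levels(self):
        with pytest.raises(ValidationError):
            og.discretize(og.ContinuousPhenotype(np.arange(2.0)), (1, 1, 1))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(6, 60),
        props=st.lists(st.integers(1, 5), min_size=2, max_size=4),
    )
    def test_counts_always_sum_to_n_and_respect_order(self, n, props):
        rng = np.random.default_rng(n)
        values = rng.normal(0, 1, n)
        try:
            h = og.discretize(og.ContinuousPhenotype(values), tuple(props))
        except ValidationError:
            return  # a level received no mass at this n — rejected by contract
        counts = np.bincount(h.codes(), minlength=len(props) + 1)[1:]
        assert counts.sum() == n
        # monotone: every sample at a lower level has value <= any higher level
        codes = h.codes()
        for l in range(1, len(props)):
            assert values[codes == l].max() <= values[codes == l + 1].min()


class TestDistributionStats:
    def test_hand_computed_fixture(self):
        s = distribution_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s.cv == pytest.approx(51.6398, abs=1e-3)
        assert s.skewness == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_sample_has_zero_skewness(self):
        x = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        assert distribution_stats(x).skewness == pytest.approx(0.0, abs=1e-12)

    def test_large_normal_kurtosis_is_three(self):
        rng = np.random.default_rng(8)
        s = distribution_stats(rng.normal(10, 2, 100_000))
        assert abs(s.kurtosis - 3.0) < 0.1


class TestMetrics:
    def test_pooled_f1_hand_computation(self):
        rep = MethodReport(
            tp=3, fp=1, fn=4, n_reps=1,
            detections_per_qtn=np.zeros(7), m=100, n_qtn=7,
        )
        assert rep.f1 == pytest.approx(2 * 0.75 * (3 / 7) / (0.75 + 3 / 7), abs=1e-4)
        assert rep.f1 == pytest.approx(0.5455, abs=1e-3)

    def test_no_false_calls_gives_zero_fpr(self):
        rep = MethodReport(
            tp=7, fp=0, fn=0, n_reps=1,
            detections_per_qtn=np.ones(7), m=100, n_qtn=7,
        )
        assert rep.fpr_permille == 0.0
        assert rep.mean_power == 100.0


class TestClassicalMaps:
    def test_bonferroni_default_and_planted_qtn_found(self):
        G = og.synth_genotypes(n=199, m=200, seed=6)
        x = G.dosages[:, 120]
        rng = np.random.default_rng(0)
        latent = (x - x.mean()) * 1.2 + rng.normal(0, 1, G.n)
        h = og.discretize(og.ContinuousPhenotype(latent), (1, 1))
        maps = og.classical_maps(G, h)  # threshold 0.05 / 200
        assert 120 in maps["chi2_map"].tolist()
        assert 120 in maps["logistic_map"].tolist()

    def test_null_calibration_at_nominal_threshold(self):
        G = og.synth_genotypes(n=199, m=400, seed=7)
        rng = np.random.default_rng(1)
        h = og.OrdinalPhenotype(rng.integers(1, 3, G.n))
        maps = og.classical_maps(G, h, threshold=0.05)
        frac = len(maps["chi2_map"]) / G.m
        se = np.sqrt(0.05 * 0.95 / G.m)
        assert abs(frac - 0.05) < 3 * se + 1 / G.m


@pytest.fixture(scope="module")
def report():
    G = og.synth_genotypes(n=199, m=500, seed=10)
    design = SimulationDesign(n_reps=6, seed=0, proportions=(1, 2, 1))
    return og.run_experiment(
        G, design, methods={"mtotc_scan", "scan_on_hdata"}
    ), design


class TestRunExperiment:
    def test_conservation(self, report):
        rep, design = report
        for meth in rep.methods.values():
            assert meth.tp + meth.fn == 7 * meth.n_reps
            assert meth.n_reps == design.n_reps

    def test_report_serializes(self, report):
        import json

        rep, _ = report
        payload = json.dumps(rep.to_dict())
        assert "mtotc_scan" in payload

    def test_retention_rates_monotone_in_threshold(self, report):
        rep, _ = report
        grid = sorted(rep.retention_total)
        totals = [rep.retention_total[t] for t in grid]
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))
        assert all(0 <= v <= 100 for v in totals)

    def test_proportion_symmetry(self):
        """Negating the trait and reversing the proportions mirrors labels.

        ``discretize(-x, reversed(props))`` assigns each sample the
        mirrored level of ``discretize(x, props)``, and the pipeline
        treats mirrored labels identically, so the called marker set is
        unchanged.
        """
        G = og.synth_genotypes(n=199, m=300, seed=12)
        design = SimulationDesign(qtn_indices=canonical_loci(300))
        rng = np.random.default_rng(0)
        od = og.simulate_odata(G, design, rng)
        h_fwd = og.discretize(od, (4, 2, 1))
        h_rev = og.discretize(og.ContinuousPhenotype(-od.values), (1, 2, 4))
        L = 3
        np.testing.assert_array_equal(h_rev.codes(), L + 1 - h_fwd.codes())
        r_fwd = og.run_mtotc_gwas(G, h_fwd)
        r_rev = og.run_mtotc_gwas(G, h_rev)
        assert {h.marker for h in r_fwd.hits} == {h.marker for h in r_rev.hits}
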