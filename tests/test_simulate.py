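"""Synthetic-data generator: drift model, tract model, sex-specific ancestry."""

import numpy as np
import pytest

from admixtide.simulate import (
    AdmixSpec,
    GeneticMapSpec,
    SimPopSpec,
    build_scenario,
    gen_admixed_cohort,
    gen_dating_cohort,
    gen_reference_freqs,
    scenario_catalogue,
    write_fixture_dataset,
)

SMALL_MAP = GeneticMapSpec(n_autosomes=4, autosome_length_M=1.0, x_length_M=1.0)


class TestReferenceFreqs:
    def test_deterministic_given_seed(self):
        specs = [SimPopSpec("A", 0.1), SimPopSpec("B", 0.2, clade="c")]
        f1 = gen_reference_freqs(specs, 500, SMALL_MAP, seed=42)
        f2 = gen_reference_freqs(specs, 500, SMALL_MAP, seed=42)
        for n in ("A", "B"):
            np.testing.assert_array_equal(f1.freqs[n], f2.freqs[n])

    def test_vanishing_drift_tracks_ancestral(self):
        specs = [SimPopSpec("A", 1e-6)]
        f = gen_reference_freqs(specs, 5000, SMALL_MAP, seed=0)
        close = np.abs(f.freqs["A"] - f.ancestral) < 0.01
        assert close.mean() > 0.99

    def test_pairwise_divergence_matches_balding_nichols(self):
        """E[(pA-pB)^2] = 2 F E[p(1-p)] for independent drift F."""
        F = 0.2
        specs = [SimPopSpec("A", F), SimPopSpec("B", F)]
        f = gen_reference_freqs(specs, 20000, SMALL_MAP, seed=1)
        observed = np.mean((f.freqs["A"] - f.freqs["B"]) ** 2)
        expected = 2 * F * np.mean(f.ancestral * (1 - f.ancestral))
        assert observed == pytest.approx(expected, rel=0.1)

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError):
            SimPopSpec("A", 0.0)
        with pytest.raises(ValueError):
            gen_reference_freqs([SimPopSpec("A", 0.5)], 0, SMALL_MAP, seed=0)


def two_way_spec(f1, m1, g=10, n=20, name="Adm"):
    return AdmixSpec(
        source_names=("S1", "S2"),
        female_fractions=(f1, 1 - f1),
        male_fractions=(m1, 1 - m1),
        generations=g,
        n_individuals=n,
        name=name,
    )


@pytest.fixture(scope="module")
def two_pop_freqs():
    specs = [SimPopSpec("S1", 0.05), SimPopSpec("S2", 0.05)]
    return gen_reference_freqs(specs, 2000, SMALL_MAP, seed=7)


class TestAdmixSpec:
    def test_coefficients(self):
        spec = two_way_spec(1.0, 0.0)
        np.testing.assert_allclose(spec.c_auto, [0.5, 0.5])
        np.testing.assert_allclose(spec.c_x, [2 / 3, 1 / 3])

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            AdmixSpec(("a", "b"), (0.6, 0.6), (0.5, 0.5), 5, 3)
        with pytest.raises(ValueError, match="non-negative"):
            AdmixSpec(("a", "b"), (1.2, -0.2), (0.5, 0.5), 5, 3)


class TestAdmixedCohort:
    def test_single_source_realizes_fully(self, two_pop_freqs):
        spec = two_way_spec(1.0, 1.0, n=5)
        _, truth = gen_admixed_cohort(two_pop_freqs, spec, seed=0)
        np.testing.assert_allclose(truth.realized_mean("autosomes"), [1.0, 0.0])

    def test_tracts_tile_each_chromosome(self, two_pop_freqs):
        spec = two_way_spec(0.5, 0.5, g=15, n=6)
        _, truth = gen_admixed_cohort(two_pop_freqs, spec, seed=3)
        lengths = two_pop_freqs.map_spec.lengths()
        for (ind, chrom, hap), tr in truth.tracts.items():
            assert tr[0, 0] == 0.0
            assert tr[-1, 1] == pytest.approx(lengths[chrom])
            np.testing.assert_allclose(tr[1:, 0], tr[:-1, 1])

    def test_realized_autosomal_proportions_near_c_auto(self, two_pop_freqs):
        spec = two_way_spec(0.7, 0.3, g=10, n=300)
        _, truth = gen_admixed_cohort(two_pop_freqs, spec, seed=1)
        realized = truth.realized_mean("autosomes")
        per_ind = truth.realized[
            (truth.realized.chromosome_set == "autosomes")
            & (truth.realized.source == "S1")
        ].proportion
        se = per_ind.std() / np.sqrt(len(per_ind))
        assert realized[0] == pytest.approx(0.5, abs=3 * se)

    def test_fully_male_source_depleted_on_x(self, two_pop_freqs):
        """Source contributed only by males: C_X = m/3 < C_A = m/2."""
        spec = two_way_spec(0.0, 1.0, g=10, n=200)
        _, truth = gen_admixed_cohort(two_pop_freqs, spec, seed=2)
        rx = truth.realized[
            (truth.realized.chromosome_set == "X") & (truth.realized.source == "S1")
        ].proportion
        se = rx.std() / np.sqrt(len(rx))
        assert rx.mean() == pytest.approx(1 / 3, abs=3 * se)
        assert rx.mean() + 3 * se < 0.5

    def test_mean_tract_length_matches_generations(self, two_pop_freqs):
        g = 30
        spec = two_way_spec(0.5, 0.5, g=g, n=100)
        _, truth = gen_admixed_cohort(two_pop_freqs, spec, seed=4)
        lens = np.concatenate(
            [tr[:, 1] - tr[:, 0] for (i, c, h), tr in truth.tracts.items() if c != "X"]
        )
        # mean length of a stationary renewal segment on a finite chromosome
        # approaches 1/g for chromosomes much longer than 1/g
        assert lens.mean() == pytest.approx(1 / g, rel=0.1)

    def test_deterministic_given_seed(self, two_pop_freqs):
        spec = two_way_spec(0.6, 0.4, n=4)
        ds1, t1 = gen_admixed_cohort(two_pop_freqs, spec, seed=9)
        ds2, t2 = gen_admixed_cohort(two_pop_freqs, spec, seed=9)
        np.testing.assert_array_equal(ds1.calls, ds2.calls)
        for k in t1.tracts:
            np.testing.assert_array_equal(t1.tracts[k], t2.tracts[k])

    def test_pseudo_haploid_calls_restricted(self, two_pop_freqs):
        spec = AdmixSpec(("S1", "S2"), (0.5, 0.5), (0.5, 0.5), 5, 6,
                         pseudo_haploid=True)
        ds, _ = gen_admixed_cohort(two_pop_freqs, spec, seed=0)
        assert set(np.unique(ds.calls)) <= {0, 2}


class TestDatingCohort:
    def test_ancestry_correlation_decays_at_rate_g(self, two_pop_freqs):
        """Markov tract model: corr of ancestry at distance d is exp(-g d)."""
        g = 2
        _, truth = gen_dating_cohort(
            two_pop_freqs, 0.5, g, 400, seed=11, source_names=("S1", "S2")
        )
        d = 0.5
        pairs = []
        for (ind, chrom, hap), tr in truth.tracts.items():
            if chrom == "X":
                continue
            a = truth.ancestry_at(ind, chrom, hap, np.array([0.1]))[0]
            b = truth.ancestry_at(ind, chrom, hap, np.array([0.1 + d]))[0]
            pairs.append((a, b))
        a, b = np.array(pairs).T
        corr = np.corrcoef(a, b)[0, 1]
        assert corr == pytest.approx(np.exp(-g * d), abs=0.15 * np.exp(-g * d) + 0.03)

    def test_zero_distance_autocovariance_is_bernoulli_variance(self, two_pop_freqs):
        alpha = 0.5
        _, truth = gen_dating_cohort(
            two_pop_freqs, alpha, 30, 300, seed=12, source_names=("S1", "S2")
        )
        anc = []
        for (ind, chrom, hap), tr in truth.tracts.items():
            if chrom == "X":
                continue
            anc.append(truth.ancestry_at(ind, chrom, hap, np.array([0.5]))[0])
        var = np.var(anc)
        assert var == pytest.approx(alpha * (1 - alpha), rel=0.1)

    def test_invalid_alpha_rejected(self, two_pop_freqs):
        with pytest.raises(ValueError, match="alpha"):
            gen_dating_cohort(two_pop_freqs, 1.5, 10, 5, seed=0)


class TestScenarios:
    def test_catalogue_lists_documented_scenarios(self):
        cat = scenario_catalogue()
        assert {"mtwapa-like", "two-source", "sex-biased", "mixed-asian-source"} <= set(cat)

    def test_unknown_scenario_rejected(self, tmp_path):
        with pytest.raises(KeyError, match="unknown scenario"):
            write_fixture_dataset(tmp_path, "no-such-scenario", seed=0)

    def test_mtwapa_like_truth_records_target_proportions(self, tmp_path):
        prefix = write_fixture_dataset(
            tmp_path, "mtwapa-like", seed=0, n_snps=400, n_admixed=4
        )
        text = prefix.with_suffix(".truth.tsv").read_text()
        assert "0.570000" in text and "0.360000" in text and "0.070000" in text

    def test_two_source_scenario_has_two_sources(self):
        _, truth, meta = build_scenario("two-source", seed=0, n_snps=300, n_admixed=3)
        assert len(truth.source_names) == 2

    def test_fixture_files_reproducible(self, tmp_path):
        p1 = write_fixture_dataset(tmp_path / "a", "two-source", 5, n_snps=300, n_admixed=3)
        p2 = write_fixture_dataset(tmp_path / "b", "two-source", 5, n_snps=300, n_admixed=3)
        for ext in (".geno", ".snp", ".ind"):
            assert p1.with_suffix(ext).read_bytes() == p2.with_suffix(ext).read_bytes()
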