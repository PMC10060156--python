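"""Mixture-weight estimation: recovery, calibration and model search."""

import numpy as np
import pytest
from scipy import stats

from admixtide.genotype_io import assign_blocks
from admixtide.qpadm import hotelling_pvalue, mixed_source_grid, qpadm_cycle, qpadm_fit
from admixtide.simulate import build_scenario


class TestFit:
    def test_recovers_three_way_proportions(self, small_scenario, small_blocks):
        ds, truth, meta = small_scenario
        fit = qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"], small_blocks)
        realized = truth.realized_mean("autosomes")
        for w, se, t in zip(fit.weights, fit.weight_se, realized):
            assert w == pytest.approx(t, abs=3 * se)
        assert fit.feasible
        assert fit.fit_p > 0.001

    def test_weights_sum_to_one_exactly(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        fit = qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"], small_blocks)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_target_equal_to_source_is_degenerate_mixture(self):
        ds, truth, meta = build_scenario(
            "two-source", seed=21, n_snps=8000, n_admixed=40,
        )
        # replace the admixed cohort by a pure African-drawn cohort
        from admixtide.simulate import (
            AdmixSpec,
            SimPopSpec,
            combine,
            gen_admixed_cohort,
            gen_reference_freqs,
            sample_panel,
        )

        rng = np.random.default_rng(21)
        specs = [
            SimPopSpec("African", 0.02, 25, clade="a"),
            SimPopSpec("Persian", 0.02, 25, clade="p"),
            SimPopSpec("R_African", 0.02, 25, clade="a"),
            SimPopSpec("R_Persian", 0.02, 25, clade="p"),
            SimPopSpec("Out1", 0.1, 25),
            SimPopSpec("Out2", 0.08, 25),
        ]
        freqs = gen_reference_freqs(specs, 8000, seed=rng)
        panels = [sample_panel(freqs, s.name, rng) for s in specs]
        pure = AdmixSpec(("African", "Persian"), (1.0, 0.0), (1.0, 0.0), 5, 40,
                         name="Pure")
        target, _ = gen_admixed_cohort(freqs, pure, rng)
        ds = combine(*panels, target)
        blocks = assign_blocks(ds, 5.0, "autosomes")
        fit = qpadm_fit(
            ds, "Pure", ["African", "Persian"],
            ["Out1", "R_African", "R_Persian", "Out2"], blocks,
        )
        assert fit.weights[0] == pytest.approx(1.0, abs=2 * fit.weight_se[0] + 1e-6)
        assert fit.fit_p > 0.01

    def test_weights_invariant_to_right_permutation(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        rights = meta["rights"]
        f1 = qpadm_fit(ds, meta["target"], meta["sources"], rights, small_blocks)
        permuted = [rights[0]] + rights[1:][::-1]
        f2 = qpadm_fit(ds, meta["target"], meta["sources"], permuted, small_blocks)
        np.testing.assert_allclose(f1.weights, f2.weights, atol=1e-6)

    def test_missing_source_detected(self):
        """Target with ancestry absent from the model fails the fit test."""
        rejected = 0
        reps = 12
        for seed in range(reps):
            ds, _, meta = build_scenario(
                "mtwapa-like", seed=500 + seed, n_snps=8000, n_admixed=40
            )
            blocks = assign_blocks(ds, 5.0, "autosomes")
            fit = qpadm_fit(
                ds, meta["target"], ["African", "Persian"], meta["rights"], blocks
            )
            if fit.fit_p < 0.05:
                rejected += 1
        assert rejected >= 0.8 * reps

    def test_requires_enough_rights(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        with pytest.raises(ValueError, match="rights"):
            qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"][:3], small_blocks)

    def test_x_blocks_minimum_enforced(self, small_scenario):
        ds, _, meta = small_scenario
        xb = assign_blocks(ds, 60.0, "X")  # 180 cM / 60 cM = 3 blocks
        with pytest.raises(ValueError, match="X-chromosome blocks"):
            qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"], xb)

    def test_fit_p_uniform_under_correct_model(self):
        """Kolmogorov–Smirnov check of p-value calibration over replicates."""
        ps = []
        for seed in range(50):
            ds, _, meta = build_scenario(
                "two-source", seed=3000 + seed, n_snps=6000, n_admixed=30
            )
            blocks = assign_blocks(ds, 5.0, "autosomes")
            fit = qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"], blocks)
            ps.append(fit.fit_p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001

    def test_x_mode_reflects_sex_bias(self):
        """Female-biased source has higher weight on X than on autosomes."""
        ds, truth, meta = build_scenario(
            "sex-biased", seed=8, n_snps=20000, n_admixed=150
        )
        ba = assign_blocks(ds, 5.0, "autosomes")
        bx = assign_blocks(ds, 5.0, "X")
        fa = qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"], ba)
        fx = qpadm_fit(ds, meta["target"], meta["sources"], meta["rights"], bx)
        gap = fx.weights[0] - fa.weights[0]
        se = np.hypot(fx.weight_se[0], fa.weight_se[0])
        # analytic gap C_X - C_A = (f - m)/6 = (0.9 - 0.1)/6
        assert gap == pytest.approx(0.8 / 6, abs=3 * se)
        assert gap > 0


class TestCycling:
    def test_two_candidates_make_three_rows(self):
        ds, _, meta = build_scenario("two-source", seed=2, n_snps=5000, n_admixed=30)
        blocks = assign_blocks(ds, 5.0, "autosomes")
        table = qpadm_cycle(ds, meta["target"], meta["sources"], meta["rights"], blocks)
        assert len(table.fits) == 3
        assert set(table.fits.n_sources) == {1, 2}

    def test_irrelevant_candidate_excluded(self):
        """A 2-way mixture with a third spurious candidate: the true pair fits,
        single-source models fail."""
        from admixtide.simulate import scenario_catalogue

        base_cfg = scenario_catalogue()["two-source"]
        pops = dict(base_cfg["populations"])
        pops["Outgroup3"] = {"drift_F": 0.09, "n": 25}
        ok = 0
        reps = 10
        for seed in range(reps):
            ds, _, meta = build_scenario(
                "two-source", seed=4000 + seed, n_snps=8000, n_admixed=40,
                populations=pops, rights=base_cfg["rights"] + ["Outgroup3"],
            )
            blocks = assign_blocks(ds, 5.0, "autosomes")
            # Outgroup2 is unrelated to the target's ancestry: spurious candidate
            cands = meta["sources"] + ["Outgroup2"]
            rights = [r for r in meta["rights"] if r != "Outgroup2"]
            table = qpadm_cycle(ds, meta["target"], cands, rights, blocks)
            singles = table.fits[table.fits.n_sources == 1]
            true_pair = table.fits[table.fits.sources == ",".join(meta["sources"])]
            if (singles.fit_p < 0.05).all() and len(true_pair) and bool(
                true_pair.iloc[0].fitting
            ):
                ok += 1
        assert ok >= 0.8 * reps

    def test_subset_cap_enforced(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        with pytest.raises(ValueError, match="cap"):
            qpadm_cycle(
                ds, meta["target"], ["a"] * 12, meta["rights"], small_blocks,
                subset_cap=100,
            )


class TestMixedSourceGrid:
    def test_endpoints_match_plain_two_source_fits(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        grid = mixed_source_grid(
            ds, meta["target"], "African", "Persian", "Indian",
            meta["rights"], [0.0, 1.0], small_blocks,
        )
        plain_ind = qpadm_fit(
            ds, meta["target"], ["African", "Indian"], meta["rights"], small_blocks
        )
        plain_per = qpadm_fit(
            ds, meta["target"], ["African", "Persian"], meta["rights"], small_blocks
        )
        assert grid.iloc[0].T2 == pytest.approx(plain_ind.chisq, rel=1e-9)
        assert grid.iloc[1].T2 == pytest.approx(plain_per.chisq, rel=1e-9)

    def test_single_point_grid(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        grid = mixed_source_grid(
            ds, meta["target"], "African", "Persian", "Indian",
            meta["rights"], 0.5, small_blocks,
        )
        assert len(grid) == 1

    def test_pi_outside_unit_interval_rejected(self, small_scenario, small_blocks):
        ds, _, meta = small_scenario
        with pytest.raises(ValueError, match="pi"):
            mixed_source_grid(
                ds, meta["target"], "African", "Persian", "Indian",
                meta["rights"], [-0.1], small_blocks,
            )

    def test_hotelling_needs_enough_blocks(self):
        with pytest.raises(ValueError, match="blocks"):
            hotelling_pvalue(5.0, q=4, n_blocks=3)
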