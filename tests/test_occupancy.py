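"""Occupancy model: geometry, enumeration, activity, fitting, predictions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crmgrammar.motifs import CRMDesign, Site
from crmgrammar.occupancy import (
    FitConfig,
    HEART_RULE,
    ModelParams,
    PMAD_MOTIF,
    TIN_MOTIF,
    VM_RULE,
    activation_probability,
    alternating_design,
    enumerate_configurations,
    fit_parameters,
    leave_two_out_cv,
    motif_number_curve,
    overlap_weight,
    partition_function,
    predict_measurements,
    predict_observables,
    predict_short_crms,
    site_occupancy,
)
from helpers_oracle import (
    brute_force_activation,
    brute_force_partition,
    random_design,
    random_params,
)

NEUTRAL = ModelParams()  # q1=q2=1, r=0: fully independent binding


def pmad(orient="sense"):
    return Site("pMad", PMAD_MOTIF, orient)


def tin(orient="antisense"):
    return Site("Tin", TIN_MOTIF, orient)


def mtm(gap, orient="antisense"):
    return CRMDesign(f"MTM{gap}", (pmad(), tin(orient), pmad()), (gap, gap))


class TestOverlapWeight:
    def test_full_overlap_at_zero_gap(self):
        for r in (0.5, 1, 3, 10):
            assert overlap_weight(0, r) == pytest.approx(1.0)

    def test_zero_beyond_contact_distance(self):
        assert overlap_weight(6, 3) == 0.0
        assert overlap_weight(7, 3) == 0.0
        assert overlap_weight(0, 0) == 0.0

    def test_half_separation_closed_form(self):
        # lens volume at gap == radius: 5/16 of full overlap
        for r in (1.0, 2.5, 4.0):
            assert overlap_weight(r, r) == pytest.approx(5 / 16)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            overlap_weight(-1, 2)
        with pytest.raises(ValueError):
            overlap_weight(1, -2)

    @given(
        st.floats(0, 20), st.floats(0, 20), st.floats(0.01, 10)
    )
    def test_monotone_non_increasing_in_gap(self, d1, d2, r):
        lo, hi = sorted((d1, d2))
        assert overlap_weight(lo, r) >= overlap_weight(hi, r)


class TestEnumeration:
    def test_two_sites_give_four_configurations(self):
        design = alternating_design("pair", 2, 4)
        configs = enumerate_configurations(design, NEUTRAL)
        assert len(configs) == 4
        assert len({c.occupancy for c in configs}) == 4

    def test_unbound_configuration_has_weight_one(self):
        design = alternating_design("a4", 4, 4)
        params = ModelParams(q1=20, q2=5, r_sense=2, r_antisense=4)
        configs = enumerate_configurations(design, params)
        unbound = next(c for c in configs if not any(c.occupancy))
        assert unbound.weight == pytest.approx(1.0)

    def test_no_interaction_limit_all_weights_one(self):
        design = alternating_design("a2", 5, 2)
        configs = enumerate_configurations(design, NEUTRAL)
        assert all(c.weight == pytest.approx(1.0) for c in configs)
        assert partition_function(design, NEUTRAL) == pytest.approx(2**5)

    def test_weights_match_brute_force(self, rng):
        for variant in ("pairs_only", "higher_order"):
            design = random_design(rng, 5)
            params = random_params(rng)
            got = {c.occupancy: c.weight for c in
                   enumerate_configurations(design, params, variant)}
            from helpers_oracle import brute_force_states
            for bits, w, _ in brute_force_states(design, params, variant):
                key = tuple(bool(b) for b in bits)
                assert got[key] == pytest.approx(w, rel=1e-9)

    def test_refuses_oversized_designs(self):
        sites = tuple(pmad() for _ in range(21))
        big = CRMDesign("big", sites, tuple([2] * 20))
        with pytest.raises(ValueError, match="capped"):
            partition_function(big, NEUTRAL)


class TestPartitionFunction:
    def test_neutral_two_site_z_is_four(self):
        assert partition_function(alternating_design("p", 2, 4), NEUTRAL) == pytest.approx(4.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(8):
            n = int(rng.integers(2, 9))
            design = random_design(rng, n)
            params = random_params(rng)
            for variant in ("pairs_only", "higher_order"):
                z = partition_function(design, params, variant)
                z_ref = brute_force_partition(design, params, variant)
                assert z == pytest.approx(z_ref, rel=1e-9)

    def test_unbindable_pseudo_site_leaves_z_unchanged(self):
        base = CRMDesign("homo", (pmad(), pmad(), pmad()), (6, 6))
        extended = CRMDesign(
            "homo+", (pmad(), pmad(), pmad(), tin()), (6, 6, 2)
        )
        params = ModelParams(q1=50, q2=10, r_sense=3, r_antisense=4, b0=1e-12)
        z_base = partition_function(base, ModelParams(a0=1.0))
        z_ext = partition_function(extended, params)
        assert z_ext == pytest.approx(z_base, rel=1e-9)


class TestIndependentBindingLimit:
    def test_site_occupancy_matches_closed_form(self):
        params = ModelParams(q1=1, q2=1, r_sense=5, r_antisense=5, a0=0.7, b0=2.5)
        design = alternating_design("mix", 6, 2)
        occ = site_occupancy(design, params)
        for site, p in zip(design.sites, occ):
            w = params.a0 if site.tf_name == "pMad" else params.b0
            assert p == pytest.approx(w / (1 + w), abs=1e-12)


class TestActivationProbability:
    def test_zero_when_no_contacts_possible(self):
        params = ModelParams(q1=100, q2=100, r_sense=2, r_antisense=2)
        design = alternating_design("a8", 6, 8)  # 8 >= 2r everywhere
        assert activation_probability(design, params, VM_RULE, "higher_order") == 0.0

    def test_dominant_configuration_limit(self):
        params = ModelParams(q1=2, q2=1e9, r_sense=4, r_antisense=4)
        assert activation_probability(mtm(2), params, VM_RULE, "higher_order") > 0.999

    def test_matches_brute_force_on_toy_design(self, rng):
        design = random_design(rng, 4)
        params = random_params(rng)
        for rule in (VM_RULE, HEART_RULE):
            for variant in ("pairs_only", "higher_order"):
                got = activation_probability(design, params, rule, variant)
                ref = brute_force_activation(design, params, rule, variant)
                assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_distance_monotonicity_in_single_gap(self, rng):
        for _ in range(20):
            params = random_params(rng)
            gaps = [int(g) for g in rng.integers(0, 9, size=5)]
            idx = int(rng.integers(0, 5))
            prev = None
            for extra in range(0, 10, 3):
                g = list(gaps)
                g[idx] += extra
                design = CRMDesign(
                    "mono",
                    tuple(pmad() if i % 2 == 0 else tin() for i in range(6)),
                    tuple(g),
                )
                p = activation_probability(design, params, VM_RULE, "higher_order")
                if prev is not None:
                    assert p <= prev + 1e-12
                prev = p

    def test_orientation_symmetry(self, rng):
        for _ in range(10):
            params = random_params(rng)
            swapped = ModelParams(
                q1=params.q1, q2=params.q2,
                r_sense=params.r_antisense, r_antisense=params.r_sense,
                a0=params.a0, b0=params.b0,
            )
            design = random_design(rng, 6)
            flipped = CRMDesign(
                design.name,
                tuple(
                    Site(
                        s.tf_name, s.sequence,
                        ("antisense" if s.orientation == "sense" else "sense")
                        if s.tf_name == "Tin" else s.orientation,
                    )
                    for s in design.sites
                ),
                design.spacings,
            )
            for variant in ("pairs_only", "higher_order"):
                p1 = activation_probability(design, params, VM_RULE, variant)
                p2 = activation_probability(flipped, swapped, VM_RULE, variant)
                assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-15)

    def test_probability_normalization(self, rng):
        design = random_design(rng, 7)
        params = random_params(rng)
        configs = enumerate_configurations(design, params, "higher_order")
        z = partition_function(design, params, "higher_order")
        assert sum(c.weight for c in configs) / z == pytest.approx(1.0, rel=1e-12)


class TestPredictObservables:
    @pytest.mark.parametrize(
        "p, n, expected_pen",
        [(0.0, 4, 0.0), (1.0, 4, 1.0), (0.5, 4, 0.9375)],
    )
    def test_link_function(self, p, n, expected_pen):
        pen, exp_ = predict_observables(p, n)
        assert pen == pytest.approx(expected_pen)
        assert exp_ == pytest.approx(p)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            predict_observables(1.2, 4)


class TestShortCRMPredictions:
    PARAMS = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)

    def test_single_pair_inactive_under_higher_order(self):
        pair = alternating_design("pair", 2, 4)
        (rec,) = predict_short_crms(self.PARAMS, [pair], VM_RULE, "higher_order")
        assert rec.predicted_penetrance == 0.0
        assert rec.predicted_expressivity == 0.0

    def test_triple_with_contact_is_active(self):
        (rec,) = predict_short_crms(self.PARAMS, [mtm(4)], VM_RULE, "higher_order")
        assert rec.predicted_expressivity > 0

    def test_consistent_with_direct_activation_calls(self):
        designs = [mtm(2), mtm(4), alternating_design("six", 6, 4)]
        records = predict_short_crms(self.PARAMS, designs, VM_RULE, "higher_order")
        for rec, d in zip(records, designs):
            p = activation_probability(d, self.PARAMS, VM_RULE, "higher_order")
            pen, exp_ = predict_observables(p, 4)
            assert rec.predicted_penetrance == pytest.approx(pen)
            assert rec.predicted_expressivity == pytest.approx(exp_)


class TestMotifNumberCurve:
    def test_two_sites_inactive_under_higher_order(self):
        params = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)
        curve = motif_number_curve(params, "antisense", 4, [2], VM_RULE)
        assert curve["higher_order"].iloc[0] == 0.0
        assert curve["pairs_only"].iloc[0] > 0

    def test_six_site_value_matches_direct_call(self):
        params = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)
        curve = motif_number_curve(params, "antisense", 4, range(1, 7), VM_RULE)
        direct = activation_probability(
            alternating_design("a4", 6, 4), params, VM_RULE, "higher_order"
        )
        assert curve["higher_order"].iloc[-1] == pytest.approx(direct)

    def test_monotone_in_motif_number(self, rng):
        for _ in range(100):
            params = random_params(rng)
            curve = motif_number_curve(params, "antisense", 4, range(1, 8), VM_RULE)
            for col in ("pairs_only", "higher_order"):
                vals = curve[col].to_numpy()
                assert np.all(np.diff(vals) >= -1e-12)


class TestFitting:
    def test_noiseless_self_consistency(self):
        from crmgrammar.simulate import heterotypic_design_set

        truth = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)
        designs = heterotypic_design_set()
        table = predict_measurements(designs, truth, VM_RULE, "higher_order")
        params, resid = fit_parameters(table, designs, VM_RULE, "higher_order")
        assert resid < 1e-6
        assert params.r_sense == pytest.approx(truth.r_sense, abs=0.1)
        assert params.r_antisense == pytest.approx(truth.r_antisense, abs=0.1)
        assert params.q1 == pytest.approx(truth.q1, rel=0.05)
        assert params.q2 == pytest.approx(truth.q2, rel=0.05)

    def test_higher_order_fits_triple_generated_data_better(self):
        from crmgrammar.simulate import heterotypic_design_set

        truth = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)
        designs = heterotypic_design_set()
        table = predict_measurements(designs, truth, VM_RULE, "higher_order")
        _, resid_pairs = fit_parameters(table, designs, VM_RULE, "pairs_only")
        _, resid_higher = fit_parameters(table, designs, VM_RULE, "higher_order")
        assert resid_higher <= resid_pairs
        assert resid_pairs > 0.01  # pairs cannot silence the pair-only design

    def test_empty_measurements_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            fit_parameters(pd.DataFrame(), [mtm(2), mtm(4)], VM_RULE)


class TestCrossValidation:
    FAST = FitConfig(n_q=7, r_step=1.0, n_refine=1, polish=False)

    def test_fold_count_is_n_choose_two(self):
        truth = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)
        designs = [mtm(2), mtm(4), mtm(6), alternating_design("a4", 4, 4)]
        table = predict_measurements(designs, truth, VM_RULE, "higher_order")
        cv = leave_two_out_cv(
            table, designs, VM_RULE, "higher_order", fit_config=self.FAST
        )
        assert cv.n_folds == 6

    def test_baseline_matches_uniform_simulation(self, rng):
        truth = ModelParams(q1=10, q2=5, r_sense=2.5, r_antisense=3.9)
        designs = [mtm(2), mtm(4), mtm(6), alternating_design("a4", 4, 4)]
        table = predict_measurements(designs, truth, VM_RULE, "higher_order")
        cv = leave_two_out_cv(
            table, designs, VM_RULE, "higher_order", fit_config=self.FAST
        )
        obs = np.concatenate(
            [table["penetrance"].to_numpy(), table["expressivity"].to_numpy()]
        )
        for t, base in zip(cv.tolerances, cv.random_baseline):
            draws = rng.uniform(0, 1, size=(20000, obs.size))
            mc = np.mean(np.abs(draws - obs) <= t)
            assert base == pytest.approx(mc, abs=0.02)
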