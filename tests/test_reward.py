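"""Reward function g(x): components, bounds, size window adaptation."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from molfeedback.chem import Fingerprint, morgan_fingerprint, parse_molecule, tanimoto
from molfeedback.feedback import derive_reward_inputs
from molfeedback.reward import (
    RewardConfig,
    RewardInputs,
    SizeWindow,
    compute_reward,
    delta,
    gamma,
    size_score,
    total_score,
    update_size_window,
)
from conftest import random_table

G_LOW, G_HIGH = -1.0 / 3.0, 7.0 / 12.0


class TestGamma:
    def test_empty_list_is_zero(self):
        assert gamma(parse_molecule("c1ccccc1"), []) == 0.0

    def test_cap_one_saturates(self):
        benzene = parse_molecule("c1ccccc1")
        assert gamma(benzene, ["c1ccccc1"], count_cap=1) == 1.0

    def test_cap_three_counts_fractionally(self):
        # phenol matches both the ring and the hydroxyl pattern: 2 of cap 3
        phenol = parse_molecule("Oc1ccccc1")
        patterns = ["c1ccccc1", "[OX2H]", "[CX3]=[OX1]"]
        assert gamma(phenol, patterns, count_cap=3) == pytest.approx(2 / 3)


class TestDelta:
    def test_empty_reference_set_is_zero(self):
        fp = morgan_fingerprint(parse_molecule("c1ccccc1"))
        assert delta(fp, set()) == 0.0

    def test_identical_reference_gives_one(self):
        fp = morgan_fingerprint(parse_molecule("c1ccccc1"))
        assert delta(fp, {fp}) == 1.0

    def test_below_cutoff_similarity_zeroed(self):
        """Benzene↔hexane ECFP4 similarity is below 0.5, so δ is exactly 0."""
        hexane = morgan_fingerprint(parse_molecule("CCCCCC"))
        benzene = morgan_fingerprint(parse_molecule("c1ccccc1"))
        assert delta(hexane, {benzene}, cutoff=0.5) == 0.0
        # a structurally close but sub-cutoff pair is gated too, yet passes
        # through ungated — the zeroing comes from the cutoff, not from δ
        toluene = morgan_fingerprint(parse_molecule("Cc1ccccc1"))
        raw = tanimoto(toluene, benzene)
        assert 0.0 < raw <= 0.5
        assert delta(toluene, {benzene}, cutoff=0.5) == 0.0
        assert delta(toluene, {benzene}, cutoff=0.0) == pytest.approx(raw)

    def test_gating_is_exact_at_cutoff(self):
        a = Fingerprint(frozenset(range(10)))
        b = Fingerprint(frozenset(range(5)))  # tanimoto exactly 0.5
        assert delta(a, {b}, cutoff=0.5) == 0.0  # "greater than", not >=


class TestSizeScore:
    def test_mid_window_is_nearly_one(self):
        assert size_score(35, SizeWindow()) >= 0.999

    def test_far_below_window_is_nearly_zero(self):
        assert size_score(0, SizeWindow()) <= 0.001

    def test_matches_logistic_closed_form(self):
        window = SizeWindow(low_center=12, high_center=40, low_slope=0.7, high_slope=0.4)
        for n in (0, 10, 25, 40, 80):
            expected = expit(0.7 * (n - 12)) * expit(0.4 * (40 - n))
            assert size_score(n, window) == pytest.approx(expected, rel=1e-12)

    def test_unimodal_over_sweep(self):
        values = [size_score(n, SizeWindow()) for n in range(101)]
        peak = values.index(max(values))
        assert all(values[i] <= values[i + 1] + 1e-12 for i in range(peak))
        assert all(values[i] >= values[i + 1] - 1e-12 for i in range(peak, 100))


class TestUpdateSizeWindow:
    def test_too_large_moves_high_center(self):
        window = SizeWindow(low_center=10, high_center=60, alpha=0.25)
        updated = update_size_window(window, 40, "too_large")
        assert updated.high_center == pytest.approx(55.0)
        assert updated.low_center == window.low_center

    def test_too_small_moves_low_center(self):
        window = SizeWindow(low_center=10, high_center=60, alpha=0.25)
        updated = update_size_window(window, 8, "too_small")
        assert updated.low_center == pytest.approx(9.5)
        assert updated.high_center == window.high_center

    def test_ok_inside_window_is_identity(self):
        window = SizeWindow(low_center=10, high_center=60)
        assert update_size_window(window, 30, "ok") == window

    def test_ok_outside_relaxes_violated_bound(self):
        window = SizeWindow(low_center=10, high_center=60, alpha=0.25)
        updated = update_size_window(window, 80, "ok")
        assert updated.high_center == pytest.approx(65.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        low=st.floats(3, 40),
        gap=st.floats(2.5, 60),
        alpha=st.floats(0.05, 1.0),
        n=st.integers(1, 120),
        verdict=st.sampled_from(["too_small", "too_large", "ok"]),
    )
    def test_update_preserves_ordering_and_moves_toward_n(self, low, gap, alpha, n, verdict):
        window = SizeWindow(low_center=low, high_center=low + gap, alpha=alpha)
        updated = update_size_window(window, n, verdict)
        assert updated.low_center < updated.high_center
        # at most one center moved, and it moved toward n
        moved_low = updated.low_center != window.low_center
        moved_high = updated.high_center != window.high_center
        assert not (moved_low and moved_high)
        if moved_low:
            assert abs(updated.low_center - n) <= abs(window.low_center - n)
        if moved_high:
            assert abs(updated.high_center - n) <= abs(window.high_center - n)


class TestComputeReward:
    def test_empty_feedback_leaves_only_size_term(self):
        mol = parse_molecule("c1ccc(-c2ccccc2)cc1CCCCCCCCCCCCCCCCCCCCCCC")
        breakdown = compute_reward(mol, RewardInputs())
        assert breakdown.gamma_plus == breakdown.gamma_minus == 0.0
        assert breakdown.delta_plus == breakdown.delta_minus == breakdown.delta_pm == 0.0
        assert breakdown.g == pytest.approx(breakdown.size_score / 6.0)

    def test_single_disliked_match_with_dead_size_term(self):
        nitrobenzene = parse_molecule("O=[N+]([O-])c1ccccc1")
        # window far above the molecule: φ ≈ 0
        window = SizeWindow(low_center=500, high_center=600, low_slope=5.0)
        inputs = RewardInputs(disliked_smarts=("[N+](=O)[O-]",), size_window=window)
        breakdown = compute_reward(nitrobenzene, inputs)
        assert breakdown.gamma_minus == 1.0
        assert breakdown.g == pytest.approx(-1.0 / 6.0, abs=1e-9)

    def test_component_corner_cases_stay_in_bound(self):
        """Brute-force all component extremes through the combining formula."""
        config = RewardConfig()
        for gp, gm, dp, dm, dpm, phi in itertools.product([0.0, 1.0], repeat=6):
            g = config.prefactor * (gp - gm + dp - dm + config.sort_of_weight * dpm + phi)
            assert G_LOW - 1e-12 <= g <= G_HIGH + 1e-12

    def test_breakdown_combination_identity(self, pool):
        rng = random.Random(11)
        table = random_table(rng, pool, n_records=5)
        inputs = derive_reward_inputs(table)
        config = RewardConfig()
        for smiles in rng.sample(pool, 10):
            b = compute_reward(parse_molecule(smiles), inputs, config)
            expected = config.prefactor * (
                b.gamma_plus
                - b.gamma_minus
                + b.delta_plus
                - b.delta_minus
                + config.sort_of_weight * b.delta_pm
                + b.size_score
            )
            assert b.g == pytest.approx(expected, abs=1e-12)

    def test_extra_matching_disliked_smarts_never_raises_g(self, pool):
        """Appending a matching disliked pattern cannot increase the reward."""
        benzene_pat = "c1ccccc1"
        nitro_pat = "[N+](=O)[O-]"
        mol = parse_molecule("O=[N+]([O-])c1ccccc1")
        base = RewardInputs(disliked_smarts=(benzene_pat,))
        more = RewardInputs(disliked_smarts=(benzene_pat, nitro_pat))
        config = RewardConfig(count_cap=2)
        assert compute_reward(mol, more, config).g <= compute_reward(mol, base, config).g
        liked_base = RewardInputs(liked_smarts=(benzene_pat,))
        liked_more = RewardInputs(liked_smarts=(benzene_pat, nitro_pat))
        assert (
            compute_reward(mol, liked_more, config).g
            >= compute_reward(mol, liked_base, config).g
        )


class TestTotalScore:
    def test_addition_identity(self):
        mol = parse_molecule("c1ccccc1")
        breakdown = compute_reward(mol, RewardInputs())
        assert total_score(0.0, breakdown) == breakdown.g
        assert total_score(0.8, breakdown) - 0.8 == pytest.approx(breakdown.g)

    def test_f_plus_minus_sixth_example(self):
        nitrobenzene = parse_molecule("O=[N+]([O-])c1ccccc1")
        window = SizeWindow(low_center=500, high_center=600, low_slope=5.0)
        inputs = RewardInputs(disliked_smarts=("[N+](=O)[O-]",), size_window=window)
        breakdown = compute_reward(nitrobenzene, inputs)
        assert total_score(0.8, breakdown) == pytest.approx(0.8 - 1.0 / 6.0, abs=1e-9)
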