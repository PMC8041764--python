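"""Reliability/validity machinery vs exhaustive small-sample oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ocsplus import (
    attenuation_correct,
    compare_cohorts,
    correlation_power,
    paired_retest,
    reliable_change_index,
    simulate_external_battery,
    spearman_brown,
    split_half_reliability,
    validity_table,
)


class TestSplitHalf:
    def test_strong_latent_trait_gives_high_reliability(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=(200, 1))
        items = latent + rng.normal(scale=0.4, size=(200, 12))
        res = split_half_reliability(items, n_iter=300, seed=1)
        assert res.estimate > 0.9
        assert res.interpretable

    def test_parallel_halves_exact_unity(self):
        # two items, identical: every split correlates x with x
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 1))
        items = np.column_stack([x, x])
        res = split_half_reliability(items, n_iter=50, seed=3)
        assert res.estimate == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        items = rng.integers(0, 2, size=(500, 10)).astype(float)
        res = split_half_reliability(items, n_iter=400, seed=5)
        assert abs(res.estimate) < 0.1

    def test_ceiling_task_flagged_uninterpretable(self):
        items = np.ones((100, 4))
        items[0, 0] = 0.0  # a single error in a ceiling-level 4-item task
        res = split_half_reliability(items, n_iter=200, seed=6)
        assert not res.interpretable

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        items = rng.normal(size=(80, 12))
        a = split_half_reliability(items, n_iter=300, seed=42)
        b = split_half_reliability(items, n_iter=300, seed=42)
        assert a.estimate == b.estimate and a.ci_low == b.ci_low

    def test_invariant_to_item_permutation(self):
        rng = np.random.default_rng(8)
        latent = rng.normal(size=(150, 1))
        items = latent + rng.normal(scale=0.8, size=(150, 10))
        a = split_half_reliability(items, n_iter=500, seed=9)
        b = split_half_reliability(items[:, ::-1], n_iter=500, seed=10)
        assert abs(a.estimate - b.estimate) < (a.ci_high - a.ci_low)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(12)
        items = rng.normal(size=(60, 8))
        res = split_half_reliability(items, n_iter=300, seed=13)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_bootstrap_split_variant_runs(self):
        rng = np.random.default_rng(14)
        latent = rng.normal(size=(120, 1))
        items = latent + rng.normal(scale=1.0, size=(120, 8))
        res = split_half_reliability(items, n_iter=300, seed=15,
                                     scheme="bootstrap_split")
        assert 0 < res.estimate <= 1.05


class TestAttenuation:
    @pytest.mark.parametrize(
        "coeff,rx,ry,expected,flag",
        [(0.5, 1.0, 1.0, 0.5, False),
         (0.3, 0.36, 0.25, 1.0, False),
         (0.5, 0.1, 0.1, 5.0, True)],
    )
    def test_examples(self, coeff, rx, ry, expected, flag):
        corrected, exceeds = attenuation_correct(coeff, rx, ry)
        assert corrected == pytest.approx(expected)
        assert exceeds is flag

    def test_identity_reliabilities_exact(self):
        for c in (-0.7, -0.2, 0.0, 0.4, 0.99):
            assert attenuation_correct(c, 1.0, 1.0)[0] == c

    def test_magnitude_never_shrinks(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            c = float(rng.uniform(-1, 1))
            rx, ry = rng.uniform(0.05, 1.0, 2)
            corrected, _ = attenuation_correct(c, rx, ry)
            assert abs(corrected) >= abs(c)

    def test_nonpositive_reliability_rejected(self):
        with pytest.raises(ValueError):
            attenuation_correct(0.5, 0.0, 1.0)


class TestRCI:
    def test_no_change_is_zero(self):
        assert reliable_change_index(8.0, 8.0, 2.0, 0.5) == 0.0

    def test_closed_form_example(self):
        # denominator = 2 * sqrt(2) * sqrt(0.5) = 2.0
        assert reliable_change_index(8, 10, 2.0, 0.5) == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x1, x2 = rng.normal(20, 5, 2)
            sd = float(rng.uniform(0.5, 6))
            r = float(rng.uniform(0, 0.99))
            assert reliable_change_index(x1, x2, sd, r) == pytest.approx(
                -reliable_change_index(x2, x1, sd, r)
            )

    def test_perfect_reliability_rejected(self):
        with pytest.raises(ValueError, match="r_xx"):
            reliable_change_index(8, 10, 2.0, 1.0)


def wilcoxon_oracle(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=d.size)
    ])
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(w_obs, ranks.sum() - w_obs), min(1.0, p)


def mannwhitney_oracle(a, b):
    """Exact two-sided Mann–Whitney p via full label-permutation
    enumeration; U by direct concordant-pair counting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    pooled = np.concatenate([a, b])
    n = pooled.size
    us = []
    for comb in itertools.combinations(range(n), a.size):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        ga, gb = pooled[mask], pooled[~mask]
        us.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, p)


def kendall_oracle(x, y):
    """O(n^2) tau-b via explicit concordant/discordant pair counts."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


class TestRetest:
    def test_identical_sessions_report_no_change(self):
        x = np.arange(10.0)
        res = paired_retest(x, x)
        assert res.n_nontied == 0
        assert not res.significant_raw
        assert np.all(res.rci == 0)
        assert "tied" in res.note

    def test_exact_p_matches_enumeration(self):
        """Signed-rank p equals the 2^n sign-flip oracle for n = 8."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            t1 = rng.normal(20, 4, 8)
            t2 = t1 + rng.normal(0.8, 1.5, 8)
            res = paired_retest(t1, t2)
            w_oracle, p_oracle = wilcoxon_oracle(t2 - t1)
            assert res.statistic == pytest.approx(w_oracle)
            assert res.p == pytest.approx(p_oracle)

    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(18)
        t1 = rng.normal(size=30)
        res = paired_retest(t1, t1 + rng.normal(size=30), family_size=15)
        assert res.alpha_corrected == pytest.approx(0.05 / 15)
        assert round(res.alpha_corrected, 4) == 0.0033

    def test_rci_sign_flips_with_session_order(self):
        rng = np.random.default_rng(19)
        t1 = rng.normal(50, 8, 40)
        t2 = t1 + rng.normal(1, 3, 40)
        fwd = paired_retest(t1, t2, r_xx=0.7)
        rev = paired_retest(t2, t1, r_xx=0.7)
        # baseline SD differs between orders; compare on a common scale
        np.testing.assert_allclose(
            fwd.rci * np.std(t1, ddof=1), -rev.rci * np.std(t2, ddof=1)
        )


class TestCompareCohorts:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame({"rule_accuracy": rng.normal(26, 8, 40)})
        out = compare_cohorts(df, df.copy(), ["rule_accuracy"])
        assert out.loc[0, "U"] == pytest.approx(40 * 40 / 2)
        assert not out.loc[0, "significant_raw"]

    def test_u_and_p_match_enumeration(self):
        """U and exact p agree with full permutation enumeration, n=12."""
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1.2, 1, 6)
        out = compare_cohorts(
            pd.DataFrame({"figure_recall": a + 40}),
            pd.DataFrame({"figure_recall": b + 40}),
            ["figure_recall"],
        )
        u_oracle, p_oracle = mannwhitney_oracle(a + 40, b + 40)
        assert out.loc[0, "U"] == pytest.approx(u_oracle)
        assert out.loc[0, "p"] == pytest.approx(p_oracle)

    def test_shifted_groups_detected_after_correction(self):
        """1-SD location shift at n=80/80 is significant (corrected) in
        >95% of simulations."""
        rng = np.random.default_rng(22)
        hits = 0
        reps = 60
        for _ in range(reps):
            a = pd.DataFrame({"figure_recall": np.clip(rng.normal(45, 8, 80), 0, 60)})
            b = pd.DataFrame({"figure_recall": np.clip(rng.normal(37, 8, 80), 0, 60)})
            out = compare_cohorts(a, b, ["figure_recall"], family_size=18)
            hits += bool(out.loc[0, "significant_corrected"])
        assert hits / reps > 0.95


class TestValidity:
    def _tables(self, n=60, seed=23, rho=0.6):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        ocs = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n)],
            "figure_copy": np.clip(np.round(50 + 6 * z), 0, 60),
        })
        ext = pd.DataFrame({
            "participant_id": ocs.participant_id,
            "rocf_copy": rho * z + math.sqrt(1 - rho**2) * rng.normal(size=n),
            "mood": rng.normal(size=n),
        })
        mapping = pd.DataFrame({
            "ocs_measure": ["figure_copy", "figure_copy"],
            "external_measure": ["rocf_copy", "mood"],
            "family": ["convergent", "divergent"],
        })
        return ocs, ext, mapping

    def test_monotone_pair_gives_tau_one(self):
        ocs = pd.DataFrame({"participant_id": list("abcde"),
                            "figure_copy": [10, 20, 30, 40, 50]})
        ext = pd.DataFrame({"participant_id": list("abcde"),
                            "rocf_copy": [1.0, 2.0, 3.0, 4.0, 5.0]})
        mapping = pd.DataFrame({"ocs_measure": ["figure_copy"],
                                "external_measure": ["rocf_copy"],
                                "family": ["convergent"]})
        out = validity_table(ocs, ext, mapping, {"figure_copy": 1.0})
        assert out.loc[0, "tau"] == pytest.approx(1.0)

    def test_tau_matches_pair_counting_oracle(self):
        """tau-b equals O(n^2) concordant/discordant enumeration with
        ties, n = 10."""
        rng = np.random.default_rng(24)
        for _ in range(20):
            x = rng.integers(0, 5, 10).astype(float)  # ties likely
            y = rng.integers(0, 5, 10).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            tau, _ = stats.kendalltau(x, y)
            assert tau == pytest.approx(kendall_oracle(x, y))

    def test_family_alpha_from_mapping_not_hardcoded(self):
        ocs, ext, mapping = self._tables()
        mapping = pd.concat([mapping] * 3, ignore_index=True)  # 3 per family
        out = validity_table(ocs, ext, mapping, {"figure_copy": 0.94})
        conv = out[out.family == "convergent"]
        div = out[out.family == "divergent"]
        assert np.allclose(conv.alpha_threshold, 0.05 / 3)
        assert np.allclose(div.alpha_threshold, 0.05 / 3)

    def test_corrected_coefficient_and_unity_flag(self):
        ocs, ext, mapping = self._tables(n=200, rho=0.9)
        out = validity_table(ocs, ext, mapping,
                             {"figure_copy": 0.3, "rocf_copy": 0.3})
        row = out[out.external_measure == "rocf_copy"].iloc[0]
        assert row["corrected_r"] == pytest.approx(row["tau"] / 0.3)
        assert bool(row["exceeds_unity"]) == bool(abs(row["corrected_r"]) > 1)

    def test_too_few_pairs_reported_missing(self):
        ocs, ext, mapping = self._tables(n=2)
        out = validity_table(ocs, ext, mapping, {})
        assert out["n"].iloc[0] == 2
        assert np.isnan(out["tau"].iloc[0])


class TestCorrelationPower:
    def test_null_rejection_at_alpha(self):
        p = correlation_power(1e-9, 100, n_reps=2000, seed=1,
                              alternative="two-sided")
        assert p == pytest.approx(0.05, abs=0.02)

    def test_power_increases_with_n(self):
        lo = correlation_power(0.3, 30, n_reps=1500, seed=2)
        hi = correlation_power(0.3, 120, n_reps=1500, seed=3)
        assert hi > lo
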