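"""Occurrence tables, OLS/Pearson, Kendall tau-b and the generic tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dndscape.cooccur_stats import (
    DegenerateInputError,
    across_taxon_association,
    bh_fdr,
    eligibility_filter,
    occurrence_by_taxon,
    pair_unachievable,
    students_t_test,
    within_taxon_association,
)
from dndscape.genome_io import ValidationError


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair count with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    s = float(np.sum(dx[iu] * dy[iu]))
    n0 = n * (n - 1) / 2
    t1 = sum(c * (c - 1) / 2 for c in np.unique(x, return_counts=True)[1])
    t2 = sum(c * (c - 1) / 2 for c in np.unique(y, return_counts=True)[1])
    denom = np.sqrt((n0 - t1) * (n0 - t2))
    return s / denom if denom > 0 else np.nan


def _profiles_frame(n, flags):
    """Minimal profile frame with only the dndBCDE feature populated."""
    from dndscape.cooccur_stats import FEATURES

    df = pd.DataFrame({"genome_id": [f"G{i}" for i in range(n)]})
    for feat in FEATURES:
        df[feat] = False
        df[f"n_{feat}"] = 0
    df["dndBCDE"] = list(flags)
    df["n_dndBCDE"] = [int(f) for f in flags]
    return df


class TestOccurrence:
    def test_fraction_is_carriers_over_genomes(self):
        prof = _profiles_frame(5, [True, True, False, False, False])
        proph = pd.DataFrame(
            {"genome_id": [f"G{i}" for i in range(5)], "n_prophages": [1, 0, 2, 0, 0]}
        )
        tax = pd.DataFrame(
            {"genome_id": [f"G{i}" for i in range(5)], "genus": ["X"] * 5}
        )
        occ = occurrence_by_taxon(prof, proph, tax, rank="genus", min_genomes=1)
        assert occ.loc[0, "occ_dndBCDE"] == pytest.approx(0.4)
        assert occ.loc[0, "occ_prophage"] == pytest.approx(0.4)
        assert occ.loc[0, "n_genomes"] == 5

    def test_min_genomes_filter_boundary(self):
        prof = _profiles_frame(99, [False] * 99)
        proph = pd.DataFrame(
            {"genome_id": prof["genome_id"], "n_prophages": 0}
        )
        tax = pd.DataFrame({"genome_id": prof["genome_id"], "genus": ["X"] * 99})
        assert len(occurrence_by_taxon(prof, proph, tax, min_genomes=100)) == 0
        assert len(occurrence_by_taxon(prof, proph, tax, min_genomes=99)) == 1

    def test_planted_prevalence_recovered(self, rng):
        n, prev = 500, 0.18
        flags = rng.random(n) < prev
        prof = _profiles_frame(n, flags)
        proph = pd.DataFrame({"genome_id": prof["genome_id"], "n_prophages": 1})
        tax = pd.DataFrame({"genome_id": prof["genome_id"], "genus": ["X"] * n})
        occ = occurrence_by_taxon(prof, proph, tax, min_genomes=1)
        se = np.sqrt(prev * (1 - prev) / n)
        assert abs(occ.loc[0, "occ_dndBCDE"] - prev) < 3 * se


class TestAcrossTaxa:
    def test_perfect_linear_fit(self):
        x = np.array([0.0, 0.5, 1.0, 1.5])
        res = across_taxon_association(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.statistic == pytest.approx(1.0)

    def test_zero_covariance_gives_zero_slope(self):
        res = across_taxon_association([0, 1, 2], [0, 1, 0])
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_significant_negative_classification(self, rng):
        x = np.linspace(0, 1, 30)
        y = 1 - x + rng.normal(0, 0.02, 30)
        res = across_taxon_association(x, y)
        assert res.statistic < -0.7 and res.r_squared > 0.5 and res.p_value < 1e-3
        assert res.classification == "significant_negative"

    def test_weak_association_not_significant(self, rng):
        x = np.linspace(0, 1, 30)
        y = -0.1 * x + rng.normal(0, 0.5, 30)
        res = across_taxon_association(x, y)
        assert res.classification in ("negative", "positive", "zero")

    def test_zero_variance_not_computable(self):
        res = across_taxon_association([1, 1, 1], [0, 1, 2])
        assert res.classification == "not_computable"

    def test_r_squared_equals_pearson_squared(self, rng):
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20) + 0.5 * x
            res = across_taxon_association(x, y)
            assert res.r_squared == pytest.approx(res.statistic**2)


class TestWithinTaxa:
    def test_full_reversal(self):
        res = within_taxon_association([1, 2, 3], [3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_hand_counted_tau(self):
        res = within_taxon_association([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx((5 - 1) / 6)

    def test_tau_b_with_ties_hand_case(self):
        res = within_taxon_association([0, 0, 1, 1], [1, 0, 1, 0])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(11, 60))
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 6, n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = within_taxon_association(x, y)
            assert res.statistic == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_exact_p_matches_naive_enumeration(self):
        x = np.array([0.0, 1.0, 1.0, 2.0, 3.0])
        y = np.array([2.0, 0.0, 1.0, 1.0, 0.0])
        res = within_taxon_association(x, y)
        taus = []
        obs = brute_force_tau_b(x, y)
        for perm in itertools.permutations(y):
            taus.append(brute_force_tau_b(x, np.array(perm)))
        expected = np.mean([abs(t) >= abs(obs) - 1e-12 for t in taus])
        assert res.p_value == pytest.approx(expected)

    def test_all_tied_not_computable(self):
        res = within_taxon_association([1, 1, 1, 1], [0, 1, 2, 3])
        assert res.classification == "not_computable"

    def test_significant_negative_at_n_500(self, rng):
        dnd = (rng.random(500) < 0.2).astype(int)
        counts = rng.poisson(np.where(dnd == 1, 0.4, 2.0))
        res = within_taxon_association(dnd, counts)
        assert res.statistic < 0 and res.p_value < 0.05
        assert res.classification == "significant_negative"


class TestEligibility:
    @pytest.mark.parametrize("n_carrying,expected", [(29, False), (30, True)])
    def test_boundary(self, n_carrying, expected):
        flags = [True] * n_carrying + [False] * 10
        assert eligibility_filter(flags) is expected

    def test_absent_feature_pair_unachievable(self):
        assert pair_unachievable(100, [0] * 100, [1] * 100)
        assert pair_unachievable(100, [1] * 100, [0] * 100)
        assert pair_unachievable(29, [1] * 29, [1] * 29)
        assert not pair_unachievable(30, [1] * 30, [1] * 30)


class TestStudentsT:
    def test_identical_samples(self):
        t, df, p = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_hand_computed_pooled_t(self):
        t, df, p = students_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.2878, abs=1e-3)

    def test_constant_equal_samples(self):
        assert students_t_test([2, 2, 2], [2, 2])[2] == 1.0

    def test_constant_unequal_samples_degenerate(self):
        with pytest.raises(DegenerateInputError):
            students_t_test([2, 2, 2], [3, 3])

    def test_agrees_with_permutation_p(self, rng):
        # pooled-t p approximates the exact permutation p on small samples
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(1.2, 1.0, 5)
        t_obs, _, p_t = students_t_test(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        combos = list(itertools.combinations(range(10), 5))
        for idx in combos:
            mask = np.zeros(10, bool)
            mask[list(idx)] = True
            diff = pooled[mask].mean() - pooled[~mask].mean()
            obs_diff = a.mean() - b.mean()
            count += abs(diff) >= abs(obs_diff) - 1e-12
        p_perm = count / len(combos)
        assert abs(p_t - p_perm) < 0.05


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_case(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_permutation_invariance(self, rng):
        p = rng.random(20)
        q1 = sorted(bh_fdr(p))
        perm = rng.permutation(p)
        q2 = sorted(bh_fdr(perm))
        np.testing.assert_allclose(q1, q2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])
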