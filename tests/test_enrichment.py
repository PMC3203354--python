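import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from sigsearch import (
    Signature,
    categorize_scores,
    fisher_enrichment,
    ks_enrichment,
    rank_datasets,
    score_compendium,
)
from sigsearch.enrichment import _freeman_halton_2x3
from sigsearch.synthetic import SyntheticSpec, simulate_compendium


class TestKsEnrichment:
    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_enrichment([], [1.0, 2.0])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(21)
        background = rng.standard_normal(2000)
        ps = [
            ks_enrichment(rng.choice(background, 40, replace=False), background)
            for _ in range(200)
        ]
        assert 0.35 < np.median(ps) < 0.65

    def test_total_separation_tiny_p(self):
        rng = np.random.default_rng(2)
        background = rng.standard_normal(2000)
        dataset = background.max() + 1 + rng.random(20)
        p = ks_enrichment(np.concatenate([dataset]), np.concatenate([background, dataset]))
        assert p < 1e-6

    def test_single_sample_dataset_valid(self):
        # n=1 two-sample K-S: D = max(F(x), 1-F(x)) where F is the
        # background ECDF at the point; exact p from enumeration over the
        # hypergeometric null of pooled orderings
        background = np.arange(10, dtype=float)
        x = np.array([4.5])
        p = ks_enrichment(x, background)
        assert 0.0 < p <= 1.0
        # exhaustive oracle: all 11 insertion positions equally likely
        n = len(background)
        d_obs = max(5 / n, 1 - 5 / n)
        count = 0
        for pos in range(n + 1):
            d = max(pos / n, 1 - pos / n)
            if d >= d_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / (n + 1))


def fisher_2x2_oracle(table):
    """Hypergeometric-summation two-sided Fisher p for a 2x2 table."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = (
        comb(c1, a) * comb(n - c1, r1 - a) / comb(n, r1)
    )
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherEnrichment:
    def test_override_excess_not_significant(self):
        # dataset has a greater proportion of non-significant samples
        # than the background -> p is exactly 1
        assert fisher_enrichment([0, 0, 10], [50, 50, 400]) == 1.0

    def test_no_deviation_near_one(self):
        # dataset mirroring background proportions exactly
        p = fisher_enrichment([1, 1, 8], [10, 10, 80])
        assert p > 0.9

    def test_2x2_reduction_oracle(self):
        # an empty sig_negative column everywhere degenerates to 2x2
        d = [4, 0, 6]
        bg = [10, 0, 90]
        p = fisher_enrichment(d, bg)
        rest = [bg[0] - d[0], bg[2] - d[2]]
        expected = fisher_2x2_oracle([[d[0], d[2]], rest])
        assert p == pytest.approx(expected, rel=1e-9)
        # and the classical scipy 2x2 as a second cross-check
        assert p == pytest.approx(
            stats.fisher_exact([[d[0], d[2]], rest])[1], rel=1e-9
        )

    def test_enumeration_vs_monte_carlo(self):
        d = [10, 0, 0]
        bg = [12, 10, 978]
        p_exact = fisher_enrichment(d, bg, mode="exact_2x3")
        p_mc = fisher_enrichment(d, bg, mode="monte_carlo", n_draws=200_000, seed=3)
        se = math.sqrt(max(p_exact, 1e-12) * (1 - p_exact) / 200_000)
        assert abs(p_mc - p_exact) < 3 * se + 2 / 200_000

    def test_exact_full_enumeration_oracle(self):
        # tiny table: enumerate every 2x3 table with the fixed margins
        # directly and sum probabilities of tables no more probable
        d = np.array([3, 1, 1])
        bg = np.array([5, 4, 11])
        rest = bg - d
        n, r1 = bg.sum(), d.sum()

        def prob(row):
            return (
                comb(bg[0], row[0])
                * comb(bg[1], row[1])
                * comb(bg[2], row[2])
                / comb(n, r1)
            )

        p_obs = prob(d)
        total = sum(
            prob((a, b, r1 - a - b))
            for a in range(min(r1, bg[0]) + 1)
            for b in range(min(r1 - a, bg[1]) + 1)
            if r1 - a - b <= bg[2]
            and prob((a, b, r1 - a - b)) <= p_obs * (1 + 1e-9)
        )
        assert fisher_enrichment(d, bg) == pytest.approx(total, rel=1e-9)

    def test_collapse_mode_matches_scipy(self):
        d = [3, 2, 5]
        bg = [10, 10, 80]
        p = fisher_enrichment(d, bg, mode="collapse_2x2")
        expected = stats.fisher_exact([[5, 5], [15, 75]])[1]
        assert p == pytest.approx(expected)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_enrichment([5, 0, 0], [3, 10, 10])

    def test_dataset_equals_background(self):
        assert fisher_enrichment([3, 3, 0], [3, 3, 0]) == 1.0


def make_score_table(groups):
    """groups: dict dataset_id -> (sa_array, p_array)."""
    rows = []
    for ds_id, (sa, p) in groups.items():
        for i, (s, pv) in enumerate(zip(sa, p)):
            rows.append(
                {
                    "sample_id": f"{ds_id}_S{i}",
                    "dataset_id": ds_id,
                    "n_up_used": 10,
                    "n_down_used": 10,
                    "W": np.nan,
                    "SA": s,
                    "p": pv,
                    "q": np.nan,
                    "category": None,
                    "defined": True,
                }
            )
    return pd.DataFrame(rows)


class TestRankDatasets:
    def test_nothing_significant_fisher_one_ks_defined(self):
        rng = np.random.default_rng(5)
        groups = {
            f"D{i}": (rng.standard_normal(10), rng.uniform(0.5, 1.0, 10))
            for i in range(4)
        }
        scores = categorize_scores(make_score_table(groups))
        table = rank_datasets(scores)
        assert (table["fisher_p"] == 1.0).all()
        assert table["ks_p"].between(0, 1).all()

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        groups = {
            f"D{i}": (rng.standard_normal(15), rng.uniform(0, 1, 15))
            for i in range(12)
        }
        scores = categorize_scores(make_score_table(groups))
        table = rank_datasets(scores)
        for col_p, col_q in (("ks_p", "ks_q"), ("fisher_p", "fisher_q")):
            t = table.sort_values(col_p)
            assert t[col_q].is_monotonic_increasing
            assert (t[col_q] <= 1.0).all()

    def test_undefined_only_dataset_skipped(self, sig2020, caplog):
        scores = make_score_table(
            {"GOOD": (np.zeros(5), np.ones(5))}
        )
        bad = pd.DataFrame(
            {
                "sample_id": ["B1", "B2"],
                "dataset_id": "BAD",
                "n_up_used": 0,
                "n_down_used": 0,
                "W": np.nan,
                "SA": np.nan,
                "p": np.nan,
                "q": np.nan,
                "category": None,
                "defined": False,
            }
        )
        scores = categorize_scores(pd.concat([scores, bad], ignore_index=True))
        with caplog.at_level("WARNING", logger="sigsearch"):
            table = rank_datasets(scores)
        assert list(table["dataset_id"]) == ["GOOD"]
        assert any("BAD" in r.message for r in caplog.records)

    def test_sorted_by_ks_q_then_fisher_q_then_id(self):
        rng = np.random.default_rng(8)
        groups = {
            f"D{i}": (rng.standard_normal(12), rng.uniform(0, 1, 12))
            for i in range(8)
        }
        scores = categorize_scores(make_score_table(groups))
        table = rank_datasets(scores)
        keys = list(zip(table["ks_q"], table["fisher_q"], table["dataset_id"]))
        assert keys == sorted(keys)

    def test_direction_summary(self):
        groups = {
            "POS": (np.full(6, 5.0), np.full(6, 1e-9)),
            "NEG": (np.full(6, -5.0), np.full(6, 1e-9)),
            "NULL": (np.zeros(6), np.ones(6)),
        }
        scores = categorize_scores(make_score_table(groups))
        table = rank_datasets(scores).set_index("dataset_id")
        assert table.loc["POS", "direction"] == "positive"
        assert table.loc["NEG", "direction"] == "negative"
        assert table.loc["NULL", "direction"] == "mixed"

    def test_tests_selection(self):
        rng = np.random.default_rng(9)
        groups = {
            f"D{i}": (rng.standard_normal(8), rng.uniform(0, 1, 8)) for i in range(3)
        }
        scores = categorize_scores(make_score_table(groups))
        ks_only = rank_datasets(scores, tests="ks")
        fisher_only = rank_datasets(scores, tests="fisher")
        assert ks_only["fisher_p"].isna().all()
        assert fisher_only["ks_p"].isna().all()


class TestRelativeSensitivity:
    """Fisher beats K-S on strong signals; K-S beats Fisher on weak ones."""

    @staticmethod
    def _run(effect, affected, sizes, perturbed_size, sig, seed):
        spec = SyntheticSpec(
            n_genes=120,
            dataset_sizes=(perturbed_size,) + sizes,
            sig=sig,
            effect_size=effect,
            affected_fraction=affected,
            perturbed_datasets=frozenset([0]),
            seed=seed,
        )
        comp = simulate_compendium(spec)
        scores = categorize_scores(score_compendium(comp, sig))
        table = rank_datasets(scores).set_index("dataset_id")
        return table.loc["D000", "fisher_p"], table.loc["D000", "ks_p"]

    def test_fisher_wins_on_strong_signal(self, sig2020):
        wins = 0
        for seed in range(100):
            f, k = self._run(3.0, 0.5, (15,) * 8, 20, sig2020, seed)
            wins += f < k
        assert wins > 50

    def test_ks_wins_on_weak_diffuse_signal(self, sig2020):
        wins = 0
        for seed in range(100):
            f, k = self._run(0.3, 0.3, (15,) * 8, 150, sig2020, seed)
            wins += k < f
        assert wins > 50
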