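"""Ranked lists, running-sum enrichment vs a brute-force oracle, and the
Monte-Carlo panel test against the exact hypergeometric tail."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdtx.data import GeneSetCollection
from sdtx.deg import GeneResult
from sdtx.enrichment import (
    RankedList,
    enrichment_score,
    gsea_preranked,
    make_ranked_list,
    montecarlo_set_test,
    screen_panel,
)


def brute_force_es(scores, hit_positions, weight):
    """Independent sequential running-sum implementation (same tie rule:
    magnitude ties resolve to the positive extreme)."""
    N, m = len(scores), len(hit_positions)
    hits = set(int(i) for i in hit_positions)
    tot = sum(abs(scores[i]) ** weight for i in hits)
    run, maxc, minc = 0.0, -np.inf, np.inf
    for i in range(N):
        if i in hits:
            run += (abs(scores[i]) ** weight) / tot if tot > 0 else 1.0 / m
        else:
            run -= 1.0 / (N - m)
        maxc, minc = max(maxc, run), min(minc, run)
    return maxc if maxc >= -minc - 1e-12 else minc


def _results(ps_dirs):
    return [
        GeneResult(f"G{i}", float(d), 1.0, 1, p)
        for i, (p, d) in enumerate(ps_dirs)
    ]


class TestRankedList:
    def test_signed_log10_scores(self):
        rl = make_ranked_list(_results([(0.01, 1), (1.0, 1), (0.1, -1)]))
        lookup = dict(zip(rl.genes, rl.scores))
        assert lookup["G0"] == pytest.approx(2.0)
        assert lookup["G1"] == pytest.approx(0.0)
        assert lookup["G2"] == pytest.approx(-1.0)

    def test_descending_order(self):
        rl = make_ranked_list(_results([(0.001, 1), (1.0, 1), (0.1, -1)]))
        assert list(rl.scores) == sorted(rl.scores, reverse=True)
        assert list(rl.genes) == ["G0", "G1", "G2"]

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame({"gene": ["A", "A"], "score": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            RankedList(df)

    def test_non_converged_dropped(self):
        results = _results([(0.01, 1), (0.5, -1)])
        results[1].converged = False
        assert len(make_ranked_list(results)) == 1


class TestEnrichmentScore:
    def test_singleton_at_top_weight_zero_is_one(self):
        assert enrichment_score(np.array([3.0, 2.0, 1.0]), np.array([0]), 0.0) == 1.0

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, weight):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 21))
        m = int(rng.integers(1, N))
        scores = np.sort(rng.normal(0, 2, N))[::-1]
        pos = np.sort(rng.choice(N, m, replace=False))
        assert enrichment_score(scores, pos, weight) == pytest.approx(
            brute_force_es(scores, pos, weight), abs=1e-9
        )

    def test_hand_computed_ranks_123_of_ten(self):
        # N=10, scores 10..1, hits at ranks 1-3, weight 1:
        # hit weights (10,9,8)/27; no misses before them, so the running sum
        # peaks at 1.0 after the third hit
        scores = np.arange(10, 0, -1).astype(float)
        es = enrichment_score(scores, np.array([0, 1, 2]), 1.0)
        assert es == pytest.approx(1.0)
        assert es == pytest.approx(brute_force_es(scores, [0, 1, 2], 1.0))

    def test_weight_zero_scale_invariance(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        pos = np.array([2, 5, 11, 20])
        a = enrichment_score(scores, pos, 0.0)
        b = enrichment_score(scores * 7.3, pos, 0.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_reversed_list_negates_es_weight_zero(self):
        rng = np.random.default_rng(4)
        N = 25
        scores = np.sort(rng.normal(0, 1, N))[::-1]
        pos = np.array([1, 6, 7, 15])
        es_fwd = enrichment_score(scores, pos, 0.0)
        es_rev = enrichment_score(-scores[::-1], (N - 1) - pos[::-1], 0.0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


def _ranked(N=60, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1.5, N))[::-1]
    return RankedList(
        pd.DataFrame({"gene": [f"G{i:03d}" for i in range(N)], "score": scores})
    )


class TestGseaPreranked:
    def test_reversed_ranking_negates_es_for_every_set(self):
        rl = _ranked(seed=5)
        rev = RankedList(
            pd.DataFrame({"gene": rl.genes, "score": -rl.scores})
        )
        sets = GeneSetCollection(
            {f"S{k}": [f"G{i:03d}" for i in range(k, 60, 7 + k)] for k in range(4)}
        )
        fwd = {r.set_name: r.es for r in gsea_preranked(rl, sets, 100, 0.0, seed=1)}
        bwd = {r.set_name: r.es for r in gsea_preranked(rev, sets, 100, 0.0, seed=1)}
        for name in fwd:
            assert bwd[name] == pytest.approx(-fwd[name], abs=1e-9)

    def test_deterministic_given_seed(self):
        rl = _ranked(seed=6)
        sets = GeneSetCollection({"A": [f"G{i:03d}" for i in (1, 5, 9, 33)]})
        r1 = gsea_preranked(rl, sets, 200, 1.0, seed=9)
        r2 = gsea_preranked(rl, sets, 200, 1.0, seed=9)
        assert r1[0].p_perm == r2[0].p_perm
        assert r1[0].nes == r2[0].nes

    def test_set_covering_whole_list_skipped(self):
        rl = _ranked(N=5, seed=7)
        sets = GeneSetCollection(
            {"ALL": [f"G{i:03d}" for i in range(5)], "OK": ["G001"]}
        )
        out = gsea_preranked(rl, sets, 100, 1.0, seed=0)
        assert [r.set_name for r in out] == ["OK"]

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(_ranked(), GeneSetCollection({"A": ["G001"]}), 10)

    def test_null_membership_p_roughly_uniform(self):
        """Random sets show ~5% of permutation p-values below 0.05."""
        rl = _ranked(N=120, seed=8)
        hits = 0
        n_sets = 250
        for i in range(n_sets):
            rng = np.random.default_rng(10_000 + i)
            members = [f"G{j:03d}" for j in rng.choice(120, 10, replace=False)]
            res = gsea_preranked(
                rl, GeneSetCollection({"S": members}), 500, 1.0, seed=i
            )
            hits += res[0].p_perm < 0.05
        rate = hits / n_sets
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sets) + 0.01


class TestMonteCarlo:
    def test_everything_significant_gives_p_one(self):
        results = _results([(0.01, 1)] * 40)
        mc = montecarlo_set_test(
            results, [f"G{i}" for i in range(5)], b_draws=1000, seed=0
        )
        assert mc.observed == 5
        assert mc.p_emp == 1.0
        assert mc.analytic_p == 1.0

    def test_nothing_significant_gives_p_one(self):
        results = _results([(0.9, 1)] * 40)
        mc = montecarlo_set_test(
            results, [f"G{i}" for i in range(5)], b_draws=1000, seed=0
        )
        assert mc.observed == 0
        assert mc.p_emp == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exact_hypergeometric(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(60, 150))
        K = int(rng.integers(5, 25))
        m = int(rng.integers(4, 12))
        ps = np.full(N, 0.5)
        ps[rng.choice(N, K, replace=False)] = 0.01
        results = _results([(p, 1) for p in ps])
        panel = [f"G{i}" for i in rng.choice(N, m, replace=False)]
        mc = montecarlo_set_test(results, panel, b_draws=4000, seed=seed)
        se = np.sqrt(mc.analytic_p * (1 - mc.analytic_p) / mc.b_draws)
        assert abs(mc.p_emp - mc.analytic_p) <= 3 * se + 1.0 / mc.b_draws

    def test_reproducible_given_seed(self):
        results = _results([(0.04, 1)] * 20 + [(0.6, -1)] * 80)
        panel = [f"G{i}" for i in range(0, 40, 4)]
        a = montecarlo_set_test(results, panel, b_draws=2000, seed=5)
        b = montecarlo_set_test(results, panel, b_draws=2000, seed=5)
        assert a.p_emp == b.p_emp and a.exceed == b.exceed

    def test_absent_panel_members_dropped_with_reduced_m(self):
        results = _results([(0.5, 1)] * 10)
        mc = montecarlo_set_test(
            results, ["G1", "G2", "ABSENT"], b_draws=1000, seed=0
        )
        assert mc.panel_size == 2
        assert mc.missing == ("ABSENT",)

    def test_validation_errors(self):
        results = _results([(0.5, 1)] * 10)
        with pytest.raises(ValueError, match="b_draws"):
            montecarlo_set_test(results, ["G1"], b_draws=10)
        with pytest.raises(ValueError, match="alpha_unc"):
            montecarlo_set_test(results, ["G1"], b_draws=1000, alpha_unc=1.5)
        with pytest.raises(ValueError, match="no panel genes"):
            montecarlo_set_test(results, ["NOPE"], b_draws=1000)


class TestScreenPanel:
    def test_disjoint_panel_gives_empty_table_and_full_missing_list(self):
        results = _results([(0.5, 1)] * 4)
        table, missing = screen_panel(results, ["X1", "X2"])
        assert table.empty
        assert missing == ["X1", "X2"]

    def test_full_panel_has_one_row_per_symbol(self):
        results = _results([(0.5, 1)] * 30)
        panel = [f"G{i}" for i in range(23)]
        table, missing = screen_panel(results, panel)
        assert len(table) == 23
        assert not missing

    def test_panel_effects_dominate_top_ranking(self):
        from sdtx.deg import ContrastSpec, run_transcriptome
        from sdtx.io import load_circadian_panel
        from sdtx.simulate import SimulationConfig, EffectSpec, simulate_cohort

        panel = load_circadian_panel()
        cfg = SimulationConfig(
            n_genes=120,
            effects=(
                EffectSpec(tuple(panel), "time_main", 0.6, (0, 1, 0)),
            ),
            seed=21,
        )
        study = simulate_cohort(cfg)
        results = run_transcriptome(study, ContrastSpec("M1"))
        top = {r.gene for r in results[:23]}
        assert len(top & set(panel)) >= 20
        table, _ = screen_panel(results, panel)
        assert table["sig_fdr"].all()
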