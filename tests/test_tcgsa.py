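"""Set-level time-course LRT, trend extraction and heatmap rendering."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdtx.data import ExpressionStudy, GeneSetCollection
from sdtx.plots import render_trend_heatmap, trend_table
from sdtx.simulate import EffectSpec, SimulationConfig, gene_names, simulate_cohort
from sdtx.tcgsa import TrajectoryResult, TrendMatrix, extract_trends, run_tcgsa_collection, tcgsa_lrt

from conftest import make_study


def _small_cohort(seed, n_genes=12, n_subj=15, effect=0.0, profile=(0, 1, 1)):
    genes = gene_names(n_genes, include_panel=False)
    effects = ()
    if effect:
        effects = (
            EffectSpec(
                tuple(genes), "set_coherent_trajectory", effect, profile
            ),
        )
    cfg = SimulationConfig(
        n_responders=n_subj, n_non_responders=0, n_controls=0,
        participation={
            "responder": (n_subj, n_subj, n_subj),
            "non_responder": (0, 0, 0),
            "control": (0, 0, 0),
        },
        n_genes=n_genes, include_panel_genes=False,
        effects=effects, n_protocol_violators=0, seed=seed,
    )
    return simulate_cohort(cfg), genes


class TestTcgsaLrt:
    def test_time_constant_set_not_significant(self):
        study, genes = _small_cohort(1)
        res = tcgsa_lrt(study, genes, set_name="NULL", cohort="patients")
        assert res.converged
        assert res.p > 0.05
        assert res.lrt_stat < 12.0

    def test_coherent_trajectory_strongly_detected(self):
        study, genes = _small_cohort(2, effect=0.3)
        res = tcgsa_lrt(study, genes, cohort="patients")
        assert res.converged
        assert res.p < 1e-6

    def test_ill_conditioned_set_reports_non_converged(self):
        study = make_study({"responder": 2}, n_genes=1)
        res = tcgsa_lrt(study, ["G0"], set_name="TINY", cohort="patients")
        assert not res.converged
        assert np.isnan(res.p)
        assert "ill-conditioned" in res.note

    def test_protocol_violators_dropped_at_t3(self):
        study, genes = _small_cohort(3, n_subj=10)
        meta = study.samples.copy()
        victim = meta["subject_id"].iloc[0]
        meta.loc[meta["subject_id"] == victim, "protocol_violation"] = True
        flagged = ExpressionStudy(study.values, meta)
        res = tcgsa_lrt(flagged, genes, cohort="patients")
        assert res.converged  # runs fine on the reduced data

    def test_chisq_reference_gives_smaller_p_than_mixture(self):
        study, genes = _small_cohort(4)
        p_chisq = tcgsa_lrt(study, genes, cohort="patients", reference="chisq").p
        p_mix = tcgsa_lrt(study, genes, cohort="patients", reference="mixture").p
        assert p_chisq <= p_mix

    def test_permutation_and_parametric_p_agree_in_rank(self):
        """Spearman agreement between the permutation p and the mixture p
        across sets with graded effect sizes."""
        p_param, p_perm = [], []
        for k, effect in enumerate(
            [0.0, 0.0, 0.03, 0.05, 0.07, 0.09, 0.12, 0.15, 0.2, 0.3]
        ):
            study, genes = _small_cohort(100 + k, n_genes=6, n_subj=10,
                                         effect=effect)
            a = tcgsa_lrt(study, genes, cohort="patients", reference="mixture")
            b = tcgsa_lrt(
                study, genes, cohort="patients", reference="perm",
                n_perm=50, seed=k,
            )
            p_param.append(a.p)
            p_perm.append(b.p)
        rho = stats.spearmanr(p_param, p_perm).statistic
        assert rho > 0.8


class TestRunCollection:
    def test_unknown_cohort_label_rejected(self, table1_study):
        sets = GeneSetCollection({"A": list(table1_study.genes[:5])})
        with pytest.raises(ValueError, match="unknown cohort"):
            run_tcgsa_collection(table1_study, sets, cohorts=["everyone"])

    def test_perturbed_set_found_null_set_not(self):
        genes = gene_names(24, include_panel=False)
        cfg = SimulationConfig(
            n_responders=20, n_non_responders=0, n_controls=0,
            participation={
                "responder": (20, 20, 20),
                "non_responder": (0, 0, 0),
                "control": (0, 0, 0),
            },
            n_genes=24, include_panel_genes=False,
            gene_sets={"HOT": tuple(genes[:12])},
            effects=(
                EffectSpec("HOT", "set_coherent_trajectory", 0.3, (0, 1, 1)),
            ),
            n_protocol_violators=0, seed=5,
        )
        study = simulate_cohort(cfg)
        sets = GeneSetCollection({"HOT": genes[:12], "COLD": genes[12:]})
        out = run_tcgsa_collection(study, sets, cohorts=["patients"])
        by_name = {r.set_name: r for r in out["patients"]}
        assert by_name["HOT"].q < 0.05
        assert by_name["COLD"].p > by_name["HOT"].p

    def test_non_converged_sets_warned_and_excluded_from_fdr(self):
        study, genes = _small_cohort(6, n_genes=10, n_subj=8)
        sets = GeneSetCollection(
            {"OK": genes[:8], "SINGLETON": [genes[9]]}
        )
        with pytest.warns(UserWarning, match="non-converged"):
            out = run_tcgsa_collection(study, sets, cohorts=["patients"])
        by_name = {r.set_name: r for r in out["patients"]}
        assert by_name["OK"].converged
        assert not by_name["SINGLETON"].converged
        assert np.isnan(by_name["SINGLETON"].q)

    def test_responder_specific_effects_enrich_responder_run(self):
        genes = gene_names(30, include_panel=False)
        cfg = SimulationConfig(
            n_responders=20, n_non_responders=8, n_controls=10,
            participation={
                "responder": (20, 20, 20),
                "non_responder": (8, 8, 8),
                "control": (10, 10, 10),
            },
            n_genes=30, include_panel_genes=False,
            gene_sets={"S1": tuple(genes[:10]), "S2": tuple(genes[10:20])},
            effects=(
                EffectSpec("S1", "set_coherent_trajectory", 0.35, (0, 1, 1),
                           "responder"),
                EffectSpec("S2", "set_coherent_trajectory", 0.35, (0, 1, 0),
                           "responder"),
            ),
            n_protocol_violators=0, seed=7,
        )
        study = simulate_cohort(cfg)
        sets = GeneSetCollection({"S1": genes[:10], "S2": genes[10:20]})
        out = run_tcgsa_collection(
            study, sets, cohorts=["responders", "controls"]
        )
        n_sig = {
            cohort: sum(
                r.converged and np.isfinite(r.q) and r.q < 0.05 for r in res
            )
            for cohort, res in out.items()
        }
        assert n_sig["responders"] > n_sig["controls"]


class TestTrends:
    def test_constant_genes_give_single_zero_row(self):
        study = make_study(
            {"responder": 4}, n_genes=3, seed=8, residual_sd=0.3
        )
        # make all three genes time-constant per subject but variable enough
        tm = extract_trends(study, ["G0", "G1", "G2"], cohort="patients",
                            n_clusters=1)
        assert tm.values.shape[1] == 3
        assert np.allclose(tm.values["T1"], 0.0)

    def test_two_gene_single_subject_hand_computed(self):
        """With one subject and unit-variance gene values, the trend rows are
        exactly the per-timepoint minus-T1 differences."""
        vals = pd.DataFrame(
            {
                "P1_T1": [-1.0, 1.0],
                "P1_T2": [0.0, 0.0],
                "P1_T3": [1.0, -1.0],
            },
            index=["GA", "GB"],
        )
        meta = pd.DataFrame(
            {
                "subject_id": ["P1"] * 3,
                "timepoint": ["T1", "T2", "T3"],
                "group": ["responder"] * 3,
                "age": [40.0] * 3,
                "sex": ["M"] * 3,
                "protocol_violation": [False] * 3,
            },
            index=pd.Index(["P1_T1", "P1_T2", "P1_T3"], name="sample_id"),
        )
        study = ExpressionStudy(vals, meta)
        tm = extract_trends(study, ["GA", "GB"], cohort="patients", n_clusters=2)
        rows = {tm.membership["GA"], tm.membership["GB"]}
        assert rows == {1, 2}
        got = {
            g: tm.values.iloc[tm.membership[g] - 1].to_numpy()
            for g in ("GA", "GB")
        }
        # values (-1,0,1) have mean 0, sd 1 (ddof=1) so z = raw values
        assert np.allclose(got["GA"], [0.0, 1.0, 2.0])
        assert np.allclose(got["GB"], [0.0, -1.0, -2.0])

    def test_first_column_zero_and_membership_partitions(self):
        study, genes = _small_cohort(9, n_genes=9, effect=0.2)
        tm = extract_trends(study, genes, cohort="patients")
        assert np.all(tm.values["T1"].to_numpy() == 0.0)
        assert sorted(tm.membership) == sorted(genes)
        assert set(tm.membership.values()) <= set(range(1, len(tm.values) + 1))

    def test_trend_matrix_rejects_nonzero_t1(self):
        bad = pd.DataFrame(
            [[0.1, 0.5, 0.2]], columns=["T1", "T2", "T3"], index=["trend_1"]
        )
        with pytest.raises(ValueError, match="zeroed at T1"):
            TrendMatrix(bad, {"G": 1})


class TestHeatmap:
    def _results_with_signal(self, tmp_path):
        study, genes = _small_cohort(10, effect=0.3)
        res = tcgsa_lrt(study, genes, set_name="HOT", cohort="patients")
        res.q = res.p
        return [res]

    def test_single_significant_set_renders(self, tmp_path):
        results = self._results_with_signal(tmp_path)
        out = render_trend_heatmap(results, tmp_path / "hm.png")
        assert out.exists() and out.stat().st_size > 0
        table = trend_table(results)
        assert table.shape[1] == 3
        assert len(table) >= 1

    def test_regeneration_is_byte_identical(self, tmp_path):
        results = self._results_with_signal(tmp_path)
        a = render_trend_heatmap(results, tmp_path / "a.png")
        b = render_trend_heatmap(results, tmp_path / "b.png")
        assert (
            hashlib.sha256(a.read_bytes()).hexdigest()
            == hashlib.sha256(b.read_bytes()).hexdigest()
        )

    def test_upregulated_trajectory_positive_at_t2_t3(self):
        results = self._results_with_signal(None)
        table = trend_table(results)
        # upregulation injected at T2/T3: the dominant trends are positive
        assert table[["T2", "T3"]].median(axis=1).max() > 0.3

    def test_nothing_significant_writes_placeholder(self, tmp_path):
        res = TrajectoryResult("NULLSET")
        with pytest.warns(UserWarning, match="placeholder"):
            out = render_trend_heatmap([res], tmp_path / "empty.png")
        assert out.exists()

    def test_exclusion_flag_removes_set(self, tmp_path):
        results = self._results_with_signal(tmp_path)
        table = trend_table(results, exclude_sets=["HOT"])
        assert table.empty
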