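"""Time-course gene-set analysis over all three timepoints.

For each gene set, genes are standardized (per-gene z-score over the
analyzed cohort) and stacked into one long response.  Two nested mixed
models are fitted by maximum likelihood and compared by likelihood ratio:

* h0: value ~ gene-specific fixed intercepts + subject random intercept;
* h1: h0 + shared timepoint fixed effects (T2, T3 vs T1) + gene-specific
  random time deviations (one iid variance for the per-gene, per-timepoint
  departures from the shared time trend).

The subject intercepts and the gene-level time deviations are *crossed*
random effects, handled by the profiled-likelihood engine in
:mod:`sdtx.mixedlm`.  h1 adds two fixed-effect parameters plus one variance
component on the boundary of its parameter space under the null, so the
default reference distribution is the 50:50 mixture
chi2(2) : chi2(3) (Self-Liang); a plain chi2(2) and a within-subject
timepoint-permutation null are available alternatives.

T3 samples from protocol-violating patients are excluded.  Trend matrices
for display give, per trend cluster, the median standardized expression
over subjects at each timepoint, zeroed at T1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .data import ExpressionStudy, GeneSetCollection, TIMEPOINTS
from .deg import bh_fdr
from .mixedlm import fit_lmm_ml, indicator, lrt

REFERENCES = ("chisq", "mixture", "perm")
_ADDED_FIXED_DF = 2  # T2 and T3 indicators


@dataclass
class TrendMatrix:
    """Trend clusters x timepoints, zeroed at T1.

    ``values`` has one row per trend cluster and columns T1..T3;
    ``membership`` maps each used gene to its cluster row (a partition).
    """

    values: pd.DataFrame
    membership: dict[str, int]

    def __post_init__(self) -> None:
        if not np.allclose(self.values.iloc[:, 0].to_numpy(), 0.0):
            raise ValueError("trend matrix must be zeroed at T1")


@dataclass
class TrajectoryResult:
    set_name: str
    lrt_stat: float = np.nan
    p: float = np.nan
    q: float = np.nan
    converged: bool = False
    n_genes_used: int = 0
    reference: str = "mixture"
    trends: TrendMatrix | None = None
    note: str = ""


def _standardized_long(
    study: ExpressionStudy, gene_set: "list[str]", cohort: str
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Cohort-filtered samples (T3 protocol violators dropped), the per-gene
    standardized value matrix and the genes actually used."""
    sub = study.filter(cohort=cohort, drop_t3_violators=True)
    present = [g for g in dict.fromkeys(gene_set) if g in sub.values.index]
    vals = sub.values.loc[present]
    sd = vals.std(axis=1, ddof=1)
    usable = sd > 1e-12
    vals = vals.loc[usable.index[usable]]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd[usable], axis=0)
    return z, sub.samples, list(z.index)


def mixture_sf(stat: float, df: int) -> float:
    """Survival function of the 50:50 chi2(df) : chi2(df+1) mixture."""
    return float(0.5 * stats.chi2.sf(stat, df) + 0.5 * stats.chi2.sf(stat, df + 1))


def _p_from_reference(stat: float, reference: str) -> float:
    if reference == "chisq":
        return float(stats.chi2.sf(stat, _ADDED_FIXED_DF))
    if reference == "mixture":
        return mixture_sf(stat, _ADDED_FIXED_DF)
    raise ValueError(f"no parametric p for reference {reference!r}")


def _set_designs(z: pd.DataFrame, meta: pd.DataFrame):
    """h1/h0 designs for the stacked standardized set data."""
    n_genes, n_samples = z.shape
    tp = meta["timepoint"].to_numpy()
    subj = meta["subject_id"].to_numpy()
    # stack gene-major: row (g, s)
    gene_lab = np.repeat(np.arange(n_genes), n_samples)
    tp_lab = np.tile(tp, n_genes)
    subj_lab = np.tile(subj, n_genes)
    X0 = indicator(gene_lab)  # gene-specific fixed intercepts
    t2 = (tp_lab == "T2").astype(float)[:, None]
    t3 = (tp_lab == "T3").astype(float)[:, None]
    X1 = np.hstack([X0, t2, t3])
    Z_subj = indicator(subj_lab)
    # gene-specific random time deviations: one effect per (gene, T2/T3)
    dev_lab = np.where(tp_lab == "T1", -1, gene_lab * 2 + (tp_lab == "T3"))
    Z_dev = np.zeros((len(tp_lab), 2 * n_genes))
    nz = dev_lab >= 0
    Z_dev[np.nonzero(nz)[0], dev_lab[nz]] = 1.0
    y = z.to_numpy().ravel()
    return y, X1, X0, Z_subj, Z_dev, tp_lab, subj_lab


def tcgsa_lrt(
    study: ExpressionStudy,
    gene_set: "list[str]",
    set_name: str = "",
    cohort: str = "patients",
    reference: str = "mixture",
    n_perm: int = 100,
    seed: int = 0,
    n_trend_clusters: int | None = None,
) -> TrajectoryResult:
    """Set-level time-course LRT for one gene set in one cohort.

    Fit failures and ill-conditioned inputs (fewer than 2 usable genes or 3
    subjects) yield ``converged=False`` results, never an exception, so a
    collection run can report excluded sets and continue.
    """
    if reference not in REFERENCES:
        raise ValueError(f"reference must be one of {REFERENCES}")
    try:
        z, meta, used = _standardized_long(study, gene_set, cohort)
    except Exception as exc:  # e.g. empty cohort after filtering
        return TrajectoryResult(set_name, reference=reference, note=str(exc))
    n_subjects = meta["subject_id"].nunique()
    if len(used) < 2 or n_subjects < 3:
        return TrajectoryResult(
            set_name,
            n_genes_used=len(used),
            reference=reference,
            note=f"ill-conditioned: {len(used)} usable genes, {n_subjects} subjects",
        )
    try:
        y, X1, X0, Z_subj, Z_dev, tp_lab, subj_lab = _set_designs(z, meta)
        f1 = fit_lmm_ml(y, X1, [Z_subj, Z_dev])
        f0 = fit_lmm_ml(y, X0, [Z_subj])
        stat = lrt(f1, f0)
        if not (f1.converged and f0.converged):
            raise RuntimeError("optimizer did not converge")
        if reference == "perm":
            p = _permutation_p(
                y, X0, Z_subj, Z_dev, tp_lab, subj_lab, stat, n_perm, seed
            )
        else:
            p = _p_from_reference(stat, reference)
    except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
        return TrajectoryResult(
            set_name, n_genes_used=len(used), reference=reference, note=str(exc)
        )
    trends = extract_trends(
        study, used, cohort=cohort, n_clusters=n_trend_clusters
    )
    return TrajectoryResult(
        set_name,
        lrt_stat=float(stat),
        p=max(float(p), np.finfo(float).tiny),
        converged=True,
        n_genes_used=len(used),
        reference=reference,
        trends=trends,
    )


def _permutation_p(
    y, X0, Z_subj, Z_dev, tp_lab, subj_lab, observed, n_perm, seed
) -> float:
    """Within-subject timepoint-label permutation null.

    h0 is invariant under relabeling timepoints within a subject (its design
    has no time term), so only h1 is refitted per permutation.
    """
    rng = np.random.default_rng(seed)
    f0 = fit_lmm_ml(y, X0, [Z_subj])
    subjects = np.unique(subj_lab)
    n_ge = 0
    for _ in range(n_perm):
        perm_tp = tp_lab.copy()
        for s in subjects:
            rows = np.nonzero(subj_lab == s)[0]
            tps = np.unique(tp_lab[rows])
            shuffled = rng.permutation(tps)
            remap = dict(zip(tps, shuffled))
            perm_tp[rows] = [remap[t] for t in tp_lab[rows]]
        t2 = (perm_tp == "T2").astype(float)[:, None]
        t3 = (perm_tp == "T3").astype(float)[:, None]
        X1p = np.hstack([X0, t2, t3])
        gene_lab = np.argmax(X0, axis=1)
        dev_lab = np.where(perm_tp == "T1", -1, gene_lab * 2 + (perm_tp == "T3"))
        Z_devp = np.zeros_like(Z_dev)
        nz = dev_lab >= 0
        Z_devp[np.nonzero(nz)[0], dev_lab[nz]] = 1.0
        f1p = fit_lmm_ml(y, X1p, [Z_subj, Z_devp], n_starts=1)
        if 2.0 * (f1p.loglik - f0.loglik) >= observed:
            n_ge += 1
    return (n_ge + 1) / (n_perm + 1)


def run_tcgsa_collection(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    cohorts: "list[str]",
    reference: str = "mixture",
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, list[TrajectoryResult]]:
    """Run the set-level test per cohort; BH q within cohort over converged
    sets.  Non-converged sets are reported with ``converged=False`` (and no
    p/q), mirroring how non-converging sets are excluded from results."""
    allowed = {"patients", "controls", "responders", "non_responders", "all"}
    unknown = [c for c in cohorts if c not in allowed]
    if unknown:
        raise ValueError(f"unknown cohort label(s) {unknown}; expected {sorted(allowed)}")
    out: dict[str, list[TrajectoryResult]] = {}
    for cohort in cohorts:
        study.filter(cohort=cohort)  # raises if the cohort is empty
        results = [
            tcgsa_lrt(
                study, members, set_name=name, cohort=cohort,
                reference=reference, n_perm=n_perm, seed=seed,
            )
            for name, members in sets
        ]
        conv = [r for r in results if r.converged]
        if conv:
            qs = bh_fdr([r.p for r in conv])
            for r, q in zip(conv, qs):
                r.q = float(q)
        excluded = [r.set_name for r in results if not r.converged]
        if excluded:
            warnings.warn(
                f"{cohort}: {len(excluded)} set(s) excluded as non-converged: "
                f"{excluded}",
                stacklevel=2,
            )
        out[cohort] = results
    return out


def trajectory_frame(results: "list[TrajectoryResult]") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "converged": [r.converged for r in results],
            "n_genes_used": [r.n_genes_used for r in results],
            "reference": [r.reference for r in results],
            "note": [r.note for r in results],
        }
    )


def extract_trends(
    study: ExpressionStudy,
    gene_set: "list[str]",
    cohort: str = "patients",
    n_clusters: int | None = None,
) -> TrendMatrix:
    """Median standardized expression per timepoint, zeroed at T1, with genes
    grouped into trend clusters.

    Per gene: z-score over the cohort samples, median over subjects at each
    timepoint, minus the T1 value.  Genes are clustered on their trend
    vectors by agglomerative hierarchical clustering (Euclidean, complete
    linkage); the default cut yields at most 5 trends per set.  Each row of
    the result is the within-cluster median trend.
    """
    z, meta, used = _standardized_long(study, gene_set, cohort)
    if not used:
        raise ValueError("no usable genes for trend extraction")
    per_gene = np.zeros((len(used), len(TIMEPOINTS)))
    for j, tp in enumerate(TIMEPOINTS):
        cols = meta.index[meta["timepoint"] == tp]
        if len(cols):
            per_gene[:, j] = z[cols].median(axis=1).to_numpy()
    per_gene -= per_gene[:, [0]]  # zero at T1

    if n_clusters is None:
        n_clusters = min(5, len(used))
    n_clusters = min(n_clusters, len(used))
    if len(used) == 1 or n_clusters == 1:
        labels = np.ones(len(used), dtype=int)
    else:
        lk = linkage(per_gene, method="complete", metric="euclidean")
        labels = fcluster(lk, t=n_clusters, criterion="maxclust")
    rows = []
    membership: dict[str, int] = {}
    for k, cl in enumerate(sorted(set(labels)), start=1):
        mask = labels == cl
        trend = np.median(per_gene[mask], axis=0)
        trend = trend - trend[0]  # cluster-median re-zeroed at T1 (exact zero)
        rows.append(trend)
        for g in np.array(used)[mask]:
            membership[str(g)] = k
    values = pd.DataFrame(
        np.vstack(rows),
        index=[f"trend_{k}" for k in range(1, len(rows) + 1)],
        columns=list(TIMEPOINTS),
    )
    return TrendMatrix(values, membership)
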