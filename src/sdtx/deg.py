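"""Per-gene longitudinal differential expression.

Three likelihood-ratio contrasts compare T2 (after sleep deprivation) with
T1 (baseline), each as a nested pair of random-intercept models fitted by
maximum likelihood with age and sex as fixed covariates and the subject as
a random intercept:

* M1 — effect of timepoint in all patients (h1 adds the T2 indicator);
* M2 — response-by-time interaction, responders vs non-responders
  (h1 adds group x T2; both models carry the main effects);
* M3 — case-by-time interaction, patients vs controls.

The tested term adds exactly one fixed-effect parameter, so the LRT
statistic 2*(l1 - l0) is referred to chi-square(1).  Benjamini-Hochberg
q-values are computed per contrast across converged genes.  Baseline (T1)
group differences use ordinary linear models with a Wald test on the group
coefficient.

Sign convention: a positive estimate means higher expression at T2 (M1) or
a larger T2-T1 change in responders (M2) / patients (M3); reference levels
are non_responder and control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionStudy
from .mixedlm import LMMDesign, fit_lmm_ml, indicator, lrt

CONTRAST_NAMES = ("M1", "M2", "M3")


@dataclass(frozen=True)
class ContrastSpec:
    """One of the three T1-vs-T2 model comparisons (h1 vs h0)."""

    name: str  # M1 | M2 | M3

    def __post_init__(self) -> None:
        if self.name not in CONTRAST_NAMES:
            raise ValueError(f"contrast must be one of {CONTRAST_NAMES}")

    @property
    def cohort(self) -> str:
        # M1/M2 are fitted on patients only; M3 adds the controls
        return "all" if self.name == "M3" else "patients"

    @property
    def tested_term(self) -> str:
        return "time" if self.name == "M1" else "group_x_time"

    def group_indicator(self, groups: pd.Series) -> np.ndarray | None:
        """1 for the non-reference comparison group (responder / patient)."""
        if self.name == "M1":
            return None
        if self.name == "M2":
            return (groups == "responder").to_numpy(float)
        return groups.isin(["responder", "non_responder"]).to_numpy(float)


@dataclass
class GeneResult:
    """Per-gene outcome of one contrast."""

    gene: str
    estimate: float
    lrt_stat: float
    df: int
    p: float
    q: float = np.nan
    converged: bool = True

    @property
    def direction(self) -> int:
        if not np.isfinite(self.estimate) or self.estimate == 0.0:
            return 0
        return 1 if self.estimate > 0 else -1


def bh_fdr(p: "list[float] | np.ndarray") -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values.

    Accepts p-values in (0, 1]; returns q-values in the input order,
    monotone non-decreasing in p-rank and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# design construction


def _contrast_frame(study: ExpressionStudy, contrast: ContrastSpec) -> pd.DataFrame:
    sub = study.filter(cohort=contrast.cohort, timepoints=("T1", "T2"))
    meta = sub.samples
    if contrast.name in ("M2", "M3"):
        want = (
            {"responder", "non_responder"}
            if contrast.name == "M2"
            else {"control"}
        )
        present = set(meta["group"])
        if contrast.name == "M2" and not want <= present:
            raise ValueError(f"M2 needs both responders and non-responders, have {present}")
        if contrast.name == "M3" and "control" not in present:
            raise ValueError("M3 needs control samples")
    # subjects with data at both timepoints drive the within-subject contrast
    per_subj = meta.groupby("subject_id")["timepoint"].nunique()
    if (per_subj >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects observed at both T1 and T2")
    return sub.values, meta


def build_contrast_designs(
    study: ExpressionStudy, contrast: ContrastSpec
) -> tuple[pd.DataFrame, "LMMDesign", "LMMDesign", int]:
    """Shared h1/h0 designs for every gene of one contrast.

    Returns (values frame over the analysis samples, h1 design, h0 design,
    column index of the tested term in the h1 design).
    """
    values, meta = _contrast_frame(study, contrast)
    time = (meta["timepoint"] == "T2").to_numpy(float)
    age = meta["age"].to_numpy(float)
    female = (meta["sex"] == "F").to_numpy(float)
    ones = np.ones(len(meta))
    grp = contrast.group_indicator(meta["group"])
    if contrast.name == "M1":
        X0 = np.column_stack([ones, age, female])
        X1 = np.column_stack([ones, age, female, time])
    else:
        X0 = np.column_stack([ones, age, female, grp, time])
        X1 = np.column_stack([ones, age, female, grp, time, grp * time])
    Z = indicator(meta["subject_id"].to_numpy())
    return values, LMMDesign(X1, [Z]), LMMDesign(X0, [Z]), X1.shape[1] - 1


def _fit_one(
    y: np.ndarray, d1: LMMDesign, d0: LMMDesign, term: int, gene: str
) -> GeneResult:
    if np.ptp(y) == 0.0 or np.var(y) < 1e-12:
        return GeneResult(gene, np.nan, 0.0, 1, 1.0, converged=False)
    try:
        f1 = fit_lmm_ml(y, d1)
        f0 = fit_lmm_ml(y, d0)
        stat = lrt(f1, f0)
    except (RuntimeError, ValueError, np.linalg.LinAlgError):
        return GeneResult(gene, np.nan, 0.0, 1, 1.0, converged=False)
    p = float(stats.chi2.sf(stat, 1))
    return GeneResult(
        gene,
        estimate=float(f1.beta[term]),
        lrt_stat=float(stat),
        df=1,
        p=max(p, np.finfo(float).tiny),
        converged=bool(f1.converged and f0.converged),
    )


def fit_gene_lrt(
    study: ExpressionStudy, gene: str, contrast: ContrastSpec
) -> GeneResult:
    """LRT for one gene under one contrast (q is left NaN; see
    :func:`run_transcriptome` for collection-level FDR)."""
    values, d1, d0, term = build_contrast_designs(study, contrast)
    if gene not in values.index:
        raise KeyError(f"gene {gene!r} not in study")
    return _fit_one(values.loc[gene].to_numpy(), d1, d0, term, gene)


def run_transcriptome(
    study: ExpressionStudy, contrast: ContrastSpec
) -> list[GeneResult]:
    """Fit every gene for one contrast; BH q across converged genes; sorted
    by p ascending (non-converged genes trail)."""
    values, d1, d0, term = build_contrast_designs(study, contrast)
    results = [
        _fit_one(values.iloc[i].to_numpy(), d1, d0, term, g)
        for i, g in enumerate(values.index)
    ]
    attach_fdr(results)
    results.sort(key=lambda r: (not r.converged, r.p, r.gene))
    return results


def attach_fdr(results: list[GeneResult]) -> None:
    conv = [r for r in results if r.converged]
    if conv:
        qs = bh_fdr([r.p for r in conv])
        for r, q in zip(conv, qs):
            r.q = float(q)
    for r in results:
        if not r.converged:
            r.q = np.nan


def baseline_differences(study: ExpressionStudy, comparison: str) -> list[GeneResult]:
    """T1-only ordinary linear models: expression ~ group + age + sex.

    ``comparison`` is ``"response"`` (responder vs non-responder, patients
    only) or ``"case"`` (patient vs control).  The reported p is the Wald
    test on the group coefficient; the LRT column carries the squared
    t-statistic for symmetry with the longitudinal results.
    """
    if comparison not in ("response", "case"):
        raise ValueError("comparison must be 'response' or 'case'")
    cohort = "patients" if comparison == "response" else "all"
    sub = study.filter(cohort=cohort, timepoints=("T1",))
    meta = sub.samples
    if comparison == "response":
        grp = (meta["group"] == "responder").to_numpy(float)
    else:
        grp = meta["group"].isin(["responder", "non_responder"]).to_numpy(float)
    if len(np.unique(grp)) < 2:
        raise ValueError(f"both comparison groups must be present at T1 ({comparison})")
    X = np.column_stack(
        [
            np.ones(len(meta)),
            grp,
            meta["age"].to_numpy(float),
            (meta["sex"] == "F").to_numpy(float),
        ]
    )
    # shared OLS pieces: pinv once, per-gene residual variance
    XtXi = np.linalg.inv(X.T @ X)
    H = XtXi @ X.T
    dof = X.shape[0] - X.shape[1]
    results: list[GeneResult] = []
    Y = sub.values.to_numpy()
    for i, gene in enumerate(sub.values.index):
        y = Y[i]
        if np.ptp(y) == 0.0:
            results.append(GeneResult(gene, np.nan, 0.0, 1, 1.0, converged=False))
            continue
        beta = H @ y
        resid = y - X @ beta
        s2 = float(resid @ resid) / dof
        se = np.sqrt(max(s2 * XtXi[1, 1], 1e-300))
        t = beta[1] / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
        results.append(
            GeneResult(
                gene,
                estimate=float(beta[1]),
                lrt_stat=float(t * t),
                df=1,
                p=max(min(p, 1.0), np.finfo(float).tiny),
            )
        )
    attach_fdr(results)
    results.sort(key=lambda r: (not r.converged, r.p, r.gene))
    return results


def results_frame(results: list[GeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "estimate": [r.estimate for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction for r in results],
            "converged": [r.converged for r in results],
        }
    )


def summarize_counts(
    results_by_contrast: dict[str, list[GeneResult]], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-contrast counts of significant genes with the up/down split
    (n_up + n_down = n_sig by construction)."""
    rows = []
    for name, results in results_by_contrast.items():
        sig = [r for r in results if r.converged and np.isfinite(r.q) and r.q < alpha]
        n_up = sum(1 for r in sig if r.direction > 0)
        n_down = sum(1 for r in sig if r.direction < 0)
        rows.append(
            {"contrast": name, "n_sig": len(sig), "n_up": n_up, "n_down": n_down}
        )
    return pd.DataFrame(rows)
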