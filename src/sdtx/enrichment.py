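"""Gene-set level analyses on per-gene differential-expression results.

* :func:`make_ranked_list` — signed -log10(p) scores (sign = direction of
  change), the input to preranked enrichment.
* :func:`gsea_preranked` — weighted Kolmogorov-Smirnov-style running-sum
  enrichment with gene-label permutations of set membership, normalized
  enrichment scores and both the classical positive/negative-pooled FDR and
  a within-direction Benjamini-Hochberg q.
* :func:`montecarlo_set_test` — the targeted over-representation test:
  probability that a random same-size gene set contains at least the
  observed number of nominally significant genes, with the exact
  hypergeometric tail reported alongside (the draw-without-replacement null
  is hypergeometric).
* :func:`screen_panel` — per-gene table for a fixed panel (e.g. the
  packaged circadian panel) with uncorrected and FDR flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneSetCollection
from .deg import GeneResult, bh_fdr


@dataclass
class RankedList:
    """(gene, score) pairs sorted by descending score; scores are
    sign(direction) * -log10(p), dimensionless."""

    entries: pd.DataFrame  # columns: gene, score

    def __post_init__(self) -> None:
        df = self.entries
        if df["gene"].duplicated().any():
            dup = sorted(df.loc[df["gene"].duplicated(), "gene"])
            raise ValueError(f"duplicate genes in ranked list: {dup[:5]}")
        if not np.isfinite(df["score"]).all():
            raise ValueError("ranked-list scores must be finite")
        # descending score, ties broken by gene symbol for determinism
        self.entries = df.sort_values(
            ["score", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)

    @property
    def genes(self) -> np.ndarray:
        return self.entries["gene"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.entries["score"].to_numpy()

    def __len__(self) -> int:
        return len(self.entries)


def make_ranked_list(results: "list[GeneResult]") -> RankedList:
    """Signed -log10(p) ranked list from per-gene results.

    Non-converged genes are dropped; p is floored at the smallest positive
    float before the log.
    """
    rows = [
        {
            "gene": r.gene,
            "score": float(r.direction) * (-np.log10(max(r.p, np.finfo(float).tiny))),
        }
        for r in results
        if r.converged
    ]
    if not rows:
        raise ValueError("no converged results to rank")
    return RankedList(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    q: float  # classical positive/negative-pooled GSEA FDR
    q_bh: float  # within-direction BH on permutation p-values
    n_members_in_list: int


def enrichment_score(
    scores: np.ndarray, hit_positions: np.ndarray, weight: float = 1.0
) -> float:
    """Running-sum enrichment score for one set.

    Hits increment by |score|^weight normalized by their total; misses
    decrement by 1/(N - m).  The ES is the running sum's maximum deviation
    from zero (signed).
    """
    N = scores.shape[0]
    m = hit_positions.shape[0]
    if m == 0 or m >= N:
        raise ValueError("set must have >= 1 and < all members in the list")
    pos = np.sort(hit_positions)
    w = np.abs(scores[pos]) ** weight
    tot = w.sum()
    if tot <= 0:  # all hit scores are zero: fall back to unweighted hits
        w = np.ones(m)
        tot = float(m)
    hit_cum = np.cumsum(w) / tot
    miss_step = 1.0 / (N - m)
    # running sum just before hit i: (pos_i - i) misses seen so far
    before = (hit_cum - w / tot) - (pos - np.arange(m)) * miss_step
    after = hit_cum - (pos - np.arange(m)) * miss_step
    candidates = np.concatenate([before, after])
    maxc, minc = float(candidates.max()), float(candidates.min())
    # max |deviation|; magnitude ties between the positive and negative
    # extreme (within fp noise) resolve to the positive one
    return maxc if maxc >= -minc - 1e-12 else minc


def _null_es(
    scores: np.ndarray, m: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES from random same-size membership (gene-label permutation).

    Vectorized over permutations: each draw is a uniform m-subset of ranks.
    """
    N = scores.shape[0]
    # m smallest of N uniform keys per row = uniform subset without replacement
    pos = np.argpartition(rng.random((n_perm, N)), m - 1, axis=1)[:, :m]
    pos.sort(axis=1)
    w = np.abs(scores[pos]) ** weight
    tot = w.sum(axis=1, keepdims=True)
    flat = tot[:, 0] <= 0
    if flat.any():  # all-zero hit scores: unweighted fallback
        w[flat] = 1.0
        tot[flat] = float(m)
    hit_cum = np.cumsum(w, axis=1) / tot
    miss = (pos - np.arange(m)) / (N - m)
    before = (hit_cum - w / tot) - miss
    after = hit_cum - miss
    cand = np.concatenate([before, after], axis=1)
    maxc = cand.max(axis=1)
    minc = cand.min(axis=1)
    return np.where(maxc >= -minc - 1e-12, maxc, minc)


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked gene-set enrichment over a collection.

    Sets with no member in the list, or covering the entire list, are
    skipped.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    scores = ranked.scores
    index = {g: i for i, g in enumerate(ranked.genes)}
    N = len(ranked)

    observed: list[tuple[str, float, int]] = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in sets:
        pos = np.array(sorted(index[g] for g in members if g in index), dtype=int)
        m = pos.shape[0]
        if m == 0 or m >= N:
            continue
        observed.append((name, enrichment_score(scores, pos, weight), m))
        if m not in null_by_size:
            null_by_size[m] = _null_es(scores, m, n_perm, weight, rng)

    results: list[EnrichmentResult] = []
    all_nes_obs: list[float] = []
    all_nes_null: list[np.ndarray] = []
    for name, es, m in observed:
        null = null_by_size[m]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            p = (1.0 + np.sum(same >= es)) / (1.0 + same.size)
            mean_abs = np.abs(same).mean() if same.size else np.nan
        else:
            same = neg_null
            p = (1.0 + np.sum(same <= es)) / (1.0 + same.size)
            mean_abs = np.abs(same).mean() if same.size else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        # normalize the null the same way for the pooled FDR
        nes_null = np.concatenate(
            [
                pos_null / (np.abs(pos_null).mean() if pos_null.size else np.nan),
                neg_null / (np.abs(neg_null).mean() if neg_null.size else np.nan),
            ]
        )
        all_nes_obs.append(nes)
        all_nes_null.append(nes_null)
        results.append(
            EnrichmentResult(name, es, nes, float(p), np.nan, np.nan, m)
        )

    _attach_gsea_fdr(results, np.array(all_nes_obs), all_nes_null)
    _attach_bh(results)
    results.sort(key=lambda r: (r.p_perm, r.set_name))
    return results


def _attach_gsea_fdr(
    results: list[EnrichmentResult],
    nes_obs: np.ndarray,
    nes_null: list[np.ndarray],
) -> None:
    """Classical GSEA FDR: pool normalized null scores and observed NES by
    sign; q(NES*) = [null fraction at least as extreme] / [observed fraction
    at least as extreme], capped at 1 and monotonized within sign."""
    if not results:
        return
    pooled = np.concatenate(nes_null) if nes_null else np.array([])
    pooled = pooled[np.isfinite(pooled)]
    for i, r in enumerate(results):
        nes = nes_obs[i]
        if not np.isfinite(nes):
            r.q = np.nan
            continue
        if nes >= 0:
            null_frac_denom = np.sum(pooled >= 0)
            null_frac = (
                np.sum(pooled >= nes) / null_frac_denom if null_frac_denom else np.nan
            )
            obs_side = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            obs_frac = np.sum(obs_side >= nes) / obs_side.size
        else:
            null_frac_denom = np.sum(pooled < 0)
            null_frac = (
                np.sum(pooled <= nes) / null_frac_denom if null_frac_denom else np.nan
            )
            obs_side = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
            obs_frac = np.sum(obs_side <= nes) / obs_side.size
        r.q = float(min(null_frac / obs_frac, 1.0)) if obs_frac > 0 else np.nan


def _attach_bh(results: list[EnrichmentResult]) -> None:
    for sign in (1, -1):
        side = [r for r in results if (r.es >= 0) == (sign > 0)]
        if side:
            qs = bh_fdr([r.p_perm for r in side])
            for r, q in zip(side, qs):
                r.q_bh = float(q)


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_perm": [r.p_perm for r in results],
            "q": [r.q for r in results],
            "q_bh": [r.q_bh for r in results],
            "n_members_in_list": [r.n_members_in_list for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Monte-Carlo panel over-representation


@dataclass
class MonteCarloResult:
    panel_size: int  # m, after dropping panel genes absent from the universe
    observed: int  # panel genes with p < alpha_unc
    b_draws: int
    exceed: int  # draws with count >= observed
    p_emp: float  # (exceed + 1) / (b_draws + 1)
    analytic_p: float  # exact hypergeometric upper tail, for cross-check
    missing: tuple[str, ...] = ()


def montecarlo_set_test(
    results: "list[GeneResult]",
    panel: "list[str]",
    b_draws: int = 10_000,
    alpha_unc: float = 0.05,
    seed: int = 0,
) -> MonteCarloResult:
    """Probability that a random same-size gene set shows at least the
    panel's number of nominally significant genes (p < ``alpha_unc``).

    Draws are without replacement from the analyzed universe, so the null is
    exactly hypergeometric; the analytic tail is always reported alongside
    the empirical p.
    """
    if b_draws < 1000:
        raise ValueError("b_draws must be >= 1000")
    if not 0.0 < alpha_unc < 1.0:
        raise ValueError("alpha_unc must lie in (0, 1)")
    universe = {r.gene: r for r in results}
    panel_upper = [g.upper() for g in panel]
    present = [g for g in panel_upper if g in universe]
    missing = tuple(g for g in panel_upper if g not in universe)
    m = len(present)
    if m == 0:
        raise ValueError("no panel genes present in the analyzed universe")
    sig = np.array([r.p < alpha_unc for r in results])
    N, K = sig.size, int(sig.sum())
    observed = sum(1 for g in present if universe[g].p < alpha_unc)

    rng = np.random.default_rng(seed)
    counts = np.empty(b_draws, dtype=int)
    for b in range(b_draws):
        counts[b] = sig[rng.choice(N, size=m, replace=False)].sum()
    exceed = int(np.sum(counts >= observed))
    p_emp = (exceed + 1) / (b_draws + 1)
    analytic = float(stats.hypergeom.sf(observed - 1, N, K, m))
    return MonteCarloResult(m, observed, b_draws, exceed, p_emp, analytic, missing)


def screen_panel(
    results: "list[GeneResult]", panel: "list[str]", alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Panel-restricted per-gene table with direction annotations and both
    uncorrected and FDR significance flags; panel genes absent from the
    results are returned separately."""
    universe = {r.gene: r for r in results}
    rows, missing = [], []
    for g in (s.upper() for s in panel):
        r = universe.get(g)
        if r is None:
            missing.append(g)
            continue
        rows.append(
            {
                "gene": g,
                "estimate": r.estimate,
                "direction": "up" if r.direction > 0 else ("down" if r.direction < 0 else "flat"),
                "p": r.p,
                "q": r.q,
                "sig_unc": bool(r.p < alpha),
                "sig_fdr": bool(np.isfinite(r.q) and r.q < alpha),
            }
        )
    columns = ["gene", "estimate", "direction", "p", "q", "sig_unc", "sig_fdr"]
    return pd.DataFrame(rows, columns=columns), missing
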