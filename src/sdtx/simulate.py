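"""Synthetic longitudinal sleep-deprivation cohort generator.

Emulates the study design every downstream stage assumes: three
clock-time-matched morning blood draws (T1 before sleep deprivation, T2
after the vigil, T3 after recovery sleep) from responders, non-responders
and healthy controls, with dropout, subject-level random intercepts,
age/sex covariate effects, and injected time, group-by-time and
gene-set-coherent effects on the log-intensity scale.

The default :class:`SimulationConfig` mirrors the published design table:
60 responders, 16 non-responders and 15 controls, participating
60/56/53, 16/16/13 and 15/15/15 at T1/T2/T3 (91 + 87 + 81 = 259 samples,
169 of them from responders), with two protocol-violating patients at T3.

The generative model for gene g in sample (subject i, timepoint t) is

    y_gi(t) = b_g + u_i + a_g * age_i + s_g * 1[female_i]
              + sum of applicable effect profiles at t + e_git,

with u_i ~ N(0, sigma_u^2) and e_git ~ N(0, sigma_e^2), all additive on the
log scale.  Genes are independent apart from shared injected effects;
set-coherent effects supply the within-set correlation that trajectory
analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionStudy, GROUPS, TIMEPOINTS

#: Published design table participation counts per group and timepoint.
TABLE1_PARTICIPATION: dict[str, tuple[int, int, int]] = {
    "responder": (60, 56, 53),
    "non_responder": (16, 16, 13),
    "control": (15, 15, 15),
}

#: Male fraction per group at enrolment (from the design table T1 row).
_MALE_FRACTION = {"responder": 36 / 60, "non_responder": 7 / 16, "control": 7 / 15}

EFFECT_KINDS = (
    "time_main",
    "group_by_time",
    "baseline_shift",
    "set_coherent_trajectory",
)

#: Truth-table contrast each effect kind is flagged under.
_KIND_TO_CONTRAST = {
    "time_main": "M1",
    "baseline_shift": "baseline",
    "set_coherent_trajectory": "trajectory",
}


@dataclass(frozen=True)
class EffectSpec:
    """One injected effect.

    ``timepoint_profile`` gives the additive shift at (T1, T2, T3); the T1
    entry must be 0 (all effects are deviations from baseline except
    ``baseline_shift``, whose magnitude applies at every timepoint).
    ``group_restriction`` limits the effect to one group ("responder",
    "non_responder", "control") or to all "patients"; ``None`` applies it to
    every subject.
    """

    target: tuple[str, ...] | str  # gene tuple, or a gene-set name
    kind: str
    magnitude: float
    timepoint_profile: tuple[float, float, float] = (0.0, 1.0, 1.0)
    group_restriction: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind != "baseline_shift" and self.timepoint_profile[0] != 0.0:
            raise ValueError("timepoint_profile must be zeroed at T1")
        if self.group_restriction is not None and self.group_restriction not in (
            *GROUPS,
            "patients",
        ):
            raise ValueError(
                f"bad group_restriction {self.group_restriction!r}"
            )

    def applies_to(self, group: str) -> bool:
        if self.group_restriction is None:
            return True
        if self.group_restriction == "patients":
            return group in ("responder", "non_responder")
        return group == self.group_restriction

    @property
    def contrast(self) -> str:
        if self.kind == "group_by_time":
            if self.group_restriction in ("responder", "non_responder"):
                return "M2"
            return "M3"
        return _KIND_TO_CONTRAST[self.kind]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Units: expression values, baselines, standard deviations and effect
    magnitudes are log-scale intensities; ages are years.
    """

    n_responders: int = 60
    n_non_responders: int = 16
    n_controls: int = 15
    participation: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(TABLE1_PARTICIPATION)
    )
    n_genes: int = 2000
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0  # spread of per-gene baselines around the mean
    subject_intercept_sd: float = 0.5
    residual_sd: float = 0.3
    age_effect_sd: float = 0.0  # per-gene age slopes ~ N(0, age_effect_sd^2)
    sex_effect_sd: float = 0.0  # per-gene female-offset ~ N(0, sex_effect_sd^2)
    effects: tuple[EffectSpec, ...] = ()
    gene_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    include_panel_genes: bool = True
    n_protocol_violators: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {
            "responder": self.n_responders,
            "non_responder": self.n_non_responders,
            "control": self.n_controls,
        }
        for grp, counts in self.participation.items():
            if grp not in sizes:
                raise ValueError(f"participation for unknown group {grp!r}")
            if len(counts) != len(TIMEPOINTS):
                raise ValueError(f"{grp}: need one participation count per timepoint")
            if any(c < 0 or c > sizes[grp] for c in counts):
                raise ValueError(
                    f"{grp}: participation counts {counts} exceed group size "
                    f"{sizes[grp]}"
                )
        for sd in (self.baseline_sd, self.subject_intercept_sd, self.residual_sd):
            if sd <= 0:
                raise ValueError("all standard deviations must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def gene_names(n_genes: int, include_panel: bool = True) -> list[str]:
    """Synthetic gene universe: the packaged circadian panel symbols first
    (so targeted panel analyses run against simulated data), padded with
    systematic placeholder symbols."""
    names: list[str] = []
    if include_panel:
        from .io import load_circadian_panel

        names = load_circadian_panel()[:n_genes]
    names += [f"G{i:05d}" for i in range(1, n_genes - len(names) + 1)]
    return names


def _resolve_targets(config: SimulationConfig, genes: list[str]) -> dict[int, list[str]]:
    """Resolve each effect's target to a concrete gene list; error on unknowns."""
    universe = set(genes)
    resolved: dict[int, list[str]] = {}
    for i, eff in enumerate(config.effects):
        if isinstance(eff.target, str):
            if eff.target not in config.gene_sets:
                raise ValueError(
                    f"effect {i}: gene set {eff.target!r} not in config.gene_sets"
                )
            members = list(config.gene_sets[eff.target])
        else:
            members = list(eff.target)
        unknown = sorted(set(members) - universe)
        if unknown:
            raise ValueError(f"effect {i}: unknown target genes {unknown[:5]}")
        resolved[i] = members
    return resolved


def simulate_cohort(config: SimulationConfig) -> ExpressionStudy:
    """Draw one synthetic study; bitwise-deterministic given the config seed."""
    genes = gene_names(config.n_genes, config.include_panel_genes)
    resolved = _resolve_targets(config, genes)  # validates before any sampling
    rng = np.random.default_rng(config.seed)

    # -- subjects -----------------------------------------------------------
    sizes = {
        "responder": config.n_responders,
        "non_responder": config.n_non_responders,
        "control": config.n_controls,
    }
    subjects: list[dict] = []
    for grp in ("responder", "non_responder", "control"):
        mu, sd = (43.54, 14.80) if grp != "control" else (40.53, 15.90)
        for j in range(sizes[grp]):
            age = float(np.clip(rng.normal(mu, sd), 18.0, 80.0))
            sex = "M" if rng.random() < _MALE_FRACTION[grp] else "F"
            subjects.append(
                {
                    "subject_id": f"{grp[:1].upper()}{j + 1:03d}",
                    "group": grp,
                    "age": age,
                    "sex": sex,
                    "intercept": rng.normal(0.0, config.subject_intercept_sd),
                }
            )
    subj_df = pd.DataFrame(subjects)

    # -- dropout: uniformly chosen participants per group and timepoint -----
    rows: list[dict] = []
    for grp in ("responder", "non_responder", "control"):
        members = subj_df.index[subj_df["group"] == grp].to_numpy()
        counts = config.participation.get(grp, (sizes[grp],) * 3)
        for t_idx, tp in enumerate(TIMEPOINTS):
            chosen = np.sort(rng.choice(members, size=counts[t_idx], replace=False))
            for m in chosen:
                rows.append({"subj_idx": int(m), "timepoint": tp})
    obs = pd.DataFrame(rows)

    # -- protocol violators among patients sampled at T3 --------------------
    t3_patients = obs.loc[
        (obs["timepoint"] == "T3")
        & subj_df.loc[obs["subj_idx"], "group"].ne("control").to_numpy(),
        "subj_idx",
    ].to_numpy()
    n_viol = min(config.n_protocol_violators, len(t3_patients))
    violators = set(
        rng.choice(t3_patients, size=n_viol, replace=False) if n_viol else []
    )

    # -- per-gene parameters -------------------------------------------------
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    age_slopes = (
        rng.normal(0.0, config.age_effect_sd, config.n_genes)
        if config.age_effect_sd > 0
        else np.zeros(config.n_genes)
    )
    sex_offsets = (
        rng.normal(0.0, config.sex_effect_sd, config.n_genes)
        if config.sex_effect_sd > 0
        else np.zeros(config.n_genes)
    )
    gene_pos = {g: i for i, g in enumerate(genes)}

    # -- assemble sample table and mean matrix -------------------------------
    n_samples = len(obs)
    meta_rows = []
    mean = np.empty((config.n_genes, n_samples))
    t_index = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    for col, (_, row) in enumerate(obs.iterrows()):
        subj = subj_df.loc[row["subj_idx"]]
        tp = row["timepoint"]
        sid = f"{subj.subject_id}_{tp}"
        meta_rows.append(
            {
                "sample_id": sid,
                "subject_id": subj.subject_id,
                "timepoint": tp,
                "group": subj.group,
                "age": subj.age,
                "sex": subj.sex,
                "protocol_violation": row["subj_idx"] in violators,
            }
        )
        mu_col = (
            baselines
            + subj.intercept
            + age_slopes * subj.age
            + sex_offsets * (1.0 if subj.sex == "F" else 0.0)
        )
        for i, eff in enumerate(config.effects):
            if not eff.applies_to(subj.group):
                continue
            if eff.kind == "baseline_shift":
                shift = eff.magnitude
            else:
                shift = eff.magnitude * eff.timepoint_profile[t_index[tp]]
            if shift != 0.0:
                idx = [gene_pos[g] for g in resolved[i]]
                mu_col = mu_col.copy()
                mu_col[idx] += shift
        mean[:, col] = mu_col

    noise = rng.normal(0.0, config.residual_sd, mean.shape)
    values = pd.DataFrame(
        mean + noise, index=pd.Index(genes, name="gene"),
        columns=[r["sample_id"] for r in meta_rows],
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionStudy(values, meta)


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Ground truth: one row per (gene, contrast) with a boolean true_effect.

    Contrasts are M1 (time in patients), M2 (response-by-time), M3
    (case-by-time), baseline (T1 group difference) and trajectory
    (set-coherent time-course).  Each effect kind flags exactly one
    contrast; recovery tests exercise one kind at a time.
    """
    genes = gene_names(config.n_genes, config.include_panel_genes)
    resolved = _resolve_targets(config, genes)
    contrasts = ("M1", "M2", "M3", "baseline", "trajectory")
    flagged: dict[str, set[str]] = {c: set() for c in contrasts}
    for i, eff in enumerate(config.effects):
        if eff.magnitude != 0.0:
            flagged[eff.contrast].update(resolved[i])
    rows = [
        {"gene": g, "contrast": c, "true_effect": g in flagged[c]}
        for c in contrasts
        for g in genes
    ]
    return pd.DataFrame(rows)


def synthetic_hallmark_collection(
    config: SimulationConfig, n_sets: int = 50, set_size: int = 30, seed: int | None = None
) -> dict[str, tuple[str, ...]]:
    """A hallmark-like collection drawn from the simulated gene universe.

    Produces ``n_sets`` disjoint-ish named sets (random draws without
    replacement per set) including one named ``HALLMARK_HEME_METABOLISM`` so
    the exclusion path can be exercised.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = np.array(gene_names(config.n_genes, config.include_panel_genes))
    names = [f"HALLMARK_SET_{i:02d}" for i in range(1, n_sets)]
    names.append("HALLMARK_HEME_METABOLISM")
    return {
        name: tuple(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        for name in names
    }
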