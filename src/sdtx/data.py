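"""Core containers for the longitudinal expression study.

An :class:`ExpressionStudy` couples a genes × samples matrix of log-scale
intensities to per-sample metadata (subject, timepoint, group, age, sex,
protocol-violation flag).  It is the single substrate every analysis stage
consumes: per-gene mixed-model contrasts, baseline linear models, enrichment
and time-course gene-set analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("T1", "T2", "T3")
GROUPS = ("responder", "non_responder", "control")
SEXES = ("M", "F")

#: Cohort labels accepted by group-level analyses.
COHORTS = ("patients", "controls", "responders", "non_responders", "all")

META_COLUMNS = (
    "sample_id",
    "subject_id",
    "timepoint",
    "group",
    "age",
    "sex",
    "protocol_violation",
)


class StudyValidationError(ValueError):
    """Raised when expression values and sample metadata are inconsistent."""


@dataclass(frozen=True)
class SampleRecord:
    """One blood draw: a subject at one of the three clock-time-matched mornings.

    T1 is the morning before sleep deprivation, T2 the morning after the
    ~36 h vigil, T3 the morning after recovery sleep.  ``protocol_violation``
    marks subjects whose T3 sample followed a broken recovery-sleep protocol;
    such T3 rows are excluded from trajectory analysis.
    """

    sample_id: str
    subject_id: str
    timepoint: str
    group: str
    age: float
    sex: str
    protocol_violation: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise StudyValidationError(
                f"sample {self.sample_id!r}: timepoint {self.timepoint!r} "
                f"not in {TIMEPOINTS}"
            )
        if self.group not in GROUPS:
            raise StudyValidationError(
                f"sample {self.sample_id!r}: group {self.group!r} not in {GROUPS}"
            )
        if self.sex not in SEXES:
            raise StudyValidationError(
                f"sample {self.sample_id!r}: sex {self.sex!r} not in {SEXES}"
            )
        if not np.isfinite(self.age) or self.age <= 0:
            raise StudyValidationError(
                f"sample {self.sample_id!r}: age must be a positive real, "
                f"got {self.age!r}"
            )


@dataclass
class ExpressionStudy:
    """Genes × samples log-intensity matrix joined to sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, one column per sample id, finite
        log-scale intensities.
    samples
        DataFrame indexed by sample id with columns ``subject_id``,
        ``timepoint``, ``group``, ``age``, ``sex``, ``protocol_violation``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.samples = self.samples.copy()
        self.samples["protocol_violation"] = self.samples[
            "protocol_violation"
        ].astype(bool)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        genes = self.values.index
        if genes.duplicated().any():
            dupes = sorted(genes[genes.duplicated()].unique())
            raise StudyValidationError(f"duplicate gene symbols: {dupes}")
        missing_meta = [c for c in META_COLUMNS[1:] if c not in self.samples.columns]
        if missing_meta:
            raise StudyValidationError(f"metadata missing columns: {missing_meta}")
        expr_ids = set(self.values.columns)
        meta_ids = set(self.samples.index)
        if expr_ids != meta_ids:
            only_expr = sorted(expr_ids - meta_ids)
            only_meta = sorted(meta_ids - expr_ids)
            raise StudyValidationError(
                "expression/metadata sample mismatch: "
                f"only in expression matrix {only_expr}; only in metadata {only_meta}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))
            g, s = bad[0]
            raise StudyValidationError(
                f"non-finite expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise StudyValidationError(f"unknown timepoints: {sorted(bad_tp)}")
        bad_grp = set(self.samples["group"]) - set(GROUPS)
        if bad_grp:
            raise StudyValidationError(f"unknown groups: {sorted(bad_grp)}")
        key = self.samples[["subject_id", "timepoint"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise StudyValidationError(
                f"duplicate (subject, timepoint): ({dup.subject_id}, {dup.timepoint})"
            )
        # group and sex must be constant per subject across timepoints
        for col in ("group", "sex"):
            per_subj = self.samples.groupby("subject_id")[col].nunique()
            unstable = per_subj[per_subj > 1]
            if len(unstable):
                raise StudyValidationError(
                    f"{col} varies within subject(s): {sorted(unstable.index)}"
                )
        # canonical ordering: samples by (subject, timepoint)
        order = self.samples.sort_values(["subject_id", "timepoint"]).index
        self.samples = self.samples.loc[order]
        self.values = self.values[order]

    # -- accessors ----------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_records(self) -> list[SampleRecord]:
        return [
            SampleRecord(sample_id=str(sid), **row[list(META_COLUMNS[1:])].to_dict())
            for sid, row in self.samples.iterrows()
        ]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        ids = list(sample_ids)
        return ExpressionStudy(self.values[ids], self.samples.loc[ids])

    def filter(
        self,
        cohort: str = "all",
        timepoints: Iterable[str] | None = None,
        drop_t3_violators: bool = False,
    ) -> "ExpressionStudy":
        """Restrict to a cohort / set of timepoints.

        ``cohort`` is one of ``patients`` (responders + non-responders),
        ``controls``, ``responders``, ``non_responders`` or ``all``.
        """
        mask = cohort_mask(self.samples, cohort)
        if timepoints is not None:
            mask &= self.samples["timepoint"].isin(list(timepoints))
        if drop_t3_violators:
            mask &= ~(
                (self.samples["timepoint"] == "T3")
                & self.samples["protocol_violation"]
            )
        ids = self.samples.index[mask]
        if len(ids) == 0:
            raise StudyValidationError(
                f"no samples left for cohort {cohort!r} with the given filters"
            )
        return self.subset_samples(list(ids))


def cohort_mask(samples: pd.DataFrame, cohort: str) -> pd.Series:
    """Boolean mask over a metadata frame for a named cohort."""
    if cohort == "all":
        return pd.Series(True, index=samples.index)
    if cohort == "patients":
        return samples["group"].isin(["responder", "non_responder"])
    if cohort == "controls":
        return samples["group"] == "control"
    if cohort == "responders":
        return samples["group"] == "responder"
    if cohort == "non_responders":
        return samples["group"] == "non_responder"
    raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50-set hallmark collection), GMT-style."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            # collapse duplicates, preserve first-seen order, uppercase symbols
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(str(m).upper(), None)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty after de-duplication")
            clean[name] = list(seen)
        if len(clean) != len(self.sets):
            raise ValueError("duplicate gene-set names")
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def exclude(self, names: Iterable[str]) -> "GeneSetCollection":
        drop = {n for n in names}
        kept = {n: m for n, m in self.sets.items() if n not in drop}
        return GeneSetCollection(kept, source=self.source)
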