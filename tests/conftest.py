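"""Shared fixtures: tiny hand-built studies and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sdtx.data import ExpressionStudy
from sdtx.simulate import SimulationConfig, simulate_cohort


def make_study(
    n_subjects_per_group: dict[str, int],
    timepoints: tuple[str, ...] = ("T1", "T2", "T3"),
    n_genes: int = 5,
    seed: int = 0,
    subject_sd: float = 0.5,
    residual_sd: float = 0.3,
    gene_shift=None,
) -> ExpressionStudy:
    """Small hand-rolled study; ``gene_shift(gene_idx, timepoint, group)``
    optionally adds a deterministic offset."""
    rng = np.random.default_rng(seed)
    cols, meta, vals = [], [], []
    genes = [f"G{i}" for i in range(n_genes)]
    for group, n in n_subjects_per_group.items():
        for j in range(n):
            sid = f"{group[:1].upper()}{j:03d}"
            age = float(rng.uniform(20, 70))
            sex = "M" if rng.random() < 0.5 else "F"
            u = rng.normal(0, subject_sd)
            for tp in timepoints:
                cols.append(f"{sid}_{tp}")
                meta.append(
                    dict(
                        sample_id=f"{sid}_{tp}",
                        subject_id=sid,
                        timepoint=tp,
                        group=group,
                        age=age,
                        sex=sex,
                        protocol_violation=False,
                    )
                )
                col = 7.0 + u + rng.normal(0, residual_sd, n_genes)
                if gene_shift is not None:
                    col = col + np.array(
                        [gene_shift(i, tp, group) for i in range(n_genes)]
                    )
                vals.append(col)
    values = pd.DataFrame(np.array(vals).T, index=genes, columns=cols)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionStudy(values, samples)


@pytest.fixture(scope="session")
def table1_study() -> ExpressionStudy:
    """Design-table cohort, modest gene count, no injected effects."""
    return simulate_cohort(SimulationConfig(n_genes=60, seed=101))


@pytest.fixture(scope="session")
def table1_config() -> SimulationConfig:
    return SimulationConfig(n_genes=60, seed=101)
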