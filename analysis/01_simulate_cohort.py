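#!/usr/bin/env python
"""Simulate the study cohort.

Generates a synthetic longitudinal sleep-deprivation cohort mirroring the
published design table (60 responders / 16 non-responders / 15 controls;
91 + 87 + 81 = 259 samples over T1/T2/T3 with dropout and two T3 protocol
violators), with injected effects:

* a time effect (T2 spike) on 40 genes in all patients,
* a responder-specific response-by-time interaction on 30 genes,
* coherent trajectories on two hallmark-like gene sets (one responder-only),
* mild circadian-panel differential expression after the vigil.

Writes the expression matrix, sample metadata, a hallmark-like GMT and the
ground-truth effect table under results/data/.
"""

import pathlib

from sdtx.data import GeneSetCollection
from sdtx.io import load_circadian_panel, write_expression, write_gmt
from sdtx.simulate import (
    EffectSpec,
    SimulationConfig,
    gene_names,
    simulate_cohort,
    synthetic_hallmark_collection,
    truth_table,
)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "data"
N_GENES = 1200
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = SimulationConfig(n_genes=N_GENES, seed=SEED)
    sets = synthetic_hallmark_collection(base, n_sets=50, set_size=30)
    genes = gene_names(N_GENES)
    panel = load_circadian_panel()
    config = base.with_(
        gene_sets=sets,
        effects=(
            EffectSpec(tuple(genes[100:140]), "time_main", 0.4, (0, 1, 0.3)),
            EffectSpec(tuple(genes[140:170]), "group_by_time", 0.5, (0, 1, 1),
                       "responder"),
            EffectSpec("HALLMARK_SET_01", "set_coherent_trajectory", 0.35,
                       (0, 1, 1)),
            EffectSpec("HALLMARK_SET_02", "set_coherent_trajectory", 0.35,
                       (0, 1, 0.5), "responder"),
            EffectSpec(tuple(panel), "time_main", 0.25, (0, 1, 0.3)),
        ),
    )
    study = simulate_cohort(config)
    write_expression(study, OUT / "expr.tsv", OUT / "meta.tsv")
    write_gmt(
        GeneSetCollection({k: list(v) for k, v in sets.items()},
                          source="synthetic hallmark-like collection"),
        OUT / "hallmark_like.gmt",
    )
    truth_table(config).to_csv(OUT / "truth.tsv", sep="\t", index=False)

    meta = study.samples
    print(f"cohort: {study.n_samples} samples, {len(study.genes)} genes")
    for tp in ("T1", "T2", "T3"):
        print(f"  {tp}: {(meta['timepoint'] == tp).sum()} samples")
    print(f"  responder samples: {(meta['group'] == 'responder').sum()}")
    print(f"  T3 protocol violators: "
          f"{((meta['timepoint'] == 'T3') & meta['protocol_violation']).sum()}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
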