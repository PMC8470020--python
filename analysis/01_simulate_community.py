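#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, under scratch/simulated/ (bulky raw inputs) and results/analysis/
(small summary tables):

* per-MAG protein FASTA files with planted multiheme-cytochrome inventories
  shaped like the ANME/sulfate-reducer bins, plus motif-free background;
* the 33-bin community annotation table (markers, autotrophic pathways,
  methanogenesis complement for the two ANME bins);
* an ASV count table with 744 true taxa and a planted 39% dominant group;
* a qPCR run (standards + triplicate unknowns) and tracer incubation records.
"""

import pathlib
import sys

import numpy as np

from magpot import synthetic

SEED = 20210953 % 2**31
SCRATCH = pathlib.Path("scratch/simulated")
RESULTS = pathlib.Path("results/analysis")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    for spec in synthetic.mhc_community_specs(seed=SEED):
        records, truth = synthetic.generate_protein_set(spec)
        synthetic.write_fasta(records, SCRATCH / f"{spec.mag_id}.faa")
        truth.to_csv(SCRATCH / f"{spec.mag_id}_truth.tsv", sep="\t", index=False)
        print(f"{spec.mag_id}: {len(records)} proteins "
              f"({int(truth['is_mhc'].sum())} planted MHCs)")

    annotations = synthetic.build_community_annotations(seed=SEED)
    annotations.to_csv(SCRATCH / "community_annotations.tsv", sep="\t", index=False)
    print(f"community annotation table: {len(annotations)} rows, "
          f"{annotations['mag_id'].nunique()} MAGs")

    weights = {"Archaea;ANME-3": 0.39, "Archaea;ANME-2a-2b": 0.04,
               "Archaea;DSEG": 0.04, "Bacteria;Proteobacteria": 0.21,
               "Bacteria;Chloroflexi": 0.09, "Bacteria;Bacteroidetes": 0.04,
               "Bacteria;Actinobacteria": 0.04, "Bacteria;Firmicutes": 0.03,
               "Bacteria;Cyanobacteria": 0.03, "Bacteria;other": 0.09}
    asv = synthetic.generate_asv_counts(744, depth=130_574, sigma=1.5,
                                        group_weights=weights, seed=SEED)
    asv.to_csv(SCRATCH / "asv_table.tsv", sep="\t", index=False)
    print(f"ASV table: {len(asv)} taxa, {asv['count'].sum()} reads")

    run = synthetic.generate_qpcr_run(
        {"total_16S": 3.03e8, "ANME3_16S": 8.85e7},
        efficiency_pct=89.5, cq_noise_sd=0.1, seed=SEED)
    run.standards.to_csv(SCRATCH / "qpcr_standards.tsv", sep="\t", index=False)
    run.samples.to_csv(SCRATCH / "qpcr_samples.tsv", sep="\t", index=False)
    print(f"qPCR run: {len(run.standards)} standard wells, "
          f"{len(run.samples)} sample wells")

    tracer = synthetic.generate_tracer_samples(true_rate=0.47, seed=SEED)
    tracer.to_csv(SCRATCH / "tracer_records.tsv", sep="\t", index=False)
    print(f"tracer records: {len(tracer)} (incl. killed controls)")


if __name__ == "__main__":
    main()
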