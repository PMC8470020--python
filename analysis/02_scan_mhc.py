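#!/usr/bin/env python
"""Multiheme-cytochrome inventory of the simulated ANME community.

Scans the planted protein sets for CxxCH heme-binding motifs, predicts
C-terminal transmembrane anchors, and rolls the calls up per MAG. Verifies
that the scanner recovers the planted truth exactly (precision = recall = 1)
and writes the per-MAG cytochrome inventory to results/analysis/.
"""

import pathlib

from magpot import motifs, synthetic

SEED = 20210953 % 2**31
RESULTS = pathlib.Path("results/analysis")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    summaries = []
    for spec in synthetic.mhc_community_specs(seed=SEED):
        records, truth = synthetic.generate_protein_set(spec)
        mhc_records, table = motifs.scan_proteins(records)
        called = {r.protein_id for r in mhc_records}
        planted = set(truth.loc[truth["is_mhc"], "protein_id"])
        s = motifs.summarize_mag(spec.mag_id, mhc_records)
        summaries.append(s)
        print(f"{spec.mag_id}: {s.n_mhc} MHCs ({s.n_mhc_gt10} with >10 motifs, "
              f"max {s.max_motifs}, {s.n_with_tm} with C-terminal TM helix); "
              f"precision={len(called & planted) / max(len(called), 1):.2f} "
              f"recall={len(called & planted) / max(len(planted), 1):.2f}")
        table.to_csv(RESULTS / f"mhc_scan_{spec.mag_id}.tsv", sep="\t", index=False)

    frame = motifs.summaries_to_frame(summaries)
    frame.to_csv(RESULTS / "mhc_summary.tsv", sep="\t", index=False)
    print("\nper-MAG cytochrome inventory written to",
          RESULTS / "mhc_summary.tsv")


if __name__ == "__main__":
    main()
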