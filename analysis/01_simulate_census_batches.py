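#!/usr/bin/env python
"""Generate the planted census batches the downstream analyses consume.

Three batches emulate the statistical structure of the generation
census at one-tenth scale (so the written tables stay small): an
autoregressive-model-like batch with high assignability and moderate
escape, a masked-model-like batch with sparse assignability, and a
background-control batch.  Each directory gets FASTA, structure-hit
and homology-hit tables, a fold map, and the planted truth JSON.

Writes to scratch/census/<batch>/ (inputs are regenerated on demand;
nothing here is needed at rest).
"""

import pathlib
import sys

from foldcensus.synthetic import PlantedBatchSpec, make_synthetic_hit_tables

OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "census"

BATCHES = {
    # one-tenth of the documented census sizes
    "autoregressive": PlantedBatchSpec.from_counts(
        n_valid=9_998, n_assigned=3_269, n_distinct_folds=668,
        n_escaped_among_assigned=1_896, n_invalid=2, seed=11,
    ),
    "masked_gibbs": PlantedBatchSpec.from_counts(
        n_valid=14_404, n_assigned=792, n_distinct_folds=356,
        n_escaped_among_assigned=300, seed=12,
    ),
    "background": PlantedBatchSpec.from_counts(
        n_valid=7_425, n_assigned=453, n_distinct_folds=300,
        n_escaped_among_assigned=200, seed=13,
    ),
}


def main():
    for name, spec in BATCHES.items():
        batch = make_synthetic_hit_tables(spec)
        outdir = OUT / name
        batch.write(str(outdir))
        t = batch.truth
        print(
            f"{name}: {t['n_sequences']} sequences "
            f"({t['n_invalid']} invalid), {t['n_assigned']} assignable "
            f"over {t['n_distinct_folds']} folds, "
            f"{t['n_escaped_among_assigned']} escaped -> {outdir}"
        )
    return 0


if __name__ == "__main__":
    sys.exit(main())
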