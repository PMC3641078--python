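#!/usr/bin/env python
"""Simulate the study's sort-seq library.

Generates a mutagenized 75-nt promoter library around a fixed wild type
(~7 substitutions per sequence; equal thirds whole-window, CRP-targeted
and RNAP-targeted, like the pooled assay it emulates), with a sparse
block-structured ground truth (strong additive effects and ~3% nonzero
pairwise interactions, 62% antagonistic, confined to the CRP/RNAP
binding-site blocks), reads it out through 9 logarithmic fluorescence
gates with a background floor and intrinsic noise, and emits 10%
duplicate measurements.

Outputs: scratch/data/sortseq.tsv (the records), scratch/data/truth.json
(the generating model) and results/simulation_summary.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

from promland.codec import write_records_tsv
from promland.simulate import (
    BinningSpec,
    assemble_records,
    pooled_mutagenized_library,
    sample_landscape,
    write_ground_truth,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 11
N_RECORDS = 20_000          # scaled-down library; the emulated assay had ~1.3e5
RATE = 7 / 75


def main() -> None:
    truth = sample_landscape(
        L=75, epistatic_sparsity=0.03, epistatic_scale=0.4,
        antagonistic_bias=0.62, seed=SEED,
    )
    # calibrate the gates on a pilot library, as a cytometer operator would
    pilot = pooled_mutagenized_library(truth.wildtype, 10_000, truth.region_map, seed=SEED + 1)
    spec = BinningSpec.default_for_latent(
        truth.model.predict(pilot, truth.wildtype), K=9
    )
    n_dup = int(round(0.10 * N_RECORDS))
    library = pooled_mutagenized_library(
        truth.wildtype, N_RECORDS - n_dup, truth.region_map, seed=SEED + 2
    )
    records = assemble_records(
        truth, library, spec, n_duplicates=n_dup, seed=SEED + 2, condition="library"
    )

    data_dir = ROOT / "scratch" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    write_records_tsv(records, data_dir / "sortseq.tsv")
    write_ground_truth(truth, spec, SEED, data_dir / "truth.json")

    loads = [sum(a != b for a, b in zip(s, truth.wildtype)) for s in records["sequence"]]
    summary = {
        "n_records": int(len(records)),
        "n_distinct_sequences": int(records["sequence"].nunique()),
        "mean_mutations_per_sequence": float(np.mean(loads)),
        "bin_occupancy": np.bincount(records["bin"], minlength=10)[1:].tolist(),
        "true_nonzero_J": len(truth.model.J),
        "binning": spec.to_json_dict(),
        "seed": SEED,
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "simulation_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"wrote {len(records)} records ({summary['n_distinct_sequences']} distinct)")
    print(f"mean mutation load {summary['mean_mutations_per_sequence']:.2f}")
    print(f"bin occupancy {summary['bin_occupancy']}")
    print(f"ground truth: {len(truth.model.J)} nonzero pairwise interactions")


if __name__ == "__main__":
    sys.exit(main())
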