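#!/usr/bin/env python
"""Estimate intrinsic noise and decompose the explainable variance.

Duplicate sequences recorded in different bins give an upper bound on the
intrinsic-noise share of the g(y) variance; replicate wild-type controls
give a lower estimate.  The additive and epistatic R^2 values are then
converted into shares of the *explainable* variance (total minus noise).

Outputs: results/noise_and_variance.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

from promland.additive import BinTransform
from promland.codec import filter_records, read_records_tsv
from promland.noise import (
    epistasis_variance_share,
    explainable_variance_share,
    noise_report,
)
from promland.simulate import BinningSpec, phenotype_to_bin, substream

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    truth = json.loads((ROOT / "scratch" / "data" / "truth.json").read_text())
    wt = truth["wildtype"]
    records, _ = filter_records(
        read_records_tsv(ROOT / "scratch" / "data" / "sortseq.tsv"), wt, 20
    )
    fit = json.loads((ROOT / "results" / "additive_fit.json").read_text())
    epi = json.loads((ROOT / "results" / "epistatic_fit.json").read_text())
    g = BinTransform(np.array(fit["g"]))

    # replicate wild-type control measurements through the same gates
    b = truth["binning"]
    spec = BinningSpec(b["K"], np.array(b["thresholds"]),
                       b["background_floor"], b["noise_sd"], b["noise_slope"])
    alpha_true = truth["model"]["alpha"]
    controls = g(phenotype_to_bin(np.full(300, alpha_true), spec,
                                  substream(truth["seed"], "controls")))

    rep = noise_report(records, g, controls)
    lo, hi = rep["control_lower_estimate"], rep["duplicate_upper_bound"]
    print(f"intrinsic noise interval: {100 * lo:.0f}%-{100 * hi:.0f}% "
          f"({rep['n_duplicate_groups']} duplicate groups)")

    r2_add, r2_epi = fit["r2_transformed"], epi["r2_in"]
    shares = {}
    for tag, nf in (("lower_noise", lo), ("upper_noise", hi)):
        shares[tag] = {
            "noise_fraction": nf,
            "additive_share": explainable_variance_share(r2_add, nf),
            "epistasis_share": epistasis_variance_share(r2_epi, r2_add, nf),
        }
        print(f"noise {100 * nf:.0f}%: additive model explains "
              f"{100 * shares[tag]['additive_share']:.0f}% of explainable variance, "
              f"pairwise epistasis adds {100 * shares[tag]['epistasis_share']:.1f}%")

    rep["explainable_variance"] = shares
    (ROOT / "results" / "noise_and_variance.json").write_text(json.dumps(rep, indent=1))


if __name__ == "__main__":
    sys.exit(main())
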