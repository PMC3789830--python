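#!/usr/bin/env python
"""Simulate the allele-specific expression phenotyping experiment.

Two designs are written as one long-format table under results/:

* phenotyping — an unknown strain (truly carrying Xce^b) crossed to two
  Xce^a carriers, one Xce^b carrier and one Xce^c carrier, 17 F1 females
  each, 5 genes x 3 tissues by pyrosequencing;
* reciprocals — three reciprocal F1 pairs with unequal Xce alleles,
  15 females per orientation, with a +0.25 log-odds parent-of-origin
  shift applied when the stronger allele is maternal.
"""

import argparse
from pathlib import Path

from xcemap import write_xci_table
from xcemap.synthetic_data import CrossDesign, reciprocal_design, simulate_xci


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    pheno_design = [
        CrossDesign("UNKNOWN/b", "A/J", "b", "a", 17),
        CrossDesign("UNKNOWN/b", "129S1/SvlmJ", "b", "a", 17),
        CrossDesign("UNKNOWN/b", "C57BL/6J", "b", "b", 17),
        CrossDesign("UNKNOWN/b", "CAST/EiJ", "b", "c", 17),
    ]
    meas, truth = simulate_xci(pheno_design, theta_c=60.0, seed=args.seed + 10)
    write_xci_table(meas, args.outdir / "xci_phenotyping.csv")
    truth.to_json(args.outdir / "xci_phenotyping_truth.json")
    print(f"phenotyping: {len(meas)} measurements, "
          f"true cross means {truth.mu_of_cross}")

    poe_design = (
        reciprocal_design("CAST/EiJ", "c", "WSB/EiJ", "b", 15)
        + reciprocal_design("A/J", "a", "WSB/EiJ", "b", 15)
        + reciprocal_design("CAST/EiJ", "c", "PWK/PhJ", "e", 15)
    )
    meas2, truth2 = simulate_xci(
        poe_design, genes=("g1", "g2", "g3"),
        tissues=("brain", "kidney", "liver"),
        poe_shift=0.25, seed=args.seed + 11,
    )
    write_xci_table(meas2, args.outdir / "xci_reciprocals.csv")
    truth2.to_json(args.outdir / "xci_reciprocals_truth.json")
    print(f"reciprocals: {len(meas2)} measurements, poe_shift=0.25 log-odds")


if __name__ == "__main__":
    main()
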