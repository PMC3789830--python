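#!/usr/bin/env python
"""Call the unknown strain's Xce allele from the fitted posteriors.

Reconstructs the cross posteriors from results/mu_chains.csv, computes the
tail probability of each cross against the 0.5 line, excludes partner
alleles whose posterior shows clear skew, and reports the allele call with
its position in the allelic series a < e < b < c < d. Writes the call as
JSON.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from xcemap import call_allele
from xcemap.xci_model import XCIPosterior

FOCAL = "UNKNOWN/b"
PARTNER_ALLELES = {
    ("UNKNOWN/b", "A/J"): "a",
    ("UNKNOWN/b", "129S1/SvlmJ"): "a",
    ("UNKNOWN/b", "C57BL/6J"): "b",
    ("UNKNOWN/b", "CAST/EiJ"): "c",
}


def posterior_from_chains(df: pd.DataFrame) -> XCIPosterior:
    crosses = sorted(tuple(c.split("x", 1)) for c in df["cross"].unique())
    n_chains = df["chain"].nunique()
    n_draws = df["iteration"].nunique()
    mu = np.empty((n_chains, n_draws, len(crosses)))
    for k, c in enumerate(crosses):
        sub = df[df["cross"] == f"{c[0]}x{c[1]}"].sort_values(["chain", "iteration"])
        mu[:, :, k] = sub["mu"].to_numpy().reshape(n_chains, n_draws)
    return XCIPosterior(
        {"mu": mu}, crosses, [], [], {c: FOCAL for c in crosses},
        {c: 0 for c in crosses}, {c: len(df) for c in crosses}, set(),
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha-share", type=float, default=0.05)
    args = ap.parse_args()

    df = pd.read_csv(args.outdir / "mu_chains.csv")
    post = posterior_from_chains(df)
    call = call_allele(post, FOCAL, PARTNER_ALLELES, alpha_share=args.alpha_share)
    with open(args.outdir / "allele_call.json", "w") as fh:
        json.dump(dataclasses.asdict(call), fh, indent=1)
    print(f"call for {FOCAL}: {call.call}")
    print(f"  excluded {call.excluded}, included {call.included}")
    print(f"  tail probabilities {call.tail_probs}")
    if call.note:
        print(f"  note: {call.note}")


if __name__ == "__main__":
    main()
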