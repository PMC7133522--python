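#!/usr/bin/env python
"""Phylogenetic conservation of responses at each location.

Runs consenTRAIT per location: consensus clades at the >90% threshold on
the location's subtree, tau_D for positive and negative responses, and
the 1000-randomization permutation p-values. Compares recovered depths
with the planted truth. Writes results/consentrait_per_location.tsv.
"""
import json
from pathlib import Path

import pandas as pd

from phyloresponse import depth_to_dissimilarity, read_newick
from phyloresponse.io import read_response
from phyloresponse.pipeline import consentrait_on_subtree

SEED = 20260927
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = read_newick(ROOT / "study/tree.nwk")
    truth = json.loads((ROOT / "study/truth.json").read_text())
    rows = []
    for resp_path in sorted(ROOT.glob("response_*.tsv")):
        loc = resp_path.stem.replace("response_", "")
        response = read_response(resp_path, location=loc)
        res = consentrait_on_subtree(tree, response,
                                     n_randomizations=1000, seed=SEED)
        rows.append({
            "location": loc,
            "n_otus": len(response.otu_ids),
            "n_clades": len(res.clades),
            "tau_pos": res.tau_pos, "p_pos": res.p_pos,
            "tau_neg": res.tau_neg, "p_neg": res.p_neg,
        })
        print(f"{loc}: tau_D(+)={res.tau_pos:.4f} (p={res.p_pos:.3f}), "
              f"tau_D(-)={res.tau_neg:.4f} (p={res.p_neg:.3f}); "
              f"~{depth_to_dissimilarity(0.5 * (res.tau_pos + res.tau_neg)):.1f}% "
              "16S dissimilarity")
    frame = pd.DataFrame(rows)
    frame.to_csv(ROOT / "consentrait_per_location.tsv", sep="\t", index=False)
    n_sig = ((frame["p_pos"] <= 0.05) | (frame["p_neg"] <= 0.05)).sum()
    print(f"responses phylogenetically conserved at {n_sig} of {len(frame)} "
          f"locations; planted mean depth was "
          f"{truth['mean_planted_depth']:.4f}")


if __name__ == "__main__":
    main()
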