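#!/usr/bin/env python
"""Directional gene sets, overlap regions and attenuation of dark regulation.

From the regulation calls: builds the directional sets for dark and the two
inhibitors-in-light, counts shared genes (same direction in all sets of a
region), tests dark+DBMIB against the dark control to find genes whose dark
response is attenuated when respiration is blocked, and reports the summary
fractions.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from darkrep import (
    DirectionalGeneSet,
    MulcomParams,
    attenuation_set,
    build_set,
    call_regulated,
    compute_dx,
    directional_overlap,
    mul_opt,
    normalize,
    summary_fractions,
)
from darkrep.containers import DARK, DARK_DBMIB, LIGHT_DBMIB, LIGHT_DCMU
from darkrep.errors import CoarsePermutationWarning
from darkrep.io import ensure_dir, read_signal_matrix
from darkrep.pipeline import DEFAULT_T_GRID, default_m_grid


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/analysis/data"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    warnings.simplefilter("ignore", CoarsePermutationWarning)

    sm = read_signal_matrix(args.data / "signals.tsv", args.data / "samples.tsv")
    norm, _ = normalize(sm)
    dx = compute_dx(norm)
    base = MulcomParams(n_permutations=1000, fdr_threshold=0.003,
                        seed=args.seed)
    params = mul_opt(dx, default_m_grid(dx, [DARK]), list(DEFAULT_T_GRID),
                     base, test_conditions=[DARK])

    sets = {}
    for cond in (DARK, LIGHT_DCMU, LIGHT_DBMIB):
        sets[cond] = build_set(call_regulated(dx, [cond], params), cond)

    overlap = directional_overlap(list(sets.values()))
    out = ensure_dir(args.out)
    rows = [{"sets": "&".join(sorted(r)), "concordant": True, "count": c}
            for r, c in overlap.regions.items()]
    rows += [{"sets": "&".join(sorted(r)), "concordant": False, "count": c}
             for r, c in overlap.discordant.items()]
    pd.DataFrame(rows).sort_values(["sets", "concordant"]).to_csv(
        out / "overlap_regions.tsv", sep="\t", index=False)

    dark_set = sets[DARK]
    shared_any = sum(
        1 for gene, d in dark_set.members.items()
        if any(gene in sets[c] and sets[c].members.loc[gene] == d
               for c in (LIGHT_DCMU, LIGHT_DBMIB)))
    res_att = call_regulated(dx, [DARK_DBMIB], params, control_condition=DARK)
    att = attenuation_set(dark_set, res_att)
    sets["dark-attenuated"] = att

    report = summary_fractions(sets.values(), universe_size=len(norm.genes),
                               reference_label=DARK)
    report["inhibitor_responsive_dark_genes"] = {
        "n": shared_any, "pct_of_dark": 100.0 * shared_any / len(dark_set)}
    (out / "classification.json").write_text(json.dumps(report, indent=2,
                                                        sort_keys=True))

    print(f"dark-regulated: {len(dark_set)} genes "
          f"({100 * len(dark_set) / len(norm.genes):.1f}% of "
          f"{len(norm.genes)} tested)")
    print(f"also responding to DCMU or DBMIB in the light (same direction): "
          f"{shared_any} ({100 * shared_any / len(dark_set):.1f}% of "
          "dark-regulated)")
    print(f"dark response attenuated by DBMIB in the dark: {len(att)} "
          f"({100 * len(att) / len(dark_set):.1f}% of dark-regulated)")
    print(f"shared by all three light-condition sets: "
          f"{overlap.shared(DARK, LIGHT_DCMU, LIGHT_DBMIB)} genes")


if __name__ == "__main__":
    main()
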