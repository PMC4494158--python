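#!/usr/bin/env python
"""Correlation-matrix PCA of condition profiles and inhibitor concordance.

Profiles (experiment-averaged expression per condition/time; one shared
time-0 profile since the stimulus is added at time 0) are compared by
Pearson correlation; the PCA of that matrix summarises how closely the
inhibitor-in-light profiles track the dark response.  Also computes the
induction-ratio scatter correlations between dark and each inhibitor.
"""

import argparse
from pathlib import Path

import pandas as pd

from darkrep import (
    correlation_matrix,
    induction_ratio_correlation,
    normalize,
    pc1_projection,
    pca,
    standard_profile_set,
)
from darkrep.containers import DARK, LIGHT, LIGHT_DBMIB, LIGHT_DCMU
from darkrep.io import ensure_dir, read_signal_matrix


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/analysis/data"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    sm = read_signal_matrix(args.data / "signals.tsv", args.data / "samples.tsv")
    norm, _ = normalize(sm)
    prof = standard_profile_set(norm, conditions=[LIGHT, DARK, LIGHT_DCMU,
                                                  LIGHT_DBMIB])
    corr = correlation_matrix(prof)
    res = pca(corr)
    out = ensure_dir(args.out)

    flat = corr.copy()
    flat.index = [f"{c}@{t}" for c, t in corr.index]
    flat.columns = flat.index
    flat.to_csv(out / "profile_correlations.tsv", sep="\t",
                index_label="profile")
    scores = res.scores.copy()
    scores.index = [f"{c}@{t}" for c, t in res.scores.index]
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="profile")
    pd.DataFrame({"component": scores.columns, "eigenvalue": res.eigenvalues,
                  "variance_fraction": res.variance_ratio}
                 ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)

    print("PC1 %.1f%% / PC2 %.1f%% of profile variance"
          % (100 * res.variance_ratio[0], 100 * res.variance_ratio[1]))
    pc1 = pc1_projection(res)
    print("PC1 scores (light vs dark-like separation):")
    for (cond, t), v in pc1.items():
        print(f"  {cond:>12s} t={t:2d}  {v:+.3f}")
    for cond in (LIGHT_DBMIB, LIGHT_DCMU):
        r = induction_ratio_correlation(norm, DARK, cond, 60)
        print(f"induction-ratio corr(dark, {cond}) at 60 min: {r:.4f}")


if __name__ == "__main__":
    main()
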