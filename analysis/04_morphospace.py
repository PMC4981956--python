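#!/usr/bin/env python
"""Morphospace analyses: (i) OLS regression of standard length on total
vertebral count; (ii) correlation-mode PCA of the eight shape variables;
(iii) convex-hull overlap between extinct and extant groups in the
PC1-PC2 plane. Writes scores, loadings, variance fractions and the
overlap report."""

import argparse
from pathlib import Path

import pandas as pd

from eelmorph import fit_regression, morphospace_overlap, run_pca
from eelmorph import io as emio
from eelmorph.morphospace import DEFAULT_VARIABLES, plot_morphospace


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true", help="also write a scatter PNG")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    records = emio.read_specimen_table(args.fixture / "specimens.csv")
    x = [r.n_vertebrae for r in records]
    y = [r.L_axis1 for r in records]
    reg = fit_regression(x, y)
    print(f"regression: L_axis1 = {reg.intercept:.1f} + {reg.slope:.2f} * n "
          f"(r^2 = {reg.r_squared:.3f}, n = {reg.n})")

    table = pd.DataFrame(
        [{v: getattr(r, v) for v in DEFAULT_VARIABLES} for r in records],
        index=[r.taxon_id for r in records],
    )
    pca = run_pca(table, mode="correlation")
    pd.DataFrame(pca.scores, index=pca.taxa,
                 columns=[f"PC{i+1}" for i in range(len(pca.variables))]
                 ).to_csv(args.out_dir / "pca_scores.csv", float_format="%.4f")
    pd.DataFrame(pca.loadings, index=pca.variables,
                 columns=[f"PC{i+1}" for i in range(len(pca.variables))]
                 ).to_csv(args.out_dir / "pca_loadings.csv", float_format="%.4f")
    pd.DataFrame({"variance_fraction": pca.variance_fraction}
                 ).to_csv(args.out_dir / "pca_variance.csv", float_format="%.4f")
    pc12 = 100 * pca.variance_fraction[:2].sum()
    print(f"PCA: PC1+PC2 explain {pc12:.2f}% of the variance "
          f"({len(pca.taxa)} taxa, {len(pca.variables)} variables)")

    groups = {r.taxon_id: r.status for r in records}
    rep = morphospace_overlap(pca, groups, plane=(0, 1))
    with open(args.out_dir / "overlap_report.txt", "w") as fh:
        fh.write(f"groups: {rep.group_a} vs {rep.group_b} in PC1-PC2\n")
        fh.write("overlap taxa: " + (", ".join(sorted(rep.overlap_taxa)) or "none") + "\n")
    print(f"hull overlap ({rep.group_a} vs {rep.group_b}): "
          f"{len(rep.overlap_taxa)} taxa" +
          (f" ({', '.join(sorted(rep.overlap_taxa))})" if rep.overlap_taxa else ""))

    if args.plot:
        plot_morphospace(pca, groups, args.out_dir / "morphospace.png")
        print(f"scatter written to {args.out_dir / 'morphospace.png'}")


if __name__ == "__main__":
    main()
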