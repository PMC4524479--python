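#!/usr/bin/env python
"""Category comparisons and the conservation correlation.

From the classified site table of 02_classify_polarize.py: Wilcoxon tests
for differences in derived-allele frequency among region and degeneracy
categories, a chi-square test of ancestral nucleotide x derived-count
class, EU-FE divergence per category, and the correlation between
per-amino-acid deleterious proportions (reference gamma fits) and the
BLOSUM62 diagonal conservation score.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from polardfe.compare import (
    blosum_identity_correlation, chi_square_table, wilcoxon_category_test,
)
from polardfe.reference import per_aa_deleterious_proportions

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sites = pd.read_csv(OUT / "site_table.tsv", sep="\t",
                        keep_default_na=False)
    resolved = sites[sites["status"] == "RESOLVED"].copy()
    resolved["freq"] = resolved["derived_count"].astype(int) / 12
    report = {}

    groups = [resolved.loc[resolved["region"] == r, "freq"].to_numpy()
              for r in ("LTR", "INTERGENIC", "CODING")]
    p = wilcoxon_category_test(groups)
    report["wilcoxon_region_p"] = p
    print(f"Wilcoxon LTR/intergenic/coding: P = {p:.3g}")

    deg_groups = [resolved.loc[resolved["degeneracy"] == d, "freq"].to_numpy()
                  for d in ("4", "2", "0")]
    p = wilcoxon_category_test(deg_groups)
    report["wilcoxon_degeneracy_p"] = p
    print(f"Wilcoxon 4-/2-/0-fold: P = {p:.3g}")

    # essential vs nonessential, on per-gene means
    coding = resolved[resolved["gene_id"] != ""]
    gene_means = coding.groupby("gene_id").agg(
        freq=("freq", "mean"), essential=("essential", "first"))
    flags = gene_means["essential"].astype(str)
    ess = gene_means[flags == "1"]["freq"].to_numpy()
    non = gene_means[flags == "0"]["freq"].to_numpy()
    p = wilcoxon_category_test([ess, non])
    report["wilcoxon_essential_p"] = p
    print(f"Wilcoxon essential vs nonessential genes "
          f"(n = {len(ess)} and {len(non)} gene means): P = {p:.3g}")

    # ancestral nucleotide x derived-count class at zero-fold sites
    zf = resolved[resolved["degeneracy"] == "0"]
    table = pd.crosstab(zf["ancestral_nt"],
                        np.minimum(zf["derived_count"].astype(int), 2))
    stat, df, p = chi_square_table(table.to_numpy())
    report["chisq_ancestral_nt"] = {"stat": stat, "df": df, "p": p}
    print(f"chi-square ancestral nt x derived-count class (0-fold): "
          f"X2 = {stat:.1f}, df = {df}, P = {p:.3g}")

    props = per_aa_deleterious_proportions(threshold=1.0)
    r2, p = blosum_identity_correlation(props)
    report["blosum_r2"] = r2
    report["blosum_p"] = p
    print(f"BLOSUM62 conservation correlation (reference per-amino-acid "
          f"gamma fits): r^2 = {r2:.3f}, P = {p:.4f}")

    (OUT / "comparisons.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'comparisons.json'}")


if __name__ == "__main__":
    main()
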