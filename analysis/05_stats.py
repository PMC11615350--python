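#!/usr/bin/env python
"""Statistics on the classified peaks.

Reads the calls table from 02_classify.py and computes: (i) a two-sample
KS test comparing the nearest-TSS distance distributions of WT-enriched vs
KO-enriched peaks, and (ii) per-category exact 2x2 tests with BH
correction comparing the genomic distribution of WT vs KO consensus peaks
(the pipeline already wrote these; this script re-derives the KS result
from the calls table itself).  Writes results under results/stats/.
"""

from pathlib import Path

import pandas as pd

from chipdiff import category_fdr_test, ks_two_sample

RUN = Path("results/run")
OUTDIR = Path("results/stats")


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    calls = pd.read_csv(RUN / "calls.tsv", sep="\t")
    wt_d = calls.loc[calls["label"] == "WT_enriched", "tss_distance"].dropna()
    ko_d = calls.loc[calls["label"] == "KO_enriched", "tss_distance"].dropna()
    ks = ks_two_sample(wt_d, ko_d)
    pd.DataFrame(
        [{"statistic": ks.statistic, "p_value": ks.p_value,
          "n_wt_enriched": ks.n1, "n_ko_enriched": ks.n2}]
    ).to_csv(OUTDIR / "tss_distance_ks.tsv", sep="\t", index=False)
    print(f"KS(WT-enriched vs KO-enriched TSS distances): "
          f"D = {ks.statistic:.3f}, p = {ks.p_value:.3g} "
          f"(n = {ks.n1} vs {ks.n2})")

    counts = (
        calls.groupby("label")["region_category"].value_counts().unstack(fill_value=0)
    )
    if {"WT_enriched", "KO_enriched"}.issubset(counts.index):
        cats = sorted(set(counts.columns))
        a = {c: int(counts.loc["WT_enriched"].get(c, 0)) for c in cats}
        b = {c: int(counts.loc["KO_enriched"].get(c, 0)) for c in cats}
        fdr = category_fdr_test(a, b)
        fdr.to_csv(OUTDIR / "category_fdr.tsv", sep="\t", index=False)
        print("genomic-category comparison (WT- vs KO-enriched peaks):")
        print(fdr.to_string(index=False))
    print(f"results under {OUTDIR}")


if __name__ == "__main__":
    main()
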