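#!/usr/bin/env python
"""Metagene profiles around TSSs, stratified by CGI status.

Reads the synthetic tracks from 01_simulate.py, computes TSS-anchored
+/- 10 kb metagene matrices (50 bp bins) per genotype for CGI-containing
vs CGI-free genes, averages replicate profiles, and writes profile TSVs
plus a figure under results/metagene/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chipdiff import metagene_matrix
from chipdiff.io import read_bedgraph, read_gene_table

SYNTH = "results/synthetic"
OUTDIR = Path("results/metagene")


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    with open(f"{SYNTH}/paths.json") as fh:
        paths = json.load(fh)
    ann = read_gene_table(paths["genes"], paths["cgis"], paths["chrom_sizes"])
    strata = {
        "cgi": [g for g in ann.genes if g.has_cgi],
        "non_cgi": [g for g in ann.genes if not g.has_cgi],
    }
    profiles = {}
    for gt in ("WT", "KO"):
        tracks = [read_bedgraph(p, ann.chrom_sizes) for p in paths["ip_tracks"][gt]]
        for name, genes in strata.items():
            per_rep = [
                metagene_matrix(t, genes, flank_bp=10000, bin_size=50).profile
                for t in tracks
            ]
            profiles[f"{gt}_{name}"] = np.mean(per_rep, axis=0)
    x = np.arange(-10000, 10000, 50)
    df = pd.DataFrame({"offset_bp": x, **profiles})
    df.to_csv(OUTDIR / "profiles.tsv", sep="\t", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for name, prof in profiles.items():
            ax.plot(x, prof, label=name)
        ax.set_xlabel("distance from TSS (bp)")
        ax.set_ylabel("mean coverage")
        ax.legend()
        fig.tight_layout()
        fig.savefig(OUTDIR / "profiles.png", dpi=120)
    except ImportError:
        pass
    for name, prof in profiles.items():
        print(f"{name}: mean profile {prof.mean():.2f}, peak {prof.max():.2f}")
    print(f"profiles under {OUTDIR}")


if __name__ == "__main__":
    main()
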