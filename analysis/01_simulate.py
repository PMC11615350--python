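#!/usr/bin/env python
"""Generate the synthetic ChIP experiment used by the downstream analyses.

Emulates the study design: WT and KO genotypes, triplicate IP samples with
one shared input per genotype, 600 planted binding sites (150 WT-enriched,
150 KO-enriched, 300 unchanged; a quarter of each enriched class
genotype-exclusive) on a 2-chromosome toy genome with 200 genes, 60% of
them CGI-flagged.  Writes narrowPeak/bedGraph/BED files plus the truth
table under results/synthetic/.
"""

import json

from chipdiff import TruthParams, generate_annotation, generate_experiment

SEED = 42
OUTDIR = "results/synthetic"


def main() -> None:
    ann = generate_annotation(n_genes=200, n_chroms=2, cgi_fraction=0.6, seed=SEED)
    exp = generate_experiment(
        ann, TruthParams(), noise_sd=0.2, dropout_rate=0.1, seed=SEED
    )
    paths = exp.write(OUTDIR)
    with open(f"{OUTDIR}/paths.json", "w") as fh:
        json.dump(paths, fh, indent=2)
    n_cgi = sum(g.has_cgi for g in ann.genes)
    print(f"wrote synthetic experiment to {OUTDIR}")
    print(f"  genes: {len(ann.genes)} ({n_cgi} CGI-flagged)")
    print(f"  planted sites: {len(exp.truth)} "
          f"({(exp.truth['label'] == 'WT_enriched').sum()} WT-enriched, "
          f"{(exp.truth['label'] == 'KO_enriched').sum()} KO-enriched, "
          f"{(exp.truth['label'] == 'unchanged').sum()} unchanged)")


if __name__ == "__main__":
    main()
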