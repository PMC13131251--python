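"""Harmonize the per-contrast result tables into a gene x contrast matrix.

Reads the simulated probe-level tables, drops ambiguous annotations,
collapses probes to gene-level effects with Wald-recovered standard
errors, aligns by gene symbol, and applies the coverage filter
(>= 13 of 18 contrasts). Writes the wide effect/variance matrices under
results/harmonized/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sdmeta import harmonize


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/sim_data")
    ap.add_argument("--out", default="results/harmonized")
    args = ap.parse_args()
    inputs, out = Path(args.inputs), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    meta = pd.read_csv(inputs / "contrast_metadata.tsv", sep="\t")
    records = [harmonize.ContrastRecord.from_row(r) for _, r in meta.iterrows()]
    gene_effects = {}
    for rec in records:
        tab = harmonize.read_contrast_table(
            inputs / f"contrast_{rec.contrast_id}.tsv", rec
        )
        gene_effects[rec.contrast_id] = harmonize.collapse_to_gene(tab)
        print(f"  {rec.label}: {len(tab)} probe rows -> "
              f"{len(gene_effects[rec.contrast_id])} genes")

    matrix = harmonize.align_and_filter(gene_effects, records)
    harmonize.write_matrix(matrix, out / "effects.tsv", out / "variances.tsv")
    total = len(set().union(*(set(t["gene"]) for t in gene_effects.values())))
    print(f"aligned {total} symbols; {len(matrix.genes)} genes pass the "
          f">= {harmonize.default_min_contrasts(len(records))}-of-{len(records)} "
          f"coverage filter (median coverage "
          f"{int(matrix.coverage.median())})")


if __name__ == "__main__":
    main()
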