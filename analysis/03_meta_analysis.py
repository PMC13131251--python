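"""Per-gene random-effects meta-analysis, plain and moderator-adjusted.

Fits the intercept-only REML random-effects model per gene (the pooled
SD effect) and the exploratory meta-regression with centered SD duration
plus a recovery-sleep factor, applies BH FDR over stable fits, and
exports forest-plot data for the top gene. Writes tables under
results/meta/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sdmeta import harmonize, metacore, pipeline


def load_matrix(harmonized: Path, inputs: Path) -> harmonize.GeneEffectMatrix:
    meta = pd.read_csv(inputs / "contrast_metadata.tsv", sep="\t")
    records = [harmonize.ContrastRecord.from_row(r) for _, r in meta.iterrows()]
    effects = pd.read_csv(harmonized / "effects.tsv", sep="\t", index_col=0)
    effects = effects.drop(columns=["coverage"])
    variances = pd.read_csv(harmonized / "variances.tsv", sep="\t", index_col=0)
    return harmonize.GeneEffectMatrix(records, effects, variances)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", default="results/sim_data")
    ap.add_argument("--harmonized", default="results/harmonized")
    ap.add_argument("--out", default="results/meta")
    ap.add_argument("--q", type=float, default=0.05)
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    matrix = load_matrix(Path(args.harmonized), Path(args.inputs))
    for model in ("intercept", "moderated"):
        res = metacore.run_meta(matrix, model=model, q=args.q)
        res.table.to_csv(out / f"meta_{model}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        print(f"{model} model: {res.n_total} genes, {res.n_stable} stable, "
              f"{res.n_significant} DEGs at FDR < {args.q}")
        if model == "intercept":
            top = res.table.dropna(subset=["pval"]).sort_values("pval").iloc[0]
            forest = pipeline.export_forest(top["gene"], matrix, res)
            forest.to_csv(out / "forest_top_gene.tsv", sep="\t", index=False,
                          float_format="%.6g")
            print(f"top gene {top['gene']}: pooled log2FC "
                  f"{top['log2fc']:+.3f} [{top['ci_lb']:+.3f}, "
                  f"{top['ci_ub']:+.3f}], FDR {top['fdr']:.2e} "
                  f"(forest data exported)")


if __name__ == "__main__":
    main()
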