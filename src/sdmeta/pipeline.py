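"""Pipeline orchestration, report exports, and the power utility.

Composes harmonize -> metacore (intercept-only and moderated) ->
enrichment (directional and absolute rankings) -> RNA-seq validation
behind a single configuration, writing stage outputs plus a manifest
(input checksums, seeds, summary counts) under an output directory.
Also provides forest-plot data export, heatmap-linkage export, the
moderated-vs-plain dilution comparison, and a two-sample t-test power
check.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from . import __version__, enrich, harmonize, metacore, rnaseq_validate
from .harmonize import GeneEffectMatrix
from .metacore import CI_Z, MetaResultsTable

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "export_forest",
    "dilution_slope",
    "power_check",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run.

    ``contrast_tables`` maps contrast_id -> TSV path; the remaining
    paths point to the contrast metadata, GMT gene sets, counts and
    sample tables as written by the synthetic-data module (or any files
    of the same schema).
    """

    contrast_tables: dict[str, str]
    metadata_path: str
    gmt_path: str
    counts_path: str
    samples_path: str
    out_dir: str
    min_contrasts: int | None = None
    q: float = 0.05
    gsea_nperm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    seed: int = 0
    probe_corr: str = "independent"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        paths = [
            *self.contrast_tables.values(),
            self.metadata_path,
            self.gmt_path,
            self.counts_path,
            self.samples_path,
        ]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stage outputs (TSV) and ``manifest.json`` land in ``config.out_dir``.
    A stage failure raises :class:`StageError` naming the stage; outputs
    of earlier stages persist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_df = pd.read_csv(config.metadata_path, sep="\t")

    matrix = _stage("harmonize")(_harmonize)(config, meta_df)
    harmonize.write_matrix(matrix, out / "effects.tsv", out / "variances.tsv")

    fits = {}
    for model in ("intercept", "moderated"):
        res = _stage(f"metacore:{model}")(metacore.run_meta)(
            matrix, model=model, q=config.q
        )
        fits[model] = res
        res.table.to_csv(out / f"meta_{model}.tsv", sep="\t", index=False, float_format="%.6g")

    gsea = {}
    collection = _stage("enrich")(enrich.read_gmt)(
        config.gmt_path, min_size=config.gsea_min_size, max_size=config.gsea_max_size
    )
    scores = fits["intercept"].table.set_index("gene")["log2fc"].dropna()
    for mode in ("directional", "absolute"):
        ranked = enrich.ranked_list(scores, mode=mode)
        res = _stage(f"enrich:{mode}")(enrich.gsea_pvalues)(
            ranked, collection, nperm=config.gsea_nperm, seed=config.seed
        )
        gsea[mode] = res
        res.to_csv(out / f"gsea_{mode}.tsv", sep="\t", index=False, float_format="%.6g")

    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(config.samples_path, sep="\t")
    de = _stage("rnaseq_validate")(rnaseq_validate.run_validation_de)(counts, samples)
    de.to_csv(out / "validation_de.tsv", sep="\t", index=False, float_format="%.6g")
    summary = _stage("congruence")(rnaseq_validate.congruence)(
        fits["intercept"].table, de, q=config.q
    )
    summary.as_frame().to_csv(out / "validation_summary.tsv", sep="\t", index=False)

    slope = _stage("dilution")(dilution_slope)(
        fits["intercept"], fits["moderated"], q=config.q
    )
    _export_heatmap(fits["intercept"], matrix, out / "heatmap_top_degs.tsv", q=config.q)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "q": config.q,
        "inputs": {
            str(p): _sha256(p)
            for p in sorted(
                {
                    *config.contrast_tables.values(),
                    config.metadata_path,
                    config.gmt_path,
                    config.counts_path,
                    config.samples_path,
                }
            )
        },
        "counts": {
            "n_contrasts": len(matrix.contrasts),
            "n_genes_analysed": fits["intercept"].n_total,
            "n_stable": fits["intercept"].n_stable,
            "n_degs": fits["intercept"].n_significant,
            "n_degs_moderated": fits["moderated"].n_significant,
            "n_gene_sets": {m: len(t) for m, t in gsea.items()},
            "n_enriched": {
                m: int((t["fdr"] < config.q).sum()) for m, t in gsea.items()
            },
        },
        "congruence": summary.__dict__,
        "dilution_slope": slope,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _harmonize(config: PipelineConfig, meta_df: pd.DataFrame) -> GeneEffectMatrix:
    records = [harmonize.ContrastRecord.from_row(r) for _, r in meta_df.iterrows()]
    gene_effects = {}
    for rec in records:
        tab = harmonize.read_contrast_table(
            config.contrast_tables[rec.contrast_id], rec
        )
        gene_effects[rec.contrast_id] = harmonize.collapse_to_gene(
            tab, probe_corr=config.probe_corr
        )
    return harmonize.align_and_filter(
        gene_effects, records, min_contrasts=config.min_contrasts
    )


def export_forest(
    gene: str, matrix: GeneEffectMatrix, meta: MetaResultsTable
) -> pd.DataFrame:
    """Forest-plot data for one gene: one row per contributing contrast
    (label, log2FC, 95% Wald CI) plus the pooled "RE Model" row."""
    table = meta.table.set_index("gene")
    if gene not in table.index or gene not in matrix.effects.index:
        universe = sorted(set(table.index) & set(matrix.effects.index))
        near = difflib.get_close_matches(gene, universe, n=3)
        raise KeyError(f"unknown gene {gene!r}; nearest symbols: {near}")
    y, v, mask = matrix.gene_arrays(gene)
    labels = [c.label for c, m in zip(matrix.contrasts, mask) if m]
    half = CI_Z * np.sqrt(v)
    rows = pd.DataFrame(
        {
            "label": labels,
            "log2fc": y,
            "ci_lb": y - half,
            "ci_ub": y + half,
            "kind": "contrast",
        }
    )
    fit = table.loc[gene]
    pooled = pd.DataFrame(
        {
            "label": ["RE Model"],
            "log2fc": [fit["log2fc"]],
            "ci_lb": [fit["ci_lb"]],
            "ci_ub": [fit["ci_ub"]],
            "kind": "pooled",
        }
    )
    return pd.concat([rows, pooled], ignore_index=True)


def dilution_slope(
    intercept_fit: MetaResultsTable, moderated_fit: MetaResultsTable, q: float = 0.05
) -> float:
    """Slope of moderated-model SD effects on plain-model effects over
    the plain-model DEGs.

    A slope above 1 indicates that contrasts with recovery sleep diluted
    the intercept-only estimates relative to the moderator-adjusted SD
    effects.
    """
    plain = intercept_fit.table.set_index("gene")
    mod = moderated_fit.table.set_index("gene")
    degs = plain.index[(plain["fdr"] < q).fillna(False)]
    degs = [g for g in degs if g in mod.index and np.isfinite(mod.loc[g, "log2fc"])]
    if len(degs) < 3:
        raise ValueError("too few DEGs for the dilution comparison")
    x = plain.loc[degs, "log2fc"].to_numpy(float)
    y = mod.loc[degs, "log2fc"].to_numpy(float)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    return float(ols.params[1])


def _export_heatmap(
    fit: MetaResultsTable, matrix: GeneEffectMatrix, path, q: float, top: int = 50
) -> None:
    """Log2FC rows for the top DEGs in complete-linkage leaf order
    (Euclidean distance); inspection export, not a tested surface."""
    tab = fit.table.dropna(subset=["pval"]).sort_values("pval")
    genes = [g for g in tab["gene"].head(top) if g in matrix.effects.index]
    if len(genes) < 2:
        return
    block = matrix.effects.loc[genes].fillna(0.0)
    order = leaves_list(linkage(block.to_numpy(), method="complete"))
    block.iloc[order].to_csv(path, sep="\t", float_format="%.6g")


def power_check(n_total: int, d: float = 0.5, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test at standardized effect d.

    The total sample splits into groups of floor(n/2) and ceil(n/2);
    power comes from the noncentral t distribution.
    """
    if n_total < 4:
        raise ValueError("n_total must be at least 4")
    if d <= 0:
        raise ValueError("effect size d must be positive")
    n1 = n_total // 2
    n2 = n_total - n1
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
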