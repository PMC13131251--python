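"""Synthetic multi-study contrast tables with known ground truth.

The generator emulates the statistical structure a gene-wise
random-effects meta-analysis of sleep-deprivation (SD) experiments
assumes: per-gene true effects (mostly null, small non-null log2FC),
per-gene between-contrast heterogeneity tau^2, contrast-level sampling
variance scaling with 1/n, a recovery-sleep (RS) moderator that undoes a
configurable fraction of the SD effect, gene missingness across
contrasts, and multi-probe genes. A companion generator produces a
negative-binomial count matrix with a two-group log2 mean shift for the
validation stage.

The default design mirrors the meta-analytic study conditions: 18
SD-vs-control contrasts from 8 studies, SD durations 3-12 h, recovery
sleep on 6 contrasts (1-18 h), and per-contrast animal counts summing to
293.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "DEFAULT_DESIGN",
    "simulate_contrast_tables",
    "simulate_validation_counts",
    "simulate_gene_sets",
    "write_gmt",
    "write_inputs",
]

#: (dataset_id, sd_hours, rs_hours, n) for the 18 default contrasts.
#: Synthetic stand-ins for the real study designs; n sums to 293 and six
#: contrasts include recovery sleep.
DEFAULT_DESIGN: tuple[tuple[str, float, float, int], ...] = (
    ("DS01", 6, 0, 15),
    ("DS01", 9, 0, 15),
    ("DS01", 12, 0, 15),
    ("DS02", 6, 0, 4),
    ("DS02", 6, 18, 5),
    ("DS03", 6, 1, 16),
    ("DS03", 6, 2, 16),
    ("DS03", 5, 3, 16),
    ("DS03", 5, 6, 17),
    ("DS04", 12, 0, 9),
    ("DS05", 5, 0, 20),
    ("DS06", 3, 0, 27),
    ("DS06", 6, 0, 27),
    ("DS06", 9, 0, 27),
    ("DS06", 12, 0, 27),
    ("DS07", 4, 0, 4),
    ("DS08", 6, 0, 16),
    ("DS08", 4, 2, 17),
)

#: Reference group size at which the contrast sampling variance equals
#: ``base_sv``; variances scale as base_sv * (N_REF / n).
N_REF = 10


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Study-design and generative parameters for the contrast simulator.

    Parameters
    ----------
    n_genes
        Number of genes in the simulated universe.
    prop_de
        Fraction of genes with a non-null true SD effect. Assignment is
        stratified: exactly ``round(prop_de * n_genes)`` genes are DE.
    effect_sd
        Standard deviation (log2FC units) of non-null true effects.
    tau2_range
        Per-gene between-contrast heterogeneity variance is drawn
        uniformly from this closed interval.
    base_sv
        Contrast-level sampling variance at the reference group size
        (``N_REF`` animals); scales as 1/n.
    rs_reversal
        Fraction of the SD effect undone in recovery-sleep contrasts
        (1 = full reversal). The RS moderator is generated as a binary
        factor; RS hours are recorded in the metadata but do not enter
        the generative model.
    missing_rate
        Per-(gene, contrast) probability that the gene is absent from
        that contrast's result table.
    probes_per_gene
        Mapping probe-count -> probability. Probe multiplicity is drawn
        once per (gene, dataset), emulating platform-specific probe
        sets; probes carry independent noise around the same
        contrast-level effect.
    design
        Sequence of (dataset_id, sd_hours, rs_hours, n) contrast
        descriptors; defaults to the 18-contrast, 8-study design.
    seed
        Seed for all randomness; a fixed seed gives byte-identical
        outputs.
    """

    n_genes: int = 4000
    prop_de: float = 0.1
    effect_sd: float = 0.3
    tau2_range: tuple[float, float] = (0.0, 0.05)
    base_sv: float = 0.04
    rs_reversal: float = 1.0
    missing_rate: float = 0.1
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    design: tuple[tuple[str, float, float, int], ...] = DEFAULT_DESIGN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if len(self.design) == 0:
            raise ConfigurationError("at least one contrast is required")
        for frac, name in [
            (self.prop_de, "prop_de"),
            (self.missing_rate, "missing_rate"),
            (self.rs_reversal, "rs_reversal"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {frac}")
        if self.base_sv < 0:
            raise ConfigurationError("base_sv must be non-negative")
        lo, hi = self.tau2_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("tau2_range must satisfy 0 <= lo <= hi")
        if not self.probes_per_gene or any(
            k < 1 or p < 0 for k, p in self.probes_per_gene.items()
        ):
            raise ConfigurationError("probes_per_gene must map counts>=1 to p>=0")
        for _, sd_h, rs_h, n in self.design:
            if sd_h <= 0 or rs_h < 0 or n < 2:
                raise ConfigurationError(
                    "each contrast needs sd_hours>0, rs_hours>=0, n>=2"
                )

    @property
    def contrast_metadata(self) -> pd.DataFrame:
        """Contrast metadata table (dataset_id, contrast_id, sd_hours, rs_hours, n)."""
        rows = []
        per_ds: dict[str, int] = {}
        for ds, sd_h, rs_h, n in self.design:
            per_ds[ds] = per_ds.get(ds, 0) + 1
            rows.append(
                {
                    "dataset_id": ds,
                    "contrast_id": f"{ds}_c{per_ds[ds]}",
                    "sd_hours": float(sd_h),
                    "rs_hours": float(rs_h),
                    "n": int(n),
                }
            )
        return pd.DataFrame(rows)


def _gene_symbols(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"Gene{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_gene_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene generative parameters.

    Exactly ``round(prop_de * n_genes)`` genes are assigned non-null
    effects (stratified assignment, so counts are exact rather than
    binomial). For a DE gene the recovery-sleep coefficient is
    ``-rs_reversal * mu_true``: in an RS contrast the expected effect is
    ``mu_true * (1 - rs_reversal)``.
    """
    genes = _gene_symbols(config.n_genes)
    n_de = int(round(config.prop_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    is_de = np.zeros(config.n_genes, dtype=bool)
    is_de[de_idx] = True

    mu = np.zeros(config.n_genes)
    mu[is_de] = rng.normal(0.0, config.effect_sd, size=n_de)
    tau2 = rng.uniform(config.tau2_range[0], config.tau2_range[1], size=config.n_genes)
    rs_effect = np.where(is_de, -config.rs_reversal * mu, 0.0)

    return pd.DataFrame(
        {
            "gene": genes,
            "mu_true": mu,
            "tau2_true": tau2,
            "rs_effect_true": rs_effect,
            "is_de": is_de,
        }
    )


def simulate_contrast_tables(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-contrast differential-expression result tables.

    For gene g in contrast c the contrast-level effect is

        m_gc = mu_g + rs_effect_g * [rs_c > 0] + u_gc,   u_gc ~ N(0, tau2_g)

    and each probe reports an independent draw y ~ N(m_gc, v_c) with
    sampling variance v_c = base_sv * (N_REF / n_c), t = y / sqrt(v_c)
    and a two-sided normal p-value. Genes are dropped per contrast with
    probability ``missing_rate``.

    Returns
    -------
    (truth, tables, metadata)
        ``truth`` is the per-gene ground-truth table, ``tables`` maps
        contrast_id -> probe-level result table (columns element_id,
        gene_symbol, log2fc, tstat, pvalue), ``metadata`` is the
        contrast-metadata table.
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_gene_truth(config, rng)
    meta = config.contrast_metadata

    genes = truth["gene"].to_numpy()
    mu = truth["mu_true"].to_numpy()
    tau = np.sqrt(truth["tau2_true"].to_numpy())
    rs_eff = truth["rs_effect_true"].to_numpy()
    G, C = config.n_genes, len(meta)

    # probe multiplicity per (gene, dataset): platforms share probes
    # across their contrasts
    datasets = meta["dataset_id"].unique()
    probe_counts = np.array(sorted(config.probes_per_gene))
    probe_probs = np.array([config.probes_per_gene[k] for k in probe_counts], float)
    probe_probs = probe_probs / probe_probs.sum()
    probes = {
        ds: rng.choice(probe_counts, size=G, p=probe_probs) for ds in datasets
    }

    present = rng.random((G, C)) >= config.missing_rate
    u = rng.normal(0.0, 1.0, size=(G, C)) * tau[:, None]

    tables: dict[str, pd.DataFrame] = {}
    for c, row in meta.iterrows():
        v_c = config.base_sv * (N_REF / row["n"])
        rs_ind = 1.0 if row["rs_hours"] > 0 else 0.0
        m = mu + rs_eff * rs_ind + u[:, c]
        keep = present[:, c]
        n_probes = probes[row["dataset_id"]]
        idx = np.repeat(np.arange(G)[keep], n_probes[keep])
        probe_no = np.concatenate([np.arange(1, k + 1) for k in n_probes[keep]])
        noise = rng.normal(0.0, np.sqrt(v_c), size=idx.size) if v_c > 0 else 0.0
        y = m[idx] + noise
        with np.errstate(divide="ignore", invalid="ignore"):
            if v_c > 0:
                t = y / np.sqrt(v_c)
            else:
                t = np.where(y == 0, 0.0, np.sign(y) * np.inf)
        p = 2.0 * stats.norm.sf(np.abs(t))
        tables[row["contrast_id"]] = pd.DataFrame(
            {
                "element_id": [
                    f"{row['dataset_id']}_{genes[i]}_p{j}"
                    for i, j in zip(idx, probe_no)
                ],
                "gene_symbol": genes[idx],
                "log2fc": y,
                "tstat": np.broadcast_to(t, y.shape),
                "pvalue": p,
            }
        )
    return truth, tables, meta


def simulate_validation_counts(
    truth: pd.DataFrame,
    n_samples_per_group: int,
    seed: int,
    dispersion: float = 0.05,
    mean_log_expression: float = np.log(100.0),
    sd_log_expression: float = 1.2,
    lib_size_range: tuple[float, float] = (0.5, 2.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group RNA-seq count matrix for the validation stage.

    Counts are gamma-Poisson (negative binomial) with per-gene baseline
    means drawn log-normally; SD samples carry a 2**mu_true mean shift.
    Per-sample library-size factors are drawn log-uniformly over
    ``lib_size_range`` so TMM normalisation is exercised.

    Returns (counts, samples): counts is genes x samples, samples has
    columns sample_id and condition in {CTRL, SD}.
    """
    if n_samples_per_group < 2:
        raise ConfigurationError("n_samples_per_group must be >= 2")
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = truth["gene"].to_numpy()
    mu_true = truth["mu_true"].to_numpy()
    G = len(genes)
    n = 2 * n_samples_per_group

    base = rng.lognormal(mean_log_expression, sd_log_expression, size=G)
    condition = np.array(["CTRL"] * n_samples_per_group + ["SD"] * n_samples_per_group)
    shift = np.where(condition == "SD", 1.0, 0.0)
    lo, hi = lib_size_range
    libf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    mean = base[:, None] * 2.0 ** (mu_true[:, None] * shift[None, :]) * libf[None, :]
    # gamma-Poisson mixture: var = mean + dispersion * mean^2
    lam = mean * rng.gamma(1.0 / dispersion, dispersion, size=(G, n))
    counts = rng.poisson(lam)

    samples = pd.DataFrame(
        {"sample_id": [f"S{i:03d}" for i in range(1, n + 1)], "condition": condition}
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=samples["sample_id"])
    counts_df.index.name = "gene"
    return counts_df, samples


def write_inputs(
    out_dir,
    config: SimConfig,
    n_validation_per_group: int = 20,
    n_random_sets: int = 30,
    n_signal_sets: int = 10,
) -> dict:
    """Simulate one full study and write every pipeline input to disk.

    Writes per-contrast TSVs, the contrast metadata, a GMT file (random
    plus truth-enriched sets), the validation count and sample tables,
    and the ground-truth table. Returns a dict of paths keyed like
    :class:`sdmeta.pipeline.PipelineConfig` fields (plus ``truth_path``).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, tables, meta = simulate_contrast_tables(config)

    contrast_paths = {}
    for cid, tab in tables.items():
        path = out / f"contrast_{cid}.tsv"
        tab.to_csv(path, sep="\t", index=False, float_format="%.8g")
        contrast_paths[cid] = str(path)
    meta.to_csv(out / "contrast_metadata.tsv", sep="\t", index=False)
    truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False, float_format="%.8g")

    sets = simulate_gene_sets(
        truth, n_random=n_random_sets, n_signal=n_signal_sets, seed=config.seed + 1
    )
    write_gmt(sets, out / "gene_sets.gmt")

    counts, samples = simulate_validation_counts(
        truth, n_validation_per_group, seed=config.seed + 2
    )
    counts.to_csv(out / "validation_counts.tsv", sep="\t")
    samples.to_csv(out / "validation_samples.tsv", sep="\t", index=False)

    return {
        "contrast_tables": contrast_paths,
        "metadata_path": str(out / "contrast_metadata.tsv"),
        "gmt_path": str(out / "gene_sets.gmt"),
        "counts_path": str(out / "validation_counts.tsv"),
        "samples_path": str(out / "validation_samples.tsv"),
        "truth_path": str(out / "gene_truth.tsv"),
    }


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_random: int = 30,
    n_signal: int = 10,
    size_range: tuple[int, int] = (15, 60),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene sets for enrichment fixtures: random sets plus sets enriched
    in up- or down-regulated true DE genes (half each)."""
    rng = np.random.default_rng(seed)
    genes = truth["gene"].to_numpy()
    up = truth.loc[truth["is_de"] & (truth["mu_true"] > 0), "gene"].to_numpy()
    down = truth.loc[truth["is_de"] & (truth["mu_true"] < 0), "gene"].to_numpy()
    sets: dict[str, list[str]] = {}
    for i in range(n_random):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"RANDOM_{i + 1:02d}"] = list(rng.choice(genes, size=size, replace=False))
    for i in range(n_signal):
        pool, tag = (up, "UP") if i % 2 == 0 else (down, "DOWN")
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        n_sig = min(len(pool), max(3, int(0.6 * size)))
        members = list(rng.choice(pool, size=n_sig, replace=False)) + list(
            rng.choice(genes, size=size - n_sig, replace=False)
        )
        sets[f"SIGNAL_{tag}_{i + 1:02d}"] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets, path, descriptions=None) -> None:
    """Write gene sets in GMT format (name, description, tab-separated members).

    ``sets`` is a mapping name -> member list or an iterable of
    (name, members) pairs. Duplicate set names or empty sets are
    rejected.
    """
    if isinstance(sets, dict):
        items = list(sets.items())
    else:
        items = [(name, members) for name, members in sets]
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene-set names: {dupes}")
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in items:
            members = list(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
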