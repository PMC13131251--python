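"""Gene-level harmonization of per-contrast differential-expression tables.

Probe-level result tables (element id, gene symbol, log2FC, t, p) are
cleaned of rows without unambiguous gene annotation, collapsed to
gene-level average effect sizes with standard errors recovered from the
reported t-statistics (Wald identity se = |log2FC / t|), and aligned
across contrasts by exact gene symbol into a gene x contrast
effect/variance matrix. Genes observed in too few contrasts are removed
by a coverage filter (default: at least ceil(0.722 * C) contrasts, i.e.
13 of 18).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContrastRecord",
    "GeneEffectMatrix",
    "FormatError",
    "read_contrast_table",
    "collapse_to_gene",
    "align_and_filter",
    "default_min_contrasts",
]

REQUIRED_COLUMNS = ("element_id", "gene_symbol", "log2fc", "tstat", "pvalue")

#: delimiters that mark a multi-gene (ambiguous) annotation
AMBIGUOUS_DELIMITERS = ("|", ",")

#: probes with |t| below this contribute no usable standard error
T_TOLERANCE = 1e-8


class FormatError(ValueError):
    """Raised when an input table violates the expected schema."""


@dataclass(frozen=True)
class ContrastRecord:
    """One SD-vs-control comparison and its moderators."""

    dataset_id: str
    contrast_id: str
    sd_hours: float
    rs_hours: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_hours <= 0:
            raise ValueError("sd_hours must be positive")
        if self.rs_hours < 0:
            raise ValueError("rs_hours must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @property
    def label(self) -> str:
        """Display label, e.g. ``DS03 6h +2hRS``."""
        lab = f"{self.dataset_id} {self.sd_hours:g}h"
        if self.rs_hours > 0:
            lab += f" +{self.rs_hours:g}hRS"
        return lab

    @classmethod
    def from_row(cls, row) -> "ContrastRecord":
        return cls(
            dataset_id=str(row["dataset_id"]),
            contrast_id=str(row["contrast_id"]),
            sd_hours=float(row["sd_hours"]),
            rs_hours=float(row["rs_hours"]),
            n=int(row["n"]),
        )


@dataclass
class GeneEffectMatrix:
    """Aligned genes x contrasts effects and sampling variances.

    ``effects`` and ``variances`` are DataFrames indexed by gene symbol
    with one column per contrast_id; absent cells are NaN and share an
    identical pattern. ``coverage`` counts present contrasts per gene.
    """

    contrasts: list[ContrastRecord]
    effects: pd.DataFrame
    variances: pd.DataFrame
    coverage: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if not self.effects.columns.equals(self.variances.columns):
            raise ValueError("effects/variances column mismatch")
        if not self.effects.index.equals(self.variances.index):
            raise ValueError("effects/variances index mismatch")
        if not (self.effects.isna() == self.variances.isna()).all().all():
            raise ValueError("effects and variances must share absence pattern")
        self.coverage = self.effects.notna().sum(axis=1)

    @property
    def genes(self) -> list[str]:
        return list(self.effects.index)

    def gene_arrays(self, gene: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(y, v, present-mask) over contrast order for one gene."""
        y = self.effects.loc[gene].to_numpy(float)
        v = self.variances.loc[gene].to_numpy(float)
        mask = ~np.isnan(y)
        return y[mask], v[mask], mask


def default_min_contrasts(n_contrasts: int) -> int:
    """Coverage threshold: ceil(0.722 * C); 13 when C = 18."""
    return math.ceil(0.722 * n_contrasts)


def _is_ambiguous(symbol: str) -> bool:
    return any(d in symbol for d in AMBIGUOUS_DELIMITERS)


def read_contrast_table(path, contrast: ContrastRecord | None = None) -> pd.DataFrame:
    """Read one probe-level result table, excluding rows that lack an
    unambiguous gene symbol.

    Dropped rows: empty/missing symbols, symbols containing a multi-gene
    delimiter (``|`` or ``,``), and element ids annotated with more than
    one distinct symbol. Non-numeric log2fc/tstat rows are dropped with
    a warning reporting the count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"element_id": str, "gene_symbol": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    sym = df["gene_symbol"].fillna("").str.strip()
    keep = (sym != "") & ~sym.map(_is_ambiguous)
    df = df.loc[keep].assign(gene_symbol=sym[keep])

    # element ids mapped to more than one distinct symbol are ambiguous
    n_sym = df.groupby("element_id")["gene_symbol"].transform("nunique")
    df = df.loc[n_sym == 1]

    for col in ("log2fc", "tstat", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["log2fc"].isna() | df["tstat"].isna()
    if bad.any():
        warnings.warn(
            f"{path}: dropped {int(bad.sum())} row(s) with non-numeric "
            "log2fc/tstat",
            stacklevel=2,
        )
        df = df.loc[~bad]
    return df.reset_index(drop=True)


def collapse_to_gene(probe_rows: pd.DataFrame, probe_corr: str = "independent") -> pd.DataFrame:
    """Collapse probe-level rows to gene-level effects.

    Per gene with P probes: log2fc is the arithmetic mean of probe
    log2FCs; each probe's standard error is recovered as |log2fc / t|;
    the gene sampling variance pools the probe variances either as the
    variance of a mean of independent measurements, (sum se_p^2) / P^2,
    or, with ``probe_corr="perfect"``, as their plain mean. Probes with
    |t| below tolerance contribute to the mean effect but are excluded
    from variance pooling; a gene whose probes all lack a usable t is
    dropped with a warning.
    """
    if probe_corr not in ("independent", "perfect"):
        raise ValueError(f"unknown probe_corr: {probe_corr!r}")
    rows = []
    dropped = []
    for gene, grp in probe_rows.groupby("gene_symbol", sort=True):
        l2fc = grp["log2fc"].to_numpy(float)
        t = grp["tstat"].to_numpy(float)
        usable = np.abs(t) > T_TOLERANCE
        if not usable.any():
            dropped.append(gene)
            continue
        se_p = np.abs(l2fc[usable] / t[usable])
        p_use = usable.sum()
        if probe_corr == "independent":
            sv = float(np.sum(se_p**2) / p_use**2)
        else:
            sv = float(np.mean(se_p**2))
        rows.append(
            {
                "gene": gene,
                "log2fc": float(np.mean(l2fc)),
                "se": math.sqrt(sv),
                "sv": sv,
                "n_probes": int(len(grp)),
            }
        )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} gene(s) with no probe of usable "
            f"t-statistic (e.g. {dropped[:3]})",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["gene", "log2fc", "se", "sv", "n_probes"])


def align_and_filter(
    gene_effects: dict[str, pd.DataFrame],
    contrasts: list[ContrastRecord] | pd.DataFrame,
    min_contrasts: int | None = None,
) -> GeneEffectMatrix:
    """Align gene-level effects across contrasts and apply the coverage filter.

    Symbols are matched case-sensitively and exactly; the contrast order
    of the metadata is preserved. Genes present in fewer than
    ``min_contrasts`` contrasts (default ceil(0.722 * C)) are removed.
    """
    if isinstance(contrasts, pd.DataFrame):
        contrasts = [ContrastRecord.from_row(r) for _, r in contrasts.iterrows()]
    if len(contrasts) == 0:
        raise ValueError("at least one contrast is required")
    if min_contrasts is None:
        min_contrasts = default_min_contrasts(len(contrasts))
    if min_contrasts < 2:
        raise ValueError("min_contrasts must be at least 2")

    eff_cols, var_cols = {}, {}
    for rec in contrasts:
        if rec.contrast_id not in gene_effects:
            raise KeyError(f"no gene-effect table for contrast {rec.contrast_id}")
        tab = gene_effects[rec.contrast_id]
        if tab["gene"].duplicated().any():
            dup = tab.loc[tab["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(
                f"duplicate (gene, contrast) pair after collapse: "
                f"{dup!r} in {rec.contrast_id} — collapse failed upstream"
            )
        eff_cols[rec.contrast_id] = tab.set_index("gene")["log2fc"]
        var_cols[rec.contrast_id] = tab.set_index("gene")["sv"]

    effects = pd.DataFrame(eff_cols)[[c.contrast_id for c in contrasts]]
    variances = pd.DataFrame(var_cols)[[c.contrast_id for c in contrasts]]
    coverage = effects.notna().sum(axis=1)
    keep = coverage >= min_contrasts
    return GeneEffectMatrix(
        contrasts=list(contrasts),
        effects=effects.loc[keep],
        variances=variances.loc[keep],
    )


def write_matrix(matrix: GeneEffectMatrix, effects_path, variances_path) -> None:
    """Write the wide effect/variance matrices as TSV (6 significant digits)."""
    out = matrix.effects.copy()
    out["coverage"] = matrix.coverage
    out.to_csv(effects_path, sep="\t", float_format="%.6g")
    matrix.variances.to_csv(variances_path, sep="\t", float_format="%.6g")
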