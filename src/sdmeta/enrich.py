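"""Preranked gene-set enrichment on pooled effect sizes.

Genes are ranked by the meta-analytic log2FC (directional mode) or its
absolute value (non-directional mode). For each gene set the classic
weighted Kolmogorov-Smirnov running sum is walked down the ranking: hits
increment by |r|^p / sum_{set} |r|^p, misses by 1/(N - |S|); the
enrichment score (ES) is the signed maximal deviation and the leading
edge contains the set members at or before (after, for negative ES) the
extremum. Significance comes from gene permutations: random same-size
sets drawn from the ranked universe, with a side-matched permutation
p-value and Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metacore import bh_adjust

__all__ = [
    "GeneSetCollection",
    "RankedList",
    "read_gmt",
    "ranked_list",
    "enrichment_score",
    "gsea_pvalues",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with per-set descriptions; members deduplicated."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            name: list(dict.fromkeys(members)) for name, members in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RankedList:
    """Genes in descending statistic order with a deterministic tie-break.

    Ties are broken by descending |statistic| then ascending gene
    symbol. ``genes`` and ``stats`` are aligned arrays in rank order.
    """

    genes: np.ndarray
    stats: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        self.index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)


def ranked_list(scores, mode: str = "directional") -> RankedList:
    """Build a ranked list from gene -> log2FC scores.

    ``mode="directional"`` ranks by signed log2FC; ``mode="absolute"``
    by |log2FC| (non-directional enrichment).
    """
    if mode not in ("directional", "absolute"):
        raise ValueError(f"unknown mode: {mode!r}")
    s = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores)
    s = s.astype(float)
    s.index = s.index.astype(str).rename(None)
    if mode == "absolute":
        s = s.abs()
    df = pd.DataFrame({"stat": s, "absstat": s.abs(), "gene": s.index})
    df = df.sort_values(
        ["stat", "absstat", "gene"], ascending=[False, False, True], kind="stable"
    )
    return RankedList(genes=df["gene"].to_numpy(), stats=df["stat"].to_numpy())


def read_gmt(path, min_size: int = 10, max_size: int = 500) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated members).

    Sets outside [min_size, max_size] (measured on raw membership) are
    excluded; malformed lines raise with their line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected >= 3 "
                    f"tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = list(dict.fromkeys(m for m in members if m))
            if not min_size <= len(members) <= max_size:
                continue
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _es_from_positions(
    abs_w: np.ndarray, total_miss: int, positions: np.ndarray
) -> tuple[float, int, int]:
    """ES from sorted hit positions.

    ``abs_w`` are the hit weights |r|^p at each (sorted ascending)
    position; ``total_miss`` = N - s. Returns (es, extremum-rank,
    extremum-hit-index) where extremum-hit-index is the index into
    ``positions`` attaining the extremum (for leading-edge slicing).
    """
    wsum = abs_w.sum()
    if wsum <= 0:
        raise ValueError("degenerate ranking: zero total hit weight in set")
    miss_inc = 1.0 / total_miss if total_miss > 0 else 0.0
    cum = np.cumsum(abs_w) / wsum
    j = np.arange(len(positions))
    # running-sum value just after each hit, and just before each hit
    top = cum - (positions - j) * miss_inc
    bot = np.concatenate([[0.0], cum[:-1]]) - (positions - j) * miss_inc
    i_top = int(np.argmax(top))
    i_bot = int(np.argmin(bot))
    if top[i_top] >= -bot[i_bot]:
        return float(top[i_top]), int(positions[i_top]), i_top
    return float(bot[i_bot]), int(positions[i_bot]), i_bot


def enrichment_score(
    ranked: RankedList, members, p_exp: float = 1.0
) -> tuple[float, list[str]]:
    """Weighted-KS enrichment score and leading edge for one gene set.

    Members absent from the ranked universe are dropped first. On an
    exact tie between the positive and negative extremum the positive
    one is reported.
    """
    pos = np.array(sorted(ranked.index[g] for g in members if g in ranked.index))
    if pos.size == 0:
        raise ValueError("set has no overlap with the ranked universe")
    abs_w = np.abs(ranked.stats[pos]) ** p_exp
    es, ext_rank, ext_idx = _es_from_positions(abs_w, len(ranked) - pos.size, pos)
    if es >= 0:
        lead = pos[: ext_idx + 1]
    else:
        lead = pos[ext_idx:]
    return es, [ranked.genes[i] for i in lead]


def gsea_pvalues(
    ranked: RankedList,
    collection: GeneSetCollection,
    nperm: int = 1000,
    seed: int = 0,
    p_exp: float = 1.0,
) -> pd.DataFrame:
    """Gene-permutation significance for every set in a collection.

    For each distinct set size s, ``nperm`` random size-s subsets of the
    ranked universe are scored. The p-value is one-sided conditional on
    the sign of the observed ES (the preranked-GSEA convention):
    (1 + #{same-side permutation ES at least as extreme}) /
    (#{same-side permutation ES} + 1), so the minimum attainable p is
    1/(n_side + 1) >= 1/(nperm + 1) and null p-values are uniform. NES
    divides the ES by the mean |permutation ES| on the matching side.
    FDR is Benjamini-Hochberg across the collection.
    """
    if nperm < 100:
        raise ValueError("nperm must be at least 100")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    abs_stats = np.abs(ranked.stats) ** p_exp

    observed = {}
    for name, members in collection.sets.items():
        inset = [g for g in members if g in ranked.index]
        if not inset:
            continue
        es, lead = enrichment_score(ranked, members, p_exp=p_exp)
        observed[name] = (len(inset), es, lead)

    # permutation null per distinct set size
    null_es: dict[int, np.ndarray] = {}
    for s in sorted({v[0] for v in observed.values()}):
        es_perm = np.empty(nperm)
        for b in range(nperm):
            pos = np.sort(rng.choice(N, size=s, replace=False))
            es_perm[b], _, _ = _es_from_positions(abs_stats[pos], N - s, pos)
        null_es[s] = es_perm

    rows = []
    for name, (size, es, lead) in observed.items():
        perm = null_es[size]
        if es >= 0:
            side = perm[perm >= 0]
            n_extreme = int(np.sum(side >= es))
        else:
            side = perm[perm < 0]
            n_extreme = int(np.sum(side <= es))
        p = (1 + n_extreme) / (len(side) + 1)
        denom = np.mean(np.abs(side)) if len(side) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        rows.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "pval": p,
                "leading_edge": ",".join(lead),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["pval"].to_numpy())
        out = out[["set", "size", "es", "nes", "pval", "fdr", "leading_edge"]]
    return out
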