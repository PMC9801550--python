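"""CpG-to-gene and CpG-to-promoter aggregation and integration rules.

A gene is called differentially methylated (DM) when at least
``min_cpgs`` CpGs annotated to it are DM in the same direction (the
minimum drops to one CpG for genes on an explicit exception list, e.g.
Wnt-pathway genes).  A promoter is DM when at least one promoter-region
CpG (TSS1500, TSS200, 5'UTR or 1stExon) is DM.  Directions are handled
independently, so a gene with both hyper- and hypomethylated CpGs can
appear in both tables.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    PROMOTER_FEATURES,
    ValidationError,
)

logger = logging.getLogger("regmeth")


def _joined_calls(calls: pd.Series, annotation: CpGAnnotation) -> pd.DataFrame:
    gene_map = annotation.gene_map()
    gene_map["call"] = calls.reindex(gene_map["cpg_id"]).to_numpy()
    return gene_map


def call_dm_genes(
    calls: pd.Series,
    annotation: CpGAnnotation,
    min_cpgs: int = 2,
    one_cpg_gene_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Gene-level DM table with per-direction CpG counts.

    ``calls`` maps cpg_id to hyper/hypo/ns.  Returns one row per
    (gene, direction) passing the rule, with columns n_dm_cpgs,
    n_total_cpgs and pct_dm = 100 * n_dm / n_total, sorted by pct_dm
    descending (ties by gene id).
    """
    exceptions = set(one_cpg_gene_list)
    joined = _joined_calls(calls, annotation)
    known_genes = set(joined["gene"])
    unknown = exceptions - known_genes
    if unknown:
        logger.warning("exception-list genes absent from annotation: %s", sorted(unknown))

    total = joined.groupby("gene")["cpg_id"].nunique()
    rows = []
    for direction in ("hyper", "hypo"):
        counts = (
            joined.loc[joined["call"] == direction].groupby("gene")["cpg_id"].nunique()
        )
        for gene, n_dm in counts.items():
            needed = 1 if gene in exceptions else min_cpgs
            if n_dm >= needed:
                n_tot = int(total[gene])
                rows.append((gene, direction, int(n_dm), n_tot, 100.0 * n_dm / n_tot))
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "n_dm_cpgs", "n_total_cpgs", "pct_dm"]
    )
    return table.sort_values(
        ["pct_dm", "gene"], ascending=[False, True], ignore_index=True
    )


def call_dm_promoters(
    calls: pd.Series, annotation: CpGAnnotation, min_cpgs: int = 1
) -> pd.DataFrame:
    """Promoter-level DM table restricted to promoter feature groups."""
    joined = _joined_calls(calls, annotation)
    prom = joined[joined["feature_group"].isin(PROMOTER_FEATURES)]
    total = prom.groupby("gene")["cpg_id"].nunique()
    rows = []
    for direction in ("hyper", "hypo"):
        counts = prom.loc[prom["call"] == direction].groupby("gene")["cpg_id"].nunique()
        for gene, n_dm in counts.items():
            if n_dm >= min_cpgs:
                rows.append((gene, direction, int(n_dm), int(total[gene])))
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "n_dm_promoter_cpgs", "n_total_promoter_cpgs"]
    )
    return table.sort_values(["gene", "direction"], ignore_index=True)


def dm_fraction_of_gene_set(dm_genes: Iterable[str], gene_set: Iterable[str]) -> float:
    """Percentage of a gene set that is differentially methylated."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    return 100.0 * len(set(dm_genes) & gene_set) / len(gene_set)


def promoter_methylation_matrix(
    beta: BetaMatrix, annotation: CpGAnnotation
) -> pd.DataFrame:
    """Gene x sample matrix of unweighted mean promoter-CpG beta."""
    gene_map = annotation.gene_map()
    prom = gene_map[gene_map["feature_group"].isin(PROMOTER_FEATURES)]
    prom = prom.drop_duplicates(["cpg_id", "gene"])
    if prom.empty:
        return pd.DataFrame(columns=beta.sample_ids)
    merged = prom.merge(
        beta.frame, left_on="cpg_id", right_index=True, how="inner"
    )
    return merged.groupby("gene")[beta.sample_ids].mean()


def correlate_promoter_expression(
    prom_meth: pd.DataFrame,
    expression: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of promoter methylation vs expression.

    Genes are classified negative/positive when the correlation is
    significant at ``alpha``, none otherwise; genes with a constant
    methylation or expression vector over the shared samples are flagged
    undefined and excluded from sign classification.
    """
    shared = [s for s in prom_meth.columns if s in expression.frame.columns]
    if len(shared) < 3:
        raise ValidationError(f"need >=3 shared samples, got {len(shared)}")
    rows = []
    genes = prom_meth.index.intersection(expression.frame.index)
    for gene in genes:
        x = prom_meth.loc[gene, shared].to_numpy(dtype=float)
        y = expression.frame.loc[gene, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((gene, np.nan, np.nan, "undefined"))
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha:
            sign = "negative" if r < 0 else "positive"
        else:
            sign = "none"
        rows.append((gene, r, p, sign))
    return pd.DataFrame(rows, columns=["gene", "r", "p", "sign"]).set_index("gene")


def overlap_promoter_sets(
    named_sets: Mapping[str, Iterable[str]], reference: str | None = None
) -> dict:
    """Intersection structure of named gene sets.

    Returns the count of every exact membership pattern, the common
    intersection, and (for the designated reference set, default the
    first) the percentage of its members present in all other sets.
    """
    sets = {name: set(members) for name, members in named_sets.items()}
    if len(sets) < 2:
        raise ValidationError("need at least two sets")
    names = list(sets)
    if reference is None:
        reference = names[0]
    if reference not in sets:
        raise ValidationError(f"unknown reference set {reference!r}")

    universe = set().union(*sets.values())
    pattern_counts: dict[tuple[str, ...], int] = {}
    for g in universe:
        pattern = tuple(n for n in names if g in sets[n])
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1

    common = set.intersection(*sets.values())
    others = [sets[n] for n in names if n != reference]
    in_all_others = sets[reference] & set.intersection(*others) if others else set()
    shared_pct = (
        100.0 * len(in_all_others) / len(sets[reference]) if sets[reference] else 0.0
    )
    return {
        "pattern_counts": pattern_counts,
        "common": common,
        "reference": reference,
        "reference_shared_fraction": shared_pct,
    }


def fold_threshold_gene_set(
    expression_by_tissue: pd.DataFrame,
    target_tissue: str,
    fold: float = 5.0,
    pseudo: float = 0.01,
    mode: str = "ratio",
) -> set[str]:
    """Tissue-specific gene set by a fold-change rule.

    ``expression_by_tissue`` is a gene x tissue matrix of linear-scale
    expression.  In ``ratio`` mode a gene is included iff
    target / (mean of other tissues + pseudo) >= fold (the
    tissue-specificity rule); in ``logfc`` mode iff
    log2((target + pseudo) / (mean others + pseudo)) > fold (a generic
    log-fold-threshold set builder).
    """
    if target_tissue not in expression_by_tissue.columns:
        raise ValidationError(f"unknown tissue {target_tissue!r}")
    others = [c for c in expression_by_tissue.columns if c != target_tissue]
    if not others:
        raise ValidationError("need at least two tissues")
    target = expression_by_tissue[target_tissue]
    other_mean = expression_by_tissue[others].mean(axis=1)
    if mode == "ratio":
        keep = target / (other_mean + pseudo) >= fold
    elif mode == "logfc":
        keep = np.log2((target + pseudo) / (other_mean + pseudo)) > fold
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return set(expression_by_tissue.index[keep])


def translate_gene_set(
    gene_set: Iterable[str], orthology: Mapping[str, str] | pd.DataFrame
) -> set[str]:
    """Translate gene symbols through a two-column orthology mapping."""
    if isinstance(orthology, pd.DataFrame):
        orthology = dict(zip(orthology.iloc[:, 0], orthology.iloc[:, 1]))
    return {orthology[g] for g in gene_set if g in orthology}
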