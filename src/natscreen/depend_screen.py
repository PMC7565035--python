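"""CRISPR gene-effect dependency analysis.

Essentiality summaries over cell lines, a cumulative rank curve of median
gene effects, pairwise co-dependency correlations, and the paralog
compensation screen relating a candidate buffer gene's expression to a
dependent gene's knockout effect.

All correlations use pairwise-complete observations (cells missing in
either series are dropped).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "essentiality_summary",
    "cumulative_rank_curve",
    "codependency_matrix",
    "compensation_screen",
]


def essentiality_summary(
    gene_effect: pd.DataFrame,
    dependency_threshold: float = -0.5,
) -> pd.DataFrame:
    """Per-gene essentiality over cell lines.

    * ``median_gene_effect`` — median over non-missing cell lines (more
      negative means greater sensitivity to knockout);
    * ``dependent_fraction`` — share of cell lines with gene effect at or
      below ``dependency_threshold`` (a proxy for a published dependency
      probability call);
    * ``essentiality_percentile`` — 100 x fraction of all summarised genes
      with a strictly greater (less essential) median, so the single most
      essential gene among N sits at 100 (N-1)/N.

    Genes with no observed effect in any line are excluded with a warning.
    """
    if gene_effect.empty:
        raise ValueError("gene effect matrix is empty")
    values = gene_effect.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    all_missing = ~observed.any(axis=1)
    if all_missing.any():
        dropped = list(gene_effect.index[all_missing])
        warnings.warn(f"excluding genes with all-missing effects: {dropped}",
                      stacklevel=2)
    keep = gene_effect.index[~all_missing]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(values[~all_missing], axis=1)
        dep_frac = np.nanmean(values[~all_missing] <= dependency_threshold, axis=1)
    n = len(keep)
    percentile = np.array(
        [100.0 * np.sum(medians > m) / n for m in medians]
    )
    out = pd.DataFrame({
        "gene": keep,
        "median_gene_effect": medians,
        "dependent_fraction": dep_frac,
        "essentiality_percentile": percentile,
    })
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


def cumulative_rank_curve(gene_effect: pd.DataFrame) -> pd.DataFrame:
    """Genes sorted by ascending median effect with cumulative fraction.

    Ties in the median are ordered by gene name; the cumulative fraction is
    strictly increasing, ending at 1.
    """
    if len(gene_effect) < 2:
        raise ValueError("need at least 2 genes for a cumulative curve")
    summary = essentiality_summary(gene_effect)
    ordered = summary.sort_values(
        ["median_gene_effect", "gene"], kind="stable"
    ).reset_index(drop=True)
    ordered["cumulative_fraction"] = (np.arange(len(ordered)) + 1) / len(ordered)
    return ordered[["gene", "median_gene_effect", "cumulative_fraction"]]


def _pairwise_complete(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    return joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)


def codependency_matrix(
    gene_effect: pd.DataFrame,
    gene_set: list[str] | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of gene-effect profiles.

    Returns ``(r_matrix, pairs)``: a symmetric correlation matrix with unit
    diagonal, and a tidy table of unordered pairs with r, two-sided p and a
    significance flag at raw ``alpha`` (Benjamini-Hochberg optional, off by
    default). Pairs with fewer than ``min_shared`` shared cell lines are
    not evaluable (NaN r, excluded from flagging).
    """
    genes = sorted(gene_set) if gene_set is not None else list(gene_effect.index)
    missing = [g for g in genes if g not in gene_effect.index]
    if missing:
        raise ValueError(f"genes absent from gene effect matrix: {missing}")
    r_matrix = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            x, y = _pairwise_complete(gene_effect.loc[ga], gene_effect.loc[gb])
            if len(x) < min_shared or np.std(x) == 0 or np.std(y) == 0:
                r, p, evaluable = float("nan"), float("nan"), False
            else:
                r, p = stats.pearsonr(x, y)
                r, p = float(r), float(p)
                evaluable = True
            r_matrix.loc[ga, gb] = r_matrix.loc[gb, ga] = r
            rows.append((ga, gb, len(x), r, p, evaluable))
    pairs = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_shared", "r", "p", "evaluable"]
    )
    pairs["p_adjusted"] = np.nan
    ev = pairs["evaluable"]
    if ev.any():
        if bh_correct:
            pairs.loc[ev, "p_adjusted"] = multipletests(
                pairs.loc[ev, "p"], method="fdr_bh"
            )[1]
        else:
            pairs.loc[ev, "p_adjusted"] = pairs.loc[ev, "p"]
    pairs["significant"] = ev & (pairs["p_adjusted"] < alpha)
    return r_matrix, pairs


def compensation_screen(
    gene_effect: pd.DataFrame,
    cell_line_expression: pd.DataFrame,
    dependent_gene: str,
    candidate_genes: list[str] | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Rank candidate buffer genes for one dependent gene.

    For each candidate, the Pearson correlation between its expression and
    the dependent gene's effect across shared cell lines. Positive r means
    buffering: higher candidate expression goes with an effect closer to
    zero. Ranked descending by r; ties broken by gene name; constant-
    expression candidates are excluded.
    """
    if dependent_gene not in gene_effect.index:
        raise ValueError(f"dependent gene {dependent_gene!r} not in gene effect matrix")
    if candidate_genes is None:
        candidate_genes = [g for g in cell_line_expression.index if g != dependent_gene]
    effect = gene_effect.loc[dependent_gene]
    rows = []
    for gene in candidate_genes:
        if gene not in cell_line_expression.index:
            raise ValueError(f"candidate gene {gene!r} not in expression matrix")
        x, y = _pairwise_complete(cell_line_expression.loc[gene], effect)
        if len(x) < min_shared or np.std(x) == 0 or np.std(y) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((dependent_gene, gene, len(x), float(r), float(p)))
    out = pd.DataFrame(
        rows, columns=["dependent_gene", "candidate_buffer_gene", "n_shared", "r", "p"]
    )
    out = out.sort_values(
        ["r", "candidate_buffer_gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
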