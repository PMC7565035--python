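"""Tumour-vs-normal differential expression screen.

Per gene per eligible tissue: a two-sided Student's t-test on log2(x+1)
expression values, a log2 fold change as the difference of group means, and
an up/down/ns call against raw fold-change and p-value thresholds.

No multiple-testing correction is applied in this screen: significance is
a raw p-value threshold (default 0.01) combined with a fold-change band.
False-discovery-rate adjustment is used only in the survival screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["eligible_tissues", "de_screen", "de_tally"]


def eligible_tissues(samples: pd.DataFrame, min_per_group: int = 10) -> list[str]:
    """Tissues with at least ``min_per_group`` tumour AND normal samples."""
    counts = (
        samples.groupby(["tissue", "tumour_or_normal"])["sample"]
        .nunique().unstack(fill_value=0)
    )
    for col in ("tumour", "normal"):
        if col not in counts:
            counts[col] = 0
    ok = counts[(counts["tumour"] >= min_per_group) & (counts["normal"] >= min_per_group)]
    return sorted(ok.index)


def de_screen(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    genes: list[str] | None = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    min_per_group: int = 10,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Differential expression over genes x eligible tissues.

    ``log2_fc`` = mean(log2 tumour) - mean(log2 normal); direction is
    ``up``/``down`` when |log2_fc| >= log2(fc_threshold) and p < p_threshold,
    else ``ns``. Degenerate zero-variance contrasts are marked not evaluable
    (p NaN, direction ns).
    """
    if tissues is None:
        tissues = eligible_tissues(samples, min_per_group)
    if genes is None:
        gene_index = expression.index
    else:
        missing = [g for g in genes if g not in expression.index]
        if missing:
            raise ValueError(f"genes absent from expression matrix: {missing}")
        gene_index = pd.Index(genes)
    log2_band = np.log2(fc_threshold)

    frames = []
    for tissue in tissues:
        sub = samples[samples["tissue"] == tissue]
        t_ids = [s for s in sub.loc[sub["tumour_or_normal"] == "tumour", "sample"]
                 if s in expression.columns]
        n_ids = [s for s in sub.loc[sub["tumour_or_normal"] == "normal", "sample"]
                 if s in expression.columns]
        a = expression.loc[gene_index, t_ids].to_numpy(dtype=float)
        b = expression.loc[gene_index, n_ids].to_numpy(dtype=float)
        mean_t, mean_n = a.mean(axis=1), b.mean(axis=1)
        lfc = mean_t - mean_n
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1)
        pooled_var = a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)
        evaluable = pooled_var > 0
        p = np.where(evaluable, p, np.nan)
        direction = np.where(
            evaluable & (np.abs(lfc) >= log2_band) & (p < p_threshold),
            np.where(lfc > 0, "up", "down"),
            "ns",
        )
        frames.append(pd.DataFrame({
            "gene": gene_index,
            "tissue": tissue,
            "n_tumour": len(t_ids),
            "n_normal": len(n_ids),
            "mean_log2_tumour": mean_t,
            "mean_log2_normal": mean_n,
            "log2_fc": lfc,
            "p": p,
            "evaluable": evaluable,
            "direction": direction,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["gene", "tissue", "n_tumour", "n_normal", "mean_log2_tumour",
                     "mean_log2_normal", "log2_fc", "p", "evaluable", "direction"]
        )
    return pd.concat(frames, ignore_index=True)


def de_tally(de_results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene tally of up-, down- and non-significant tissues.

    up + down + ns equals the number of screened tissues for every gene.
    """
    tally = (
        de_results.groupby(["gene", "direction"]).size().unstack(fill_value=0)
    )
    for col in ("up", "down", "ns"):
        if col not in tally:
            tally[col] = 0
    tally = tally[["up", "down", "ns"]].astype(int)
    tally["n_tissues"] = tally.sum(axis=1)
    return tally.reset_index()
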