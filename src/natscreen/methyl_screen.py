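"""Methylation-expression anti-correlation discovery.

A probe passes the screen only when ALL of the following hold (the criteria
are conjunctive and order-free):

1. region filter — the probe lies in the promoter (2 kb upstream of the
   TSS), the gene body, or the first intron;
2. beta floor — mean beta exceeds ``beta_floor`` (default 0.2) in either the
   normal or the tumour group;
3. differential methylation — |mean(beta tumour) - mean(beta normal)| is at
   least ``min_delta_beta`` (default 0.1) with a two-sided t-test
   p < ``p_beta`` (default 0.05);
4. anti-correlation — Pearson r between beta and log2 expression across
   tumour samples is at most ``r_max`` (default -0.2);
5. expression gate — the gene's tumour-vs-normal |log2 fold change| in that
   tissue is at least log2(``gate_fc``) (default 1.5).

Relaxing any single threshold never removes a passing probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALLOWED_REGIONS",
    "MethylThresholds",
    "probe_region_filter",
    "methylation_expression_screen",
]

ALLOWED_REGIONS = frozenset({"promoter_2kb", "gene_body", "first_intron"})


@dataclass(frozen=True)
class MethylThresholds:
    beta_floor: float = 0.2
    min_delta_beta: float = 0.1
    p_beta: float = 0.05
    r_max: float = -0.2
    gate_fc: float = 1.5
    use_median: bool = False           # group-difference statistic on beta
    corr_include_normal: bool = False  # correlate over tumour+normal samples


def probe_region_filter(
    probes: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Keep probes in allowed regions for genes under study.

    Probes with a missing gene annotation are excluded with a warning.
    """
    unannotated = probes["gene"].isna() | (probes["gene"].astype(str) == "")
    if unannotated.any():
        warnings.warn(
            f"excluding {int(unannotated.sum())} probe(s) without gene annotation",
            stacklevel=2,
        )
    out = probes[~unannotated & probes["region"].isin(ALLOWED_REGIONS)]
    if genes is not None:
        out = out[out["gene"].isin(set(genes))]
    return out.reset_index(drop=True)


def methylation_expression_screen(
    methylation: pd.DataFrame,
    probes: pd.DataFrame,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    de_results: pd.DataFrame,
    thresholds: MethylThresholds = MethylThresholds(),
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Evaluate every region-eligible probe for each gated (gene, tissue) pair.

    The expression gate uses ``de_results`` log2 fold changes; probes of
    genes whose |log2_fc| is below the gate in a tissue are still reported
    (with ``gate_ok`` False) so filter behaviour is auditable, but they can
    never pass. Probes with fewer than 3 paired samples for the correlation
    are not evaluable.
    """
    th = thresholds
    probes = probe_region_filter(probes, genes)
    gate_band = np.log2(th.gate_fc)
    de = de_results.set_index(["gene", "tissue"])["log2_fc"]

    rows = []
    for (gene, tissue), lfc in de.items():
        gene_probes = probes[probes["gene"] == gene]
        if gene_probes.empty:
            continue
        sub = samples[samples["tissue"] == tissue]
        t_ids = [s for s in sub.loc[sub["tumour_or_normal"] == "tumour", "sample"]
                 if s in methylation.columns]
        n_ids = [s for s in sub.loc[sub["tumour_or_normal"] == "normal", "sample"]
                 if s in methylation.columns]
        corr_ids = list(t_ids)
        if th.corr_include_normal:
            corr_ids += n_ids
        corr_ids = [s for s in corr_ids if s in expression.columns]
        gate_ok = bool(abs(lfc) >= gate_band)
        for _, probe in gene_probes.iterrows():
            pid = probe["probe_id"]
            if pid not in methylation.index:
                continue
            beta_t = methylation.loc[pid, t_ids].to_numpy(dtype=float)
            beta_n = methylation.loc[pid, n_ids].to_numpy(dtype=float)
            rows.append(_evaluate_probe(
                pid, gene, probe["region"], tissue, beta_t, beta_n,
                methylation.loc[pid, corr_ids].to_numpy(dtype=float),
                expression.loc[gene, corr_ids].to_numpy(dtype=float)
                if gene in expression.index else np.array([]),
                lfc, gate_ok, th,
            ))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "gene", "region", "tissue", "mean_beta_normal",
                 "mean_beta_tumour", "delta_beta", "p_beta", "r", "p_r",
                 "log2_fc", "gate_ok", "evaluable", "passes"],
    )


def _evaluate_probe(pid, gene, region, tissue, beta_t, beta_n, beta_corr,
                    expr_corr, lfc, gate_ok, th: MethylThresholds) -> tuple:
    nan = float("nan")
    if len(beta_t) < 2 or len(beta_n) < 2:
        return (pid, gene, region, tissue, nan, nan, nan, nan, nan, nan,
                lfc, gate_ok, False, False)
    mean_n, mean_t = float(beta_n.mean()), float(beta_t.mean())
    if th.use_median:
        delta = float(np.median(beta_t) - np.median(beta_n))
    else:
        delta = mean_t - mean_n
    if np.var(beta_t, ddof=1) + np.var(beta_n, ddof=1) == 0:
        p_beta = 1.0 if delta == 0 else 0.0
    else:
        p_beta = float(stats.ttest_ind(beta_t, beta_n).pvalue)
    # Pearson correlation over paired samples (tumour-only by default).
    if len(beta_corr) < 3 or len(expr_corr) < 3:
        return (pid, gene, region, tissue, mean_n, mean_t, delta, p_beta,
                nan, nan, lfc, gate_ok, False, False)
    if np.std(beta_corr) == 0 or np.std(expr_corr) == 0:
        r, p_r = nan, nan
        evaluable = False
    else:
        r, p_r = stats.pearsonr(beta_corr, expr_corr)
        r, p_r = float(r), float(p_r)
        evaluable = True
    passes = bool(
        evaluable
        and gate_ok
        and max(mean_n, mean_t) > th.beta_floor
        and abs(delta) >= th.min_delta_beta
        and p_beta < th.p_beta
        and r <= th.r_max
    )
    return (pid, gene, region, tissue, mean_n, mean_t, delta, p_beta, r, p_r,
            lfc, gate_ok, evaluable, passes)
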