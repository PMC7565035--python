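"""Mutation and copy-number burden analysis.

Per-gene and per-tumour-type alteration frequencies, ORF-length-normalised
mutation burden split by missense vs truncating class, recurrent-event
detection, a positional profile of N-terminal missense mutations, and the
amplification-versus-expression association test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nt_substrate import AMINO_ACIDS, classify_substitution, MutationEffect

__all__ = [
    "TRUNCATING_CONSEQUENCES",
    "alteration_frequencies",
    "normalised_burden",
    "recurrent_mutations",
    "positional_mutation_profile",
    "amplification_expression_association",
    "AmplificationAssociation",
]

#: Consequence classes counted as truncating.
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice"})

_OVERALL = "ALL"


def _check_known_samples(table: pd.DataFrame, samples: pd.DataFrame, label: str) -> None:
    known = set(samples["sample"])
    unknown = sorted(set(table["sample"]) - known)
    if unknown:
        raise ValueError(
            f"{label} references samples missing from the sample table: {unknown}"
        )


def alteration_frequencies(
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    samples: pd.DataFrame,
    freq_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene alteration frequencies, overall and per tumour type.

    A sample counts once per gene regardless of how many alterations it
    carries. Denominators are profiled tumour samples per type (the full
    tumour sample universe), never the number of mutated samples. Rows with
    tumour_type ``ALL`` pool every profiled tumour sample.

    Alteration classes reported: ``mutation`` (any non-silent mutation),
    ``amplification`` (call +2), ``deletion`` (call -2) and ``any``.
    """
    _check_known_samples(mutations, samples, "mutation table")
    _check_known_samples(cnv, samples, "cnv table")
    tumour = samples[samples["tumour_or_normal"] == "tumour"]
    type_of = dict(zip(tumour["sample"], tumour["tumour_type"]))
    denominators = tumour.groupby("tumour_type")["sample"].nunique().to_dict()
    denominators[_OVERALL] = tumour["sample"].nunique()

    mut = mutations[mutations["consequence"] != "silent"]
    events = {
        "mutation": mut[["sample", "gene"]],
        "amplification": cnv.loc[cnv["call"] == 2, ["sample", "gene"]],
        "deletion": cnv.loc[cnv["call"] == -2, ["sample", "gene"]],
    }
    events["any"] = pd.concat(events.values(), ignore_index=True)

    rows = []
    for klass, ev in events.items():
        ev = ev.drop_duplicates()
        ev = ev[ev["sample"].isin(type_of)]
        for scope in [_OVERALL, *sorted(denominators.keys() - {_OVERALL})]:
            if scope == _OVERALL:
                sub = ev
            else:
                sub = ev[ev["sample"].map(type_of) == scope]
            counts = sub.groupby("gene")["sample"].nunique()
            for gene, n in counts.items():
                freq = n / denominators[scope]
                rows.append((gene, scope, klass, int(n), denominators[scope], freq,
                             freq >= freq_threshold))
    out = pd.DataFrame(
        rows,
        columns=["gene", "tumour_type", "alteration_class", "n_altered",
                 "n_profiled", "frequency", "flagged"],
    )
    return out.sort_values(
        ["alteration_class", "gene", "tumour_type"], kind="stable"
    ).reset_index(drop=True)


def normalised_burden(
    mutations: pd.DataFrame,
    gene_models: pd.DataFrame,
    reference_gene: str,
) -> pd.DataFrame:
    """ORF-length-normalised mutation burden per gene and class.

    For each class (missense, truncating) independently: counts are divided
    by the gene's ORF length in amino acids, then by the reference gene's
    per-residue rate. A reference gene with zero count in a class leaves
    that class undefined (NaN), not zero.
    """
    if reference_gene not in set(gene_models["symbol"]):
        raise ValueError(f"reference gene {reference_gene!r} not in gene models")
    lengths = dict(zip(gene_models["symbol"], gene_models["orf_length_aa"]))
    bad = gene_models.loc[gene_models["orf_length_aa"] <= 0, "symbol"].tolist()
    if bad:
        raise ValueError(f"genes with non-positive ORF length: {bad}")

    is_trunc = mutations["consequence"].isin(TRUNCATING_CONSEQUENCES)
    is_missense = mutations["consequence"] == "missense"
    counts = pd.DataFrame(index=pd.Index(gene_models["symbol"], name="gene"))
    counts["missense_count"] = (
        mutations.loc[is_missense].groupby("gene").size().reindex(counts.index, fill_value=0)
    )
    counts["truncating_count"] = (
        mutations.loc[is_trunc].groupby("gene").size().reindex(counts.index, fill_value=0)
    )
    length = counts.index.map(lengths).astype(float)
    for klass in ("missense", "truncating"):
        rate = counts[f"{klass}_count"] / length
        ref_rate = counts.loc[reference_gene, f"{klass}_count"] / lengths[reference_gene]
        counts[f"normalised_{klass}"] = rate / ref_rate if ref_rate > 0 else np.nan
    return counts.reset_index()


def recurrent_mutations(
    mutations: pd.DataFrame,
    min_count: int = 3,
    class_filter: str | set[str] | None = None,
    gene_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Recurring mutation events.

    The identity of an event is (gene, position, alt residue, consequence);
    the same position with a different alternate residue is a distinct
    event. ``class_filter`` may be ``"truncating"``, ``"missense"`` or an
    explicit set of consequences. ``gene_groups`` maps member gene symbols
    to a pooled group label (e.g. multi-copy histone genes counted
    collectively) applied before counting. Sorted by count descending, ties
    by gene then position.
    """
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    mut = mutations.copy()
    if class_filter == "truncating":
        mut = mut[mut["consequence"].isin(TRUNCATING_CONSEQUENCES)]
    elif class_filter == "missense":
        mut = mut[mut["consequence"] == "missense"]
    elif class_filter is not None:
        mut = mut[mut["consequence"].isin(set(class_filter))]
    if gene_groups:
        mut["gene"] = mut["gene"].map(lambda g: gene_groups.get(g, g))
    if mut.empty:
        return pd.DataFrame(
            columns=["gene", "protein_pos", "ref_aa", "alt_aa", "consequence",
                     "count", "by_tumour_type"]
        )
    key = ["gene", "protein_pos", "ref_aa", "alt_aa", "consequence"]
    grouped = mut.groupby(key, sort=False)
    counts = grouped.size().rename("count")
    breakdown = grouped["tumour_type"].apply(
        lambda s: ";".join(f"{t}:{n}" for t, n in sorted(s.value_counts().items()))
    ).rename("by_tumour_type")
    out = pd.concat([counts, breakdown], axis=1).reset_index()
    out = out[out["count"] >= min_count]
    return out.sort_values(
        ["count", "gene", "protein_pos"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def positional_mutation_profile(
    mutations: pd.DataFrame,
    gene_models: pd.DataFrame | None = None,
    max_position: int = 5,
) -> dict:
    """Missense mutation profile over the first ``max_position`` residues.

    Returns a dict with:

    * ``position_counts`` — missense count at each position 1..max_position;
    * ``p2_records`` — the P2 missense records annotated with their
      N-terminal substitution effect (sequence context from ``gene_models``
      when available, else a generic non-motif backbone);
    * ``p2_gene_counts`` — P2 missense count per gene;
    * ``preserving_fraction`` — fraction of classifiable P2 records whose
      substitution preserves the NAT class.
    """
    missense = mutations[
        (mutations["consequence"] == "missense")
        & (mutations["protein_pos"] <= max_position)
    ].copy()
    position_counts = (
        missense.groupby("protein_pos").size()
        .reindex(range(1, max_position + 1), fill_value=0)
        .rename_axis("position").rename("missense_count").reset_index()
    )
    nterms = {}
    if gene_models is not None:
        nterms = dict(zip(gene_models["symbol"], gene_models["nterm_seq"]))

    p2 = missense[missense["protein_pos"] == 2].copy()
    effects = []
    for _, rec in p2.iterrows():
        ref, alt = rec["ref_aa"], rec["alt_aa"]
        if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS or ref == alt:
            effects.append("unclassifiable")
            continue
        seq = nterms.get(rec["gene"], "M" + ref + "LKLK")
        if len(seq) < 2 or seq[1] != ref:
            seq = "M" + ref + "LKLK"
        effects.append(classify_substitution(seq, 2, alt).effect.value)
    p2["nt_effect"] = effects
    classifiable = p2[p2["nt_effect"] != "unclassifiable"]
    preserving_fraction = (
        float((classifiable["nt_effect"] == MutationEffect.preserves_class.value).mean())
        if len(classifiable)
        else float("nan")
    )
    p2_gene_counts = (
        p2.groupby("gene").size().rename("p2_missense_count").reset_index()
    )
    return {
        "position_counts": position_counts,
        "p2_records": p2.reset_index(drop=True),
        "p2_gene_counts": p2_gene_counts,
        "preserving_fraction": preserving_fraction,
    }


@dataclass(frozen=True)
class AmplificationAssociation:
    """Expression contrast between amplified and non-amplified samples."""

    gene: str
    tumour_type: str
    n_amplified: int
    n_not_amplified: int
    mean_log2_amplified: float
    mean_log2_not_amplified: float
    log2_fc: float
    t: float
    p: float
    evaluable: bool


def amplification_expression_association(
    cnv: pd.DataFrame,
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    gene: str,
    tumour_type: str,
    min_group_size: int = 3,
    welch: bool = False,
) -> AmplificationAssociation:
    """Two-sided t-test on log2 expression, amplified (call +2) vs not.

    Gains (+1) are not amplifications; the non-amplified group is every
    profiled tumour sample of the type without a +2 call for the gene.
    Groups smaller than ``min_group_size`` make the association
    not-evaluable (never p = 1). Student's t by default, Welch by flag.
    """
    if gene not in expression.index:
        raise ValueError(f"gene {gene!r} not in expression matrix")
    tumour = samples[
        (samples["tumour_or_normal"] == "tumour")
        & (samples["tumour_type"] == tumour_type)
    ]
    ids = [s for s in tumour["sample"] if s in expression.columns]
    amp_ids = set(
        cnv.loc[(cnv["gene"] == gene) & (cnv["call"] == 2), "sample"]
    ) & set(ids)
    non_ids = [s for s in ids if s not in amp_ids]
    amp_ids = sorted(amp_ids)
    if len(amp_ids) < min_group_size or len(non_ids) < min_group_size:
        return AmplificationAssociation(
            gene, tumour_type, len(amp_ids), len(non_ids),
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            evaluable=False,
        )
    a = expression.loc[gene, amp_ids].to_numpy(dtype=float)
    b = expression.loc[gene, non_ids].to_numpy(dtype=float)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        t, p = (float("inf"), 0.0) if mean_a != mean_b else (0.0, 1.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return AmplificationAssociation(
        gene, tumour_type, len(amp_ids), len(non_ids),
        mean_a, mean_b, mean_a - mean_b, t, p, evaluable=True,
    )
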