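"""End-to-end orchestration over a cohort directory.

Reads the TSV/JSON cohort written by :func:`natscreen.cohort_sim.write_cohort`
(or any equivalently shaped directory), runs every screen in order, writes
per-screen TSV outputs plus a ``report.json`` that records each threshold
actually used and — when a ``truth.json`` is present — a recovery summary of
planted signals found, missed and falsely called.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as nio
from .cohort_sim import SyntheticCohort
from . import genomic_screen, expr_screen, methyl_screen, depend_screen, surv_screen
from .methyl_screen import MethylThresholds

__all__ = ["RunConfig", "read_cohort", "run_all"]

logger = logging.getLogger("natscreen")

REQUIRED_FILES = (
    "genes.tsv", "samples.tsv", "expression.tsv", "methylation.tsv",
    "probes.tsv", "mutations.tsv", "cnv.tsv", "gene_effect.tsv",
    "cell_line_expression.tsv",
)
OPTIONAL_FILES = ("survival.tsv", "truth.json")


@dataclass
class GenomicOptions:
    freq_threshold: float = 0.05
    min_recurrence: int = 3
    reference_gene: str | None = None  # default: most-mutated gene
    min_group_size: int = 3
    welch: bool = False


@dataclass
class ExpressionOptions:
    fc_threshold: float = 1.5
    p_threshold: float = 0.01
    min_per_group: int = 10


@dataclass
class DependencyOptions:
    dependency_threshold: float = -0.5
    gene_set: list[str] | None = None
    dependent_gene: str | None = None  # default: taken from truth.json if present
    codependency_alpha: float = 0.05
    bh_correct: bool = False


@dataclass
class SurvivalOptions:
    min_events: int = 10
    fdr: float = 0.05
    z_scale: bool = True
    include_logrank: bool = True


@dataclass
class RunConfig:
    cohort_dir: str = "."
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    genomic: GenomicOptions = field(default_factory=GenomicOptions)
    expression: ExpressionOptions = field(default_factory=ExpressionOptions)
    methylation: MethylThresholds = field(default_factory=MethylThresholds)
    dependency: DependencyOptions = field(default_factory=DependencyOptions)
    survival: SurvivalOptions = field(default_factory=SurvivalOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a nested dict, rejecting any unknown key by name."""
        data = dict(data)
        kwargs = {}
        sections = {
            "genomic": GenomicOptions,
            "expression": ExpressionOptions,
            "methylation": MethylThresholds,
            "dependency": DependencyOptions,
            "survival": SurvivalOptions,
        }
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        for name, value in data.items():
            if name in sections:
                section_cls = sections[name]
                valid = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(
                        f"unknown configuration key(s) in {name!r}: {sorted(bad)}"
                    )
                kwargs[name] = section_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def thresholds_block(self) -> dict:
        """Every threshold actually in force, for the report provenance block."""
        return {
            "genomic": dataclasses.asdict(self.genomic),
            "expression": dataclasses.asdict(self.expression),
            "methylation": dataclasses.asdict(self.methylation),
            "dependency": dataclasses.asdict(self.dependency),
            "survival": dataclasses.asdict(self.survival),
            "seed": self.seed,
        }


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Inverse of ``write_cohort``; validates cross-references.

    A missing ``survival.tsv`` disables the survival screen rather than
    failing. Sample ids appearing in any omics table but absent from
    ``samples.tsv`` raise an error listing the offenders.
    """
    directory = Path(directory)
    missing = [f for f in REQUIRED_FILES if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"cohort directory {directory} is missing required file(s): {missing}"
        )
    genes = nio.read_table(directory / "genes.tsv")
    samples = nio.read_table(directory / "samples.tsv")
    expression = nio.read_matrix(directory / "expression.tsv")
    methylation = nio.read_matrix(directory / "methylation.tsv")
    probes = nio.read_table(directory / "probes.tsv")
    mutations = nio.read_table(directory / "mutations.tsv")
    cnv = nio.read_table(directory / "cnv.tsv")
    gene_effect = nio.read_matrix(directory / "gene_effect.tsv")
    cl_expr = nio.read_matrix(directory / "cell_line_expression.tsv")
    survival = None
    if (directory / "survival.tsv").exists():
        survival = nio.read_table(directory / "survival.tsv")
    truth = {}
    if (directory / "truth.json").exists():
        truth = json.loads((directory / "truth.json").read_text())

    known = set(samples["sample"])
    for label, ids in (
        ("expression.tsv", expression.columns),
        ("methylation.tsv", methylation.columns),
    ):
        dangling = sorted(set(ids) - known)
        if dangling:
            raise ValueError(f"{label} has sample ids not in samples.tsv: {dangling}")
    for label, table in (("mutations.tsv", mutations), ("cnv.tsv", cnv)):
        if len(table):
            dangling = sorted(set(table["sample"]) - known)
            if dangling:
                raise ValueError(
                    f"{label} has sample ids not in samples.tsv: {dangling}"
                )
    if survival is not None and len(survival):
        dangling = sorted(set(survival["sample"]) - known)
        if dangling:
            raise ValueError(
                f"survival.tsv has sample ids not in samples.tsv: {dangling}"
            )
    return SyntheticCohort(
        genes=genes, samples=samples, expression=expression,
        methylation=methylation, probes=probes, mutations=mutations, cnv=cnv,
        gene_effect=gene_effect, cell_line_expression=cl_expr,
        survival=survival, truth=truth,
    )


def _default_reference_gene(mutations: pd.DataFrame, genes: pd.DataFrame) -> str | None:
    """Most-mutated gene (missense), deterministic tie-break by name."""
    missense = mutations[mutations["consequence"] == "missense"]
    if missense.empty:
        return None
    counts = missense.groupby("gene").size().sort_index()
    return counts.sort_values(ascending=False, kind="stable").index[0]


def run_all(config: RunConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Execute every screen over a cohort directory and write outputs.

    Returns the report dictionary (also written to ``report.json``).
    """
    logging.basicConfig(level=config.log_level)
    if cohort is None:
        cohort = read_cohort(config.cohort_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": config.thresholds_block(), "outputs": {}}

    def _emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        nio.write_table(frame, path)
        report["outputs"][name] = str(path)

    t0 = time.perf_counter()
    # Genomic screen -------------------------------------------------------
    freqs = genomic_screen.alteration_frequencies(
        cohort.mutations, cohort.cnv, cohort.samples,
        freq_threshold=config.genomic.freq_threshold,
    )
    _emit("alteration_frequencies.tsv", freqs)
    reference = config.genomic.reference_gene or _default_reference_gene(
        cohort.mutations, cohort.genes
    )
    if reference is not None:
        burden = genomic_screen.normalised_burden(
            cohort.mutations, cohort.genes, reference
        )
        _emit("burden.tsv", burden)
        report["thresholds"]["genomic"]["reference_gene"] = reference
    recurrence = genomic_screen.recurrent_mutations(
        cohort.mutations, min_count=config.genomic.min_recurrence
    )
    _emit("recurrence.tsv", recurrence)
    profile = genomic_screen.positional_mutation_profile(cohort.mutations, cohort.genes)
    _emit("p2_profile.tsv", profile["p2_records"])
    logger.info("genomic screen done in %.2fs", time.perf_counter() - t0)

    # Expression screen ----------------------------------------------------
    t0 = time.perf_counter()
    de = expr_screen.de_screen(
        cohort.expression, cohort.samples,
        fc_threshold=config.expression.fc_threshold,
        p_threshold=config.expression.p_threshold,
        min_per_group=config.expression.min_per_group,
    )
    _emit("de_results.tsv", de)
    _emit("de_tally.tsv", expr_screen.de_tally(de))
    logger.info("expression screen done in %.2fs", time.perf_counter() - t0)

    # Methylation screen ---------------------------------------------------
    t0 = time.perf_counter()
    meth = methyl_screen.methylation_expression_screen(
        cohort.methylation, cohort.probes, cohort.expression, cohort.samples,
        de, thresholds=config.methylation,
    )
    _emit("methylation_hits.tsv", meth[meth["passes"]].reset_index(drop=True))
    _emit("methylation_probes.tsv", meth)
    logger.info("methylation screen done in %.2fs", time.perf_counter() - t0)

    # Dependency screen ----------------------------------------------------
    t0 = time.perf_counter()
    essentiality = depend_screen.essentiality_summary(
        cohort.gene_effect, config.dependency.dependency_threshold
    )
    _emit("essentiality.tsv", essentiality)
    _, codep = depend_screen.codependency_matrix(
        cohort.gene_effect, config.dependency.gene_set,
        alpha=config.dependency.codependency_alpha,
        bh_correct=config.dependency.bh_correct,
    )
    _emit("codependency.tsv", codep)
    dependent = config.dependency.dependent_gene
    if dependent is None and cohort.truth.get("planted_compensation"):
        dependent = cohort.truth["planted_compensation"][0]["dependent_gene"]
    if dependent is not None:
        comp = depend_screen.compensation_screen(
            cohort.gene_effect, cohort.cell_line_expression, dependent
        )
        _emit("compensation.tsv", comp)
    logger.info("dependency screen done in %.2fs", time.perf_counter() - t0)

    # Survival screen ------------------------------------------------------
    if cohort.survival is not None:
        t0 = time.perf_counter()
        surv = surv_screen.survival_screen(
            cohort.expression, cohort.survival,
            z_scale=config.survival.z_scale,
            min_events=config.survival.min_events,
            fdr=config.survival.fdr,
            include_logrank=config.survival.include_logrank,
        )
        _emit("survival_associations.tsv", surv)
        logger.info("survival screen done in %.2fs", time.perf_counter() - t0)
    else:
        surv = None
        logger.info("survival.tsv absent; survival screen skipped")

    if cohort.truth:
        report["recovery"] = _recovery_summary(
            cohort, config, freqs, de, meth, essentiality, surv, out_dir
        )
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report["outputs"]["report.json"] = str(report_path)
    return report


def _recovery_summary(cohort, config, freqs, de, meth, essentiality, surv,
                      out_dir) -> dict:
    """Compare screen outputs against the planted-signal truth record."""
    truth = cohort.truth
    summary: dict = {}

    # Differential expression.
    de_idx = de.set_index(["gene", "tissue"])
    found, missed = [], []
    for p in truth.get("planted_de", []):
        if p["log2_effect"] == 0:
            continue
        want = "up" if p["log2_effect"] > 0 else "down"
        key = (p["gene"], p["tumour_type"])
        hit = key in de_idx.index and de_idx.loc[key, "direction"] == want
        (found if hit else missed).append(p)
    planted_keys = {(p["gene"], p["tumour_type"]) for p in truth.get("planted_de", [])}
    fp = [
        {"gene": g, "tissue": t}
        for (g, t), row in de_idx.iterrows()
        if row["direction"] != "ns" and (g, t) not in planted_keys
    ]
    summary["de"] = {"found": found, "missed": missed, "false_positives": fp}

    # Methylation.
    passing = meth[meth["passes"]]
    found, missed = [], []
    planted_probe_keys = set()
    for p in truth.get("planted_meth", []):
        key = (p["gene"], p["tumour_type"])
        planted_probe_keys.add((p.get("probe_id"), p["tumour_type"]))
        hit = (
            (passing["gene"] == p["gene"]) & (passing["tissue"] == p["tumour_type"])
        ).any()
        (found if hit else missed).append(p)
    fp = [
        {"probe_id": r["probe_id"], "tissue": r["tissue"]}
        for _, r in passing.iterrows()
        if (r["probe_id"], r["tissue"]) not in planted_probe_keys
    ]
    summary["methylation"] = {"found": found, "missed": missed, "false_positives": fp}

    # Amplification.
    amp_freqs = freqs[freqs["alteration_class"] == "amplification"]
    found, missed = [], []
    for p in truth.get("planted_amp", []):
        flagged = (
            (amp_freqs["gene"] == p["gene"])
            & (amp_freqs["tumour_type"] == p["tumour_type"])
            & amp_freqs["flagged"]
        ).any()
        assoc = genomic_screen.amplification_expression_association(
            cohort.cnv, cohort.expression, cohort.samples,
            p["gene"], p["tumour_type"],
            min_group_size=config.genomic.min_group_size,
            welch=config.genomic.welch,
        )
        hit = flagged and assoc.evaluable and assoc.p < 0.05 and assoc.log2_fc > 0
        (found if hit else missed).append(p)
    summary["amplification"] = {"found": found, "missed": missed}

    # Hotspots.
    recurrence = genomic_screen.recurrent_mutations(
        cohort.mutations, min_count=config.genomic.min_recurrence
    )
    found, missed = [], []
    for p in truth.get("planted_hotspot", []):
        hit = (
            (recurrence["gene"] == p["gene"])
            & (recurrence["protein_pos"] == p["position"])
            & (recurrence["alt_aa"] == p["alt_residue"])
            & (recurrence["count"] >= p["count"])
        ).any()
        (found if hit else missed).append(p)
    summary["hotspot"] = {"found": found, "missed": missed}

    # Essentiality.
    ess_idx = essentiality.set_index("gene")
    found, missed = [], []
    for p in truth.get("planted_essential", []):
        hit = (
            p["gene"] in ess_idx.index
            and ess_idx.loc[p["gene"], "essentiality_percentile"] >= 95.0
        )
        (found if hit else missed).append(p)
    summary["essential"] = {"found": found, "missed": missed}

    # Compensation.
    found, missed = [], []
    for p in truth.get("planted_compensation", []):
        comp = depend_screen.compensation_screen(
            cohort.gene_effect, cohort.cell_line_expression, p["dependent_gene"]
        )
        top = comp.iloc[0]["candidate_buffer_gene"] if len(comp) else None
        hit = top == p["buffer_gene"]
        (found if hit else missed).append(p)
    summary["compensation"] = {"found": found, "missed": missed}

    # Survival.
    if surv is not None:
        surv_idx = surv.set_index(["gene", "tumour_type"])
        found, missed = [], []
        for p in truth.get("planted_survival", []):
            key = (p["gene"], p["tumour_type"])
            want = "worse_with_high" if p["log_hazard_per_sd"] > 0 else "better_with_high"
            hit = (
                key in surv_idx.index
                and bool(surv_idx.loc[key, "significant"])
                and surv_idx.loc[key, "direction"] == want
            )
            (found if hit else missed).append(p)
        summary["survival"] = {"found": found, "missed": missed}
    return summary
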