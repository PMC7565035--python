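"""Synthetic multi-omic cohort generator with planted, machine-readable signals.

Generates a tumour/normal expression matrix, a methylation beta-value matrix
with probe annotation, a somatic mutation table, thresholded copy-number
calls, a CRISPR gene-effect matrix over cell lines with matched cell-line
expression, and a survival table — all from a single seed, with every
planted signal recorded in a ``truth`` dictionary so downstream screens can
be validated without any external download.

Data models
-----------
* expression: per-gene Gaussian on the log2(x+1) scale with a per-tissue
  offset; planted differential expression shifts tumour samples of one type.
* methylation: Beta-distributed probe values; a planted probe is coupled to
  the gene's within-type expression z-score to hit a target Pearson r, with
  a configured tumour-minus-normal shift of the mean.
* mutations: per-gene Poisson background with rate proportional to ORF
  length, uniform positions, uniform alternate residue; planted hotspots
  contribute exactly ``count`` identical records (alt ``*`` = nonsense).
* CNV: GISTIC-style calls in {-2..2}; a planted amplification puts call +2
  in a fixed fraction of one type's tumour samples and boosts expression.
* gene effect: Gaussian background, N(mean, 0.15) for planted essentials;
  a planted compensation pair couples the dependent gene's effect to the
  buffer gene's cell-line expression z-score.
* survival: exponential event times with hazard multiplied by
  exp(coef * z(expression)); uniform censoring tuned to the configured rate.

A single global seed drives independent per-data-type sub-streams, so adding
signals to one data type never perturbs another type's draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as nio

__all__ = [
    "ConfigError",
    "PlantedDE",
    "PlantedMeth",
    "PlantedAmp",
    "PlantedHotspot",
    "PlantedEssential",
    "PlantedCompensation",
    "PlantedCodependency",
    "PlantedSurvival",
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "write_cohort",
    "null_config",
    "strong_config",
    "survival_config",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
REGION_CLASSES = ("promoter_2kb", "gene_body", "first_intron")
CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "silent")
_CONSEQ_PROBS = (0.72, 0.08, 0.10, 0.05, 0.05)


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


class PlantedDE(NamedTuple):
    gene: str
    tumour_type: str
    log2_effect: float


class PlantedMeth(NamedTuple):
    gene: str
    tumour_type: str
    target_r: float
    delta_beta: float


class PlantedAmp(NamedTuple):
    gene: str
    tumour_type: str
    frequency: float
    log2_boost: float


class PlantedHotspot(NamedTuple):
    gene: str
    position: int
    alt_residue: str  # "*" plants a nonsense (truncating) hotspot
    count: int


class PlantedEssential(NamedTuple):
    gene: str
    mean_effect: float


class PlantedCompensation(NamedTuple):
    dependent_gene: str
    buffer_gene: str
    strength: float


class PlantedCodependency(NamedTuple):
    gene_a: str
    gene_b: str
    strength: float


class PlantedSurvival(NamedTuple):
    gene: str
    tumour_type: str
    log_hazard_per_sd: float


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic cohort."""

    seed: int = 0
    n_genes: int = 30
    n_tumour_types: int = 3
    n_tumour_samples_per_type: int = 30
    n_normal_samples_per_type: int = 30
    n_cell_lines: int = 60

    planted_de: list[PlantedDE] = field(default_factory=list)
    planted_meth: list[PlantedMeth] = field(default_factory=list)
    planted_amp: list[PlantedAmp] = field(default_factory=list)
    planted_hotspot: list[PlantedHotspot] = field(default_factory=list)
    planted_essential: list[PlantedEssential] = field(default_factory=list)
    planted_compensation: list[PlantedCompensation] = field(default_factory=list)
    planted_codependency: list[PlantedCodependency] = field(default_factory=list)
    planted_survival: list[PlantedSurvival] = field(default_factory=list)

    # Background parameters.
    expr_mean: float = 5.0
    expr_sd: float = 0.5
    tissue_offset_sd: float = 0.3
    meth_beta_a: float = 5.0
    meth_beta_b: float = 5.0
    probes_per_gene: int = 3
    mut_rate_per_residue: float = 1e-5  # per residue per tumour sample
    cnv_background_rate: float = 0.01
    effect_sd: float = 0.15
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        self.planted_de = [PlantedDE(*t) for t in self.planted_de]
        self.planted_meth = [PlantedMeth(*t) for t in self.planted_meth]
        self.planted_amp = [PlantedAmp(*t) for t in self.planted_amp]
        self.planted_hotspot = [PlantedHotspot(*t) for t in self.planted_hotspot]
        self.planted_essential = [PlantedEssential(*t) for t in self.planted_essential]
        self.planted_compensation = [
            PlantedCompensation(*t) for t in self.planted_compensation
        ]
        self.planted_codependency = [
            PlantedCodependency(*t) for t in self.planted_codependency
        ]
        self.planted_survival = [PlantedSurvival(*t) for t in self.planted_survival]

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_tumour_types",
            "n_tumour_samples_per_type",
            "n_normal_samples_per_type",
            "n_cell_lines",
            "probes_per_gene",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("expr_sd", "meth_beta_a", "meth_beta_b", "effect_sd",
                     "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.mut_rate_per_residue < 0:
            raise ConfigError("mut_rate_per_residue must be non-negative")
        genes = set(self.gene_symbols())
        types = set(self.tumour_types())
        for i, p in enumerate(self.planted_de):
            self._check_gene_type(genes, types, p.gene, p.tumour_type,
                                  f"planted_de[{i}]")
        for i, p in enumerate(self.planted_meth):
            self._check_gene_type(genes, types, p.gene, p.tumour_type,
                                  f"planted_meth[{i}]")
            if not -1.0 <= p.target_r <= 0.0:
                raise ConfigError(f"planted_meth[{i}].target_r must be in [-1, 0]")
            if not -1.0 <= p.delta_beta <= 1.0:
                raise ConfigError(f"planted_meth[{i}].delta_beta must be in [-1, 1]")
        for i, p in enumerate(self.planted_amp):
            self._check_gene_type(genes, types, p.gene, p.tumour_type,
                                  f"planted_amp[{i}]")
            if not 0.0 <= p.frequency <= 1.0:
                raise ConfigError(f"planted_amp[{i}].frequency must be in [0, 1]")
        for i, p in enumerate(self.planted_hotspot):
            if p.gene not in genes:
                raise ConfigError(f"planted_hotspot[{i}].gene unknown: {p.gene}")
            if p.position < 1:
                raise ConfigError(f"planted_hotspot[{i}].position must be >= 1")
            if p.count < 1:
                raise ConfigError(f"planted_hotspot[{i}].count must be >= 1")
            if p.alt_residue != "*" and p.alt_residue not in _AA:
                raise ConfigError(
                    f"planted_hotspot[{i}].alt_residue must be an amino acid or '*'"
                )
        for i, p in enumerate(self.planted_essential):
            if p.gene not in genes:
                raise ConfigError(f"planted_essential[{i}].gene unknown: {p.gene}")
        for i, p in enumerate(self.planted_compensation):
            if p.dependent_gene not in genes:
                raise ConfigError(
                    f"planted_compensation[{i}].dependent_gene unknown: {p.dependent_gene}"
                )
            if p.buffer_gene not in genes:
                raise ConfigError(
                    f"planted_compensation[{i}].buffer_gene unknown: {p.buffer_gene}"
                )
        for i, p in enumerate(self.planted_codependency):
            if p.gene_a not in genes or p.gene_b not in genes:
                raise ConfigError(f"planted_codependency[{i}] references unknown gene")
        for i, p in enumerate(self.planted_survival):
            self._check_gene_type(genes, types, p.gene, p.tumour_type,
                                  f"planted_survival[{i}]")

    @staticmethod
    def _check_gene_type(genes, types, gene, ttype, label) -> None:
        if gene not in genes:
            raise ConfigError(f"{label}.gene unknown: {gene}")
        if ttype not in types:
            raise ConfigError(f"{label}.tumour_type unknown: {ttype}")

    # -- derived universes ------------------------------------------------

    def gene_symbols(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def tumour_types(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tumour_types)]


@dataclass
class SyntheticCohort:
    """In-memory multi-omic cohort; matrices are genes/probes x samples."""

    genes: pd.DataFrame            # symbol, role, orf_length_aa, nterm_seq
    samples: pd.DataFrame          # sample, tissue, tumour_or_normal, tumour_type
    expression: pd.DataFrame       # log2(x+1) scale, genes x samples
    methylation: pd.DataFrame      # beta in [0, 1], probes x samples
    probes: pd.DataFrame           # probe_id, gene, region
    mutations: pd.DataFrame        # MAF-like
    cnv: pd.DataFrame              # sample, gene, call in {-2..2}
    gene_effect: pd.DataFrame      # genes x cell lines
    cell_line_expression: pd.DataFrame
    survival: pd.DataFrame | None  # sample, tumour_type, time, event
    truth: dict


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_STREAMS = (
    "genes", "expression", "methylation", "mutations",
    "cnv", "gene_effect", "cell_line_expression", "survival",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one cohort; identical configs give bit-identical output."""
    config.validate()
    rng = _rngs(config.seed)
    genes = config.gene_symbols()
    types = config.tumour_types()

    gene_table = _simulate_genes(config, rng["genes"])
    samples = _sample_table(config)
    t_mask = (samples["tumour_or_normal"] == "tumour").to_numpy()

    expression = _simulate_expression(config, gene_table, samples, rng["expression"])
    cnv = _simulate_cnv(config, samples, expression, rng["cnv"])
    methylation, probes = _simulate_methylation(
        config, samples, expression, rng["methylation"]
    )
    mutations = _simulate_mutations(config, gene_table, samples, rng["mutations"])
    gene_effect, cl_expression = _simulate_dependency(
        config, rng["gene_effect"], rng["cell_line_expression"]
    )
    survival = _simulate_survival(config, samples, expression, rng["survival"])

    truth = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "tumour_types": types,
        "planted_de": [p._asdict() for p in config.planted_de],
        "planted_meth": [
            {**p._asdict(), "probe_id": _planted_probe_id(gene_table, p.gene)}
            for p in config.planted_meth
        ],
        "planted_amp": [p._asdict() for p in config.planted_amp],
        "planted_hotspot": [p._asdict() for p in config.planted_hotspot],
        "planted_essential": [p._asdict() for p in config.planted_essential],
        "planted_compensation": [p._asdict() for p in config.planted_compensation],
        "planted_codependency": [p._asdict() for p in config.planted_codependency],
        "planted_survival": [p._asdict() for p in config.planted_survival],
    }
    return SyntheticCohort(
        genes=gene_table,
        samples=samples,
        expression=expression,
        methylation=methylation,
        probes=probes,
        mutations=mutations,
        cnv=cnv,
        gene_effect=gene_effect,
        cell_line_expression=cl_expression,
        survival=survival,
        truth=truth,
    )


def _simulate_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    symbols = config.gene_symbols()
    roles = [("catalytic", "auxiliary", "paralog")[i % 3] for i in range(len(symbols))]
    lengths = rng.integers(150, 900, size=len(symbols))
    aa = np.array(list(_AA))
    nterms = ["M" + "".join(rng.choice(aa, size=9)) for _ in symbols]
    return pd.DataFrame(
        {
            "symbol": symbols,
            "role": roles,
            "orf_length_aa": lengths.astype(int),
            "nterm_seq": nterms,
        }
    )


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for ttype in config.tumour_types():
        for i in range(config.n_tumour_samples_per_type):
            rows.append((f"{ttype}-T{i + 1:04d}", ttype, "tumour", ttype))
        for i in range(config.n_normal_samples_per_type):
            rows.append((f"{ttype}-N{i + 1:04d}", ttype, "normal", ttype))
    return pd.DataFrame(rows, columns=["sample", "tissue", "tumour_or_normal",
                                       "tumour_type"])


def _simulate_expression(
    config: SimConfig,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    symbols = list(genes["symbol"])
    sample_ids = list(samples["sample"])
    n_g, n_s = len(symbols), len(sample_ids)
    gene_means = rng.normal(config.expr_mean, 1.0, size=n_g)
    tissue_offsets = rng.normal(
        0.0, config.tissue_offset_sd, size=(n_g, config.n_tumour_types)
    )
    tissue_idx = pd.Categorical(
        samples["tissue"], categories=config.tumour_types()
    ).codes
    values = (
        gene_means[:, None]
        + tissue_offsets[:, tissue_idx]
        + rng.normal(0.0, config.expr_sd, size=(n_g, n_s))
    )
    expr = pd.DataFrame(values, index=pd.Index(symbols, name="gene"),
                        columns=sample_ids)
    is_tumour = (samples["tumour_or_normal"] == "tumour").to_numpy()
    for p in config.planted_de:
        mask = is_tumour & (samples["tumour_type"] == p.tumour_type).to_numpy()
        expr.loc[p.gene, np.array(sample_ids)[mask]] += p.log2_effect
    # Floor at zero: log2(x+1) values are non-negative.
    return expr.clip(lower=0.0)


def _simulate_cnv(
    config: SimConfig,
    samples: pd.DataFrame,
    expression: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows: list[tuple[str, str, int]] = []
    sample_ids = samples["sample"].to_numpy()
    is_tumour = (samples["tumour_or_normal"] == "tumour").to_numpy()
    # Sparse background of low-level gains/losses in tumour samples.
    tumour_ids = sample_ids[is_tumour]
    for gene in expression.index:
        hit = rng.random(len(tumour_ids)) < config.cnv_background_rate
        calls = rng.choice([-1, 1], size=int(hit.sum()))
        rows.extend(
            (sid, gene, int(call)) for sid, call in zip(tumour_ids[hit], calls)
        )
    for p in config.planted_amp:
        mask = is_tumour & (samples["tumour_type"] == p.tumour_type).to_numpy()
        type_tumours = sample_ids[mask]
        n_carriers = int(round(p.frequency * len(type_tumours)))
        carriers = rng.choice(type_tumours, size=n_carriers, replace=False)
        for sid in carriers:
            rows.append((sid, p.gene, 2))
            expression.loc[p.gene, sid] += p.log2_boost
    df = pd.DataFrame(rows, columns=["sample", "gene", "call"])
    # Planted +2 wins over any background call for the same (sample, gene).
    df = (
        df.sort_values("call", key=lambda s: s.abs(), kind="stable")
        .drop_duplicates(["sample", "gene"], keep="last")
        .sort_values(["sample", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return df


def _planted_probe_id(genes: pd.DataFrame, gene: str) -> str:
    """The planted probe for a gene is its first (promoter) probe."""
    idx = list(genes["symbol"]).index(gene)
    return f"cg{idx + 1:06d}_1"


def _simulate_methylation(
    config: SimConfig,
    samples: pd.DataFrame,
    expression: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    symbols = list(expression.index)
    sample_ids = list(samples["sample"])
    probe_rows = []
    for gi, gene in enumerate(symbols):
        for k in range(config.probes_per_gene):
            probe_rows.append(
                (f"cg{gi + 1:06d}_{k + 1}", gene, REGION_CLASSES[k % 3])
            )
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene", "region"])
    beta = rng.beta(
        config.meth_beta_a, config.meth_beta_b,
        size=(len(probes), len(sample_ids)),
    )
    meth = pd.DataFrame(beta, index=pd.Index(probes["probe_id"], name="probe_id"),
                        columns=sample_ids)
    is_tumour = (samples["tumour_or_normal"] == "tumour").to_numpy()
    for p in config.planted_meth:
        probe_id = _planted_probe_id(
            pd.DataFrame({"symbol": symbols}), p.gene
        )
        t_mask = is_tumour & (samples["tumour_type"] == p.tumour_type).to_numpy()
        n_mask = ~is_tumour & (samples["tumour_type"] == p.tumour_type).to_numpy()
        t_ids = np.array(sample_ids)[t_mask]
        n_ids = np.array(sample_ids)[n_mask]
        z = _zscore(expression.loc[p.gene, t_ids].to_numpy())
        noise = rng.normal(size=len(t_ids))
        r = p.target_r
        latent = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
        meth.loc[probe_id, t_ids] = np.clip(
            0.5 + p.delta_beta + 0.08 * latent, 0.01, 0.99
        )
        meth.loc[probe_id, n_ids] = np.clip(
            0.5 + 0.08 * rng.normal(size=len(n_ids)), 0.01, 0.99
        )
    return meth, probes


def _simulate_mutations(
    config: SimConfig,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tumour = samples[samples["tumour_or_normal"] == "tumour"]
    tumour_ids = tumour["sample"].to_numpy()
    type_of = dict(zip(tumour["sample"], tumour["tumour_type"]))
    aa = np.array(list(_AA))
    rows = []
    for _, g in genes.iterrows():
        lam = config.mut_rate_per_residue * int(g["orf_length_aa"]) * len(tumour_ids)
        n_mut = rng.poisson(lam)
        if n_mut == 0:
            continue
        carriers = rng.choice(tumour_ids, size=n_mut, replace=True)
        positions = rng.integers(1, int(g["orf_length_aa"]) + 1, size=n_mut)
        conseq = rng.choice(CONSEQUENCES, size=n_mut, p=_CONSEQ_PROBS)
        for sid, pos, cq in zip(carriers, positions, conseq):
            nterm = g["nterm_seq"]
            ref = nterm[pos - 1] if pos <= len(nterm) else str(rng.choice(aa))
            if cq in ("missense", "silent"):
                alt = str(rng.choice(aa[aa != ref]))
            elif cq == "nonsense":
                alt = "*"
            else:
                alt = "-"  # frameshift/splice: no single alternate residue
            rows.append((sid, g["symbol"], int(pos), ref, alt, cq, type_of[sid]))
    for p in config.planted_hotspot:
        g = genes.loc[genes["symbol"] == p.gene].iloc[0]
        nterm = g["nterm_seq"]
        ref = nterm[p.position - 1] if p.position <= len(nterm) else "Q"
        conseq = "nonsense" if p.alt_residue == "*" else "missense"
        # Distinct carrier samples so each record is one mutated sample.
        carriers = [tumour_ids[i % len(tumour_ids)] for i in range(p.count)]
        for sid in carriers:
            rows.append(
                (sid, p.gene, int(p.position), ref, p.alt_residue, conseq,
                 type_of[sid])
            )
    df = pd.DataFrame(
        rows,
        columns=["sample", "gene", "protein_pos", "ref_aa", "alt_aa",
                 "consequence", "tumour_type"],
    )
    return df.sort_values(
        ["gene", "protein_pos", "sample"], kind="stable"
    ).reset_index(drop=True)


def _simulate_dependency(
    config: SimConfig,
    rng_effect: np.random.Generator,
    rng_expr: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    symbols = config.gene_symbols()
    lines = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    effect = pd.DataFrame(
        rng_effect.normal(0.0, config.effect_sd, size=(len(symbols), len(lines))),
        index=pd.Index(symbols, name="gene"), columns=lines,
    )
    cl_expr = pd.DataFrame(
        rng_expr.normal(config.expr_mean, 1.0, size=(len(symbols), len(lines))),
        index=pd.Index(symbols, name="gene"), columns=lines,
    )
    for p in config.planted_essential:
        effect.loc[p.gene] = rng_effect.normal(
            p.mean_effect, config.effect_sd, size=len(lines)
        )
    for p in config.planted_codependency:
        latent = rng_effect.normal(size=len(lines))
        for gene in (p.gene_a, p.gene_b):
            effect.loc[gene] = (
                -0.5
                + p.strength * latent
                + rng_effect.normal(0.0, config.effect_sd, size=len(lines))
            )
    for p in config.planted_compensation:
        z = _zscore(cl_expr.loc[p.buffer_gene].to_numpy())
        effect.loc[p.dependent_gene] = (
            -0.8
            + p.strength * z
            + rng_effect.normal(0.0, config.effect_sd, size=len(lines))
        )
    return effect, cl_expr


def _censoring_horizon(baseline_hazard: float, rate: float) -> float:
    """Upper bound of the Uniform(0, u) censoring time giving the target rate.

    Under the null hazard, P(censored) = (1 - exp(-h u)) / (h u); solve for u.
    """
    if rate <= 0:
        return np.inf

    def f(u: float) -> float:
        x = baseline_hazard * u
        return (1.0 - np.exp(-x)) / x - rate

    return brentq(f, 1e-9 / baseline_hazard, 1e9 / baseline_hazard)


def _simulate_survival(
    config: SimConfig,
    samples: pd.DataFrame,
    expression: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tumour = samples[samples["tumour_or_normal"] == "tumour"]
    lp = pd.Series(0.0, index=tumour["sample"].to_numpy())
    for p in config.planted_survival:
        ids = tumour.loc[tumour["tumour_type"] == p.tumour_type, "sample"].to_numpy()
        z = _zscore(expression.loc[p.gene, ids].to_numpy())
        lp.loc[ids] += p.log_hazard_per_sd * z
    hazard = config.baseline_hazard * np.exp(lp.to_numpy())
    event_time = rng.exponential(1.0 / hazard)
    horizon = _censoring_horizon(config.baseline_hazard, config.censoring_rate)
    if np.isinf(horizon):
        censor_time = np.full(len(event_time), np.inf)
    else:
        censor_time = rng.uniform(0.0, horizon, size=len(event_time))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample": tumour["sample"].to_numpy(),
            "tumour_type": tumour["tumour_type"].to_numpy(),
            "time": time,
            "event": event,
        }
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, str]:
    """Write a cohort to TSV/JSON files; returns {name: path} manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _write(name: str, writer, *args) -> None:
        path = directory / name
        writer(*args, path)
        manifest[name] = str(path)

    _write("genes.tsv", nio.write_table, cohort.genes)
    _write("samples.tsv", nio.write_table, cohort.samples)
    _write("expression.tsv", nio.write_matrix, cohort.expression)
    _write("methylation.tsv", nio.write_matrix, cohort.methylation)
    _write("probes.tsv", nio.write_table, cohort.probes)
    _write("mutations.tsv", nio.write_table, cohort.mutations)
    _write("cnv.tsv", nio.write_table, cohort.cnv)
    _write("gene_effect.tsv", nio.write_matrix, cohort.gene_effect)
    _write("cell_line_expression.tsv", nio.write_matrix, cohort.cell_line_expression)
    if cohort.survival is not None:
        _write("survival.tsv", nio.write_table, cohort.survival)
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=2, sort_keys=True) + "\n")
    manifest["truth.json"] = str(truth_path)
    return manifest


# ---------------------------------------------------------------------------
# Canonical configurations
# ---------------------------------------------------------------------------

def null_config(seed: int, **overrides) -> SimConfig:
    """A cohort with no planted signals: every screen should be null-calibrated."""
    return SimConfig(seed=seed, **overrides)


def strong_config(seed: int) -> SimConfig:
    """Documented 'strong' planted defaults used for signal-recovery checks.

    One gene per signal class; the methylation target gene also carries a
    differential-expression effect so the expression-change gate of the
    methylation screen is satisfiable.
    """
    return SimConfig(
        seed=seed,
        n_genes=30,
        n_tumour_types=3,
        n_tumour_samples_per_type=30,
        n_normal_samples_per_type=30,
        n_cell_lines=60,
        planted_de=[("G0001", "T01", 1.0), ("G0002", "T01", 1.0)],
        planted_meth=[("G0002", "T01", -0.6, -0.2)],
        planted_amp=[("G0003", "T01", 0.12, 1.0)],
        planted_hotspot=[("G0004", 7, "*", 5)],
        planted_essential=[("G0005", -1.0)],
        planted_compensation=[("G0006", "G0007", 0.6)],
        planted_survival=[("G0008", "T01", 0.7)],
    )


def survival_config(seed: int, log_hazard_per_sd: float = 0.7,
                    n_tumour_samples: int = 200) -> SimConfig:
    """Survival-recovery default: one planted hazard effect at larger n.

    Survival power needs more samples than the 30/30 groups used by the
    expression-level signals, so it gets its own cohort shape.
    """
    return SimConfig(
        seed=seed,
        n_genes=20,
        n_tumour_types=2,
        n_tumour_samples_per_type=n_tumour_samples,
        n_normal_samples_per_type=10,
        n_cell_lines=20,
        planted_survival=[("G0001", "T01", log_hazard_per_sd)],
    )
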