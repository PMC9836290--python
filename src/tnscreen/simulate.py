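"""Synthetic transposon insertion libraries under a survival bottleneck.

The generator reproduces the screen's generative structure so the analysis
is exercisable end to end without deposited sequencing data:

* a genome tiled with non-overlapping genes and intergenic gaps;
* a pooled library of unique insertion sites (~1 site per 37 bp and ~19
  sites per non-essential gene at full screen scale) with log-normal clone
  abundances; essential genes carry no insertions in their internal
  window;
* a lethal one-hour arrest applied only to the treated pool, modeled as a
  single binomial thinning with per-gene survival probability s_g
  (wild-type-like genes share a baseline s0; mutants of protective genes
  have s_g < s0 and end up depleted, mutants of detrimental genes have
  s_g > s0 and end up enriched);
* exponential regrowth during recovery in which the treated pool lags the
  control by one generation (the treated sample at t hours has grown
  (t - 1) * generations_per_hour generations, the control t *
  generations_per_hour);
* multinomial read sampling at a configurable depth per library.

Planted truth is returned for recovery evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GeneModel, InsertionProfile, SampleMeta
from .pipeline import internal_window

__all__ = [
    "SimConfig",
    "SimTruth",
    "Library",
    "RecoverySummary",
    "simulate_annotation",
    "plant_truth",
    "simulate_library",
    "simulate_experiment",
    "evaluate_recovery",
]

_CLASSES = ("neutral", "protective", "detrimental", "essential")


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are desk-scale (500 kb genome, 200 genes, 5x10^5 reads per
    library) but preserve the screen's per-bp and per-gene insertion
    densities (one site per 37 bp, ~19 sites per ~700 bp gene);
    :meth:`full_scale` keeps the same densities at full library size
    (10^5 sites on a 3.7 Mb genome).
    """

    genome_length: int = 500_000
    n_genes: int = 200
    gene_length_mean: float = 700.0
    gene_length_sd: float = 200.0
    gene_length_min: int = 120
    #: minimum fraction of the genome left intergenic (placement check)
    intergenic_fraction: float = 0.1
    n_insertions: int = 13_500
    ta_restricted: bool = False
    depth: int = 500_000
    generations_per_hour: float = 1.0
    bottleneck_cells: int = 10_000_000
    #: sigma of the log-normal initial clone abundances
    abundance_sigma: float = 0.5
    #: survival probability of wild-type-like clones through the arrest
    baseline_survival: float = 0.1
    control_times: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    treated_times: tuple[float, ...] = (2.0, 3.0, 4.0)
    #: per-site gamma dispersion of read sampling; 0 disables it
    read_dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_insertions", "depth", "bottleneck_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not (0 <= self.intergenic_fraction < 1):
            raise ValueError("require 0 <= intergenic_fraction < 1")
        if not (0 < self.baseline_survival <= 1):
            raise ValueError("require 0 < baseline_survival <= 1")

    @classmethod
    def full_scale(cls, **overrides) -> "SimConfig":
        """Parameters matching the screen's reported library density:
        10^5 unique sites on a 3.7 Mb genome (one per 37 bp) and ~700 bp
        genes (~19 sites per non-essential gene)."""
        params = dict(
            genome_length=3_700_000,
            n_genes=4_200,
            gene_length_mean=700.0,
            gene_length_sd=200.0,
            gene_length_min=120,
            intergenic_fraction=0.15,
            n_insertions=100_000,
            depth=5_000_000,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("control_times", "treated_times"):
            if key in data:
                data[key] = tuple(float(t) for t in data[key])
        return cls(**data)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-local generator derived deterministically from the seed."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class SimTruth:
    """Planted per-gene ground truth.

    ``survival`` maps gene_id to the clone survival probability through the
    arrest, ``growth`` to the relative growth multiplier per generation
    during recovery (1 = wild-type), and ``label`` to one of neutral /
    protective / detrimental / essential. ``baseline_survival`` applies to
    intergenic insertions and neutral genes.
    """

    baseline_survival: float
    survival: dict[str, float] = field(default_factory=dict)
    growth: dict[str, float] = field(default_factory=dict)
    label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s0 = self.baseline_survival
        for gene_id, lab in self.label.items():
            s = self.survival[gene_id]
            if lab == "protective" and not s < s0:
                raise ValueError(f"{gene_id}: protective gene needs survival < baseline")
            if lab == "detrimental" and not s > s0:
                raise ValueError(f"{gene_id}: detrimental gene needs survival > baseline")
            if lab not in _CLASSES:
                raise ValueError(f"{gene_id}: unknown class {lab!r}")

    def genes_with_label(self, lab: str) -> list[str]:
        return [g for g, x in self.label.items() if x == lab]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("gene_id\tclass\tsurvival\tgrowth\n")
            out.write(f"__baseline__\tneutral\t{self.baseline_survival:.6g}\t1\n")
            for gene_id in self.label:
                out.write(
                    f"{gene_id}\t{self.label[gene_id]}\t"
                    f"{self.survival[gene_id]:.6g}\t{self.growth[gene_id]:.6g}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t")
        base = df[df["gene_id"] == "__baseline__"]
        if len(base) != 1:
            raise ValueError(f"{path}: missing __baseline__ row")
        s0 = float(base["survival"].iloc[0])
        df = df[df["gene_id"] != "__baseline__"]
        return cls(
            baseline_survival=s0,
            survival=dict(zip(df["gene_id"], df["survival"].astype(float))),
            growth=dict(zip(df["gene_id"], df["growth"].astype(float))),
            label=dict(zip(df["gene_id"], df["class"])),
        )


@dataclass
class Library:
    """A pooled insertion library: distinct sites with clone abundances."""

    contig: str
    positions: np.ndarray  # sorted, 1-based
    abundance: np.ndarray  # relative clone abundances, same length
    gene_index: np.ndarray  # index into the annotation, -1 = intergenic
    genes: list[GeneModel]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class RecoverySummary:
    """Confusion summary of screen verdicts against planted truth."""

    tp: int
    fn: int
    fp: int
    tn: int
    sign_errors: int
    sensitivity: float
    specificity: float
    sign_accuracy: float


# ---------------------------------------------------------------------------
# Genome / annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> tuple[list[GeneModel], str | None]:
    """Tile non-overlapping genes with intergenic gaps along one contig.

    Gene lengths are normal (mean, sd) truncated at the minimum; gaps share
    the remaining sequence via a uniform multinomial split (each gap at
    least 1 bp). Reproducible under a fixed seed. Returns the gene list
    and, when ``ta_restricted`` is set, the random genome sequence.
    Raises if the requested genes cannot fit in the genome.
    """
    rng = config.rng(stage=1)
    n = config.n_genes
    lengths = np.maximum(
        np.rint(rng.normal(config.gene_length_mean, config.gene_length_sd, size=n)),
        config.gene_length_min,
    ).astype(np.int64)
    budget = math.floor(config.genome_length * (1 - config.intergenic_fraction))
    if int(lengths.sum()) > budget or int(lengths.sum()) + n + 1 > config.genome_length:
        raise ValueError(
            f"genes cannot fit: {int(lengths.sum())} gene bp exceeds the "
            f"{budget} bp budget of a {config.genome_length} bp genome "
            f"(intergenic_fraction={config.intergenic_fraction:g})"
        )
    spare = config.genome_length - int(lengths.sum()) - (n + 1)
    gaps = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1))) + 1 if n >= 0 else []
    strands = rng.choice(["+", "-"], size=n)
    genes = []
    cursor = 0
    width = len(str(max(n, 1)))
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor + 1
        end = cursor + int(lengths[i])
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:0{width}d}",
                contig="chr1",
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        cursor = end
    sequence = None
    if config.ta_restricted:
        seq_rng = config.rng(stage=5)
        sequence = "".join(
            np.array(list("ACGT"))[seq_rng.integers(0, 4, size=config.genome_length)]
        )
    return genes, sequence


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def plant_truth(
    genes: Sequence[GeneModel],
    config: SimConfig,
    n_protective: int = 10,
    n_detrimental: int = 10,
    n_essential: int = 10,
    protective_factor: float = 0.1,
    detrimental_factor: float = 10.0,
    growth_rates: dict[str, float] | None = None,
) -> SimTruth:
    """Assign planted fitness classes to a random subset of genes.

    Protective genes (their mutants die: survival s0 * protective_factor),
    detrimental genes (their mutants thrive: min(1, s0 *
    detrimental_factor)), and essential genes (no insertions at all) are
    drawn disjointly at random; every other gene is neutral at the
    baseline. ``growth_rates`` overrides per-gene recovery growth
    multipliers (default 1 everywhere).
    """
    rng = config.rng(stage=2)
    n_special = n_protective + n_detrimental + n_essential
    if n_special > len(genes):
        raise ValueError("more planted genes requested than genes available")
    chosen = rng.choice(len(genes), size=n_special, replace=False)
    s0 = config.baseline_survival
    survival = {g.gene_id: s0 for g in genes}
    growth = {g.gene_id: 1.0 for g in genes}
    label = {g.gene_id: "neutral" for g in genes}
    for idx in chosen[:n_protective]:
        gid = genes[idx].gene_id
        survival[gid] = s0 * protective_factor
        label[gid] = "protective"
    for idx in chosen[n_protective : n_protective + n_detrimental]:
        gid = genes[idx].gene_id
        survival[gid] = min(1.0, s0 * detrimental_factor)
        label[gid] = "detrimental"
    for idx in chosen[n_protective + n_detrimental :]:
        gid = genes[idx].gene_id
        label[gid] = "essential"
    if growth_rates:
        growth.update(growth_rates)
    return SimTruth(
        baseline_survival=s0, survival=survival, growth=growth, label=label
    )


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------

def simulate_library(
    annotation: Sequence[GeneModel],
    config: SimConfig,
    truth: SimTruth | None = None,
    sequence: str | None = None,
) -> Library:
    """Sample distinct insertion sites and initial clone abundances.

    Sites are uniform over genomic positions (or over TA dinucleotides of
    ``sequence`` when ``ta_restricted``), excluding the internal windows of
    essential genes. Initial clone abundances are log-normal. Raises when
    more sites are requested than candidate positions exist.
    """
    rng = config.rng(stage=3)
    if config.ta_restricted:
        if sequence is None:
            raise ValueError("ta_restricted requires the genome sequence")
        arr = np.frombuffer(sequence.encode(), dtype="S1")
        candidates = np.flatnonzero((arr[:-1] == b"T") & (arr[1:] == b"A")) + 1
    else:
        candidates = np.arange(1, config.genome_length + 1, dtype=np.int64)
    if truth is not None:
        mask = np.ones(len(candidates), dtype=bool)
        for gene in annotation:
            if truth.label.get(gene.gene_id) == "essential":
                ws, we = internal_window(gene)
                mask &= ~((candidates >= ws) & (candidates <= we))
        candidates = candidates[mask]
    if config.n_insertions > len(candidates):
        raise ValueError(
            f"n_insertions={config.n_insertions} exceeds the "
            f"{len(candidates)} available sites"
        )
    positions = np.sort(
        rng.choice(candidates, size=config.n_insertions, replace=False, shuffle=False)
    )
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(positions))
    # assign each site to the gene body containing it (-1 = intergenic)
    starts = np.array([g.start for g in annotation], dtype=np.int64)
    ends = np.array([g.end for g in annotation], dtype=np.int64)
    gene_index = np.full(len(positions), -1, dtype=np.int64)
    if len(annotation):
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions <= ends[np.clip(idx, 0, None)])
        gene_index[valid] = idx[valid]
    return Library(
        contig=annotation[0].contig if annotation else "chr1",
        positions=positions,
        abundance=abundance,
        gene_index=gene_index,
        genes=list(annotation),
    )


# ---------------------------------------------------------------------------
# Experiment
# ---------------------------------------------------------------------------

def simulate_experiment(
    library: Library,
    truth: SimTruth,
    config: SimConfig,
) -> tuple[list[InsertionProfile], list[SampleMeta]]:
    """Run the pooled screen forward: split, arrest, regrow, sequence.

    The library is split into a control and a treated pool (independent
    multinomial draws of ``bottleneck_cells`` cells from the clone
    abundances). Treated clones survive the arrest with per-gene
    probability s_g (binomial thinning); both pools then regrow
    exponentially, the treated pool one generation behind (at t hours:
    (t - 1) * generations_per_hour generations vs t *
    generations_per_hour). Each harvested library is a multinomial read
    sample of ``depth`` reads from the clone proportions. Returns the
    profiles and a matching sample sheet.
    """
    rng = config.rng(stage=4)
    n = len(library)
    w = library.abundance / library.abundance.sum()
    s = np.full(n, truth.baseline_survival)
    g = np.ones(n)
    for i, gi in enumerate(library.gene_index):
        if gi >= 0:
            gid = library.genes[gi].gene_id
            s[i] = truth.survival.get(gid, truth.baseline_survival)
            g[i] = truth.growth.get(gid, 1.0)

    control_cells = rng.multinomial(config.bottleneck_cells, w)
    treated_cells = rng.multinomial(config.bottleneck_cells, w)
    survivors = rng.binomial(treated_cells, s)

    profiles, sheet = [], []

    def _harvest(cells: np.ndarray, generations: float, sample_id: str) -> InsertionProfile:
        mass = cells * np.exp2(g * generations)
        total = mass.sum()
        if config.depth == 0 or total == 0:
            reads = np.zeros(n, dtype=np.int64)
        else:
            p = mass / total
            if config.read_dispersion > 0:
                shape = 1.0 / config.read_dispersion
                p = p * rng.gamma(shape, config.read_dispersion, size=n)
                p = p / p.sum()
            reads = rng.multinomial(config.depth, p)
        counts = {
            (library.contig, int(library.positions[i])): int(reads[i])
            for i in np.flatnonzero(reads)
        }
        return InsertionProfile(sample_id=sample_id, counts=counts)

    for t in config.control_times:
        sid = f"control_{t:g}h"
        profiles.append(_harvest(control_cells, t * config.generations_per_hour, sid))
        sheet.append(SampleMeta(sid, "control", float(t), 1))
    for t in config.treated_times:
        sid = f"treated_{t:g}h"
        profiles.append(_harvest(survivors, (t - 1.0) * config.generations_per_hour, sid))
        sheet.append(SampleMeta(sid, "treated", float(t), 1))
    return profiles, sheet


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(
    verdicts: "Mapping[str, ScreenVerdict] | Sequence[ScreenVerdict]",
    truth: SimTruth,
) -> RecoverySummary:
    """Score screen verdicts against the planted truth.

    Planted positives are the protective and detrimental genes. A true
    positive is a hit whose direction matches the planted one (protective
    -> depleted_hit, detrimental -> enriched_hit); a hit on a planted gene
    with the wrong sign counts as a sign error and a miss, not a true
    positive. Specificity is computed over the genes planted neutral or
    essential. Sign accuracy is the fraction of hits on planted genes with
    the correct sign (nan when there are none). Raises when the gene
    universes differ.
    """
    if not isinstance(verdicts, Mapping):
        verdicts = {v.gene_id: v for v in verdicts}
    if set(verdicts) != set(truth.label):
        raise ValueError("verdicts and truth cover different gene universes")
    expected = {"protective": "depleted_hit", "detrimental": "enriched_hit"}
    tp = fn = fp = tn = sign_errors = 0
    for gene_id, v in verdicts.items():
        lab = truth.label[gene_id]
        is_hit = v.verdict in ("depleted_hit", "enriched_hit")
        if lab in expected:
            if not is_hit:
                fn += 1
            elif v.verdict == expected[lab]:
                tp += 1
            else:
                sign_errors += 1
                fn += 1
        else:
            if is_hit:
                fp += 1
            else:
                tn += 1
    n_pos, n_neg = tp + fn, fp + tn
    n_planted_hits = tp + sign_errors
    return RecoverySummary(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sign_errors=sign_errors,
        sensitivity=tp / n_pos if n_pos else math.nan,
        specificity=tn / n_neg if n_neg else math.nan,
        sign_accuracy=tp / n_planted_hits if n_planted_hits else math.nan,
    )
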