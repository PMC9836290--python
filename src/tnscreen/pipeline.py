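"""The Tn-seq replication-arrest screen analysis.

The pipeline takes per-position insertion read counts for a set of treated
and control libraries and identifies genes whose disruption helps or hurts
survival of a transient replication arrest:

1. discard genomic positions with fewer than ``min_reads_per_position``
   reads (noise from rare insertions or misaligned reads);
2. quantile-normalize the samples so their count distributions are
   comparable (rank means, ties averaged);
3. sum normalized reads per gene over the 5–95% internal window (terminal
   insertions are sometimes tolerated even in essential genes, so the gene
   extremities are ignored);
4. pair each treated library with the control harvested one hour earlier —
   the arrested pool is one division generation behind, so generation
   matching is required for abundance ratios to reflect fitness;
5. compute per-gene log2 fold changes of insertion read frequency for each
   matched pair;
6. classify candidates with four hard criteria: gene length > 200 bp, more
   than 5 insertion sites in the final pair's control library,
   |log2 FC| > 1 at the final time, and a change that is amplified (not
   fading) over the recovery time course.

Mutants of genes required for survival are depleted (FC < 0); mutants of
genes detrimental to survival are enriched (FC > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GeneModel, InsertionProfile, SampleMeta

__all__ = [
    "PipelineConfig",
    "GeneSampleStats",
    "FoldChangePair",
    "FoldChangeSeries",
    "ScreenVerdict",
    "ScreenResult",
    "filter_low_coverage",
    "quantile_normalize_matrix",
    "quantile_normalize",
    "internal_window",
    "aggregate_gene",
    "match_samples",
    "log2_fold_change",
    "classify_gene",
    "run_screen",
    "build_results_table",
]

_AMPLIFIED_MODES = ("final_max", "non_decreasing", "strict_increase")
# guard against float-representation error in floor(fraction * length)
_FLOOR_EPS = 1e-9


@dataclass
class PipelineConfig:
    """All thresholds and conventions of the screen, with the defaults used
    throughout.

    Thresholds are strict: a gene of length exactly ``min_gene_length``, a
    control with exactly ``min_control_sites`` sites, or a final
    |log2 FC| exactly ``fc_threshold`` all fail their criterion, while a
    position with exactly ``min_reads_per_position`` reads is retained.
    """

    min_reads_per_position: int = 3
    window_lower: float = 0.05
    window_upper: float = 0.95
    min_gene_length: int = 200
    min_control_sites: int = 5
    fc_threshold: float = 1.0
    pairing_offset_h: float = 1.0
    final_time_h: float = 4.0
    #: "final_max" (|FC| at the final time within amplified_tolerance of the
    #: series maximum), "non_decreasing", or "strict_increase"
    amplified_mode: str = "final_max"
    amplified_tolerance: float = 0.2
    #: divide gene reads by the sample's genome-wide retained total
    use_frequency: bool = True
    #: added to both frequencies before the log-ratio; 0 = no pseudocount
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.window_lower < self.window_upper <= 1):
            raise ValueError("require 0 <= window_lower < window_upper <= 1")
        for name in (
            "min_reads_per_position",
            "min_gene_length",
            "min_control_sites",
            "fc_threshold",
            "pairing_offset_h",
            "amplified_tolerance",
            "pseudocount",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.amplified_mode not in _AMPLIFIED_MODES:
            raise ValueError(f"amplified_mode must be one of {_AMPLIFIED_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


@dataclass(frozen=True)
class GeneSampleStats:
    """Per gene x sample summary over the internal window.

    ``reads`` is the sum of normalized reads at retained positions inside
    the window, ``sites`` the number of such distinct positions, and
    ``frequency`` the reads divided by the sample's genome-wide total of
    retained normalized reads (0 when the total is 0).
    """

    gene_id: str
    sample_id: str
    reads: float
    sites: int
    frequency: float


@dataclass(frozen=True)
class FoldChangePair:
    treated_time_h: float
    control_time_h: float
    log2_fc: float  # may be +/-inf; nan encodes "undefined" (both zero)


@dataclass
class FoldChangeSeries:
    """Generation-matched log2 fold changes for one gene, ordered by
    treated harvest time."""

    gene_id: str
    pairs: list[FoldChangePair] = field(default_factory=list)

    def final(self, final_time_h: float) -> FoldChangePair:
        for p in self.pairs:
            if p.treated_time_h == final_time_h:
                return p
        raise ValueError(
            f"{self.gene_id}: no fold-change pair at treated time {final_time_h} h"
        )

    def defined(self) -> list[FoldChangePair]:
        return [p for p in self.pairs if not math.isnan(p.log2_fc)]


@dataclass(frozen=True)
class ScreenVerdict:
    """Classification of one gene with its four criterion flags.

    ``verdict`` is ``depleted_hit`` / ``enriched_hit`` when all four
    criteria hold (sign of the final FC decides which), ``excluded`` when
    the gene fails an eligibility criterion (length or control sites), and
    ``neutral`` otherwise.
    """

    gene_id: str
    verdict: str
    length_ok: bool
    control_sites_ok: bool
    fc_ok: bool
    amplified_ok: bool


@dataclass
class ScreenResult:
    """Output of :func:`run_screen`."""

    table: pd.DataFrame
    stats: dict[str, list[GeneSampleStats]]  # sample_id -> per-gene stats
    fc_series: dict[str, FoldChangeSeries]  # gene_id -> series (replicate-averaged)
    verdicts: dict[str, ScreenVerdict]
    stage_counts: dict[str, object]


# ---------------------------------------------------------------------------
# Stage 1: position filter
# ---------------------------------------------------------------------------

def filter_low_coverage(profile: InsertionProfile, min_reads: int) -> InsertionProfile:
    """Drop positions with fewer than ``min_reads`` reads.

    The boundary is retained: a position with exactly ``min_reads`` reads
    survives. The input profile is not modified.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    kept = {pos: c for pos, c in profile.counts.items() if c >= min_reads}
    return InsertionProfile(profile.sample_id, kept)


# ---------------------------------------------------------------------------
# Stage 2: quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a (positions x samples) matrix.

    Each column's values are replaced by the across-sample means of the
    sorted columns (rank means), reassigned by within-column rank; tied
    values receive the mean of the rank-means their ranks span. After
    normalization every column has the identical sorted vector and the
    identical sum; within-column rank order is preserved.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (positions x samples) matrix")
    n_obs, n_samples = X.shape
    if n_obs == 0 or n_samples == 0:
        return X.copy()
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_obs)
        assigned[order] = rank_means
        # average assigned values over groups of equal input values
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return out


def quantile_normalize(profiles: Sequence[InsertionProfile]) -> list[InsertionProfile]:
    """Quantile-normalize a set of (already filtered) sparse profiles.

    The rank-mean construction needs equal-length vectors, so it runs over
    the union of positions retained in at least one sample, with zeros
    filled in for samples lacking a position. Each output profile keeps its
    own input key set (the zero-filled union rows participate only in the
    rank construction); within-sample rank order is preserved.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    keys = sorted({pos for p in profiles for pos in p.counts})
    if not keys:
        return [p.copy() for p in profiles]
    index = {pos: i for i, pos in enumerate(keys)}
    X = np.zeros((len(keys), len(profiles)))
    for j, p in enumerate(profiles):
        for pos, c in p.counts.items():
            X[index[pos], j] = c
    Xn = quantile_normalize_matrix(X)
    out = []
    for j, p in enumerate(profiles):
        out.append(
            InsertionProfile(
                p.sample_id, {pos: float(Xn[index[pos], j]) for pos in p.counts}
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage 3: per-gene aggregation over the internal window
# ---------------------------------------------------------------------------

def internal_window(
    gene: GeneModel, lower: float = 0.05, upper: float = 0.95
) -> tuple[int, int]:
    """1-based inclusive internal window of a gene.

    ``win_start = start + floor(lower * L)`` and
    ``win_end = end - floor((1 - upper) * L)``; strand-independent, since
    tolerated terminal insertions occur at both gene extremities. For tiny
    genes the window can be empty (win_start > win_end); such genes
    contribute zero reads.
    """
    if not (0 <= lower < upper <= 1):
        raise ValueError("require 0 <= lower < upper <= 1")
    L = gene.length
    ws = gene.start + math.floor(lower * L + _FLOOR_EPS)
    we = gene.end - math.floor((1 - upper) * L + _FLOOR_EPS)
    return ws, we


def aggregate_gene(
    profile: InsertionProfile,
    genes: Sequence[GeneModel],
    config: PipelineConfig | None = None,
) -> list[GeneSampleStats]:
    """Summarize one (filtered, normalized) sample per gene.

    Sums retained normalized reads and counts distinct retained sites
    inside each gene's internal window; ``frequency`` divides by the
    sample's genome-wide retained total. A position inside two overlapping
    genes' windows counts for both. Genes on contigs absent from the
    profile get reads = sites = 0.
    """
    config = config or PipelineConfig()
    total = profile.total()
    # per-contig sorted position/count arrays for O(log n) window queries
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, float]]] = {}
    for (contig, pos), c in profile.counts.items():
        tmp.setdefault(contig, []).append((pos, c))
    for contig, items in tmp.items():
        items.sort()
        positions = np.array([p for p, _ in items], dtype=np.int64)
        cumsum = np.concatenate([[0.0], np.cumsum([c for _, c in items])])
        by_contig[contig] = (positions, cumsum)

    stats = []
    for gene in genes:
        ws, we = internal_window(gene, config.window_lower, config.window_upper)
        reads, sites = 0.0, 0
        if ws <= we and gene.contig in by_contig:
            positions, cumsum = by_contig[gene.contig]
            lo = int(np.searchsorted(positions, ws, side="left"))
            hi = int(np.searchsorted(positions, we, side="right"))
            sites = hi - lo
            reads = float(cumsum[hi] - cumsum[lo])
        frequency = reads / total if total > 0 else 0.0
        stats.append(
            GeneSampleStats(
                gene_id=gene.gene_id,
                sample_id=profile.sample_id,
                reads=reads,
                sites=sites,
                frequency=frequency,
            )
        )
    return stats


# ---------------------------------------------------------------------------
# Stage 4: generation-matched pairing
# ---------------------------------------------------------------------------

def match_samples(
    sheet: Sequence[SampleMeta], offset_h: float = 1.0
) -> list[tuple[SampleMeta, SampleMeta]]:
    """Pair each treated sample with the control harvested ``offset_h``
    earlier, within the same replicate.

    The arrested pool is one division generation behind, so the treated
    sample at t hours is compared with the control at t - offset hours.
    Pairing is mandatory: a treated sample with no matching control raises
    ``ValueError`` listing the orphans. Unpaired controls are ignored.
    Pairs are returned sorted by treated time (then replicate).
    """
    controls = {
        (s.replicate, round(s.time_h, 6)): s for s in sheet if s.condition == "control"
    }
    treated = [s for s in sheet if s.condition == "treated"]
    pairs, orphans = [], []
    for t in sorted(treated, key=lambda s: (s.time_h, s.replicate)):
        key = (t.replicate, round(t.time_h - offset_h, 6))
        if key in controls:
            pairs.append((t, controls[key]))
        else:
            orphans.append(t.sample_id)
    if orphans:
        raise ValueError(
            "treated sample(s) with no control at t - "
            f"{offset_h:g} h (same replicate): {', '.join(orphans)}"
        )
    return pairs


# ---------------------------------------------------------------------------
# Stage 5: log2 fold change
# ---------------------------------------------------------------------------

def log2_fold_change(
    treated: GeneSampleStats,
    control: GeneSampleStats,
    config: PipelineConfig | None = None,
) -> float:
    """log2 of the treated/control insertion read frequency ratio.

    Returns +inf when only the control frequency is zero, -inf when only
    the treated frequency is zero, and nan (undefined) when both are zero.
    With ``use_frequency=False`` the raw normalized read sums are compared
    instead; a positive ``pseudocount`` is added to both values first.
    """
    if treated.gene_id != control.gene_id:
        raise ValueError(
            f"gene mismatch: {treated.gene_id!r} vs {control.gene_id!r}"
        )
    config = config or PipelineConfig()
    attr = "frequency" if config.use_frequency else "reads"
    t = getattr(treated, attr) + config.pseudocount
    c = getattr(control, attr) + config.pseudocount
    if t == 0 and c == 0:
        return math.nan
    if c == 0:
        return math.inf
    if t == 0:
        return -math.inf
    return math.log2(t / c)


# ---------------------------------------------------------------------------
# Stage 6: classification
# ---------------------------------------------------------------------------

def _amplified(series: FoldChangeSeries, final: FoldChangePair, config: PipelineConfig) -> bool:
    """Criterion (iv): the change persists and strengthens over time.

    All defined FCs must share the sign of the final FC, and the change
    must not fade: in the default ``final_max`` mode the final |FC| must be
    the largest of the series within a relative tolerance
    (|FC_final| >= (1 - amplified_tolerance) * max |FC|), which tolerates
    read-sampling noise; ``non_decreasing`` and ``strict_increase``
    demand exactly monotone |FC| step by step.
    """
    if math.isnan(final.log2_fc) or final.log2_fc == 0:
        return False
    defined = series.defined()
    sign = math.copysign(1.0, final.log2_fc)
    for p in defined:
        if p.log2_fc == 0 or math.copysign(1.0, p.log2_fc) != sign:
            return False
    mags = [abs(p.log2_fc) for p in defined]
    if config.amplified_mode == "final_max":
        final_mag = abs(final.log2_fc)
        if math.isinf(final_mag):
            return True
        return final_mag >= (1.0 - config.amplified_tolerance) * max(mags)
    for prev, cur in zip(mags, mags[1:]):
        if config.amplified_mode == "strict_increase":
            if not cur > prev:
                return False
        else:  # non_decreasing
            if not cur >= prev:
                return False
    return True


def classify_gene(
    gene: GeneModel,
    control_sites_at_final_pair: int,
    fc: FoldChangeSeries,
    config: PipelineConfig | None = None,
) -> ScreenVerdict:
    """Apply the four candidate criteria to one gene.

    (i) length strictly greater than ``min_gene_length``; (ii) strictly
    more than ``min_control_sites`` distinct insertion sites in the control
    library of the final pair; (iii) |log2 FC| strictly greater than
    ``fc_threshold`` at the final time; (iv) an amplified change over the
    time course (see :func:`_amplified`). A gene failing (i) or (ii) is
    ``excluded``; one failing only (iii)/(iv) is ``neutral``; otherwise the
    sign of the final FC decides ``depleted_hit`` (< 0) vs
    ``enriched_hit`` (> 0).
    """
    config = config or PipelineConfig()
    final = fc.final(config.final_time_h)  # raises if the final pair is missing
    length_ok = gene.length > config.min_gene_length
    control_sites_ok = control_sites_at_final_pair > config.min_control_sites
    fc_ok = (not math.isnan(final.log2_fc)) and abs(final.log2_fc) > config.fc_threshold
    amplified_ok = _amplified(fc, final, config)
    if not (length_ok and control_sites_ok):
        verdict = "excluded"
    elif fc_ok and amplified_ok:
        verdict = "depleted_hit" if final.log2_fc < 0 else "enriched_hit"
    else:
        verdict = "neutral"
    return ScreenVerdict(
        gene_id=gene.gene_id,
        verdict=verdict,
        length_ok=length_ok,
        control_sites_ok=control_sites_ok,
        fc_ok=fc_ok,
        amplified_ok=amplified_ok,
    )


# ---------------------------------------------------------------------------
# End to end
# ---------------------------------------------------------------------------

def _mean_defined(values: list[float]) -> float:
    defined = [v for v in values if not math.isnan(v)]
    if not defined:
        return math.nan
    if any(math.isinf(v) for v in defined):
        pos = any(v == math.inf for v in defined)
        neg = any(v == -math.inf for v in defined)
        if pos and neg:
            return math.nan
        return math.inf if pos else -math.inf
    return float(np.mean(defined))


def run_screen(
    profiles: Sequence[InsertionProfile],
    annotation: Sequence[GeneModel],
    sheet: Sequence[SampleMeta],
    config: PipelineConfig | None = None,
) -> ScreenResult:
    """Run the whole screen: filter -> normalize -> aggregate -> pair ->
    fold change -> classify.

    Deterministic given its inputs. With replicated samples, pairing is
    done within replicate and per-gene FCs are averaged across replicates
    (mean of defined values); the criterion-(ii) control site count uses
    the minimum across replicates. Per-stage record counts are returned in
    ``stage_counts``.
    """
    config = config or PipelineConfig()
    by_id = {p.sample_id: p for p in profiles}
    missing = [s.sample_id for s in sheet if s.sample_id not in by_id]
    if missing:
        raise ValueError(f"sample sheet entries without profiles: {missing}")
    sheet = list(sheet)
    used = [by_id[s.sample_id] for s in sheet]

    stage_counts: dict[str, object] = {
        "samples": len(sheet),
        "genes": len(annotation),
        "positions_input": {p.sample_id: p.n_sites() for p in used},
    }

    filtered = [filter_low_coverage(p, config.min_reads_per_position) for p in used]
    stage_counts["positions_retained"] = {p.sample_id: p.n_sites() for p in filtered}

    normalized = quantile_normalize(filtered) if filtered else []
    stage_counts["positions_union"] = len(
        {pos for p in filtered for pos in p.counts}
    )

    stats: dict[str, list[GeneSampleStats]] = {
        p.sample_id: aggregate_gene(p, annotation, config) for p in normalized
    }

    pairs = match_samples(sheet, config.pairing_offset_h)
    stage_counts["pairs"] = [
        (t.sample_id, c.sample_id) for t, c in pairs
    ]

    gene_ids = [g.gene_id for g in annotation]
    # FC per (gene, treated_time) across replicates
    treated_times = sorted({t.time_h for t, _ in pairs})
    per_gene_fc: dict[str, FoldChangeSeries] = {}
    for gi, gene_id in enumerate(gene_ids):
        fc_pairs = []
        for tt in treated_times:
            fcs = [
                log2_fold_change(stats[t.sample_id][gi], stats[c.sample_id][gi], config)
                for t, c in pairs
                if t.time_h == tt
            ]
            fc_pairs.append(
                FoldChangePair(
                    treated_time_h=tt,
                    control_time_h=tt - config.pairing_offset_h,
                    log2_fc=_mean_defined(fcs),
                )
            )
        per_gene_fc[gene_id] = FoldChangeSeries(gene_id=gene_id, pairs=fc_pairs)

    verdicts: dict[str, ScreenVerdict] = {}
    if annotation:
        final_controls = [
            c for t, c in pairs if t.time_h == config.final_time_h
        ]
        if not final_controls:
            raise ValueError(
                f"no matched pair at final_time_h = {config.final_time_h:g} h"
            )
        for gi, gene in enumerate(annotation):
            control_sites = min(
                stats[c.sample_id][gi].sites for c in final_controls
            )
            verdicts[gene.gene_id] = classify_gene(
                gene, control_sites, per_gene_fc[gene.gene_id], config
            )
    stage_counts["hits"] = sum(
        v.verdict in ("depleted_hit", "enriched_hit") for v in verdicts.values()
    )

    table = build_results_table(annotation, sheet, stats, per_gene_fc, verdicts)
    return ScreenResult(
        table=table,
        stats=stats,
        fc_series=per_gene_fc,
        verdicts=verdicts,
        stage_counts=stage_counts,
    )


def build_results_table(
    annotation: Sequence[GeneModel],
    sheet: Sequence[SampleMeta],
    stats: Mapping[str, list[GeneSampleStats]],
    fc_series: Mapping[str, FoldChangeSeries],
    verdicts: Mapping[str, ScreenVerdict],
) -> pd.DataFrame:
    """Assemble the per-gene results table (one row per gene).

    Columns: gene_id, length, ``sites_<sample>`` and ``reads_<sample>`` per
    sample, ``log2_fc_<t>h`` per matched treated time, the four criteria
    flags, and the verdict. Raises on ragged inputs (gene sets that do not
    agree across the pieces).
    """
    gene_ids = [g.gene_id for g in annotation]
    for sid, rows in stats.items():
        if [r.gene_id for r in rows] != gene_ids:
            raise ValueError(f"stats for sample {sid!r} do not match the annotation")
    if annotation and (set(fc_series) != set(gene_ids) or set(verdicts) != set(gene_ids)):
        raise ValueError("fold-change series / verdicts do not cover the annotation")

    ordered_samples = sorted(
        sheet, key=lambda s: (s.condition != "control", s.time_h, s.replicate)
    )
    treated_times = sorted(
        {p.treated_time_h for s in fc_series.values() for p in s.pairs}
    )
    records = []
    for gi, gene in enumerate(annotation):
        rec: dict[str, object] = {"gene_id": gene.gene_id, "length": gene.length}
        for s in ordered_samples:
            rec[f"sites_{s.sample_id}"] = stats[s.sample_id][gi].sites
            rec[f"reads_{s.sample_id}"] = stats[s.sample_id][gi].reads
        series = {p.treated_time_h: p.log2_fc for p in fc_series[gene.gene_id].pairs}
        for tt in treated_times:
            fc = series.get(tt, math.nan)
            rec[f"log2_fc_{tt:g}h"] = math.nan if math.isnan(fc) else fc
        v = verdicts[gene.gene_id]
        rec.update(
            length_ok=v.length_ok,
            control_sites_ok=v.control_sites_ok,
            fc_ok=v.fc_ok,
            amplified_ok=v.amplified_ok,
            verdict=v.verdict,
        )
        records.append(rec)
    if not records:
        cols = ["gene_id", "length"]
        cols += [f"sites_{s.sample_id}" for s in ordered_samples]
        cols += [f"reads_{s.sample_id}" for s in ordered_samples]
        cols += ["length_ok", "control_sites_ok", "fc_ok", "amplified_ok", "verdict"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame.from_records(records)
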