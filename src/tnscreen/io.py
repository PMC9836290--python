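"""Readers and writers for every external representation the screen touches.

Formats
-------
* Annotation: GFF3 (``gene`` features) or a minimal 5-column TSV
  ``gene_id  contig  start  end  strand``.
* Per-position insertion counts: TSV ``contig  position  <sample> ...``,
  one row per genomic coordinate, plus an optional wiggle (variableStep)
  export per sample.
* Sample sheet: TSV ``sample_id  condition  time_h  replicate``.
* Gene-level results: TSV produced by :func:`write_gene_results`.

All coordinates are 1-based inclusive (the GFF3 convention), everywhere.
Count maps are sparse: a position absent from the map is a zero. Counts are
integers until normalization and reals afterwards; writers emit reals with
6 significant digits.
"""

from __future__ import annotations

import csv

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "SampleMeta",
    "InsertionProfile",
    "read_annotation",
    "write_annotation_gff3",
    "write_annotation_tsv",
    "read_insertion_table",
    "write_insertion_table",
    "write_wiggle",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_gene_results",
    "read_gene_results",
]

#: (contig, 1-based position)
Position = tuple[str, int]

_ANNOTATION_COLUMNS = ("gene_id", "contig", "start", "end", "strand")
_SHEET_COLUMNS = ("sample_id", "condition", "time_h", "replicate")
_CONDITIONS = ("treated", "control")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene with 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        """Gene length in bp (end - start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: condition, recovery time, replicate."""

    sample_id: str
    condition: str
    time_h: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(
                f"{self.sample_id}: condition must be one of {_CONDITIONS}, got {self.condition!r}"
            )
        if self.time_h < 0:
            raise ValueError(f"{self.sample_id}: time_h must be non-negative")


@dataclass
class InsertionProfile:
    """Sparse per-sample map from genomic coordinate to read count.

    ``counts`` maps ``(contig, position)`` to a non-negative count; positions
    absent from the map are zeros.
    """

    sample_id: str
    counts: dict[Position, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.counts.items():
            if value < 0:
                raise ValueError(f"{self.sample_id}: negative count at {key}")

    def total(self) -> float:
        """Sum of all retained counts in this sample."""
        return float(sum(self.counts.values()))

    def n_sites(self) -> int:
        """Number of distinct positions with a retained count."""
        return len(self.counts)

    def copy(self) -> "InsertionProfile":
        return InsertionProfile(self.sample_id, dict(self.counts))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _validate_genes(genes: list[GeneModel]) -> list[GeneModel]:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)
    return genes


def _read_annotation_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        strand = feat.strand if feat.strand in ("+", "-") else None
        if strand is None:
            raise ValueError(f"gene {feat.id}: strand must be '+' or '-', got {feat.strand!r}")
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
            )
        )
    return _validate_genes(genes)


def _read_annotation_tsv(path: Path) -> list[GeneModel]:
    genes = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and tuple(c.strip() for c in row) == _ANNOTATION_COLUMNS:
                continue  # optional header
            if len(row) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 tab-separated columns, got {len(row)}"
                )
            gene_id, contig, start_s, end_s, strand = (c.strip() for c in row)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: start/end must be integers"
                ) from exc
            try:
                genes.append(GeneModel(gene_id, contig, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return _validate_genes(genes)


def read_annotation(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read a gene annotation from GFF3 or minimal TSV.

    Parameters
    ----------
    path
        Annotation file. Must exist.
    format
        ``"gff3"`` or ``"tsv"``; inferred from the file extension when None
        (``.gff``, ``.gff3`` → GFF3, anything else → TSV).

    Returns
    -------
    list of GeneModel with 1-based inclusive coordinates, exactly as stored
    in the file. Duplicate gene ids, end < start, or malformed rows raise
    ``ValueError`` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "gff3":
        return _read_annotation_gff3(path)
    if format == "tsv":
        return _read_annotation_tsv(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes as GFF3 ``gene`` features."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                f"{g.contig}\ttnscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_annotation_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes in the minimal 5-column TSV dialect (with header)."""
    with open(path, "w") as out:
        out.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for g in genes:
            out.write(f"{g.gene_id}\t{g.contig}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Insertion count tables
# ---------------------------------------------------------------------------

def read_insertion_table(path: str | Path) -> list[InsertionProfile]:
    """Read a per-position read-count table.

    The table is TSV with header ``contig  position  <sample_id> ...`` and
    integer counts. Returns one sparse :class:`InsertionProfile` per sample
    column; zero cells are omitted from the maps. Negative or non-integer
    counts and duplicate ``(contig, position)`` rows raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["contig", "position"]:
        raise ValueError(
            f"{path}: header must start with 'contig\\tposition', got {list(df.columns[:2])}"
        )
    sample_ids = list(df.columns[2:])
    if df.duplicated(subset=["contig", "position"]).any():
        dup = df[df.duplicated(subset=["contig", "position"])].iloc[0]
        raise ValueError(f"{path}: duplicate row for ({dup['contig']}, {dup['position']})")
    for sid in sample_ids:
        col = df[sid].to_numpy()
        if len(col) == 0:
            continue
        if not np.issubdtype(col.dtype, np.number):
            raise ValueError(f"{path}: non-numeric count in sample {sid!r}")
        if np.any(col < 0):
            raise ValueError(f"{path}: negative count in sample {sid!r}")
        if not np.all(col == np.floor(col)):
            raise ValueError(f"{path}: non-integer count in sample {sid!r}")
    contigs = df["contig"].to_numpy()
    positions = df["position"].to_numpy(dtype=np.int64)
    profiles = []
    for sid in sample_ids:
        col = df[sid].to_numpy()
        nz = np.flatnonzero(col)
        counts = {
            (str(contigs[i]), int(positions[i])): int(col[i]) for i in nz
        }
        profiles.append(InsertionProfile(sample_id=str(sid), counts=counts))
    return profiles


def _format_count(value: float) -> str:
    if float(value) == int(value):
        return str(int(value))
    return format(float(value), ".6g")


def write_insertion_table(profiles: Iterable[InsertionProfile], path: str | Path) -> None:
    """Write sparse profiles as one TSV over the union of their positions.

    Cells for positions a sample lacks are written as 0. Integer counts are
    written as integers, normalized counts with 6 significant digits.
    """
    profiles = list(profiles)
    union: set[Position] = set()
    for p in profiles:
        union.update(p.counts)
    keys = sorted(union)
    with open(path, "w") as out:
        out.write("contig\tposition\t" + "\t".join(p.sample_id for p in profiles) + "\n")
        for contig, pos in keys:
            cells = [_format_count(p.counts.get((contig, pos), 0)) for p in profiles]
            out.write(f"{contig}\t{pos}\t" + "\t".join(cells) + "\n")


def write_wiggle(profile: InsertionProfile, path: str | Path) -> None:
    """Export one sample as a 1-based variableStep wiggle track."""
    by_contig: dict[str, list[tuple[int, float]]] = {}
    for (contig, pos), value in profile.counts.items():
        by_contig.setdefault(contig, []).append((pos, value))
    with open(path, "w") as out:
        out.write(f'track type=wiggle_0 name="{profile.sample_id}"\n')
        for contig in sorted(by_contig):
            out.write(f"variableStep chrom={contig}\n")
            for pos, value in sorted(by_contig[contig]):
                out.write(f"{pos}\t{_format_count(value)}\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the TSV sample sheet ``sample_id condition time_h replicate``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(_SHEET_COLUMNS):
        raise ValueError(f"{path}: expected columns {_SHEET_COLUMNS}, got {list(df.columns)}")
    samples = [
        SampleMeta(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            time_h=float(r.time_h),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
    seen: set[tuple[str, float, int]] = set()
    for s in samples:
        key = (s.condition, s.time_h, s.replicate)
        if key in seen:
            raise ValueError(f"{path}: duplicate (condition, time_h, replicate) {key}")
        seen.add(key)
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_SHEET_COLUMNS) + "\n")
        for s in samples:
            out.write(f"{s.sample_id}\t{s.condition}\t{s.time_h:g}\t{s.replicate}\n")


# ---------------------------------------------------------------------------
# Gene-level results
# ---------------------------------------------------------------------------

def write_gene_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene results table as TSV.

    One row per gene: id, length, per-sample site counts and normalized
    reads, per-pair log2 fold changes, the four criteria flags, and the
    verdict. Undefined fold changes are serialized as the explicit token
    ``NA`` (never omitted); infinities as ``inf`` / ``-inf``. Reals carry 6
    significant digits.
    """
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_gene_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_gene_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return df
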