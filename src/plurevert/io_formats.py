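"""Readers and writers for every on-disk format the pipeline touches.

All in-memory coordinates are 0-based half-open. BED-family files are read
and written in their native 0-based half-open convention, so coordinates
never shift on a round trip.

Formats handled here:

* peak summits: narrowPeak (10-column) or 4-column BED,
* per-base coverage: bedGraph,
* CpG methylation: TSV with chrom/pos/coverage/methylated columns,
* gene models: TSV with gene_id/chrom/strand/tss/biotype columns,
* genomic intervals: BED4/BED6,
* genomes: FASTA (via Biopython),
* JASPAR-style position count matrices,
* expression matrices, per-comparison statistics and colony tables: CSV/TSV
  via pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class PeakSummit:
    """One peak summit call from one sample/condition."""

    chrom: str
    summit_pos: int
    score: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.summit_pos < 0:
            raise ValueError("summit_pos must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass(frozen=True, order=True)
class MethylationRecord:
    """Coverage and methylated-read count for one CpG."""

    chrom: str
    pos: int
    coverage: int
    methylated: int

    def __post_init__(self) -> None:
        if self.pos < 0 or self.coverage < 0:
            raise ValueError("pos and coverage must be >= 0")
        if not (0 <= self.methylated <= self.coverage):
            raise ValueError(
                f"methylated ({self.methylated}) must be within "
                f"[0, coverage={self.coverage}] at {self.chrom}:{self.pos}"
            )

    @property
    def fraction(self) -> float:
        if self.coverage == 0:
            return float("nan")
        return self.methylated / self.coverage


@dataclass(frozen=True, order=True)
class GeneModel:
    """Minimal gene annotation: one TSS per gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")


@dataclass
class CoverageTrack:
    """Per-base read depth per chromosome plus the library size.

    ``depth`` maps each chromosome to a non-negative integer vector of
    per-base coverage. ``library_size`` defaults to the total signal mass
    (sum of depth x interval length) of the source bedGraph but may be
    overridden when the true mapped-read count is known.
    """

    depth: dict[str, np.ndarray] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self) -> None:
        for chrom, vec in self.depth.items():
            vec = np.asarray(vec)
            if (vec < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depth[chrom] = vec.astype(np.int64)
        if self.library_size == 0:
            self.library_size = int(
                sum(int(v.sum()) for v in self.depth.values())
            )
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth over [start, end); positions beyond the stored vector are 0."""
        if end <= start:
            raise ValueError("window end must exceed start")
        out = np.zeros(end - start, dtype=np.int64)
        vec = self.depth.get(chrom)
        if vec is None:
            return out
        lo, hi = max(start, 0), min(end, len(vec))
        if lo < hi:
            out[lo - start : hi - start] = vec[lo:hi]
        return out


# ---------------------------------------------------------------------------
# peak summits (narrowPeak / BED)
# ---------------------------------------------------------------------------


def read_peak_summits(path: str | Path, sample_id: str) -> list[PeakSummit]:
    """Read summit calls from a narrowPeak or 4-column BED file.

    For narrowPeak the summit is ``start + column-10 offset``; for BED4 the
    interval must be 1 bp wide and its start is the summit. Records are
    returned sorted by (chrom, summit_pos).
    """
    records: list[PeakSummit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 10:  # narrowPeak
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    score = float(fields[6])  # signalValue column
                    offset = int(fields[9])
                    if end <= start:
                        raise ValueError("end <= start")
                    if offset < 0 or offset >= end - start:
                        raise ValueError(
                            f"summit offset {offset} outside region of "
                            f"length {end - start}"
                        )
                    summit = start + offset
                elif len(fields) >= 4:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    score = float(fields[3])
                    if end <= start:
                        raise ValueError("end <= start")
                    summit = start
                else:
                    raise ValueError(f"expected >= 4 columns, got {len(fields)}")
                records.append(PeakSummit(chrom, summit, score, sample_id))
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.summit_pos))
    return records


def write_peak_summits(
    summits: Iterable[PeakSummit], path: str | Path, width: int = 1
) -> None:
    """Write summits as narrowPeak with a ``width``-bp region around each."""
    with open(path, "w") as fh:
        for i, s in enumerate(summits):
            start = max(0, s.summit_pos - width // 2)
            end = start + width
            fh.write(
                f"{s.chrom}\t{start}\t{end}\tpeak_{i}\t0\t.\t"
                f"{s.score:g}\t-1\t-1\t{s.summit_pos - start}\n"
            )


# ---------------------------------------------------------------------------
# coverage (bedGraph)
# ---------------------------------------------------------------------------


def read_coverage(
    path: str | Path, library_size: int | None = None
) -> CoverageTrack:
    """Read a bedGraph into a per-base :class:`CoverageTrack`.

    Intervals must be non-overlapping within each chromosome. Unless
    ``library_size`` is given, it is set to the total signal mass
    (sum of depth x interval length).
    """
    intervals: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 4:
                    raise ValueError("expected 4 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                value = float(fields[3])
                if end <= start:
                    raise ValueError("end <= start")
                if value < 0:
                    raise ValueError(f"negative depth {value}")
                if value != int(value):
                    raise ValueError(f"non-integer depth {value}")
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            intervals.setdefault(chrom, []).append((start, end, int(value)))
    depth: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}: overlapping bedGraph intervals on {chrom} "
                    f"({s1}-{e1} and {s2}-...)"
                )
        vec = np.zeros(ivs[-1][1], dtype=np.int64)
        for s, e, v in ivs:
            vec[s:e] = v
        depth[chrom] = vec
    track = CoverageTrack(depth=depth)
    if library_size is not None:
        track.library_size = int(library_size)
    return track


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as a run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            vec = track.depth[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = int(vec[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

_METH_COLUMNS = ["chrom", "pos", "coverage", "methylated"]


def read_methylation_table(path: str | Path) -> list[MethylationRecord]:
    """Read a chrom/pos/coverage/methylated TSV, sorted by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_METH_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MethylationRecord(
                    str(row.chrom), int(row.pos), int(row.coverage),
                    int(row.methylated),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: {exc}") from exc
    records.sort()
    return records


def write_methylation_table(
    records: Iterable[MethylationRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.pos, r.coverage, r.methylated) for r in records],
        columns=_METH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "biotype"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    genes = [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss),
                  str(r.biotype))
        for r in df.itertuples(index=False)
    ]
    if len({g.gene_id for g in genes}) != len(genes):
        raise ParseError(f"{path}: duplicate gene_id")
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.biotype) for g in genes],
        columns=_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                strand = fields[5] if len(fields) >= 6 else "."
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]),
                                    strand)
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# JASPAR-style position count matrices
# ---------------------------------------------------------------------------


def read_pwms(path: str | Path) -> dict[str, np.ndarray]:
    """Read JASPAR-style count matrices into L x 4 arrays (A, C, G, T order).

    Format: a ``>motif_id name`` header followed by four lines
    ``A  [ counts... ]`` etc. Brackets are optional.
    """
    pwms: dict[str, np.ndarray] = {}
    motif_id = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows
        if motif_id is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise ParseError(f"{path}: motif {motif_id} missing base rows")
        mat = np.array([rows[b] for b in "ACGT"], dtype=float).T
        if mat.shape[0] < 1:
            raise ParseError(f"{path}: motif {motif_id} has no columns")
        pwms[motif_id] = mat
        rows = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            base, _, rest = line.partition(" ")
            base = base.upper()
            if base not in "ACGT" or motif_id is None:
                raise ParseError(f"{path}, line {lineno}: unexpected line")
            rest = rest.replace("[", " ").replace("]", " ")
            try:
                rows[base] = [float(x) for x in rest.split()]
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    flush()
    return pwms


def write_pwms(pwms: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for motif_id, mat in pwms.items():
            fh.write(f">{motif_id} {motif_id}\n")
            for j, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in np.asarray(mat)[:, j])
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# tabular inputs (expression, comparisons, colonies)
# ---------------------------------------------------------------------------

COLONY_COLUMNS = [
    "colony_id", "condition", "differentiation_time_h", "assay_time_h",
    "rfp_area_px", "gfp_pos_px", "mean_gfp", "antibody",
]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples FPKM table; first column is the gene id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative FPKM values")
    return df


def read_comparisons(path: str | Path) -> pd.DataFrame:
    """Per-comparison table: gene, cond_a, cond_b, fold_change, q_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "cond_a", "cond_b", "fold_change", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ParseError(f"{path}: q_value outside [0, 1]")
    # condition names are labels even when they look numeric ("0", "96")
    for col in ("gene", "cond_a", "cond_b"):
        df[col] = df[col].astype(str)
    return df


def read_colony_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["gfp_pos_px"] > df["rfp_area_px"]).any():
        raise ParseError(f"{path}: gfp_pos_px exceeds rfp_area_px")
    return df
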