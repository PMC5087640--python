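"""Gene models, coverage tracks and expression tables, with readers/writers.

All coordinates are held internally in the BED convention: 0-based,
half-open intervals. GFF3 input (1-based, closed) is converted on ingestion.
The TSS is the first transcribed base (``start`` for + genes, ``end - 1``
for − genes); the TES is the last transcribed base.

Coverage is held at a fixed bin width per chromosome; bin values are
length-weighted mean depths, so ``sum(values) * bin_width`` recovers the
total sequenced mass (``library_total``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GeneModelSet",
    "CoverageTrack",
    "ExpressionTable",
    "read_genome",
    "write_genome",
    "read_gene_models",
    "write_gene_models",
    "read_coverage",
    "write_coverage",
    "read_expression_table",
    "write_expression_table",
]


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (bounds, overlap, duplication)."""


@dataclass(frozen=True)
class GeneModel:
    """One gene as a single stranded interval (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        """First transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneModelSet:
    """An ordered collection of genes plus the chrom-sizes table they live on.

    Iteration order is the input order; gene_ids are unique and every gene
    must lie within its chromosome's bounds.
    """

    def __init__(self, genes: Iterable[GeneModel], genome: Mapping[str, int]):
        self.genes: list[GeneModel] = list(genes)
        self.genome: dict[str, int] = dict(genome)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.genome:
                raise ValidationError(
                    f"gene {g.gene_id!r}: unknown chromosome {g.chrom!r}"
                )
            if g.end > self.genome[g.chrom]:
                raise ValidationError(
                    f"gene {g.gene_id!r}: end {g.end} exceeds {g.chrom} "
                    f"length {self.genome[g.chrom]}"
                )

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except AttributeError:
            self._by_id = {g.gene_id: g for g in self.genes}
            return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class CoverageTrack:
    """Fixed-bin depth for one mark in one condition.

    ``values[chrom]`` has ``ceil(chrom_length / bin_width)`` entries; each
    entry is the length-weighted mean depth over that bin (uncovered bases
    count as zero depth).
    """

    mark: str
    condition: str
    bin_width: int
    values: dict[str, np.ndarray]
    genome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ValidationError(f"negative coverage on {chrom}")
            self.values[chrom] = arr
            if chrom in self.genome:
                expected = n_bins(self.genome[chrom], self.bin_width)
                if arr.size != expected:
                    raise ValidationError(
                        f"{chrom}: expected {expected} bins for length "
                        f"{self.genome[chrom]} at bin width {self.bin_width}, "
                        f"got {arr.size}"
                    )

    @property
    def library_total(self) -> float:
        """Total mass: sum over bins of value × bin_width (recomputed)."""
        return float(sum(a.sum() for a in self.values.values())) * self.bin_width

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            mark=self.mark,
            condition=self.condition,
            bin_width=self.bin_width,
            values={c: a * factor for c, a in self.values.items()},
            genome=dict(self.genome),
        )


class ExpressionTable:
    """Gene-level FPKM per condition, optionally with replicates.

    Backed by a DataFrame indexed by gene_id whose columns are sample names;
    a sample named ``cond`` is a single measurement for that condition and
    ``cond:rep1``, ``cond:rep2`` ... are replicates.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_id(s): {dups}")
        values = df.to_numpy(dtype=float)  # raises on non-numeric
        if np.any(values < 0):
            raise ValidationError("FPKM values must be >= 0")
        self.df = df.astype(float)
        cond_cols: dict[str, list[str]] = {}
        for col in df.columns:
            cond = col.split(":", 1)[0]
            cond_cols.setdefault(cond, []).append(col)
        self._cond_cols = cond_cols

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def conditions(self) -> list[str]:
        return list(self._cond_cols)

    def n_replicates(self, condition: str) -> int:
        return len(self._cond_cols[condition])

    def replicate_values(self, condition: str) -> pd.DataFrame:
        """All replicate columns for a condition (n_genes × n_reps)."""
        if condition not in self._cond_cols:
            raise KeyError(f"condition {condition!r} not in table")
        return self.df[self._cond_cols[condition]]

    def condition_mean(self, condition: str) -> pd.Series:
        return self.replicate_values(condition).mean(axis=1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionTable) and self.df.equals(other.df)


# ---------------------------------------------------------------------------
# helpers

def n_bins(chrom_length: int, bin_width: int) -> int:
    return math.ceil(chrom_length / bin_width)


def _fmt(x: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# genome (chrom sizes)

def read_genome(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom-sizes TSV into an ordered mapping."""
    genome: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        chrom, length = fields
        if chrom in genome:
            raise ValidationError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        try:
            genome[chrom] = int(length)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad length {length!r}") from exc
    return genome


def write_genome(genome: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in genome.items())
    )


# ---------------------------------------------------------------------------
# gene models (BED6 / GFF3)

def read_gene_models(
    path: str | Path,
    genome: Mapping[str, int],
    fmt: str | None = None,
    gff_feature_types: Sequence[str] = ("gene",),
) -> GeneModelSet:
    """Read gene models from BED6 or GFF3 into the internal convention.

    ``fmt`` is ``"bed"`` or ``"gff3"``; when None it is inferred from the
    file suffix (``.gff``/``.gff3`` → GFF3, otherwise BED).
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        genes = _parse_bed6(path)
    elif fmt == "gff3":
        genes = _parse_gff3(path, tuple(gff_feature_types))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return GeneModelSet(genes, genome)


def _parse_bed6(path: Path) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(
                f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}"
            )
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        try:
            genes.append(GeneModel(name, chrom, start_i, end_i, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_gff3(path: Path, feature_types: tuple[str, ...]) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(
                f"{path}:{lineno}: GFF3 needs 9 tab-separated columns, "
                f"got {len(fields)}"
            )
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype not in feature_types:
            continue
        try:
            # GFF3 is 1-based closed; internal is 0-based half-open.
            start_i, end_i = int(start) - 1, int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        gene_id = attr_map.get("ID") or attr_map.get("gene_id")
        if gene_id is None:
            raise FormatError(f"{path}:{lineno}: no ID attribute")
        try:
            genes.append(GeneModel(gene_id, chrom, start_i, end_i, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: GeneModelSet, path: str | Path) -> None:
    """Write as BED6 (score column written as 0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# coverage (bedGraph)

def read_coverage(
    path: str | Path,
    genome: Mapping[str, int],
    bin_width: int = 50,
    mark: str = "",
    condition: str = "",
) -> CoverageTrack:
    """Rasterize a bedGraph onto fixed bins.

    Interval values are spread as mass (value × overlap length) into the
    bins they touch, then divided by bin_width, i.e. each bin holds the
    length-weighted mean depth with uncovered bases contributing zero.
    Overlapping intervals and negative values are rejected.
    """
    path = Path(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(
                f"{path}:{lineno}: bedGraph needs 4 columns, got {len(fields)}"
            )
        chrom, start, end, value = fields
        try:
            start_i, end_i, val = int(start), int(end), float(value)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad interval") from exc
        if val < 0:
            raise ValidationError(f"{path}:{lineno}: negative value {val}")
        if chrom not in genome:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if not (0 <= start_i < end_i <= genome[chrom]):
            raise ValidationError(
                f"{path}:{lineno}: interval [{start_i}, {end_i}) outside "
                f"{chrom} (length {genome[chrom]})"
            )
        per_chrom.setdefault(chrom, []).append((start_i, end_i, val))

    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        acc = np.zeros(n_bins(length, bin_width), dtype=float)
        intervals = sorted(per_chrom.get(chrom, []))
        prev_end = -1
        for start_i, end_i, val in intervals:
            if start_i < prev_end:
                raise ValidationError(
                    f"{path}: overlapping intervals on {chrom} near {start_i}"
                )
            prev_end = end_i
            _add_interval_mass(acc, start_i, end_i, val, bin_width)
        values[chrom] = acc
    return CoverageTrack(
        mark=mark, condition=condition, bin_width=bin_width,
        values=values, genome=dict(genome),
    )


def _add_interval_mass(
    acc: np.ndarray, start: int, end: int, value: float, bin_width: int
) -> None:
    """Accumulate value weighted by the covered fraction of each bin.

    Whole bins receive ``value`` exactly (no multiply/divide round-trip),
    so bin-aligned bedGraphs reproduce their source values bit for bit.
    """
    b0, b1 = start // bin_width, (end - 1) // bin_width
    if b0 == b1:
        acc[b0] += value * ((end - start) / bin_width)
        return
    left = (b0 + 1) * bin_width - start
    acc[b0] += value if left == bin_width else value * (left / bin_width)
    right = end - b1 * bin_width
    acc[b1] += value if right == bin_width else value * (right / bin_width)
    if b1 > b0 + 1:
        acc[b0 + 1 : b1] += value


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write as bedGraph, merging runs of equal bins and skipping zeros."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            length = track.genome.get(chrom, arr.size * bw)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for b0, b1 in zip(starts, ends):
                v = arr[b0]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{b0 * bw}\t{min(b1 * bw, length)}\t{_fmt(v)}\n"
                )


# ---------------------------------------------------------------------------
# expression tables

def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV with a gene_id key column and one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing 'gene_id' column")
    df = df.set_index("gene_id")
    try:
        return ExpressionTable(df)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.df.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)
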