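"""Genomic file formats and interval arithmetic.

All in-memory coordinates are 0-based half-open (`[start, end)`), the BED and
bedGraph convention. GTF input (1-based, inclusive) is shifted on read; no
other code path performs coordinate conversion. Regions absent from a
bedGraph read as zero signal, matching bedGraph semantics, not as missing
data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomeLayout",
    "GeneModel",
    "IntervalSet",
    "CoverageTrack",
    "read_genes",
    "write_genes",
    "read_coverage",
    "gene_window",
]

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a semantic contract."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of the working genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column `<chrom>\\t<length>` file (UCSC chrom.sizes)."""
        names, lengths = [], []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                n = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {parts[1]!r} is not an integer")
            names.append(parts[0])
            lengths.append(n)
        return cls(tuple(names), tuple(lengths))

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{l}\n" for c, l in zip(self.chrom_names, self.chrom_lengths))
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: coordinates, strand, class labels, activity status.

    The TSS is `start` on the plus strand and `end` on the minus strand
    (half-open anchor); downstream means increasing coordinate on `+` and
    decreasing on `-`.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    classes: frozenset[str] = field(default_factory=frozenset)
    active: bool = True

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


def gene_window(gene: GeneModel, flank: int, layout: GenomeLayout) -> tuple[int, int]:
    """Gene body extended by `flank` bp on each side, clamped to the chromosome.

    Returns a half-open `(start, end)` interval.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    length = layout.length(gene.chrom)
    return max(0, gene.start - flank), min(length, gene.end + flank)


# ---------------------------------------------------------------------------
# gene annotation IO


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 or GTF (by extension: .gtf/.gff/.gff3).

    BED is 0-based half-open and used verbatim; GTF coordinates are shifted
    to 0-based half-open on read. Models are returned in file order.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return _read_gtf(path)
    return _read_bed6(path)


def _read_bed6(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        parts = s.split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(parts)}")
        chrom, start_s, end_s, name, _score, strand = parts[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}")
        if end <= start:
            raise ValidationError(f"{path}:{lineno}: end <= start ({end} <= {start})")
        if strand not in STRANDS:
            raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
        genes.append(GeneModel(name, chrom, start, end, strand))
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    # pyranges handles the 1-based inclusive -> 0-based half-open shift.
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if "Feature" in df.columns:
        df = df[df.Feature == "gene"]
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=getattr(row, "gene_id"),
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=str(row.Strand),
            )
        )
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (name = gene_id, score = 0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# interval sets


class IntervalSet:
    """A set of genomic intervals (0-based half-open), possibly overlapping."""

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int]],
        layout: GenomeLayout | None = None,
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[tuple[str, int, int]] = []
        for chrom, start, end in intervals:
            if end <= start or start < 0:
                raise ValidationError(f"bad interval {chrom}:{start}-{end}")
            if layout is not None and end > layout.length(chrom):
                raise ValidationError(
                    f"interval {chrom}:{start}-{end} exceeds chromosome length"
                )
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._intervals.append((chrom, start, end))

    def __len__(self) -> int:
        return len(self._intervals)

    def tuples(self) -> list[tuple[str, int, int]]:
        return sorted(self._intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def covers_gene(self, gene: GeneModel, flank: int = 0) -> bool:
        return self.overlaps(gene.chrom, max(0, gene.start - flank), gene.end + flank)

    def merged_length(self) -> int:
        """Total bp covered, counting overlapping intervals once."""
        total = 0
        for tree in self._trees.values():
            t = IntervalTree(tree)
            t.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in t)
        return total

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout | None = None) -> "IntervalSet":
        rows = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
        return cls(rows, layout=layout)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.tuples():
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# coverage tracks


class CoverageTrack:
    """Piecewise-constant, non-negative signal over a genome.

    Stored per chromosome as sorted, non-overlapping segments
    `(starts, ends, values)`; everything outside the segments is zero.
    Cumulative integrals are precomputed so window means and binned profiles
    are O(log segments) per query point.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        assay: str | None = None,
        condition: str | None = None,
        strand: str | None = None,
    ) -> None:
        self.layout = layout
        self.assay = assay
        self.condition = condition
        self.strand = strand  # None = unstranded; '+'/'-' for stranded assays
        self._seg: dict[str, dict[str, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: zero/negative-length interval")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping intervals in coverage")
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative coverage value")
            if starts.size and (starts[0] < 0 or ends[-1] > layout.length(chrom)):
                raise ValidationError(f"{chrom}: coverage outside chromosome bounds")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._seg[chrom] = {"starts": starts, "ends": ends, "values": values, "cum": cum}

    # -- queries -----------------------------------------------------------

    def _F(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, x) for each x (vectorized)."""
        seg = self._seg.get(chrom)
        if seg is None or seg["starts"].size == 0:
            return np.zeros_like(np.asarray(x, dtype=np.float64))
        x = np.asarray(x, dtype=np.float64)
        idx = np.searchsorted(seg["ends"], x, side="right")
        out = seg["cum"][idx]
        inside = idx < seg["starts"].size
        ii = idx[inside]
        partial = seg["values"][ii] * np.clip(x[inside] - seg["starts"][ii], 0.0, None)
        out[inside] += partial
        return out

    def integral(self, chrom: str, start: float, end: float) -> float:
        # summed locally over overlapping segments (not as a difference of
        # chromosome-wide cumulative sums) so the result depends only on the
        # signal inside the window, to the last ulp
        seg = self._seg.get(chrom)
        if seg is None or seg["starts"].size == 0:
            return 0.0
        i0 = int(np.searchsorted(seg["ends"], start, side="right"))
        i1 = int(np.searchsorted(seg["starts"], end, side="left"))
        if i1 <= i0:
            return 0.0
        s = np.maximum(seg["starts"][i0:i1], start)
        e = np.minimum(seg["ends"][i0:i1], end)
        return float(np.sum(seg["values"][i0:i1] * np.clip(e - s, 0.0, None)))

    def mean(self, chrom: str, start: float, end: float) -> float:
        """Mean signal per bp over `[start, end)`."""
        if end <= start:
            raise ValidationError(f"zero-length window [{start}, {end})")
        return self.integral(chrom, start, end) / (end - start)

    def bin_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal per bp in each bin defined by monotone `edges`."""
        edges = np.asarray(edges, dtype=np.float64)
        f = self._F(chrom, edges)
        return np.diff(f) / np.diff(edges)

    def total(self) -> float:
        """Genome-wide total signal (integral over all chromosomes)."""
        return float(sum(seg["cum"][-1] for seg in self._seg.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        segs = {
            c: (s["starts"], s["ends"], s["values"] * factor) for c, s in self._seg.items()
        }
        return CoverageTrack(
            self.layout, segs, assay=self.assay, condition=self.condition, strand=self.strand
        )

    # -- construction / IO -------------------------------------------------

    @classmethod
    def from_dense_bins(
        cls,
        layout: GenomeLayout,
        values_by_chrom: dict[str, np.ndarray],
        bin_width: int,
        **meta,
    ) -> "CoverageTrack":
        """Build from one value per fixed-width bin; zero runs are dropped
        and equal-valued adjacent bins merged (run-length encoding)."""
        segments = {}
        for chrom, vals in values_by_chrom.items():
            vals = np.asarray(vals, dtype=np.float64)
            if vals.size == 0:
                continue
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [vals.size]])
            run_vals = vals[run_starts]
            keep = run_vals != 0
            starts = run_starts[keep] * bin_width
            ends = np.minimum(run_ends[keep] * bin_width, layout.length(chrom))
            segments[chrom] = (starts, ends, run_vals[keep])
        return cls(layout, segments, **meta)

    def to_bedgraph(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            for chrom in self.layout.chrom_names:
                seg = self._seg.get(chrom)
                if seg is None:
                    continue
                for s, e, v in zip(seg["starts"], seg["ends"], seg["values"]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        layout: GenomeLayout,
        assay: str | None = None,
        condition: str | None = None,
        strand: str | None = None,
    ) -> "CoverageTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed coordinates or value")
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            per_chrom.setdefault(parts[0], []).append((start, end, value))
        segments = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            segments[chrom] = (starts, ends, values)
        return cls(layout, segments, assay=assay, condition=condition, strand=strand)


def read_coverage(
    path: str | Path,
    layout: GenomeLayout,
    assay: str | None = None,
    condition: str | None = None,
    strand: str | None = None,
) -> CoverageTrack:
    """Read a bedGraph file into a :class:`CoverageTrack`.

    Overlapping intervals or negative values raise :class:`ValidationError`;
    queries outside listed intervals return 0.
    """
    return CoverageTrack.from_bedgraph(
        path, layout, assay=assay, condition=condition, strand=strand
    )
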