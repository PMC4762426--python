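"""Per-gene densities, normalized ratios, Z-scores and metagene profiles.

The quantification window is the gene body extended by a flank (default
500 bp) on each side. Damage-type assays (gamma-H2AX, H2AX) are normalized
per gene to H3 before the cross-condition ratio; RNAPII and GRO ratios are
taken on library-comparable densities directly. GRO is strand-resolved:
each gene is quantified on its sense strand only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import CoverageTrack, GeneModel, GenomeLayout, ValidationError, gene_window
from .labels import CONTROL, GH2AX, GRO, H2AX, H3, MUTANT, RNAPII
from .synthetic_data import track_key

__all__ = [
    "gene_density",
    "density_table",
    "library_scale",
    "ratio",
    "normalize_to_h3",
    "ratio_table",
    "zscore",
    "geometric_mean_difference",
    "MetageneProfile",
    "metagene_promoter",
    "metagene_scaled",
    "active_genes",
    "default_pseudocount",
]

logger = logging.getLogger(__name__)


def gene_density(
    track: CoverageTrack, gene: GeneModel, flank: int, layout: GenomeLayout | None = None
) -> float:
    """Mean signal per bp over the gene body +/- `flank`, clamped to the
    chromosome. For stranded tracks, pass the gene's sense-strand track."""
    layout = layout or track.layout
    start, end = gene_window(gene, flank, layout)
    if end <= start:
        raise ValidationError(f"gene {gene.gene_id}: zero-length window")
    return track.mean(gene.chrom, start, end)


def density_table(
    tracks: Mapping[tuple, CoverageTrack],
    genes: Sequence[GeneModel],
    flank: int = 500,
    scale_factors: Mapping[tuple, float] | None = None,
) -> pd.DataFrame:
    """Per-(gene, assay, condition) mean density table.

    For GRO, the sense-strand track of each gene is used. `scale_factors`
    (from :func:`library_scale`) multiply each track's densities; the factors
    used and the flank are recorded in ``df.attrs``.
    """
    rows = []
    keys = sorted(tracks.keys(), key=lambda k: (k[0], k[1], str(k[2])))
    assays = sorted({k[0] for k in keys})
    conditions = sorted({k[1] for k in keys})
    for gene in genes:
        for assay in assays:
            for condition in conditions:
                if (assay, condition, None) in tracks:
                    track = tracks[(assay, condition, None)]
                    key = (assay, condition, None)
                elif (assay, condition, gene.strand) in tracks:
                    track = tracks[(assay, condition, gene.strand)]
                    key = (assay, condition, gene.strand)
                else:
                    continue
                d = gene_density(track, gene, flank)
                if scale_factors is not None:
                    d *= scale_factors[key]
                rows.append((gene.gene_id, assay, condition, d))
    df = pd.DataFrame(rows, columns=["gene_id", "assay", "condition", "density"])
    df.attrs["flank"] = flank
    df.attrs["scale_factors"] = (
        {f"{k[0]}:{k[1]}:{k[2]}": v for k, v in scale_factors.items()}
        if scale_factors
        else None
    )
    return df


def library_scale(
    tracks: Mapping[tuple, CoverageTrack], target: float = 1e6
) -> dict[tuple, float]:
    """Scaling factor per track bringing every genome-wide total to `target`
    (signal-per-million when `target` is 1e6)."""
    factors = {}
    for key, track in tracks.items():
        total = track.total()
        if total <= 0:
            raise ValidationError(f"track {key}: zero total signal, cannot scale")
        factors[key] = target / total
    return factors


def ratio(case: float, control: float, pseudocount: float = 0.0) -> float:
    """Fold change `(case + eps) / (control + eps)`.

    Both-zero with eps=0 is undefined: returns NaN and warns rather than
    silently dropping the gene.
    """
    if case < 0 or control < 0:
        raise ValidationError("densities must be >= 0")
    if control + pseudocount == 0:
        if case == 0:
            warnings.warn("0/0 ratio with zero pseudocount; returning NaN")
            return float("nan")
        return float("inf")
    return (case + pseudocount) / (control + pseudocount)


def normalize_to_h3(signal: float, h3: float, pseudocount: float = 0.0) -> float:
    """Nucleosome-density normalization: signal density over H3 density."""
    return ratio(signal, h3, pseudocount)


def default_pseudocount(densities: Sequence[float], fraction: float = 0.01) -> float:
    """Scale-free pseudocount: `fraction` of the median density (default 1%)."""
    med = float(np.median(np.asarray(densities, dtype=float)))
    return fraction * med


def ratio_table(
    dens: pd.DataFrame,
    pseudocount: float | None = None,
    pseudocount_fraction: float = 0.01,
) -> pd.DataFrame:
    """Mutant:control ratio per gene and assay from a density table.

    gamma-H2AX and H2AX are normalized to H3 per gene within each condition
    first; RNAPII and GRO ratios are taken on densities directly. With
    `pseudocount=None`, each assay uses `pseudocount_fraction` of its median
    density (applied to both the H3 normalization and the ratio).
    """
    wide = dens.pivot_table(
        index="gene_id", columns=["assay", "condition"], values="density", sort=True
    )
    out = pd.DataFrame(index=wide.index)
    eps_used = {}

    def eps_for(assay: str) -> float:
        if pseudocount is not None:
            return pseudocount
        vals = np.concatenate([wide[(assay, CONTROL)].values, wide[(assay, MUTANT)].values])
        return default_pseudocount(vals, pseudocount_fraction)

    eps_h3 = eps_for(H3)
    for assay, col in ((GH2AX, "gh2ax_ratio"), (H2AX, "h2ax_ratio")):
        eps = eps_for(assay)
        norm_m = (wide[(assay, MUTANT)] + eps) / (wide[(H3, MUTANT)] + eps_h3)
        norm_c = (wide[(assay, CONTROL)] + eps) / (wide[(H3, CONTROL)] + eps_h3)
        out[col] = norm_m / norm_c
        eps_used[assay] = eps
    for assay, col in ((RNAPII, "rnapii_ratio"), (GRO, "gro_ratio")):
        eps = eps_for(assay)
        out[col] = (wide[(assay, MUTANT)] + eps) / (wide[(assay, CONTROL)] + eps)
        eps_used[assay] = eps

    out.index.name = "gene_id"
    out.attrs["normalization"] = {
        "gh2ax_ratio": "to_H3",
        "h2ax_ratio": "to_H3",
        "rnapii_ratio": "none",
        "gro_ratio": "none",
    }
    out.attrs["pseudocount"] = eps_used
    out.attrs["flank"] = dens.attrs.get("flank")
    return out


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standard score `(x - mean) / sd` with sample (ddof=1) sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("zscore needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("zscore undefined for constant input (sd = 0)")
    return (x - x.mean()) / sd


def geometric_mean_difference(ratios: Sequence[float]) -> float:
    """Geometric mean of fold changes: `exp(mean(log r))`."""
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("geometric mean requires all ratios > 0")
    return float(np.exp(np.mean(np.log(r))))


# ---------------------------------------------------------------------------
# metagene profiles


@dataclass
class MetageneProfile:
    """Mean signal across genes on a common coordinate frame.

    `positions` are bp offsets relative to the TSS for promoter-anchored
    profiles; for scaled profiles they are bp in the flanks and percent of
    gene body (with `segment` distinguishing the pieces). Minus-strand genes
    are orientation-flipped before aggregation, so downstream is rightward.
    """

    positions: np.ndarray
    mean: np.ndarray
    n_per_bin: np.ndarray
    n_genes: int
    bin_width: float
    kind: str
    segment: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions, "mean": self.mean, "n": self.n_per_bin})
        if self.segment is not None:
            df.insert(0, "segment", self.segment)
        df.attrs["kind"] = self.kind
        df.attrs["n_genes"] = self.n_genes
        return df


def _gene_bin_means(
    track: CoverageTrack, gene: GeneModel, edges: np.ndarray
) -> np.ndarray:
    """Bin means on genomic `edges`, NaN outside the chromosome."""
    L = track.layout.length(gene.chrom)
    clipped = np.clip(edges, 0, L)
    f = track._F(gene.chrom, clipped.astype(float))
    widths = np.diff(edges).astype(float)
    means = np.diff(f) / widths
    valid = (edges[:-1] >= 0) & (edges[1:] <= L)
    means[~valid] = np.nan
    return means


def metagene_promoter(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    span: int = 2000,
    bin_width: int = 50,
    stranded_tracks: Mapping[str, CoverageTrack] | None = None,
) -> MetageneProfile:
    """TSS-anchored profile over `[-span, +span)` in `bin_width` bins.

    Genes truncated at chromosome edges contribute only their covered bins.
    For stranded assays pass `stranded_tracks={'+': t_plus, '-': t_minus}`
    (then `track` is ignored per gene in favour of the sense track).
    """
    if not genes:
        raise ValidationError("metagene_promoter: empty gene set")
    if span % bin_width:
        raise ValidationError("bin_width must divide span")
    nbins = 2 * span // bin_width
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for gene in genes:
        t = stranded_tracks[gene.strand] if stranded_tracks else track
        if gene.strand == "+":
            edges = gene.tss + np.arange(-span, span + bin_width, bin_width)
            m = _gene_bin_means(t, gene, edges)
        else:
            edges = gene.tss + np.arange(-span, span + bin_width, bin_width)
            m = _gene_bin_means(t, gene, edges)[::-1]
        ok = ~np.isnan(m)
        sums[ok] += m[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    positions = np.arange(-span, span, bin_width)
    return MetageneProfile(
        positions=positions,
        mean=mean,
        n_per_bin=counts,
        n_genes=len(genes),
        bin_width=float(bin_width),
        kind="promoter",
    )


def metagene_scaled(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank: int = 2000,
    flank_bins: int = 20,
    min_gene_length: int | None = None,
    stranded_tracks: Mapping[str, CoverageTrack] | None = None,
) -> MetageneProfile:
    """Scaled gene-body profile: fixed-width flanks, body rescaled to
    `body_bins` bins. Genes shorter than `min_gene_length` (default
    `body_bins` bp) are skipped and logged."""
    min_len = body_bins if min_gene_length is None else min_gene_length
    used = [g for g in genes if g.length >= min_len]
    skipped = len(list(genes)) - len(used)
    if skipped:
        logger.info("metagene_scaled: skipped %d genes shorter than %d bp", skipped, min_len)
    if not used:
        raise ValidationError("metagene_scaled: all genes below minimum length")
    fw = flank / flank_bins
    total = flank_bins + body_bins + flank_bins
    sums = np.zeros(total)
    counts = np.zeros(total, dtype=np.int64)
    for gene in used:
        t = stranded_tracks[gene.strand] if stranded_tracks else track
        up = gene.start - flank + np.arange(flank_bins + 1) * fw
        body = np.linspace(gene.start, gene.end, body_bins + 1)
        down = gene.end + np.arange(flank_bins + 1) * fw
        edges = np.concatenate([up, body[1:], down[1:]])
        m = _gene_bin_means(t, gene, edges)
        if gene.strand == "-":
            m = m[::-1]
        ok = ~np.isnan(m)
        sums[ok] += m[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    positions = np.concatenate(
        [
            -flank + np.arange(flank_bins) * fw,                  # bp upstream of TSS
            np.arange(body_bins) * (100.0 / body_bins),           # percent of body
            np.arange(flank_bins) * fw,                           # bp downstream of TTS
        ]
    )
    segment = np.array(
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    return MetageneProfile(
        positions=positions,
        mean=mean,
        n_per_bin=counts,
        n_genes=len(used),
        bin_width=float(fw),
        kind="scaled",
        segment=segment,
    )


def active_genes(
    gro_density: pd.Series,
    threshold: float = 0.0,
    totals: pd.Series | None = None,
    min_total: float = 10.0,
) -> pd.Index:
    """Genes with control-condition sense-strand GRO density above `threshold`.

    With `totals` given (density x window length, i.e. expected signal
    units in the window), genes additionally need `totals >= min_total`.
    All downstream decile selections use only active genes.
    """
    if threshold < 0:
        raise ValidationError("activity threshold must be >= 0")
    mask = gro_density > threshold
    if totals is not None:
        mask &= totals.reindex(gro_density.index) >= min_total
    return gro_density.index[mask]
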