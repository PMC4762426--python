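"""Synthetic study generator.

Emulates the two-condition design the pipeline analyses: a control ("F/F")
and an MLL2-mutant ("FC/FC") cell population profiled by gamma-H2AX, H2AX,
H3 and RNAPII ChIP-seq plus stranded GRO-seq. A planted subset of short,
highly expressed genes carries elevated damage (gamma-H2AX/H3 up 1.5x) and
transcription stress (RNAPII up without a nascent-transcription increase),
a histone-like gene class concentrates inside the damaged subset,
early-replicating-fragile-site (ERFS) intervals are enriched over damaged
genes, and a targeted gene panel accumulates de novo mutations at a per-site
per-generation rate.

Every draw descends from a single master seed through named, per-stage
`numpy` `SeedSequence` streams, so outputs are bit-for-bit reproducible and
adding a stage never perturbs earlier draws. Signal is generated as expected
density per bp on a fixed bin grid; with noise enabled, per-bin counts are
Poisson around (density x bin width) and the stored value is count/width.
With noise disabled the stored value is the expected density itself, which
makes every downstream per-gene ratio equal the configured effect exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .annotations_io import (
    CoverageTrack,
    GeneModel,
    GenomeLayout,
    IntervalSet,
    ValidationError,
    write_genes,
)
from .labels import (
    ASSAYS,
    CONDITION_TOKENS,
    CONDITIONS,
    CONTROL,
    GH2AX,
    GRO,
    H2AX,
    H3,
    MUTANT,
    RNAPII,
)

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "MutationSim",
    "generate_annotation",
    "generate_tracks",
    "simulate_mutations",
    "write_study",
    "track_key",
]

# fixed spawn keys: one RNG stream per generation stage
_STAGES = {"annotation": 0, "tracks": 1, "mutations": 2}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with the study's default conditions.

    Lengths are in bp, densities in expected counts per bp. The damaged-gene
    length distribution targets a 4.1 kb median against an 11.7 kb background
    median, which puts the all-gene mixture median near 10.6 kb at the
    default 10% damaged fraction.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 8_000_000
    n_genes: int = 500
    min_gap: int = 2_500           # keeps +/-500 bp windows free of neighbours
    bin_width: int = 50

    # gene length model (log-normal, medians in bp)
    length_median_bp: float = 11_700.0
    length_sigma: float = 0.7
    damaged_length_median_bp: float = 4_100.0
    damaged_length_sigma: float = 0.6
    min_gene_length: int = 1_000

    # planted structure
    fraction_damaged: float = 0.10
    fraction_histone_like: float = 0.015
    histone_damaged_fraction: float = 0.40
    stressed_equals_damaged: bool = True
    fraction_stressed: float = 0.10   # used only when decoupled from damage

    # expression and coverage
    expression_shape: float = 2.0
    expression_scale: float = 0.05    # gamma scale; mean density 0.1/bp
    damaged_expression_factor: float = 3.0
    h3_density: float = 0.05
    h2ax_density: float = 0.05
    gh2ax_baseline_density: float = 0.05

    # effect sizes (mutant vs control)
    damage_ratio: float = 1.5
    stress_rnapii_ratio: float = 1.3
    stress_gro_ratio: float = 0.95

    noise: bool = True

    # fragile-site intervals
    erfs_base_rate: float = 0.10
    erfs_enrichment: float = 4.0      # odds ratio, damaged vs undamaged genes
    erfs_max_flank: int = 5_000

    # mutation panel
    panel_extra_genes: int = 4        # damaged, non-histone genes added to the panel
    mu: float = 6e-8                  # per site per generation
    generations: int = 45
    mutant_rate_factor: float = 50.0  # rate multiplier in the mutant condition
    n_baseline_variants: int = 5
    substitution_fraction: float = 0.7
    deletion_fraction: float = 0.2    # remainder are insertions

    def validate(self) -> None:
        for name in ("fraction_damaged", "fraction_histone_like",
                     "histone_damaged_fraction", "fraction_stressed",
                     "erfs_base_rate", "substitution_fraction", "deletion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigError(f"mu must be in [0, 1], got {self.mu}")
        for name in ("damage_ratio", "stress_rnapii_ratio", "stress_gro_ratio",
                     "erfs_enrichment", "mutant_rate_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.min_gap % self.bin_width or self.min_gene_length % self.bin_width:
            raise ConfigError("min_gap and min_gene_length must be bin_width multiples")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            tuple(f"chr{i + 1}" for i in range(self.n_chroms)),
            tuple([self.chrom_length] * self.n_chroms),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class TruthTable:
    """Planted per-gene truth (and later per-site mutation truth)."""

    genes: pd.DataFrame                      # one row per gene, indexed by gene_id
    sites: pd.DataFrame | None = None        # filled by simulate_mutations

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.genes.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
        return cls(genes=df)


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], IntervalSet, TruthTable]:
    """Place non-overlapping genes, plant the damaged/stressed/histone/panel
    structure, and lay ERFS intervals with the configured odds enrichment
    over damaged genes.

    Damaged genes draw their lengths from the short log-normal component and
    their expression from the boosted gamma component, so the planted subset
    is short and highly expressed by construction.
    """
    config.validate()
    rng = stage_rng(config.seed, "annotation")
    n = config.n_genes
    bw = config.bin_width

    n_damaged = int(np.floor(config.fraction_damaged * n + 0.5))
    damaged = np.zeros(n, dtype=bool)
    damaged[rng.choice(n, size=n_damaged, replace=False)] = True

    # stressed set: identical to damaged by default, independent otherwise
    if config.stressed_equals_damaged:
        stressed = damaged.copy()
    else:
        stressed = np.zeros(n, dtype=bool)
        n_str = int(np.floor(config.fraction_stressed * n + 0.5))
        stressed[rng.choice(n, size=n_str, replace=False)] = True

    # lengths, snapped to the bin grid
    medians = np.where(damaged, config.damaged_length_median_bp, config.length_median_bp)
    sigmas = np.where(damaged, config.damaged_length_sigma, config.length_sigma)
    lengths = np.exp(np.log(medians) + sigmas * rng.standard_normal(n))
    lengths = np.maximum(np.round(lengths / bw) * bw, config.min_gene_length).astype(np.int64)

    expression = rng.gamma(config.expression_shape, config.expression_scale, size=n)
    expression = np.maximum(expression, 1e-4)
    expression[damaged] *= config.damaged_expression_factor

    # histone-like genes, drawn preferentially from the damaged subset
    n_hist = int(np.floor(config.fraction_histone_like * n + 0.5))
    n_hist_dam = min(int(np.floor(config.histone_damaged_fraction * n_hist + 0.5)), n_damaged)
    histone = np.zeros(n, dtype=bool)
    dam_idx = np.flatnonzero(damaged)
    und_idx = np.flatnonzero(~damaged)
    histone[rng.choice(dam_idx, size=n_hist_dam, replace=False)] = True
    histone[rng.choice(und_idx, size=n_hist - n_hist_dam, replace=False)] = True

    # mutation panel: histone-like genes plus a few damaged non-histone genes
    panel = histone.copy()
    extra_pool = np.flatnonzero(damaged & ~histone)
    n_extra = min(config.panel_extra_genes, extra_pool.size)
    panel[rng.choice(extra_pool, size=n_extra, replace=False)] = True

    strands = rng.choice(np.array(["+", "-"]), size=n)

    # placement: genes scattered over chromosomes, random bin-aligned gaps
    chrom_of = rng.integers(config.n_chroms, size=n)
    starts = np.zeros(n, dtype=np.int64)
    chroms = np.empty(n, dtype=object)
    layout = config.layout
    for ci, chrom in enumerate(layout.chrom_names):
        idx = np.flatnonzero(chrom_of == ci)
        k = idx.size
        if k == 0:
            continue
        need = int(lengths[idx].sum() + (k + 1) * config.min_gap)
        slack = config.chrom_length - need
        if slack < 0:
            raise ConfigError(
                f"cannot place {k} genes on {chrom} without overlap; "
                "increase chrom_length or reduce n_genes"
            )
        props = rng.dirichlet(np.ones(k + 1))
        gaps = config.min_gap + (np.floor(props * slack / bw) * bw).astype(np.int64)
        pos = 0
        for j, gi in enumerate(idx):
            pos += gaps[j]
            starts[gi] = pos
            chroms[gi] = chrom
            pos += lengths[gi]

    # ERFS intervals: per-gene Bernoulli coverage with odds-scaled rate
    odds_u = config.erfs_base_rate / (1.0 - config.erfs_base_rate)
    odds_d = odds_u * config.erfs_enrichment
    q_d = odds_d / (1.0 + odds_d)
    cover_p = np.where(damaged, q_d, config.erfs_base_rate)
    covered = rng.random(n) < cover_p
    erfs_rows = []
    for gi in np.flatnonzero(covered):
        u1, u2 = rng.integers(0, config.erfs_max_flank + 1, size=2)
        s = max(0, int(starts[gi] - u1))
        e = min(config.chrom_length, int(starts[gi] + lengths[gi] + u2))
        erfs_rows.append((str(chroms[gi]), s, e))
    erfs = IntervalSet(erfs_rows, layout=layout)

    # assemble in coordinate order with stable ids
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "length": lengths,
            "expression": expression,
            "damaged": damaged,
            "stressed": stressed,
            "histone": histone,
            "panel": panel,
        }
    )
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    width = max(4, len(str(n - 1)))
    df.index = pd.Index([f"g{i:0{width}d}" for i in range(n)], name="gene_id")
    df["erfs_overlap"] = [
        erfs.overlaps(r.chrom, r.start, r.end) for r in df.itertuples()
    ]

    genes = [
        GeneModel(
            gene_id=gid,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            classes=frozenset(
                lab for lab, flag in (("histone", r.histone), ("panel", r.panel)) if flag
            ),
        )
        for gid, r in zip(df.index, df.itertuples())
    ]
    return genes, erfs, TruthTable(genes=df)


# ---------------------------------------------------------------------------
# coverage tracks


def track_key(assay: str, condition: str, strand: str | None = None) -> tuple:
    return (assay, condition, strand)


def _expected_density(
    config: SyntheticConfig, truth: pd.DataFrame, assay: str, condition: str, strand: str | None
) -> dict[str, np.ndarray]:
    """Expected signal density per bin for one track, per chromosome."""
    bw = config.bin_width
    n_bins = -(-config.chrom_length // bw)
    dens = {c: np.zeros(n_bins) for c in config.layout.chrom_names}
    mutant = condition == MUTANT
    for r in truth.itertuples():
        if assay == H3:
            d = config.h3_density
        elif assay == H2AX:
            d = config.h2ax_density
        elif assay == GH2AX:
            d = config.gh2ax_baseline_density
            if mutant and r.damaged:
                d *= config.damage_ratio
        elif assay == RNAPII:
            d = r.expression
            if mutant and r.stressed:
                d *= config.stress_rnapii_ratio
        elif assay == GRO:
            if r.strand != strand:
                continue  # nascent signal lives on the sense strand only
            d = r.expression
            if mutant and r.stressed:
                d *= config.stress_gro_ratio
        else:  # pragma: no cover
            raise ValueError(f"unknown assay {assay!r}")
        dens[r.chrom][r.start // bw : r.end // bw] += d
    return dens


def generate_tracks(
    config: SyntheticConfig,
    genes: Iterable[GeneModel] | None,
    truth: TruthTable,
) -> dict[tuple, CoverageTrack]:
    """Generate the 5 assays x 2 conditions coverage set (GRO per strand).

    Control densities are proportional to expression for RNAPII/GRO and flat
    for H3/H2AX/gamma-H2AX within genes; the mutant condition scales
    gamma-H2AX on damaged genes by ``damage_ratio`` and RNAPII/GRO on
    stressed genes by the stress ratios. Intergenic signal is zero.
    """
    config.validate()
    rng = stage_rng(config.seed, "tracks")
    layout = config.layout
    tracks: dict[tuple, CoverageTrack] = {}
    for assay in ASSAYS:
        strands = ("+", "-") if assay == GRO else (None,)
        for condition in CONDITIONS:
            for strand in strands:
                dens = _expected_density(config, truth.genes, assay, condition, strand)
                values = {}
                for chrom, d in dens.items():
                    if config.noise:
                        counts = rng.poisson(d * config.bin_width)
                        values[chrom] = counts / config.bin_width
                    else:
                        values[chrom] = d
                tracks[track_key(assay, condition, strand)] = CoverageTrack.from_dense_bins(
                    layout,
                    values,
                    config.bin_width,
                    assay=assay,
                    condition=condition,
                    strand=strand,
                )
    return tracks


# ---------------------------------------------------------------------------
# mutations


@dataclass
class MutationSim:
    """Variant call sets from the panel mutation simulation.

    Records are `(chrom, pos, ref, alt)` with 1-based positions. `baseline`
    is shared; each condition's endpoint is baseline plus its de novo
    records.
    """

    baseline: list[tuple]
    endpoint: dict[str, list[tuple]]
    sites: pd.DataFrame  # per de novo site: condition, gene, generation, kind


_BASES = np.array(list("ACGT"))


def _draw_variant(rng: np.random.Generator, config: SyntheticConfig) -> tuple[str, str, str]:
    """Random (ref, alt, kind) per the configured substitution/indel mix."""
    u = rng.random()
    ref = str(rng.choice(_BASES))
    if u < config.substitution_fraction:
        alt = str(rng.choice(_BASES[_BASES != ref]))
        return ref, alt, "substitution"
    if u < config.substitution_fraction + config.deletion_fraction:
        return ref + str(rng.choice(_BASES)), ref, "deletion"
    return ref, ref + str(rng.choice(_BASES)), "insertion"


def simulate_mutations(
    config: SyntheticConfig,
    truth: TruthTable,
    seed: int | None = None,
) -> MutationSim:
    """Accumulate de novo mutations over the panel.

    Each panel site mutates independently with probability
    ``1 - (1 - mu)^g`` across ``g`` generations (rate scaled by
    ``mutant_rate_factor`` in the mutant condition); the generation of
    origin of each mutation is drawn from the conditional first-hit law.
    """
    config.validate()
    rng = (
        stage_rng(config.seed, "mutations")
        if seed is None
        else np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["mutations"],)))
    )
    panel_genes = truth.genes[truth.genes["panel"]]
    if panel_genes.empty:
        raise ConfigError("no panel genes defined")

    # shared baseline variants at random panel sites
    baseline: list[tuple] = []
    taken: set[tuple[str, int]] = set()
    gene_rows = list(panel_genes.itertuples())
    for _ in range(config.n_baseline_variants):
        r = gene_rows[rng.integers(len(gene_rows))]
        pos = int(rng.integers(r.start, r.end)) + 1
        if (r.chrom, pos) in taken:
            continue
        taken.add((r.chrom, pos))
        ref, alt, _kind = _draw_variant(rng, config)
        baseline.append((r.chrom, pos, ref, alt))
    baseline.sort()

    g = config.generations
    endpoint: dict[str, list[tuple]] = {}
    site_rows = []
    for condition in CONDITIONS:
        mu = config.mu * (config.mutant_rate_factor if condition == MUTANT else 1.0)
        if mu > 1.0:
            raise ConfigError("effective mutation rate exceeds 1")
        p_site = -np.expm1(g * np.log1p(-mu)) if 0 < mu < 1 else (float(g > 0) if mu == 1 else 0.0)
        de_novo: list[tuple] = []
        if g > 0 and mu > 0:
            gens = np.arange(1, g + 1)
            w = mu * (1.0 - mu) ** (gens - 1)
            w = w / w.sum()
            for r in gene_rows:
                length = int(r.end - r.start)
                k = rng.binomial(length, p_site)
                if k == 0:
                    continue
                offsets = rng.choice(length, size=k, replace=False)
                for off in np.sort(offsets):
                    pos = int(r.start + off) + 1
                    if (r.chrom, pos) in taken:
                        continue
                    ref, alt, kind = _draw_variant(rng, config)
                    gen0 = int(rng.choice(gens, p=w))
                    de_novo.append((r.chrom, pos, ref, alt))
                    site_rows.append(
                        {
                            "condition": condition,
                            "gene_id": r.Index,
                            "chrom": r.chrom,
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                            "kind": kind,
                            "generation": gen0,
                        }
                    )
        endpoint[condition] = sorted(baseline + de_novo)
    sites = pd.DataFrame(
        site_rows,
        columns=["condition", "gene_id", "chrom", "pos", "ref", "alt", "kind", "generation"],
    )
    return MutationSim(baseline=baseline, endpoint=endpoint, sites=sites)


# ---------------------------------------------------------------------------
# on-disk study


def write_study(
    outdir: str | Path,
    config: SyntheticConfig,
    genes: list[GeneModel],
    erfs: IntervalSet,
    truth: TruthTable,
    tracks: dict[tuple, CoverageTrack],
    mutsim: MutationSim | None = None,
) -> dict[str, Path]:
    """Write the whole synthetic study to `outdir` in standard text formats.

    Layout: `genes.bed`, `erfs.bed`, `chrom.sizes`, `truth_genes.tsv`,
    `config.yaml`, `tracks/<assay>_<cond>[_strand].bedGraph`, and
    `vcf/{baseline,endpoint_*}.vcf`.
    """
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    provenance = f"stresscan synthetic study; seed={config.seed}"
    paths: dict[str, Path] = {}

    paths["config"] = outdir / "config.yaml"
    config.to_yaml(paths["config"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    config.layout.to_chrom_sizes(paths["chrom_sizes"])
    paths["genes"] = outdir / "genes.bed"
    write_genes(genes, paths["genes"])
    paths["erfs"] = outdir / "erfs.bed"
    erfs.to_bed(paths["erfs"])
    paths["truth"] = outdir / "truth_genes.tsv"
    truth.to_tsv(paths["truth"], header=provenance)

    strand_token = {None: "", "+": "_plus", "-": "_minus"}
    for (assay, condition, strand), track in tracks.items():
        name = f"{assay}_{CONDITION_TOKENS[condition]}{strand_token[strand]}.bedGraph"
        p = outdir / "tracks" / name
        track.to_bedgraph(p, header=provenance)
        paths[f"track:{assay}:{condition}:{strand}"] = p

    if mutsim is not None:
        from .mutation_burden import write_vcf

        vcfdir = outdir / "vcf"
        vcfdir.mkdir(exist_ok=True)
        paths["vcf_baseline"] = vcfdir / "baseline.vcf"
        write_vcf(mutsim.baseline, paths["vcf_baseline"], config.layout)
        for condition in CONDITIONS:
            key = f"vcf_endpoint_{CONDITION_TOKENS[condition]}"
            paths[key] = vcfdir / f"endpoint_{CONDITION_TOKENS[condition]}.vcf"
            write_vcf(mutsim.endpoint[condition], paths[key], config.layout)
        paths["sites"] = outdir / "truth_sites.tsv"
        with open(paths["sites"], "w") as fh:
            fh.write(f"# {provenance}\n")
            mutsim.sites.to_csv(fh, sep="\t", index=False)
    return paths
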