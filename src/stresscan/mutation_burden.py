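"""De novo mutation counting in a targeted panel and the binomial burden test.

Baseline and endpoint variant call sets are compared by site identity
(chrom, pos, ref, alt); records must be in minimal representation so the
match is well defined. The observed de novo count over L panel base pairs
after g generations is tested against Binomial(L, 1 - (1 - mu)^g) with an
upper-tail p-value, mu being the per-site per-generation mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .annotations_io import GeneModel, GenomeLayout, IntervalSet

__all__ = [
    "Panel",
    "BurdenResult",
    "read_vcf",
    "write_vcf",
    "count_de_novo",
    "burden_test",
]

VariantRecord = tuple  # (chrom: str, pos: int 1-based, ref: str, alt: str)


@dataclass
class Panel:
    """Targeted panel: intervals and total size L (bp, overlaps merged)."""

    intervals: IntervalSet

    @property
    def L(self) -> int:
        return self.intervals.merged_length()

    @classmethod
    def from_genes(cls, genes: Iterable[GeneModel]) -> "Panel":
        return cls(IntervalSet([(g.chrom, g.start, g.end) for g in genes]))

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout | None = None) -> "Panel":
        return cls(IntervalSet.from_bed(path, layout=layout))

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position `pos` falls in the panel."""
        return self.intervals.overlaps(chrom, pos - 1, pos)


# ---------------------------------------------------------------------------
# VCF IO


def write_vcf(
    records: Sequence[VariantRecord], path: str | Path, layout: GenomeLayout
) -> None:
    """Write site-only records as minimal VCFv4.2 text."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stresscan\n")
        for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(records):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read (chrom, pos, ref, alt) records from a VCF via pysam; multiallelic
    sites are expanded to one record per ALT."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append((rec.chrom, rec.pos, rec.ref, alt))
    return out


# ---------------------------------------------------------------------------
# de novo counting


def _is_minimal(ref: str, alt: str) -> bool:
    """Minimal representation: no trimmable shared leading/trailing base."""
    if ref == alt:
        return False
    if len(ref) > 1 and len(alt) > 1:
        if ref[-1] == alt[-1] or ref[0] == alt[0]:
            return False
    return True


def count_de_novo(
    baseline: Sequence[VariantRecord],
    endpoint: Sequence[VariantRecord],
    panel: Panel,
) -> tuple[int, list[VariantRecord]]:
    """Count endpoint records inside the panel that are absent from baseline.

    Matching is on (chrom, pos, ref, alt) only — genotype, zygosity and
    allele fraction are ignored. Non-minimal indel representations raise, as
    identity matching would silently miscount them.
    """
    for src, recs in (("baseline", baseline), ("endpoint", endpoint)):
        for chrom, pos, ref, alt in recs:
            if not _is_minimal(ref, alt):
                raise ValueError(
                    f"{src} record {chrom}:{pos} {ref}>{alt} is not in minimal "
                    "representation; normalize (left-align, trim) calls first"
                )
    base = {tuple(r) for r in baseline}
    novel = [
        r for r in endpoint
        if tuple(r) not in base and panel.contains(r[0], r[1])
    ]
    return len(novel), sorted(novel)


# ---------------------------------------------------------------------------
# burden test


@dataclass(frozen=True)
class BurdenResult:
    """Observed de novo count against the Binomial(L, 1-(1-mu)^g) expectation."""

    k: int
    L: int
    mu: float
    generations: int
    p_site: float
    expected: float
    p_value: float


def burden_test(k: int, panel: "Panel | int", mu: float, generations: int) -> BurdenResult:
    """Upper-tail binomial test P(X >= k), X ~ Binomial(L, 1 - (1 - mu)^g).

    `panel` may be a Panel (L = merged interval length) or the integer L
    directly. The tail is evaluated through the regularized incomplete beta
    function, accurate for very small p.
    """
    L = panel.L if isinstance(panel, Panel) else int(panel)
    if k < 0:
        raise ValueError("observed count k must be >= 0")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if L < 1:
        raise ValueError("panel size L must be >= 1")
    if mu == 1.0 and generations > 0:
        p_site = 1.0
    elif mu == 0.0 or generations == 0:
        p_site = 0.0
    else:
        p_site = float(-np.expm1(generations * np.log1p(-mu)))
    expected = L * p_site
    if k == 0:
        p = 1.0
    elif k > L:
        raise ValueError("k cannot exceed the number of panel sites L")
    elif p_site == 0.0:
        p = 0.0
    else:
        # P(X >= k) = I_p(k, L - k + 1), the regularized incomplete beta
        p = float(special.betainc(k, L - k + 1, p_site))
    return BurdenResult(
        k=k, L=L, mu=mu, generations=generations,
        p_site=p_site, expected=expected, p_value=p,
    )
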