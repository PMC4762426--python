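"""Headline gene sets: top-decile DNA-damage genes and transcription-stress genes.

A gene is under transcription stress when chromatin-bound RNAPII goes up
without a matching rise in nascent transcription: RNAPII mutant:control
ratio strictly > 1 and GRO ratio strictly < 1. The stress score is the
ratio of ratios (RNAPII/GRO), which directly measures the uncoupling and is
monotone in both defining criteria. Top fractions use round-half-up, which
reproduces 414 of 4140 and 216 of 2158.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import zscore

__all__ = ["top_fraction_size", "damage_rank", "stress_call", "stress_rank", "build_calls"]

logger = logging.getLogger(__name__)


def top_fraction_size(n: int, fraction: float = 0.10) -> int:
    """Round-half-up size of the top `fraction` of `n` items (at least 1)."""
    if n <= 0:
        return 0
    size = int(math.floor(n * fraction + 0.5))
    if n < 10:
        warnings.warn(f"top-fraction selection on only {n} items; using max(1, ...)")
    return max(1, size)


def _rank_desc(values: pd.Series) -> pd.Series:
    """Dense 1..n ranks, largest value first, ties broken by gene_id."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(values.index)


def damage_rank(ratios: pd.Series, decile: float = 0.10) -> pd.DataFrame:
    """Rank active genes by damage ratio (gamma-H2AX/H3, mutant:control),
    descending, and flag the top round-half-up(`decile` x n) genes.

    Ties are broken lexicographically on gene_id for reproducibility.
    Returns a frame indexed like `ratios` with columns `damage_ratio`,
    `damage_rank`, `top_damage`.
    """
    if ratios.isna().any():
        raise ValueError("damage ratios contain NaN")
    rank = _rank_desc(ratios)
    k = top_fraction_size(len(ratios), decile)
    return pd.DataFrame(
        {"damage_ratio": ratios, "damage_rank": rank, "top_damage": rank <= k}
    )


def stress_call(rnapii_ratio, gro_ratio):
    """Transcription-stress flag: RNAPII ratio > 1 and GRO ratio < 1 (strict)."""
    r = np.asarray(rnapii_ratio, dtype=float)
    g = np.asarray(gro_ratio, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(~np.isfinite(g)) or np.any(r <= 0) or np.any(g <= 0):
        raise ValueError("ratios must be finite and > 0")
    out = (r > 1.0) & (g < 1.0)
    return bool(out) if out.ndim == 0 else out


def stress_rank(
    rnapii_ratio: pd.Series, gro_ratio: pd.Series, decile: float = 0.10
) -> pd.DataFrame:
    """Flag stress genes, score them by RNAPII/GRO ratio-of-ratios, and flag
    the top round-half-up(`decile` x n_stress) among them.

    Non-stress genes get NaN stress_rank and False top_stress.
    """
    stressed = pd.Series(stress_call(rnapii_ratio.values, gro_ratio.values), index=rnapii_ratio.index)
    score = rnapii_ratio / gro_ratio
    out = pd.DataFrame(
        {
            "rnapii_ratio": rnapii_ratio,
            "gro_ratio": gro_ratio,
            "stressed": stressed,
            "stress_score": score,
            "stress_rank": np.nan,
            "top_stress": False,
        }
    )
    n_stress = int(stressed.sum())
    if n_stress == 0:
        logger.info("stress_rank: no transcription-stress genes")
        return out
    rank = _rank_desc(score[stressed])
    k = top_fraction_size(n_stress, decile)
    out.loc[rank.index, "stress_rank"] = rank.astype(float)
    out.loc[rank.index, "top_stress"] = rank <= k
    return out


def build_calls(ratio_table: pd.DataFrame, decile: float = 0.10) -> pd.DataFrame:
    """Full per-gene call table from a ratio table restricted to active genes.

    Combines damage ranking (with Z-scores of log2 damage ratios, as the
    damage ranking is a strictly monotone function of the raw ratio the two
    statistics induce the same order), stress flags, and both top-decile
    memberships. Input must have columns `gh2ax_ratio`, `rnapii_ratio`,
    `gro_ratio`.
    """
    dmg = damage_rank(ratio_table["gh2ax_ratio"], decile)
    dmg["damage_z"] = zscore(np.log2(ratio_table["gh2ax_ratio"].values))
    stress = stress_rank(ratio_table["rnapii_ratio"], ratio_table["gro_ratio"], decile)
    calls = pd.concat([dmg, stress], axis=1)
    calls.index.name = "gene_id"
    calls.attrs["decile"] = decile
    return calls
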