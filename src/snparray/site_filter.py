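"""Per-call invalidation and per-site candidate filters.

A genotype call is invalidated (treated as missing) when its read depth is
outside [dp_min, dp_max] or its genotype quality is below gq_min; the
defaults DP < 10, DP > 100, GQ < 20 use strict inequalities, so boundary
values survive. A site is then dropped when its missing rate exceeds 0.1,
its minor allele frequency over valid calls is below 0.05, or an indel lies
within 20 bp of it. Removal criteria are strict inequalities, so MAF = 0.05
and missing rate = 0.1 pass.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import Genotype, SiteCall, Variant, VariantClass

__all__ = [
    "SiteStats",
    "call_is_valid",
    "valid_call_mask",
    "site_stats",
    "flag_near_indel",
    "apply_site_filters",
    "filter_report",
]

DP_MIN_DEFAULT = 10
DP_MAX_DEFAULT = 100
GQ_MIN_DEFAULT = 20
MAF_MIN_DEFAULT = 0.05
MISSING_MAX_DEFAULT = 0.1
INDEL_RADIUS_DEFAULT = 20


@dataclass(frozen=True)
class SiteStats:
    """Filter diagnostics for one SNP site."""

    missing_rate: float
    maf: float  # nan when no valid call remains
    near_indel: bool
    passed: bool


def call_is_valid(
    call: SiteCall,
    dp_min: int = DP_MIN_DEFAULT,
    dp_max: int = DP_MAX_DEFAULT,
    gq_min: int = GQ_MIN_DEFAULT,
) -> bool:
    """True when a call's depth and quality clear the invalidation thresholds.

    Any one failing condition invalidates the call (OR semantics); a missing
    genotype is never valid.
    """
    if not 0 < dp_min < dp_max or gq_min <= 0:
        raise ValueError("thresholds must be positive with dp_min < dp_max")
    if call.gt is Genotype.MISSING:
        return False
    return dp_min <= call.dp <= dp_max and call.gq >= gq_min


def valid_call_mask(
    v: Variant,
    dp_min: int = DP_MIN_DEFAULT,
    dp_max: int = DP_MAX_DEFAULT,
    gq_min: int = GQ_MIN_DEFAULT,
) -> np.ndarray:
    """Vectorised call_is_valid over one variant's samples."""
    return (
        (v.gts != Genotype.MISSING)
        & (v.dps >= dp_min)
        & (v.dps <= dp_max)
        & (v.gqs >= gq_min)
    )


def site_stats(
    v: Variant,
    near_indel: bool = False,
    maf_min: float = MAF_MIN_DEFAULT,
    missing_max: float = MISSING_MAX_DEFAULT,
    dp_min: int = DP_MIN_DEFAULT,
    dp_max: int = DP_MAX_DEFAULT,
    gq_min: int = GQ_MIN_DEFAULT,
) -> SiteStats:
    """Missing rate and MAF for one SNP site, plus the pass verdict.

    The missing rate counts genotypes that are absent or invalidated; the
    MAF denominator uses only the remaining valid calls (2 alleles each).
    """
    if v.vclass is not VariantClass.SNP:
        raise ValueError(f"{v.marker_id}: site_stats requires a SNP")
    if v.n_samples == 0:
        raise ValueError(f"{v.marker_id}: no samples")
    valid = valid_call_mask(v, dp_min, dp_max, gq_min)
    n_valid = int(valid.sum())
    missing_rate = 1.0 - n_valid / v.n_samples
    if n_valid == 0:
        return SiteStats(1.0, float("nan"), near_indel, False)
    alt_alleles = int(v.gts[valid].sum())
    p = alt_alleles / (2 * n_valid)
    maf = min(p, 1.0 - p)
    passed = maf >= maf_min and missing_rate <= missing_max and not near_indel
    return SiteStats(missing_rate, maf, near_indel, passed)


def flag_near_indel(
    snps: Sequence[Variant],
    indels: Sequence[Variant],
    radius_bp: int = INDEL_RADIUS_DEFAULT,
) -> list[bool]:
    """Flag SNPs within radius_bp (inclusive) of an indel's anchor position.

    Only the indel's VCF anchor position is considered; indel length is
    ignored.
    """
    by_scaffold: dict[str, list[int]] = {}
    for iv in indels:
        by_scaffold.setdefault(iv.scaffold_id, []).append(iv.pos)
    for positions in by_scaffold.values():
        positions.sort()
    flags = []
    for snp in snps:
        positions = by_scaffold.get(snp.scaffold_id)
        if not positions:
            flags.append(False)
            continue
        i = bisect.bisect_left(positions, snp.pos - radius_bp)
        flags.append(i < len(positions) and positions[i] <= snp.pos + radius_bp)
    return flags


def apply_site_filters(
    variants: Sequence[Variant],
    maf_min: float = MAF_MIN_DEFAULT,
    missing_max: float = MISSING_MAX_DEFAULT,
    indel_radius: int = INDEL_RADIUS_DEFAULT,
    dp_min: int = DP_MIN_DEFAULT,
    dp_max: int = DP_MAX_DEFAULT,
    gq_min: int = GQ_MIN_DEFAULT,
) -> tuple[list[Variant], list[SiteStats]]:
    """Filter a cohort's variants down to the candidate SNP pool.

    Indels in the input are used for the proximity flag and are never
    emitted themselves. Returns the passing SNPs (input order preserved)
    and one :class:`SiteStats` per input SNP.
    """
    snps = [v for v in variants if v.vclass is VariantClass.SNP]
    indels = [v for v in variants if v.vclass is VariantClass.INDEL]
    near = flag_near_indel(snps, indels, indel_radius)
    stats = [
        site_stats(v, flag, maf_min, missing_max, dp_min, dp_max, gq_min)
        for v, flag in zip(snps, near)
    ]
    passing = [v for v, st in zip(snps, stats) if st.passed]
    return passing, stats


def filter_report(snps: Sequence[Variant], stats: Sequence[SiteStats]) -> pd.DataFrame:
    """Tabulate per-site filter diagnostics (one row per input SNP)."""
    return pd.DataFrame(
        {
            "marker_id": [v.marker_id for v in snps],
            "scaffold": [v.scaffold_id for v in snps],
            "pos": [v.pos for v in snps],
            "missing_rate": [st.missing_rate for st in stats],
            "maf": [st.maf for st in stats],
            "near_indel": [st.near_indel for st in stats],
            "passed": [st.passed for st in stats],
        }
    )
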