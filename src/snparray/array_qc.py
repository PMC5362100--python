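"""Post-genotyping quality control and summary statistics.

Sample gating uses the platform defaults: a sample passes when its call
rate is at least 0.970 and, when a DQC value is available, the DQC is at
least 0.82. Markers are then sorted into the six clustering categories
(PolyHighResolution, NoMinorHom, MonoHighResolution, OTV,
CallRateBelowThreshold, Other); category assignment here is call-based —
OTV is intensity-defined and can only enter through externally supplied
labels. "Converted" markers are the polymorphic, well-resolved ones:
PolyHighResolution plus NoMinorHom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .variant_io import NOCALL, CallMatrix

__all__ = [
    "SNPCategory",
    "SampleQC",
    "CR_THRESHOLD_DEFAULT",
    "DQC_THRESHOLD_DEFAULT",
    "sample_qc",
    "sample_qc_table",
    "classify_snp",
    "classify_matrix",
    "ConversionSummary",
    "conversion_summary",
    "snp_type_summary",
    "spacing_distribution",
    "gene_snp_distribution",
    "SPACING_BIN_EDGES",
]

CR_THRESHOLD_DEFAULT = 0.970
DQC_THRESHOLD_DEFAULT = 0.82
SPACING_BIN_EDGES = (200, 500, 1000, 2000, 3000, 4000, 5000)


class SNPCategory(enum.Enum):
    POLY_HIGH_RESOLUTION = "PolyHighResolution"
    NO_MINOR_HOM = "NoMinorHom"
    MONO_HIGH_RESOLUTION = "MonoHighResolution"
    OTV = "OTV"
    CALL_RATE_BELOW_THRESHOLD = "CallRateBelowThreshold"
    OTHER = "Other"


CONVERTED_CATEGORIES = (SNPCategory.POLY_HIGH_RESOLUTION, SNPCategory.NO_MINOR_HOM)


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    call_rate: float
    dqc: float | None
    passed: bool


def sample_qc(
    matrix: CallMatrix,
    cr_threshold: float = CR_THRESHOLD_DEFAULT,
    dqc_threshold: float = DQC_THRESHOLD_DEFAULT,
) -> list[SampleQC]:
    """Per-sample call rate and pass/fail against the CR and DQC cutoffs."""
    if matrix.calls.empty:
        raise ValueError("cannot QC an empty call matrix")
    called = (matrix.calls != NOCALL).mean(axis=0)
    out = []
    for sample in matrix.sample_ids:
        cr = float(called[sample])
        dqc = None
        if matrix.dqc is not None and not pd.isna(matrix.dqc[sample]):
            dqc = float(matrix.dqc[sample])
        passed = cr >= cr_threshold and (dqc is None or dqc >= dqc_threshold)
        out.append(SampleQC(sample, cr, dqc, passed))
    return out


def sample_qc_table(results: Sequence[SampleQC]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "call_rate": [r.call_rate for r in results],
            "dqc": [r.dqc if r.dqc is not None else np.nan for r in results],
            "passed": [r.passed for r in results],
        }
    )


def classify_snp(
    calls: Sequence[str], cr_threshold: float = CR_THRESHOLD_DEFAULT
) -> SNPCategory:
    """Classify one marker's call vector (over passing samples only).

    A marker call rate below the threshold dominates; otherwise the set of
    observed genotype classes decides: all three of {AA, AB, BB} present is
    PolyHighResolution, one homozygote class plus hets is NoMinorHom, a
    single homozygote class alone is MonoHighResolution, and any other
    pattern (both homozygotes with no het, or hets only) is Other.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call vector")
    n_called = sum(c != NOCALL for c in calls)
    if n_called / len(calls) < cr_threshold:
        return SNPCategory.CALL_RATE_BELOW_THRESHOLD
    present = {c for c in calls if c != NOCALL}
    homs = present & {"AA", "BB"}
    het = "AB" in present
    if len(homs) == 2 and het:
        return SNPCategory.POLY_HIGH_RESOLUTION
    if len(homs) == 1 and het:
        return SNPCategory.NO_MINOR_HOM
    if len(homs) == 1 and not het:
        return SNPCategory.MONO_HIGH_RESOLUTION
    return SNPCategory.OTHER


def classify_matrix(
    matrix: CallMatrix,
    passing_samples: Sequence[str] | None = None,
    cr_threshold: float = CR_THRESHOLD_DEFAULT,
    external_labels: Mapping[str, SNPCategory] | None = None,
) -> pd.Series:
    """Per-marker categories; external (e.g. intensity-based OTV) labels win."""
    sub = matrix.subset_samples(passing_samples) if passing_samples else matrix
    cats = {
        marker: classify_snp(row, cr_threshold)
        for marker, row in zip(sub.marker_ids, sub.calls.to_numpy())
    }
    if external_labels:
        for marker, label in external_labels.items():
            if marker in cats:
                cats[marker] = label
    return pd.Series(cats, name="category").reindex(matrix.marker_ids)


@dataclass(frozen=True)
class ConversionSummary:
    table: pd.DataFrame  # category counts and percentages
    converted: int
    converted_pct: float


def conversion_summary(
    categories: Iterable[SNPCategory] | Mapping[SNPCategory, int],
) -> ConversionSummary:
    """Category counts/percentages plus the converted (polymorphic) total.

    Accepts either one category per designed marker or precomputed
    category counts. Percentages are of the design total, one decimal.
    """
    if isinstance(categories, Mapping):
        counts = {c: int(categories.get(c, 0)) for c in SNPCategory}
    else:
        counts = {c: 0 for c in SNPCategory}
        for c in categories:
            counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no markers to summarise")
    table = pd.DataFrame(
        {
            "category": [c.value for c in SNPCategory],
            "count": [counts[c] for c in SNPCategory],
            "percent": [round_half_up(100 * counts[c] / total, 1) for c in SNPCategory],
        }
    )
    converted = sum(counts[c] for c in CONVERTED_CATEGORIES)
    return ConversionSummary(
        table, converted, round_half_up(100 * converted / total, 1)
    )


def snp_type_summary(design: pd.DataFrame, converted_ids: Iterable[str]) -> pd.DataFrame:
    """Per allele-pair marker counts and conversion rates (plus a totals row).

    Types are unordered ref/alt pairs printed alphabetically (A/C ... G/T);
    no strand collapsing, so A/G and C/T stay separate. Rates are rounded
    to 2 decimals, shares to 1.
    """
    converted = set(converted_ids)
    types = design.apply(lambda r: "/".join(sorted((r["ref"], r["alt"]))), axis=1)
    df = pd.DataFrame(
        {"type": types, "converted": design["marker_id"].isin(converted)}
    )
    grouped = df.groupby("type", sort=True).agg(
        on_chip=("type", "size"), converted=("converted", "sum")
    )
    grouped = grouped.sort_values(["on_chip", "type"], ascending=[False, True])
    n_chip, n_conv = int(grouped["on_chip"].sum()), int(grouped["converted"].sum())
    rows = []
    for t, row in grouped.iterrows():
        rows.append(
            {
                "type": t,
                "on_chip": int(row["on_chip"]),
                "on_chip_pct": round_half_up(100 * row["on_chip"] / n_chip, 1),
                "converted": int(row["converted"]),
                "converted_pct": (
                    round_half_up(100 * row["converted"] / n_conv, 1)
                    if n_conv
                    else np.nan
                ),
                "conversion_rate": round_half_up(row["converted"] / row["on_chip"], 2),
            }
        )
    rows.append(
        {
            "type": "Total",
            "on_chip": n_chip,
            "on_chip_pct": 100.0,
            "converted": n_conv,
            "converted_pct": 100.0 if n_conv else np.nan,
            "conversion_rate": round_half_up(n_conv / n_chip, 2) if n_chip else np.nan,
        }
    )
    return pd.DataFrame(rows)


def spacing_distribution(
    markers: pd.DataFrame,
    bin_edges: Sequence[int] = SPACING_BIN_EDGES,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Histogram of consecutive same-scaffold marker intervals.

    A scaffold with k markers contributes k-1 intervals, so the percentage
    denominator is n_markers - n_scaffolds. Alongside the histogram, two
    average-spacing readings are reported: total spanned length over total
    intervals, and the unweighted mean of per-scaffold average spacings.
    """
    edges = list(bin_edges)
    labels = [f"<{edges[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
    labels += [f">{edges[-1]}"]
    counts = np.zeros(len(labels), dtype=int)
    total_span = 0
    per_scaffold_means = []
    n_intervals = 0
    for _, grp in markers.groupby("scaffold", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        n_intervals += len(gaps)
        total_span += int(pos[-1] - pos[0])
        per_scaffold_means.append(gaps.mean())
        idx = np.searchsorted(edges, gaps, side="right")
        np.add.at(counts, idx, 1)
    hist = pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percent": [
                round_half_up(100 * c / n_intervals, 1) if n_intervals else np.nan
                for c in counts
            ],
        }
    )
    stats = {
        "n_intervals": float(n_intervals),
        "mean_spacing_bp": total_span / n_intervals if n_intervals else float("nan"),
        "mean_of_scaffold_means_bp": (
            float(np.mean(per_scaffold_means)) if per_scaffold_means else float("nan")
        ),
    }
    return hist, stats


GENE_BIN_LABELS = ("1", "2-5", "6-10", ">10")


def gene_snp_distribution(annotation: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene marker counts binned {1, 2-5, 6-10, >10}, over genic markers.

    Gene-associated markers are those with any non-intergenic effect; the
    mean is markers-in-genes over genes hit, one decimal.
    """
    genic = annotation[
        (annotation["effect"] != "intergenic") & (annotation["gene_id"] != ".")
    ]
    per_gene = genic.groupby("gene_id").size()
    bins = {label: 0 for label in GENE_BIN_LABELS}
    for n in per_gene:
        if n == 1:
            bins["1"] += 1
        elif n <= 5:
            bins["2-5"] += 1
        elif n <= 10:
            bins["6-10"] += 1
        else:
            bins[">10"] += 1
    n_genes = len(per_gene)
    hist = pd.DataFrame(
        {
            "bin": list(bins),
            "count": list(bins.values()),
            "percent": [
                round_half_up(100 * c / n_genes, 1) if n_genes else np.nan
                for c in bins.values()
            ],
        }
    )
    stats = {
        "n_genes": float(n_genes),
        "n_markers_in_genes": float(len(genic)),
        "mean_snps_per_gene": (
            round_half_up(len(genic) / n_genes, 1) if n_genes else float("nan")
        ),
    }
    return hist, stats
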