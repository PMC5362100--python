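"""Array-versus-sequencing genotype concordance.

For each marker, the genotypes of samples called on both platforms are
compared; the concordance rate is the matching fraction. Markers with no
comparable sample have an undefined rate and are excluded from summaries
over converted markers; in the all-on-chip mean, designed markers that
never produced a comparable call contribute a rate of 0 (a marker that
cannot be called at all is a failed assay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .variant_io import NOCALL, CallMatrix

__all__ = [
    "ConcordanceRecord",
    "genotype_concordance",
    "concordance_summary",
    "concordance_table",
    "ConcordanceSummary",
]


@dataclass(frozen=True)
class ConcordanceRecord:
    marker_id: str
    n_compared: int
    n_match: int

    def __post_init__(self) -> None:
        if self.n_match > self.n_compared:
            raise ValueError(f"{self.marker_id}: matches exceed comparisons")

    @property
    def rate(self) -> float:
        """Matching fraction; NaN when no sample was comparable."""
        return self.n_match / self.n_compared if self.n_compared else float("nan")


def genotype_concordance(
    array: CallMatrix,
    seq: CallMatrix,
    shared_samples: Sequence[str] | None = None,
) -> list[ConcordanceRecord]:
    """Per-marker concordance between two call matrices.

    Both matrices must carry the shared samples and the array's markers;
    the sequencing matrix is assumed to be expressed in the design's
    ref/alt (A/B) orientation already. Samples missing on either platform
    at a marker drop out of both numerator and denominator.
    """
    if shared_samples is None:
        shared_samples = [s for s in array.sample_ids if s in set(seq.sample_ids)]
    shared = list(shared_samples)
    if not shared:
        raise ValueError("no shared samples between the two matrices")
    missing_m = [m for m in array.marker_ids if m not in set(seq.marker_ids)]
    if missing_m:
        raise ValueError(
            f"markers absent from the sequencing matrix: {missing_m[:5]}"
        )
    a = array.calls.loc[array.marker_ids, shared].to_numpy()
    b = seq.calls.loc[array.marker_ids, shared].to_numpy()
    both = (a != NOCALL) & (b != NOCALL)
    out = []
    for i, marker in enumerate(array.marker_ids):
        n_cmp = int(both[i].sum())
        n_match = int((both[i] & (a[i] == b[i])).sum())
        out.append(ConcordanceRecord(marker, n_cmp, n_match))
    return out


def concordance_table(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in records],
            "n_compared": [r.n_compared for r in records],
            "n_match": [r.n_match for r in records],
            "rate": [r.rate for r in records],
        }
    )


@dataclass(frozen=True)
class ConcordanceSummary:
    mean_converted: float
    mean_all_on_chip: float
    n_converted_with_rate: int
    n_on_chip: int
    binned: pd.DataFrame
    share_above_threshold_pct: float
    threshold: float


def concordance_summary(
    records: Sequence[ConcordanceRecord] | np.ndarray,
    converted_ids: Iterable[str] | None = None,
    design_ids: Iterable[str] | None = None,
    threshold: float = 0.971,
    bin_width: float = 0.02,
) -> ConcordanceSummary:
    """Mean rates over converted and over all on-chip markers, plus bins.

    ``records`` may also be a plain array of per-marker rates (then all
    markers count as converted). Undefined rates are excluded from the
    converted mean; on-chip markers without a record enter the all-chip
    mean as 0. The cumulative share of converted markers with a rate
    strictly above ``threshold`` is reported as a percentage.
    """
    if isinstance(records, np.ndarray):
        rate_by_marker = {str(i): float(r) for i, r in enumerate(records)}
    else:
        rate_by_marker = {r.marker_id: r.rate for r in records}
    converted = (
        set(converted_ids) if converted_ids is not None else set(rate_by_marker)
    )
    design = set(design_ids) if design_ids is not None else set(rate_by_marker)

    conv_rates = np.array(
        [
            rate_by_marker[m]
            for m in converted
            if m in rate_by_marker and not np.isnan(rate_by_marker[m])
        ]
    )
    all_rates = np.array(
        [
            0.0
            if (m not in rate_by_marker or np.isnan(rate_by_marker[m]))
            else rate_by_marker[m]
            for m in design
        ]
    )
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    edges[-1] = 1.0 + 1e-9  # keep rate 1.0 in the top bin
    counts, _ = np.histogram(conv_rates, bins=edges)
    binned = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": np.minimum(edges[1:], 1.0),
            "count": counts,
        }
    )
    share = (
        100.0 * float((conv_rates > threshold).sum()) / len(conv_rates)
        if len(conv_rates)
        else float("nan")
    )
    return ConcordanceSummary(
        mean_converted=float(conv_rates.mean()) if len(conv_rates) else float("nan"),
        mean_all_on_chip=float(all_rates.mean()) if len(all_rates) else float("nan"),
        n_converted_with_rate=int(len(conv_rates)),
        n_on_chip=int(len(all_rates)),
        binned=binned,
        share_above_threshold_pct=round_half_up(share, 1)
        if not np.isnan(share)
        else share,
        threshold=threshold,
    )
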