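"""Genotyping accuracy from a full-sib family via Mendelian consistency.

Markers are grouped by the parents' genotype combination; within each group
an offspring call incompatible with Mendelian transmission is an
"unexpected" call. Same-homozygote parent pairs (AA x AA and BB x BB) fold
into one canonical class, while the hom x het orientations (AA x AB vs
AB x AA) stay separate. Markers where either parent is uncalled are
excluded entirely. The detectable error differs by design: AA x AA and
AA x BB expose every miscall of a certain kind, AA x AB / AB x AA expose
half (a miscall to the other permitted genotype is invisible), and
AB x AB can expose none.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._utils import round_half_up
from .variant_io import NOCALL, CallMatrix

__all__ = [
    "FamilyCombo",
    "classify_parent_combo",
    "expected_offspring",
    "allowed_offspring",
    "family_error_table",
    "per_individual_accuracy",
    "fisher_exact_2x2",
]


class FamilyCombo(enum.Enum):
    AAxAA = "AA x AA"
    AAxAB = "AA x AB"
    AAxBB = "AA x BB"
    ABxAA = "AB x AA"
    ABxAB = "AB x AB"
    UNTYPED = "untyped"


_HOMS = {"AA", "BB"}

COMBO_ROWS = (
    FamilyCombo.AAxAA,
    FamilyCombo.AAxAB,
    FamilyCombo.AAxBB,
    FamilyCombo.ABxAA,
    FamilyCombo.ABxAB,
)


def classify_parent_combo(p1: str, p2: str) -> FamilyCombo:
    """Canonical parent-genotype combination; parent order is preserved."""
    if p1 == NOCALL or p2 == NOCALL:
        return FamilyCombo.UNTYPED
    for g in (p1, p2):
        if g not in ("AA", "AB", "BB"):
            raise ValueError(f"invalid parental call {g!r}")
    if p1 in _HOMS and p2 in _HOMS:
        return FamilyCombo.AAxAA if p1 == p2 else FamilyCombo.AAxBB
    if p1 in _HOMS:  # p2 == AB
        return FamilyCombo.AAxAB
    if p2 in _HOMS:  # p1 == AB
        return FamilyCombo.ABxAA
    return FamilyCombo.ABxAB


def expected_offspring(combo: FamilyCombo) -> frozenset[str]:
    """Mendelian-permitted offspring genotypes, in canonical A/B labels."""
    if combo is FamilyCombo.UNTYPED:
        raise ValueError("untyped combo has no expected offspring set")
    return {
        FamilyCombo.AAxAA: frozenset({"AA"}),
        FamilyCombo.AAxAB: frozenset({"AA", "AB"}),
        FamilyCombo.ABxAA: frozenset({"AA", "AB"}),
        FamilyCombo.AAxBB: frozenset({"AB"}),
        FamilyCombo.ABxAB: frozenset({"AA", "AB", "BB"}),
    }[combo]


def allowed_offspring(p1: str, p2: str) -> frozenset[str]:
    """Permitted offspring genotypes for the *actual* parental calls."""
    alleles1 = frozenset(p1)
    alleles2 = frozenset(p2)
    return frozenset(
        "".join(sorted((a1, a2))) for a1 in alleles1 for a2 in alleles2
    )


def family_error_table(
    parent1: Mapping[str, str] | pd.Series,
    parent2: Mapping[str, str] | pd.Series,
    offspring: CallMatrix,
    concordance: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Mendelian-error accounting per parent combo, with a pooled totals row.

    Columns: combo, n_markers, n_error_markers, error_marker_pct,
    call_rate, concordance_rate, error_call_rate. An "error marker" has at
    least one unexpected offspring call; the error call rate is unexpected
    calls over non-missing offspring calls. A per-marker concordance map
    (against re-sequencing) is averaged per combo when supplied, otherwise
    that column is NaN.
    """
    p1 = pd.Series(parent1)
    p2 = pd.Series(parent2)
    markers = offspring.marker_ids
    missing = [m for m in markers if m not in p1.index or m not in p2.index]
    if missing:
        raise ValueError(f"markers lack parental calls: {missing[:5]}")

    calls = offspring.calls.loc[markers].to_numpy()
    rows = []
    pooled = {
        "n_markers": 0,
        "n_error_markers": 0,
        "n_calls": 0,
        "n_unexpected": 0,
        "conc": [],
    }
    combos = np.array(
        [classify_parent_combo(p1[m], p2[m]).value for m in markers]
    )
    called = calls != NOCALL
    unexpected = np.zeros_like(called)
    for i, m in enumerate(markers):
        if combos[i] == FamilyCombo.UNTYPED.value:
            continue
        allowed = allowed_offspring(p1[m], p2[m])
        unexpected[i] = called[i] & ~np.isin(calls[i], list(allowed))

    for combo in COMBO_ROWS:
        mask = combos == combo.value
        n_markers = int(mask.sum())
        n_calls = int(called[mask].sum())
        n_unexp = int(unexpected[mask].sum())
        n_err_markers = int((unexpected[mask].sum(axis=1) > 0).sum()) if n_markers else 0
        conc = np.nan
        if concordance is not None and n_markers:
            cs = pd.Series(concordance)
            vals = cs.reindex(np.array(markers)[mask]).dropna()
            conc = float(vals.mean()) if len(vals) else np.nan
            pooled["conc"].extend(vals.tolist())
        rows.append(
            {
                "combo": combo.value,
                "n_markers": n_markers,
                "n_error_markers": n_err_markers,
                "error_marker_pct": (
                    round_half_up(100 * n_err_markers / n_markers, 1)
                    if n_markers
                    else np.nan
                ),
                "call_rate": (
                    n_calls / (n_markers * calls.shape[1]) if n_markers else np.nan
                ),
                "concordance_rate": conc,
                "error_call_rate": n_unexp / n_calls if n_calls else np.nan,
            }
        )
        pooled["n_markers"] += n_markers
        pooled["n_error_markers"] += n_err_markers
        pooled["n_calls"] += n_calls
        pooled["n_unexpected"] += n_unexp

    nm, ne = pooled["n_markers"], pooled["n_error_markers"]
    rows.append(
        {
            "combo": "total",
            "n_markers": nm,
            "n_error_markers": ne,
            "error_marker_pct": round_half_up(100 * ne / nm, 1) if nm else np.nan,
            "call_rate": (
                pooled["n_calls"] / (nm * calls.shape[1]) if nm else np.nan
            ),
            "concordance_rate": (
                float(np.mean(pooled["conc"])) if pooled["conc"] else np.nan
            ),
            "error_call_rate": (
                pooled["n_unexpected"] / pooled["n_calls"]
                if pooled["n_calls"]
                else np.nan
            ),
        }
    )
    return pd.DataFrame(rows)


def per_individual_accuracy(
    parent1: Mapping[str, str] | pd.Series,
    parent2: Mapping[str, str] | pd.Series,
    offspring: CallMatrix,
) -> pd.DataFrame:
    """Per-offspring unexpected-call counts and accuracy, plus the mean.

    accuracy_i = 1 - unexpected_i / typed_i, where typed_i counts markers
    with both parents called and a non-missing call in offspring i. The
    mean accuracy appears in a final row with sample_id "mean".
    """
    p1 = pd.Series(parent1)
    p2 = pd.Series(parent2)
    markers = offspring.marker_ids
    calls = offspring.calls.loc[markers].to_numpy()
    typed_combo = np.array(
        [
            classify_parent_combo(p1[m], p2[m]) is not FamilyCombo.UNTYPED
            for m in markers
        ]
    )
    allowed_sets = [
        allowed_offspring(p1[m], p2[m]) if typed_combo[i] else frozenset()
        for i, m in enumerate(markers)
    ]
    rows = []
    accs = []
    for j, sample in enumerate(offspring.sample_ids):
        col = calls[:, j]
        typed = typed_combo & (col != NOCALL)
        n_typed = int(typed.sum())
        n_unexp = int(
            sum(
                1
                for i in np.nonzero(typed)[0]
                if col[i] not in allowed_sets[i]
            )
        )
        acc = 1.0 - n_unexp / n_typed if n_typed else np.nan
        accs.append(acc)
        rows.append(
            {
                "sample_id": sample,
                "n_typed": n_typed,
                "n_unexpected": n_unexp,
                "accuracy": acc,
            }
        )
    rows.append(
        {
            "sample_id": "mean",
            "n_typed": float(np.mean([r["n_typed"] for r in rows])),
            "n_unexpected": float(np.mean([r["n_unexpected"] for r in rows])),
            "accuracy": float(np.nanmean(accs)) if accs else np.nan,
        }
    )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact probability for a 2x2 contingency table.

    The two-sided p sums the hypergeometric point probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(_stats.fisher_exact(arr, alternative="two-sided")[1])
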