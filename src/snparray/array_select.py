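"""Window-based marker selection for the array design.

The genome is tiled by consecutive non-overlapping 3-kb windows anchored at
position 1; within each window the single best candidate is kept (highest
priority, then highest MAF, then smallest position). Scaffolds that come out
of the primary pass with fewer markers than their expected share (scaffold
length / 2,800 bp target spacing, floored, minimum 1) get a second pass over
1-kb windows that fills the deficit with the best remaining candidates, one
per still-empty window, best candidates first. Must-include markers (e.g.
trait-associated SNPs) and large-effect SNPs are seeded into the design
before either pass and must-includes survive any capacity trim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .effect_annot import PrioritizedSNP

__all__ = [
    "SelectionConfig",
    "ArrayDesign",
    "expected_snp_count",
    "primary_window_scan",
    "fillin_scan",
    "assemble_design",
    "probe_sequences",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable knobs of the selection pipeline (all lengths in bp)."""

    primary_window_bp: int = 3000
    fillin_window_bp: int = 1000
    target_spacing_bp: int = 2800
    capacity: int = 200_000
    probe_flank_bp: int = 35
    fillin_by_quality: bool = True  # False = left-to-right window order

    def __post_init__(self) -> None:
        if self.fillin_window_bp >= self.primary_window_bp:
            raise ValueError("fill-in window must be smaller than primary window")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")


def _rank(snp: PrioritizedSNP) -> tuple[int, float, int]:
    """Sort key: better candidates sort first."""
    return (-snp.priority, -snp.maf, snp.pos)


def expected_snp_count(scaffold_length_bp: int, target_spacing_bp: int = 2800) -> int:
    """Expected marker count for a scaffold at the target average spacing."""
    if scaffold_length_bp < 1:
        raise ValueError("scaffold length must be >= 1")
    return max(1, scaffold_length_bp // target_spacing_bp)


def _window_index(pos: int, window_bp: int) -> int:
    return (pos - 1) // window_bp


def primary_window_scan(
    candidates: Sequence[PrioritizedSNP], window_bp: int = 3000
) -> list[PrioritizedSNP]:
    """Pick the best candidate in each non-overlapping window of one scaffold."""
    _check_one_scaffold(candidates)
    best: dict[int, PrioritizedSNP] = {}
    for snp in candidates:
        w = _window_index(snp.pos, window_bp)
        if w not in best or _rank(snp) < _rank(best[w]):
            best[w] = snp
    return [best[w] for w in sorted(best)]


def fillin_scan(
    candidates: Sequence[PrioritizedSNP],
    already_selected: Sequence[PrioritizedSNP],
    scaffold_length_bp: int,
    window_bp: int = 1000,
    expected: int | None = None,
    by_quality: bool = True,
) -> list[PrioritizedSNP]:
    """Fill a scaffold's marker deficit from windows not yet holding a marker.

    Runs only when the scaffold holds fewer markers than expected. Among
    windows with no selected marker, the best remaining candidate of each
    window is eligible; windows are consumed in order of their best
    candidate's rank (or left to right when by_quality is False) until the
    deficit is covered or candidates run out.
    """
    _check_one_scaffold(list(candidates) + list(already_selected))
    if expected is None:
        expected = expected_snp_count(scaffold_length_bp)
    deficit = expected - len(already_selected)
    if deficit <= 0:
        return []
    taken = {s.pos for s in already_selected}
    occupied = {_window_index(s.pos, window_bp) for s in already_selected}
    best: dict[int, PrioritizedSNP] = {}
    for snp in candidates:
        if snp.pos in taken:
            continue
        w = _window_index(snp.pos, window_bp)
        if w in occupied:
            continue
        if w not in best or _rank(snp) < _rank(best[w]):
            best[w] = snp
    if by_quality:
        order = sorted(best.values(), key=_rank)
    else:
        order = [best[w] for w in sorted(best)]
    added = order[:deficit]
    added.sort(key=lambda s: s.pos)
    return added


@dataclass
class ArrayDesign:
    """The ordered, deduplicated marker list submitted for manufacture."""

    markers: list[PrioritizedSNP]
    probes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(m.scaffold_id, m.pos) for m in self.markers]
        if keys != sorted(keys):
            raise ValueError("design markers must be sorted by scaffold then pos")
        if len(set(keys)) != len(keys):
            raise ValueError("design contains duplicate (scaffold, pos) markers")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [m.marker_id for m in self.markers],
                "scaffold": [m.scaffold_id for m in self.markers],
                "pos": [m.pos for m in self.markers],
                "ref": [m.variant.ref_allele for m in self.markers],
                "alt": [m.variant.alt_allele for m in self.markers],
                "effect": [m.effect.value for m in self.markers],
                "priority": [m.priority for m in self.markers],
                "maf": [m.maf for m in self.markers],
                "must_include": [m.must_include for m in self.markers],
                "probe": [self.probes.get(m.marker_id, ".") for m in self.markers],
            }
        )


def _check_one_scaffold(snps: Sequence[PrioritizedSNP]) -> None:
    scaffolds = {s.scaffold_id for s in snps}
    if len(scaffolds) > 1:
        raise ValueError(f"expected one scaffold, got {sorted(scaffolds)}")


def assemble_design(
    all_candidates: Sequence[PrioritizedSNP],
    must_include_ids: Sequence[str] = (),
    config: SelectionConfig | None = None,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> ArrayDesign:
    """Run seeding, the primary scan and the fill-in pass over all scaffolds.

    When scaffold lengths are not supplied, the last candidate position per
    scaffold stands in for its length (this only shrinks expected counts).
    Over capacity, non-must-include markers are dropped in ascending
    (priority, MAF) order.
    """
    cfg = config or SelectionConfig()
    must = set(must_include_ids)
    by_id = {c.marker_id: c for c in all_candidates}
    unresolved = sorted(must - set(by_id))
    if unresolved:
        raise ValueError(f"must-include ids not found among candidates: {unresolved}")

    # dedupe candidates on (scaffold, pos): best-ranked wins, must-include first
    import dataclasses

    all_candidates = [
        dataclasses.replace(c, must_include=True)
        if c.marker_id in must and not c.must_include
        else c
        for c in all_candidates
    ]
    dedup: dict[tuple[str, int], PrioritizedSNP] = {}
    for c in all_candidates:
        key = (c.scaffold_id, c.pos)
        inc = dedup.get(key)
        if (
            inc is None
            or (c.marker_id in must and inc.marker_id not in must)
            or (
                (c.marker_id in must) == (inc.marker_id in must)
                and _rank(c) < _rank(inc)
            )
        ):
            dedup[key] = c

    by_scaffold: dict[str, list[PrioritizedSNP]] = {}
    for c in dedup.values():
        by_scaffold.setdefault(c.scaffold_id, []).append(c)

    selected: list[PrioritizedSNP] = []
    for scaffold in sorted(by_scaffold):
        cands = sorted(by_scaffold[scaffold], key=lambda s: s.pos)
        seeds = [c for c in cands if c.marker_id in must or c.large_effect]
        seed_pos = {c.pos for c in seeds}
        rest = [c for c in cands if c.pos not in seed_pos]
        primary = primary_window_scan(rest, cfg.primary_window_bp)
        chosen = sorted(seeds + primary, key=lambda s: s.pos)
        length = (
            scaffold_lengths.get(scaffold, cands[-1].pos)
            if scaffold_lengths
            else cands[-1].pos
        )
        expected = expected_snp_count(length, cfg.target_spacing_bp)
        extra = fillin_scan(
            [c for c in cands if c.pos not in {x.pos for x in chosen}],
            chosen,
            length,
            cfg.fillin_window_bp,
            expected,
            by_quality=cfg.fillin_by_quality,
        )
        selected.extend(sorted(chosen + extra, key=lambda s: s.pos))

    if len(selected) > cfg.capacity:
        protected = [s for s in selected if s.must_include]
        droppable = sorted(
            (s for s in selected if not s.must_include),
            key=lambda s: (s.priority, s.maf, s.scaffold_id, s.pos),
        )
        n_drop = len(selected) - cfg.capacity
        keep = set(id(s) for s in droppable[n_drop:]) | set(id(s) for s in protected)
        selected = [s for s in selected if id(s) in keep]

    selected.sort(key=lambda s: (s.scaffold_id, s.pos))
    return ArrayDesign(selected)


def probe_sequences(
    design: ArrayDesign, genome: Mapping[str, str], flank_bp: int = 35
) -> dict[str, str]:
    """Plus-strand probe templates with the SNP written as ``[ref/alt]``.

    Flanks truncate at scaffold edges without padding. The computed probes
    are also stored on the design.
    """
    probes: dict[str, str] = {}
    for m in design.markers:
        seq = genome[m.scaffold_id]
        pos = m.pos
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{m.marker_id}: position outside scaffold")
        left = seq[max(0, pos - 1 - flank_bp) : pos - 1]
        right = seq[pos : pos + flank_bp]
        probes[m.marker_id] = (
            f"{left}[{m.variant.ref_allele}/{m.variant.alt_allele}]{right}"
        )
    design.probes = probes
    return probes
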