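"""Functional effect classification of SNPs against gene models.

Each SNP receives exactly one effect class. Coding changes are resolved by
strand-aware codon translation under the standard genetic code; intronic
SNPs near exon boundaries get splice classes with the usual effect-predictor
distances (donor/acceptor = first/last 2 bp of an intron, splice_region =
3-8 bp into the intron or 1-3 bp into a non-coding exon). SNPs outside any
gene but within 2 kb of a gene span are upstream/downstream by the gene's
strand; everything else is intergenic.

Priorities follow the array-design scheme: 4 for protein-changing coding
(and canonical splice) variants, 3 for silent coding variants, 2 for
intron/near-gene, 1 for intergenic. "Large-effect" SNPs are those predicted
to destroy a start or stop codon, create a new stop, or hit a canonical
splice dinucleotide.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from ._utils import revcomp
from .variant_io import GeneModel, Variant, VariantClass

__all__ = [
    "EffectClass",
    "PrioritizedSNP",
    "EffectAnnotator",
    "classify_effect",
    "priority_level",
    "is_large_effect",
    "prioritize",
    "annotation_table",
]

FLANK_BP = 2000

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})


class EffectClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    START_LOST = "start_lost"
    STOP_LOST = "stop_lost"
    STOP_RETAINED = "stop_retained"
    INITIATOR_CODON = "initiator_codon"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_REGION = "splice_region"
    INTRON = "intron"
    UPSTREAM2K = "upstream2k"
    DOWNSTREAM2K = "downstream2k"
    INTERGENIC = "intergenic"


_PRIORITY: dict[EffectClass, int] = {
    EffectClass.MISSENSE: 4,
    EffectClass.STOP_GAINED: 4,
    EffectClass.START_LOST: 4,
    EffectClass.STOP_LOST: 4,
    EffectClass.INITIATOR_CODON: 4,
    EffectClass.SPLICE_DONOR: 4,
    EffectClass.SPLICE_ACCEPTOR: 4,
    EffectClass.SYNONYMOUS: 3,
    EffectClass.STOP_RETAINED: 3,
    EffectClass.INTRON: 2,
    EffectClass.SPLICE_REGION: 2,
    EffectClass.UPSTREAM2K: 2,
    EffectClass.DOWNSTREAM2K: 2,
    EffectClass.INTERGENIC: 1,
}

_LARGE_EFFECT = {
    EffectClass.STOP_GAINED,
    EffectClass.START_LOST,
    EffectClass.STOP_LOST,
    EffectClass.SPLICE_DONOR,
    EffectClass.SPLICE_ACCEPTOR,
}


def priority_level(effect: EffectClass) -> int:
    """Array-design priority (1-4) of an effect class."""
    return _PRIORITY[effect]


def is_large_effect(effect: EffectClass) -> bool:
    """True for start/stop-destroying, stop-creating or splice-site SNPs."""
    return effect in _LARGE_EFFECT


@dataclass
class PrioritizedSNP:
    """A candidate SNP annotated for array selection."""

    variant: Variant
    effect: EffectClass
    priority: int
    maf: float
    must_include: bool = False
    p_convert: float | None = None  # carried through, never computed here
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.priority != priority_level(self.effect):
            raise ValueError(
                f"{self.variant.marker_id}: priority {self.priority} inconsistent "
                f"with effect {self.effect.value}"
            )
        if self.p_convert is not None and not 0 <= self.p_convert <= 1:
            raise ValueError("p_convert must lie in [0, 1]")

    @property
    def marker_id(self) -> str:
        return self.variant.marker_id

    @property
    def scaffold_id(self) -> str:
        return self.variant.scaffold_id

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def large_effect(self) -> bool:
        return is_large_effect(self.effect)


def _aa(codon: str) -> str:
    return _CODON_TO_AA[codon]


class EffectAnnotator:
    """Classifies SNP effects against a fixed gene set and genome.

    Builds one interval tree per scaffold over gene spans padded by the
    2-kb flank, so per-SNP lookup is O(log n_genes).
    """

    def __init__(self, genes: Sequence[GeneModel], genome: Mapping[str, str]):
        self.genome = genome
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.scaffold_id, IntervalTree())
            # interval tree is half-open; pad by the flank on both sides
            tree.addi(g.start - FLANK_BP, g.end + FLANK_BP + 1, g)

    def classify(self, snp: Variant) -> tuple[EffectClass, str | None]:
        """Effect class and the gene it was called against (None = intergenic)."""
        if snp.vclass is not VariantClass.SNP:
            raise ValueError(f"{snp.marker_id}: effect classification requires a SNP")
        seq = self.genome.get(snp.scaffold_id)
        if seq is None or not 1 <= snp.pos <= len(seq):
            raise ValueError(f"{snp.marker_id}: position outside the genome")
        tree = self._trees.get(snp.scaffold_id)
        hits = tree[snp.pos] if tree is not None else ()
        best: tuple[int, str, EffectClass] | None = None
        for iv in hits:
            gene: GeneModel = iv.data
            effect = self._classify_in_gene(snp, gene)
            key = (-priority_level(effect), gene.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (-priority_level(effect), gene.gene_id, effect)
        if best is None:
            return EffectClass.INTERGENIC, None
        return best[2], best[1]

    # -- gene-local classification ------------------------------------

    def _classify_in_gene(self, snp: Variant, gene: GeneModel) -> EffectClass:
        pos = snp.pos
        if pos < gene.start or pos > gene.end:
            if gene.strand == "+":
                return (
                    EffectClass.UPSTREAM2K
                    if pos < gene.start
                    else EffectClass.DOWNSTREAM2K
                )
            return (
                EffectClass.DOWNSTREAM2K if pos < gene.start else EffectClass.UPSTREAM2K
            )
        for s, e, _ in gene.cds:
            if s <= pos <= e:
                return self._coding_effect(snp, gene)
        return self._noncoding_genic_effect(pos, gene)

    def _noncoding_genic_effect(self, pos: int, gene: GeneModel) -> EffectClass:
        introns = [
            (gene.exons[i][1] + 1, gene.exons[i + 1][0] - 1)
            for i in range(len(gene.exons) - 1)
            if gene.exons[i][1] + 1 <= gene.exons[i + 1][0] - 1
        ]
        for i_s, i_e in introns:
            if i_s <= pos <= i_e:
                d_left = pos - i_s + 1  # bases into intron from its left end
                d_right = i_e - pos + 1
                if gene.strand == "+":
                    d_donor, d_acceptor = d_left, d_right
                else:
                    d_donor, d_acceptor = d_right, d_left
                if d_donor <= 2:
                    return EffectClass.SPLICE_DONOR
                if d_acceptor <= 2:
                    return EffectClass.SPLICE_ACCEPTOR
                if min(d_donor, d_acceptor) <= 8:
                    return EffectClass.SPLICE_REGION
                return EffectClass.INTRON
        # non-coding exon (UTR): splice_region within 1-3 bp of an internal
        # exon edge, otherwise folded into the intron (genic) class
        for i, (e_s, e_e) in enumerate(gene.exons):
            if e_s <= pos <= e_e:
                near = []
                if i > 0:
                    near.append(pos - e_s + 1)
                if i < len(gene.exons) - 1:
                    near.append(e_e - pos + 1)
                if near and min(near) <= 3:
                    return EffectClass.SPLICE_REGION
                return EffectClass.INTRON
        return EffectClass.INTRON

    def _coding_effect(self, snp: Variant, gene: GeneModel) -> EffectClass:
        if not gene.frame_ok:
            warnings.warn(
                f"{snp.marker_id}: gene {gene.gene_id} CDS frame unresolvable; "
                f"classified intron",
                stacklevel=3,
            )
            return EffectClass.INTRON
        seq = self.genome[snp.scaffold_id]
        plus = gene.strand == "+"
        segments = gene.cds if plus else list(reversed(gene.cds))
        coding_parts: list[str] = []
        idx = None
        offset = 0
        for s, e, _ in segments:
            part = seq[s - 1 : e]
            if not plus:
                part = revcomp(part)
            if s <= snp.pos <= e:
                idx = offset + (snp.pos - s if plus else e - snp.pos)
            offset += e - s + 1
            coding_parts.append(part)
        coding = "".join(coding_parts)
        phase = gene.first_cds_phase
        if idx is None or idx < phase:
            warnings.warn(
                f"{snp.marker_id}: codon not resolvable in gene "
                f"{gene.gene_id}; classified intron",
                stacklevel=3,
            )
            return EffectClass.INTRON
        codon_idx, pos_in_codon = divmod(idx - phase, 3)
        codon_start = phase + codon_idx * 3
        ref_codon = coding[codon_start : codon_start + 3]
        if len(ref_codon) < 3 or ref_codon[pos_in_codon] != (
            snp.ref_allele if plus else revcomp(snp.ref_allele)
        ):
            warnings.warn(
                f"{snp.marker_id}: reference mismatch in gene {gene.gene_id}; "
                f"classified intron",
                stacklevel=3,
            )
            return EffectClass.INTRON
        alt_base = snp.alt_allele if plus else revcomp(snp.alt_allele)
        alt_codon = (
            ref_codon[:pos_in_codon] + alt_base + ref_codon[pos_in_codon + 1 :]
        )
        ref_aa, alt_aa = _aa(ref_codon), _aa(alt_codon)
        if codon_idx == 0 and ref_codon == "ATG":
            return (
                EffectClass.INITIATOR_CODON
                if alt_aa == "M"
                else EffectClass.START_LOST
            )
        if ref_aa == "*":
            return (
                EffectClass.STOP_RETAINED if alt_aa == "*" else EffectClass.STOP_LOST
            )
        if alt_aa == "*":
            return EffectClass.STOP_GAINED
        if ref_aa == alt_aa:
            return EffectClass.SYNONYMOUS
        return EffectClass.MISSENSE


def classify_effect(
    snp: Variant, genes: Sequence[GeneModel], genome: Mapping[str, str]
) -> EffectClass:
    """One-shot effect classification (builds a throwaway annotator)."""
    return EffectAnnotator(genes, genome).classify(snp)[0]


def prioritize(
    snps: Sequence[Variant],
    mafs: Sequence[float],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    must_include_ids: Sequence[str] = (),
    p_convert: Mapping[str, float] | None = None,
) -> list[PrioritizedSNP]:
    """Annotate candidate SNPs with effect, priority, MAF and flags."""
    if len(snps) != len(mafs):
        raise ValueError("snps and mafs must have equal length")
    annotator = EffectAnnotator(genes, genome)
    must = set(must_include_ids)
    out = []
    for snp, maf in zip(snps, mafs):
        effect, gene_id = annotator.classify(snp)
        out.append(
            PrioritizedSNP(
                variant=snp,
                effect=effect,
                priority=priority_level(effect),
                maf=float(maf),
                must_include=snp.marker_id in must,
                p_convert=(p_convert or {}).get(snp.marker_id),
                gene_id=gene_id,
            )
        )
    return out


def annotation_table(prioritized: Sequence[PrioritizedSNP]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [p.marker_id for p in prioritized],
            "gene_id": [p.gene_id or "." for p in prioritized],
            "effect": [p.effect.value for p in prioritized],
            "priority": [p.priority for p in prioritized],
            "large_effect": [p.large_effect for p in prioritized],
        }
    )
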