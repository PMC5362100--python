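"""Synthetic genomes, cohorts, call matrices and families with known truth.

The generator emulates the study design the toolkit targets: a draft
genome of many scaffolds carrying compact multi-exon protein-coding genes,
a re-sequenced wild cohort genotyped at Hardy-Weinberg proportions over a
chosen minor-allele-frequency spectrum with per-call depth/quality noise
and interspersed indels, an array genotyping run with injectable per-call
miscall and no-call rates, and a full-sib family (two parents plus
offspring) with Mendelian transmission and injected errors whose positions
are exported as ground truth.

Every generator is fully deterministic under the configuration seed; each
draws from its own child stream, so e.g. regenerating the family does not
disturb the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import revcomp
from .variant_io import CallMatrix, GeneModel, Genotype, Variant, VariantClass

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_population_vcf",
    "true_genotype_frame",
    "simulate_array_calls",
    "simulate_family",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_GT_TO_CALL = np.array(["AA", "AB", "BB"])


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generators.

    The cohort and family sizes and the sequencing depth mirror the array
    study being emulated (472 re-sequenced wild animals, a full-sib family
    of 24 offspring, ~20-fold coverage); genome dimensions are desk-scale.
    """

    seed: int = 0
    n_scaffolds: int = 10
    scaffold_length_bp: int = 100_000
    n_genes_per_scaffold: int = 10
    n_samples: int = 472
    maf_law: tuple = ("uniform", 0.01, 0.5)
    snp_rate: float = 0.005  # SNP sites per bp
    mean_depth: float = 20.0
    indel_rate: float = 2e-4
    array_error_rate: float = 0.01
    array_nocall_rate: float = 0.005
    n_offspring: int = 24

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "array_error_rate", "array_nocall_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one named stream, deterministic under seed."""
        return np.random.default_rng([self.seed, stream])


def _draw_maf(law: tuple, rng: np.random.Generator, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "beta":
        return np.clip(rng.beta(law[1], law[2], size) * 0.5, 1e-6, 0.5)
    if kind == "point":
        return np.full(size, float(law[1]))
    raise ValueError(f"unknown maf_law {law!r}")


# ---------------------------------------------------------------------------
# Genome and gene models


def _random_gene_region(
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]], str]:
    """One gene's genomic sequence, local 1-based exon intervals, strand."""
    n_codons = int(rng.integers(100, 300))
    coding = (
        "ATG"
        + "".join(rng.choice(_CODONS) for _ in range(n_codons))
        + str(rng.choice(_STOPS))
    )
    n_exons = int(rng.integers(2, 5))
    # split the coding sequence into n_exons chunks of >= 30 bp
    cuts = sorted(rng.choice(np.arange(30, len(coding) - 30), n_exons - 1, replace=False))
    while len(set(cuts)) < n_exons - 1 or any(
        b - a < 30 for a, b in zip(cuts, cuts[1:])
    ):
        cuts = sorted(
            rng.choice(np.arange(30, len(coding) - 30), n_exons - 1, replace=False)
        )
    bounds = [0, *cuts, len(coding)]
    chunks = [coding[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = [
        "GT" + "".join(rng.choice(_BASES, int(rng.integers(60, 300)))) + "AG"
        for _ in range(n_exons - 1)
    ]
    region_parts = []
    exons: list[tuple[int, int]] = []
    cursor = 0
    for i, chunk in enumerate(chunks):
        exons.append((cursor + 1, cursor + len(chunk)))
        region_parts.append(chunk)
        cursor += len(chunk)
        if i < len(introns):
            region_parts.append(introns[i])
            cursor += len(introns[i])
    region = "".join(region_parts)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        L = len(region)
        region = revcomp(region)
        exons = sorted((L - e + 1, L - s + 1) for s, e in exons)
    return region, exons, strand


def _phases(exons: Sequence[tuple[int, int]], strand: str) -> list[int]:
    """CDS phases for genomically sorted segments, assigned in transcription order."""
    order = list(range(len(exons))) if strand == "+" else list(
        reversed(range(len(exons)))
    )
    phases = [0] * len(exons)
    cum = 0
    for i in order:
        phases[i] = (3 - cum % 3) % 3
        cum += exons[i][1] - exons[i][0] + 1
    return phases


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random scaffolds carrying non-overlapping multi-exon genes.

    Every gene's CDS starts with ATG, ends at a stop codon, contains no
    internal stop and has length divisible by 3; exons equal CDS segments
    (no UTRs are modelled). Raises when the requested genes cannot be
    packed with 2-kb clearances.
    """
    rng = cfg.rng(1)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    for si in range(cfg.n_scaffolds):
        name = f"scaffold_{si + 1}"
        seq = list(rng.choice(_BASES, cfg.scaffold_length_bp))
        cursor = 2000 + int(rng.integers(0, 1000))
        placed = 0
        for gi in range(cfg.n_genes_per_scaffold):
            region, exons, strand = _random_gene_region(rng)
            if cursor + len(region) > cfg.scaffold_length_bp - 2000:
                break
            at = cursor  # 0-based insertion offset
            seq[at : at + len(region)] = list(region)
            global_exons = [(at + s, at + e) for s, e in exons]
            phases = _phases(global_exons, strand)
            gene_id = f"{name}.g{gi + 1}"
            genes.append(
                GeneModel(
                    gene_id,
                    name,
                    strand,
                    global_exons,
                    [(s, e, p) for (s, e), p in zip(global_exons, phases)],
                )
            )
            placed += 1
            cursor = at + len(region) + 4500 + int(rng.integers(0, 2000))
        if placed < cfg.n_genes_per_scaffold:
            raise ValueError(
                f"{name}: could only place {placed} of "
                f"{cfg.n_genes_per_scaffold} genes in {cfg.scaffold_length_bp} bp"
            )
        genome[name] = "".join(seq)
    return genome, genes


# ---------------------------------------------------------------------------
# Population genotypes


def simulate_population_vcf(
    genome: Mapping[str, str], cfg: SimConfig
) -> tuple[list[Variant], pd.DataFrame]:
    """Hardy-Weinberg population genotypes at random SNP sites, plus indels.

    Per call, depth is Poisson around the mean coverage and GQ is a noisy
    increasing function of depth (so GQ degrades exactly where depth does).
    Returns the variants (sorted by scaffold then position) and a truth
    table of the drawn per-site minor-allele frequencies.
    """
    rng = cfg.rng(2)
    variants: list[Variant] = []
    truth_rows = []
    for name in genome:
        seq = genome[name]
        L = len(seq)
        n_sites = int(round(cfg.snp_rate * L))
        n_indels = int(rng.binomial(L, cfg.indel_rate))
        snp_pos = rng.choice(np.arange(1, L + 1), size=n_sites, replace=False)
        indel_pos = rng.choice(np.arange(1, L), size=n_indels, replace=False)
        snp_pos = np.setdiff1d(snp_pos, indel_pos)
        mafs = _draw_maf(cfg.maf_law, rng, len(snp_pos))
        order = np.argsort(snp_pos)
        for pos, maf in zip(snp_pos[order], mafs[order]):
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            gts = rng.binomial(2, maf, cfg.n_samples).astype(np.int8)
            dps = rng.poisson(cfg.mean_depth, cfg.n_samples).astype(np.int32)
            gqs = np.clip(
                np.round(3.0 * dps + rng.normal(0, 5, cfg.n_samples)), 0, 99
            ).astype(np.int32)
            variants.append(
                Variant(name, int(pos), ref, alt, VariantClass.SNP, gts, dps, gqs)
            )
            truth_rows.append(
                {"marker_id": f"{name}:{int(pos)}", "scaffold": name,
                 "pos": int(pos), "true_maf": float(maf)}
            )
        for pos in np.sort(indel_pos):
            ref = seq[pos - 1]
            alt = ref + str(rng.choice(_BASES))
            gts = rng.binomial(2, 0.1, cfg.n_samples).astype(np.int8)
            dps = rng.poisson(cfg.mean_depth, cfg.n_samples).astype(np.int32)
            gqs = np.clip(
                np.round(3.0 * dps + rng.normal(0, 5, cfg.n_samples)), 0, 99
            ).astype(np.int32)
            variants.append(
                Variant(name, int(pos), ref, alt, VariantClass.INDEL, gts, dps, gqs)
            )
    variants.sort(key=lambda v: (v.scaffold_id, v.pos))
    truth = pd.DataFrame(truth_rows).set_index("marker_id") if truth_rows else (
        pd.DataFrame(columns=["scaffold", "pos", "true_maf"])
    )
    return variants, truth


def true_genotype_frame(
    variants: Sequence[Variant], sample_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """SNP genotype dosages (0/1/2) as markers x samples, for call simulation."""
    snps = [v for v in variants if v.vclass is VariantClass.SNP]
    if sample_ids is None:
        n = snps[0].n_samples if snps else 0
        sample_ids = [f"sample_{i + 1}" for i in range(n)]
    data = np.vstack([v.gts for v in snps]) if snps else np.empty((0, len(sample_ids)))
    return pd.DataFrame(
        data, index=[v.marker_id for v in snps], columns=list(sample_ids), dtype=np.int8
    )


# ---------------------------------------------------------------------------
# Array calls


def _miscall(
    gts: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform miscalls: an erroneous call becomes either wrong genotype equally."""
    err = rng.random(gts.shape) < rate
    shift = rng.integers(1, 3, gts.shape)
    out = np.where(err, (gts + shift) % 3, gts)
    return out.astype(np.int8), err


def simulate_array_calls(
    true_gts: pd.DataFrame,
    cfg: SimConfig,
    forced_mono: Sequence[str] = (),
    forced_hetfree: Sequence[str] = (),
    forced_lowcr: Sequence[str] = (),
    lowcr_nocall_rate: float = 0.1,
) -> tuple[CallMatrix, pd.Series]:
    """Genotype calls from true dosages with miscall and no-call noise.

    Designated marker subsets are forced monomorphic (all reference
    homozygote), heterozygote-free (hets re-drawn as either homozygote), or
    to an elevated no-call rate, to exercise the cluster-category
    classifier. Returns the call matrix plus a per-marker truth label
    ("mono" / "hetfree" / "lowcr" / "normal").
    """
    rng = cfg.rng(3)
    gts = true_gts.to_numpy(dtype=np.int8).copy()
    markers = list(true_gts.index)
    labels = pd.Series("normal", index=markers, name="truth_label")
    idx = {m: i for i, m in enumerate(markers)}
    for m in forced_mono:
        gts[idx[m], :] = 0
        labels[m] = "mono"
    for m in forced_hetfree:
        row = gts[idx[m]]
        hets = row == 1
        row[hets] = rng.choice([0, 2], hets.sum())
        labels[m] = "hetfree"
    for m in forced_lowcr:
        labels[m] = "lowcr"

    called, _ = _miscall(gts, cfg.array_error_rate, rng)
    calls = _GT_TO_CALL[called]
    nocall = rng.random(gts.shape) < cfg.array_nocall_rate
    lowcr_rows = np.array([idx[m] for m in forced_lowcr], dtype=int)
    if len(lowcr_rows):
        nocall[lowcr_rows] |= rng.random((len(lowcr_rows), gts.shape[1])) < lowcr_nocall_rate
    calls = np.where(nocall, "NoCall", calls)
    matrix = CallMatrix(
        pd.DataFrame(calls, index=markers, columns=list(true_gts.columns))
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# Full-sib family


def simulate_family(
    parent1_gts: pd.Series,
    parent2_gts: pd.Series,
    cfg: SimConfig,
    parent_error_rate: float | None = None,
) -> tuple[pd.Series, pd.Series, CallMatrix, pd.DataFrame]:
    """Mendelian offspring of two parents, with injected call errors.

    Parents are given as per-marker dosages (0/1/2). Each offspring
    receives one allele per parent per marker independently; miscalls are
    then injected uniformly at the array error rate and no-calls at the
    no-call rate. Returns the two parents' calls, the offspring call
    matrix, and the boolean mask of injected offspring errors.
    """
    rng = cfg.rng(4)
    markers = list(parent1_gts.index)
    if list(parent2_gts.index) != markers:
        raise ValueError("parents must share the same marker index")
    g1 = parent1_gts.to_numpy(dtype=np.int8)
    g2 = parent2_gts.to_numpy(dtype=np.int8)
    n_off = cfg.n_offspring
    t1 = (rng.random((len(markers), n_off)) < g1[:, None] / 2).astype(np.int8)
    t2 = (rng.random((len(markers), n_off)) < g2[:, None] / 2).astype(np.int8)
    off = t1 + t2

    off_called, err_mask = _miscall(off, cfg.array_error_rate, rng)
    off_calls = _GT_TO_CALL[off_called]
    nocall = rng.random(off.shape) < cfg.array_nocall_rate
    off_calls = np.where(nocall, "NoCall", off_calls)
    err_mask = err_mask & ~nocall

    pe = cfg.array_error_rate if parent_error_rate is None else parent_error_rate
    p1_called, _ = _miscall(g1, pe, rng)
    p2_called, _ = _miscall(g2, pe, rng)
    p1_calls = pd.Series(_GT_TO_CALL[p1_called], index=markers)
    p2_calls = pd.Series(_GT_TO_CALL[p2_called], index=markers)
    p1_calls[rng.random(len(markers)) < cfg.array_nocall_rate] = "NoCall"
    p2_calls[rng.random(len(markers)) < cfg.array_nocall_rate] = "NoCall"

    sample_ids = [f"offspring_{i + 1}" for i in range(n_off)]
    matrix = CallMatrix(pd.DataFrame(off_calls, index=markers, columns=sample_ids))
    errors = pd.DataFrame(err_mask, index=markers, columns=sample_ids)
    return p1_calls, p2_calls, matrix, errors
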