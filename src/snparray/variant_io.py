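"""Readers and writers for every external format the toolkit touches.

Dialects are deliberately strict and documented:

* VCF v4.x with per-sample ``GT:DP:GQ``. Multiallelic records are split into
  one biallelic :class:`Variant` per alternate allele. Phased separators are
  accepted and treated as unphased; alleles belonging to a *different*
  alternate of the same record count as reference for the split variant.
* GFF3 with gene/mRNA/exon/CDS features; one transcript per gene (the
  longest-CDS transcript wins when several are annotated).
* Call matrices are tab-separated, markers as rows, samples as columns,
  cells drawn from ``{AA, AB, BB, NoCall}``. Allele "A" always denotes the
  design reference allele.
* Design lists are tab-separated with a fixed column schema (see
  :data:`DESIGN_COLUMNS`).

All coordinates are 1-based and closed, mirroring VCF/GFF3; any half-open
arithmetic stays inside individual operations.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genotype",
    "SiteCall",
    "VariantClass",
    "Variant",
    "GeneModel",
    "CallMatrix",
    "VcfParseError",
    "CallMatrixParseError",
    "CALL_VOCABULARY",
    "NOCALL",
    "DESIGN_COLUMNS",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "load_fasta",
    "write_fasta",
    "read_call_matrix",
    "write_call_matrix",
    "read_design",
    "write_design",
]

NOCALL = "NoCall"
CALL_VOCABULARY = ("AA", "AB", "BB", NOCALL)

DESIGN_COLUMNS = [
    "marker_id",
    "scaffold",
    "pos",
    "ref",
    "alt",
    "effect",
    "priority",
    "maf",
    "must_include",
    "probe",
]


class VcfParseError(ValueError):
    pass


class CallMatrixParseError(ValueError):
    pass


class Genotype(enum.IntEnum):
    """Diploid unphased genotype relative to a single alternate allele."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class VariantClass(enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


@dataclass(frozen=True)
class SiteCall:
    """One sample's call at one site: genotype plus depth and quality."""

    gt: Genotype
    dp: int = 0
    gq: int = 0

    def __post_init__(self) -> None:
        if self.dp < 0 or self.gq < 0:
            raise ValueError("DP and GQ must be non-negative")


@dataclass
class Variant:
    """One biallelic variant with vectorised per-sample calls.

    Per-sample data is stored as three parallel numpy arrays (``gts``,
    ``dps``, ``gqs``) so that cohort-scale filtering stays vectorised; the
    ``calls`` property materialises :class:`SiteCall` objects on demand.
    """

    scaffold_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    vclass: VariantClass
    gts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    dps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    gqs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        self.gts = np.asarray(self.gts, dtype=np.int8)
        self.dps = np.asarray(self.dps, dtype=np.int32)
        self.gqs = np.asarray(self.gqs, dtype=np.int32)
        if not (len(self.gts) == len(self.dps) == len(self.gqs)):
            raise ValueError("gts/dps/gqs must have equal length")
        is_snp = (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != self.alt_allele
        )
        if (self.vclass is VariantClass.SNP) != is_snp:
            raise ValueError(
                f"{self.scaffold_id}:{self.pos} {self.ref_allele}>{self.alt_allele}: "
                f"variant class {self.vclass.value} inconsistent with allele lengths"
            )
        if self.vclass is VariantClass.SNP:
            for a in (self.ref_allele, self.alt_allele):
                if a not in "ACGT":
                    raise ValueError(f"SNP allele must be one of A/C/G/T, got {a!r}")

    @classmethod
    def from_calls(
        cls,
        scaffold_id: str,
        pos: int,
        ref_allele: str,
        alt_allele: str,
        calls: Sequence[SiteCall],
    ) -> "Variant":
        vclass = (
            VariantClass.SNP
            if len(ref_allele) == 1 == len(alt_allele) and ref_allele != alt_allele
            else VariantClass.INDEL
        )
        return cls(
            scaffold_id,
            pos,
            ref_allele,
            alt_allele,
            vclass,
            np.array([c.gt for c in calls], dtype=np.int8),
            np.array([c.dp for c in calls], dtype=np.int32),
            np.array([c.gq for c in calls], dtype=np.int32),
        )

    @property
    def n_samples(self) -> int:
        return len(self.gts)

    @property
    def calls(self) -> list[SiteCall]:
        return [
            SiteCall(Genotype(int(g)), int(d), int(q))
            for g, d, q in zip(self.gts, self.dps, self.gqs)
        ]

    @property
    def marker_id(self) -> str:
        """Synthesised marker identifier ``scaffold:pos``."""
        return f"{self.scaffold_id}:{self.pos}"


@dataclass
class GeneModel:
    """A single-transcript gene model with 1-based closed intervals."""

    gene_id: str
    scaffold_id: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for i, iv in enumerate(ivs):
                if iv[1] < iv[0]:
                    raise ValueError(f"{self.gene_id}: inverted {name} interval {iv}")
                if i and iv[0] <= ivs[i - 1][1]:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")

    @property
    def start(self) -> int:
        return self.exons[0][0] if self.exons else self.cds[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1] if self.exons else self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def first_cds_phase(self) -> int:
        """Phase of the first CDS segment in transcription order."""
        if not self.cds:
            return 0
        return self.cds[0][2] if self.strand == "+" else self.cds[-1][2]

    @property
    def frame_ok(self) -> bool:
        """True when the CDS length is divisible by 3 after phase adjustment."""
        return self.cds != [] and (self.cds_length - self.first_cds_phase) % 3 == 0


class CallMatrix:
    """Samples x markers genotype calls over ``{AA, AB, BB, NoCall}``.

    Backed by a pandas DataFrame with markers as the index and samples as
    columns (the on-disk layout); optional per-sample DQC values ride along.
    """

    def __init__(self, calls: pd.DataFrame, dqc: pd.Series | None = None):
        bad = ~calls.isin(CALL_VOCABULARY)
        if bad.any().any():
            marker = calls.index[bad.any(axis=1)][0]
            sample = calls.columns[bad.any(axis=0)][0]
            raise CallMatrixParseError(
                f"invalid call {calls.loc[marker, sample]!r} at marker {marker!r}, "
                f"sample {sample!r}"
            )
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("duplicate marker or sample identifiers")
        if dqc is not None:
            dqc = dqc.reindex(calls.columns)
            if ((dqc < 0) | (dqc > 1)).any():
                raise ValueError("DQC values must lie in [0, 1]")
        self.calls = calls
        self.dqc = dqc

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_samples, n_markers)."""
        m, s = self.calls.shape
        return s, m

    def subset_samples(self, sample_ids: Sequence[str]) -> "CallMatrix":
        dqc = self.dqc[list(sample_ids)] if self.dqc is not None else None
        return CallMatrix(self.calls[list(sample_ids)], dqc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CallMatrix) and self.calls.equals(other.calls)


# ---------------------------------------------------------------------------
# VCF


def _validate_vcf_columns(path: str | Path) -> int:
    """Check header presence and per-line column consistency; return sample count."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_cols = line.rstrip("\n").count("\t") + 1
                if n_cols < 10:
                    raise VcfParseError(
                        f"line {lineno}: VCF header declares no samples"
                    )
                continue
            if n_cols is None:
                raise VcfParseError(f"line {lineno}: record before #CHROM header line")
            if line.strip() and line.count("\t") + 1 != n_cols:
                raise VcfParseError(
                    f"line {lineno}: expected {n_cols} columns, "
                    f"found {line.count(chr(9)) + 1}"
                )
    if n_cols is None:
        raise VcfParseError("missing #CHROM header line")
    return n_cols - 9


def read_vcf(
    path: str | Path, required_fields: Iterable[str] = ("GT", "DP", "GQ")
) -> list[Variant]:
    """Read a VCF into a list of biallelic :class:`Variant` records.

    Multiallelic records are split into one Variant per alternate allele;
    a genotype allele that is a *different* alternate counts as reference
    for the split variant. Records missing DP or GQ get dp=0, gq=0.
    """
    n_samples = _validate_vcf_columns(path)
    required = set(required_fields)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - defensive
        raise VcfParseError(f"cannot parse VCF header: {exc}") from exc
    declared = set(vcf.header.formats.keys())
    missing = required - declared
    if missing:
        raise VcfParseError(f"VCF header lacks required FORMAT fields: {sorted(missing)}")
    out: list[Variant] = []
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            samples = list(rec.samples.values())
            if len(samples) != n_samples:
                raise VcfParseError(
                    f"record {rec.chrom}:{rec.pos}: sample count mismatch"
                )
            for alt_idx, alt in enumerate(alts, start=1):
                gts = np.empty(n_samples, dtype=np.int8)
                dps = np.zeros(n_samples, dtype=np.int32)
                gqs = np.zeros(n_samples, dtype=np.int32)
                for i, sample in enumerate(samples):
                    alleles = sample.get("GT", (None, None))
                    if alleles is None or any(a is None for a in alleles):
                        gts[i] = Genotype.MISSING
                    else:
                        gts[i] = sum(1 for a in alleles if a == alt_idx)
                    dp = sample.get("DP")
                    gq = sample.get("GQ")
                    dps[i] = dp if dp is not None else 0
                    gqs[i] = gq if gq is not None else 0
                vclass = (
                    VariantClass.SNP
                    if len(rec.ref) == 1 == len(alt) and rec.ref != alt
                    else VariantClass.INDEL
                )
                out.append(
                    Variant(rec.chrom, rec.pos, rec.ref, alt, vclass, gts, dps, gqs)
                )
    return out


def write_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    sample_ids: Sequence[str],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic variants as an uncompressed VCF with GT:DP:GQ calls."""
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        if v.scaffold_id not in contigs:
            contigs[v.scaffold_id] = 0
        contigs[v.scaffold_id] = max(
            contigs[v.scaffold_id], v.pos + len(v.ref_allele)
        )
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in sample_ids:
        header.add_sample(s)
    gt_map = {
        int(Genotype.HOM_REF): (0, 0),
        int(Genotype.HET): (0, 1),
        int(Genotype.HOM_ALT): (1, 1),
        int(Genotype.MISSING): (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            if v.n_samples != len(sample_ids):
                raise ValueError(
                    f"{v.marker_id}: {v.n_samples} calls but "
                    f"{len(sample_ids)} sample ids"
                )
            rec = out.new_record(
                contig=v.scaffold_id,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            for i in range(v.n_samples):
                rec.samples[i]["GT"] = gt_map[int(v.gts[i])]
                rec.samples[i]["DP"] = int(v.dps[i])
                rec.samples[i]["GQ"] = int(v.gqs[i])
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3 / FASTA


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models, one transcript per gene (longest CDS wins).

    A CDS length not divisible by 3 (after phase adjustment) triggers a
    warning; the model is kept with ``frame_ok`` False so downstream code
    can route affected SNPs away from codon arithmetic.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except EmptyInputError:
        return []
    models: list[GeneModel] = []
    gene_ids = set()
    for gene in db.features_of_type("gene"):
        gene_ids.add(gene.id)
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if transcripts:
            best, best_len = None, -1
            for t in transcripts:
                clen = sum(
                    c.end - c.start + 1 for c in db.children(t, featuretype="CDS")
                )
                if clen > best_len:
                    best, best_len = t, clen
            parent = best
        else:
            parent = gene
        exons = [
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        ]
        cds = [
            (f.start, f.end, int(f.frame) if f.frame in "012" else 0)
            for f in db.children(parent, featuretype="CDS")
        ]
        if not exons:
            exons = [(s, e) for s, e, _ in cds]
        model = GeneModel(gene.id, gene.seqid, gene.strand, exons, cds)
        if model.cds and not model.frame_ok:
            warnings.warn(
                f"gene {gene.id}: CDS length {model.cds_length} not divisible "
                f"by 3 after phase adjustment",
                stacklevel=2,
            )
        models.append(model)
    # CDS/exon features whose parent chain reaches no gene are skipped.
    for feat in db.features_of_type("CDS"):
        parents = list(db.parents(feat, featuretype="gene")) + list(
            db.parents(feat, featuretype="mRNA")
        )
        if not parents:
            warnings.warn(
                f"CDS feature at {feat.seqid}:{feat.start}-{feat.end} has no "
                f"parent gene; skipped",
                stacklevel=2,
            )
    models.sort(key=lambda m: (m.scaffold_id, m.start))
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 with gene/mRNA/exon/CDS rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.scaffold_id}\tsnparray\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(
                f"{base}gene\t{m.start}\t{m.end}{tail}.\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{m.start}\t{m.end}{tail}.\tID={mrna_id};"
                f"Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tParent={mrna_id}\n")
            for s, e, phase in m.cds:
                fh.write(f"{base}CDS\t{s}\t{e}{tail}{phase}\tParent={mrna_id}\n")


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into a dict of uppercase scaffold sequences."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Call matrices and design lists


def read_call_matrix(path: str | Path) -> CallMatrix:
    """Read a tab-separated call matrix (markers x samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        return CallMatrix(df)
    except CallMatrixParseError as exc:
        raise CallMatrixParseError(f"{path}: {exc}") from exc


def write_call_matrix(matrix: CallMatrix, path: str | Path) -> None:
    matrix.calls.to_csv(path, sep="\t", index_label="marker_id")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a design list written by :func:`write_design`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "marker_id": str,
            "scaffold": str,
            "pos": int,
            "ref": str,
            "alt": str,
            "effect": str,
            "priority": int,
            "maf": float,
            "must_include": bool,
            "probe": str,
        },
    )
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: design file lacks columns {missing}")
    return df


def write_design(design, path: str | Path) -> None:
    """Write an array design (anything exposing ``to_frame()``) as TSV.

    Refuses duplicate marker ids: a design is a set of unique assays.
    """
    df = design.to_frame() if hasattr(design, "to_frame") else design
    if df["marker_id"].duplicated().any():
        dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids in design: {dups[:5]}")
    df.to_csv(path, sep="\t", index=False, columns=DESIGN_COLUMNS)
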