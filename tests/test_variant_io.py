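"""I/O dialect tests: VCF split/round-trip, GFF3 models, matrices, designs."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from snparray import synthetic_data, variant_io
from snparray.variant_io import (
    CallMatrix,
    CallMatrixParseError,
    Genotype,
    Variant,
    VariantClass,
    VcfParseError,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=s1,length=10000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Quality">
    """
)


class TestReadVcf:
    def test_basic_genotype_encoding(self, tmp_path):
        p = _write(
            tmp_path,
            "a.vcf",
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            + "s1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:GQ\t0/0:20:50\t0/1:21:51\t1/1:22:52\n"
            + "s1\t200\t.\tC\tT\t.\t.\t.\tGT:DP:GQ\t./.:0:0\t0|1:30:60\t0/0:31:61\n",
        )
        v1, v2 = variant_io.read_vcf(p)
        assert list(v1.gts) == [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT]
        assert list(v1.dps) == [20, 21, 22] and list(v1.gqs) == [50, 51, 52]
        # missing genotype and phased separator treated as unphased
        assert v2.gts[0] == Genotype.MISSING
        assert v2.gts[1] == Genotype.HET
        assert v1.vclass is VariantClass.SNP

    def test_multiallelic_split_preserves_alt_list(self, tmp_path):
        p = _write(
            tmp_path,
            "m.vcf",
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            + "s1\t100\t.\tA\tG,T\t.\t.\t.\tGT:DP:GQ\t0/1:20:50\t1/2:20:50\t2/2:20:50\n",
        )
        out = variant_io.read_vcf(p)
        assert [v.alt_allele for v in out] == ["G", "T"]
        vg, vt = out
        # per-alt dosage; the other alternate counts as reference
        assert list(vg.gts) == [1, 1, 0]
        assert list(vt.gts) == [0, 1, 2]

    def test_indel_classification_by_length(self, tmp_path):
        p = _write(
            tmp_path,
            "i.vcf",
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            + "s1\t100\t.\tA\tAT\t.\t.\t.\tGT:DP:GQ\t0/1:20:50\n"
            + "s1\t200\t.\tGC\tG\t.\t.\t.\tGT:DP:GQ\t0/1:20:50\n",
        )
        out = variant_io.read_vcf(p)
        assert all(v.vclass is VariantClass.INDEL for v in out)

    def test_missing_dp_gq_default_to_zero(self, tmp_path):
        p = _write(
            tmp_path,
            "d.vcf",
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            + "s1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n",
        )
        (v,) = variant_io.read_vcf(p)
        assert v.dps[0] == 0 and v.gqs[0] == 0 and v.gts[0] == Genotype.HET

    def test_inconsistent_columns_name_the_line(self, tmp_path):
        p = _write(
            tmp_path,
            "bad.vcf",
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            + "s1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:GQ\t0/0:20:50\t0/1:20:50\n"
            + "s1\t200\t.\tC\tT\t.\t.\t.\tGT:DP:GQ\t0/0:20:50\n",
        )
        with pytest.raises(VcfParseError, match="line 8"):
            variant_io.read_vcf(p)

    def test_missing_header_rejected(self, tmp_path):
        p = _write(tmp_path, "noh.vcf", "s1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\n")
        with pytest.raises(VcfParseError):
            variant_io.read_vcf(p)


def test_vcf_round_trip_preserves_all_fields(tmp_path, small_cfg, small_world):
    genome, _, variants, _ = small_world
    subset = variants[:80]
    samples = [f"s{i}" for i in range(small_cfg.n_samples)]
    path = tmp_path / "rt.vcf"
    variant_io.write_vcf(subset, path, samples, {k: len(v) for k, v in genome.items()})
    back = variant_io.read_vcf(path)
    assert len(back) == len(subset)
    for a, b in zip(subset, back):
        assert (a.scaffold_id, a.pos, a.ref_allele, a.alt_allele, a.vclass) == (
            b.scaffold_id,
            b.pos,
            b.ref_allele,
            b.alt_allele,
            b.vclass,
        )
        assert (a.gts == b.gts).all()
        assert (a.dps == b.dps).all()
        assert (a.gqs == b.gqs).all()


class TestVariantInvariants:
    def test_snp_class_requires_single_differing_bases(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Variant("s1", 5, "A", "AT", VariantClass.SNP)
        with pytest.raises(ValueError, match="inconsistent"):
            Variant("s1", 5, "A", "G", VariantClass.INDEL)

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            Variant("s1", 0, "A", "G", VariantClass.SNP)

    def test_sitecall_view_matches_arrays(self):
        v = Variant(
            "s1", 5, "A", "G", VariantClass.SNP,
            np.array([0, -1]), np.array([10, 0]), np.array([40, 0]),
        )
        calls = v.calls
        assert calls[0].gt is Genotype.HOM_REF and calls[0].dp == 10
        assert calls[1].gt is Genotype.MISSING


GFF_HEADER = "##gff-version 3\n"


def _gff_gene(cds_rows, gene_id="g1", strand="+"):
    start = min(r[0] for r in cds_rows)
    end = max(r[1] for r in cds_rows)
    lines = [
        f"s1\tx\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}",
        f"s1\tx\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}.t;Parent={gene_id}",
    ]
    for s, e in cds_rows:
        lines.append(f"s1\tx\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gene_id}.t")
    phase = 0
    for s, e in cds_rows:
        lines.append(f"s1\tx\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\tParent={gene_id}.t")
        phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    return "\n".join(lines) + "\n"


class TestReadGff3:
    def test_frame_violation_warns(self, tmp_path):
        # 60 + 41 = 101 bp, not divisible by 3
        p = _write(tmp_path, "bad.gff3", GFF_HEADER + _gff_gene([(101, 160), (201, 241)]))
        with pytest.warns(UserWarning, match="not divisible"):
            (m,) = variant_io.read_gff3(p)
        assert m.cds_length == 101 and not m.frame_ok

    @pytest.mark.parametrize(
        "second,ok", [((201, 243), False), ((201, 240), False), ((201, 242), True)]
    )
    def test_frame_arithmetic(self, tmp_path, second, ok):
        import warnings

        p = _write(tmp_path, "g.gff3", GFF_HEADER + _gff_gene([(101, 160), second]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (m,) = variant_io.read_gff3(p)
        assert m.frame_ok is ok

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "e.gff3", GFF_HEADER)
        assert variant_io.read_gff3(p) == []

    def test_longest_cds_transcript_wins(self, tmp_path):
        text = GFF_HEADER + (
            "s1\tx\tgene\t100\t400\t.\t+\t.\tID=g1\n"
            "s1\tx\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1\n"
            "s1\tx\tCDS\t100\t159\t.\t+\t0\tParent=t1\n"
            "s1\tx\tmRNA\t100\t400\t.\t+\t.\tID=t2;Parent=g1\n"
            "s1\tx\tCDS\t100\t159\t.\t+\t0\tParent=t2\n"
            "s1\tx\tCDS\t200\t259\t.\t+\t0\tParent=t2\n"
        )
        p = _write(tmp_path, "t.gff3", text)
        (m,) = variant_io.read_gff3(p)
        assert m.cds_length == 120

    def test_round_trip_with_generator_models(self, tmp_path, small_world):
        _, genes, _, _ = small_world
        p = tmp_path / "rt.gff3"
        variant_io.write_gff3(genes, p)
        back = variant_io.read_gff3(p)
        by_id = {g.gene_id: g for g in genes}
        assert len(back) == len(genes)
        for b in back:
            a = by_id[b.gene_id]
            assert (a.strand, a.exons, a.cds) == (b.strand, b.exons, b.cds)


class TestCallMatrix:
    def test_round_trip_96_samples(self, tmp_path):
        rng = np.random.default_rng(5)
        calls = pd.DataFrame(
            rng.choice(["AA", "AB", "BB", "NoCall"], size=(40, 96)),
            index=[f"m{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(96)],
        )
        m = CallMatrix(calls)
        path = tmp_path / "m.tsv"
        variant_io.write_call_matrix(m, path)
        back = variant_io.read_call_matrix(path)
        assert back == m

    def test_unknown_token_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "marker\ts1\ts2\nm1\tAA\tBA\n")
        with pytest.raises(CallMatrixParseError, match="'BA'.*'m1'.*'s2'"):
            variant_io.read_call_matrix(p)

    def test_all_aa(self, tmp_path):
        p = _write(tmp_path, "aa.tsv", "marker\ts1\ts2\nm1\tAA\tAA\nm2\tAA\tAA\n")
        m = variant_io.read_call_matrix(p)
        assert (m.calls == "AA").all().all()


class TestDesignIO:
    def _design_frame(self, n=100):
        return pd.DataFrame(
            {
                "marker_id": [f"s1:{i * 10 + 1}" for i in range(n)],
                "scaffold": "s1",
                "pos": [i * 10 + 1 for i in range(n)],
                "ref": "A",
                "alt": "G",
                "effect": "intergenic",
                "priority": 1,
                "maf": 0.25,
                "must_include": False,
                "probe": ".",
            }
        )

    def test_round_trip(self, tmp_path):
        df = self._design_frame()
        p = tmp_path / "d.tsv"
        variant_io.write_design(df, p)
        back = variant_io.read_design(p)
        assert list(back["marker_id"]) == list(df["marker_id"])
        assert (back["pos"] == df["pos"]).all()

    def test_duplicate_marker_ids_refused(self, tmp_path):
        df = self._design_frame(3)
        df.loc[2, "marker_id"] = df.loc[0, "marker_id"]
        with pytest.raises(ValueError, match="duplicate"):
            variant_io.write_design(df, tmp_path / "dup.tsv")

    def test_empty_design_is_header_only(self, tmp_path):
        p = tmp_path / "empty.tsv"
        variant_io.write_design(self._design_frame(0), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("marker_id\t")


def test_generated_fasta_parses_back(tmp_path, small_world):
    genome, _, _, _ = small_world
    p = tmp_path / "g.fasta"
    variant_io.write_fasta(genome, p)
    assert variant_io.load_fasta(p) == genome
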