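"""Format readers/writers: VCF split semantics, coordinate conventions,
gene-model parsing, signature matrices, and round-trips."""

import numpy as np
import pytest

from clonemut.errors import (
    ConfigurationError,
    CoordinateError,
    FormatError,
    InputError,
)
from clonemut.variant_io import (
    CHANNELS_96,
    GeneModel,
    GenotypeObservation,
    ReferenceGenome,
    ReferenceSignatureSet,
    VariantSite,
    read_gene_models,
    read_signature_matrix,
    read_vcf,
    reverse_complement,
    write_signature_matrix,
    write_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tDonor\tNT2
"""


def write_text_vcf(tmp_path, body):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_multiallelic_split_genotypes(self, tmp_path):
        """A 1/2 call is het for both split alts; 0/1 is het for alt1 only."""
        path = write_text_vcf(
            tmp_path,
            "chr1\t100\t.\tA\tG,T\t.\t.\t.\tGT:DP\t1/2:40\t0/1:60\n",
        )
        sites = read_vcf(path)
        assert [(s.ref, s.alt) for s in sites] == [("A", "G"), ("A", "T")]
        ag, at = sites
        assert ag.observations["Donor"].gt == "het"
        assert at.observations["Donor"].gt == "het"
        assert ag.observations["NT2"].gt == "het"
        assert at.observations["NT2"].gt == "hom_ref"

    def test_direct_field_mapping(self, tmp_path):
        path = write_text_vcf(
            tmp_path, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP\t0/0:55\t0/1:60\n"
        )
        (site,) = read_vcf(path, ["NT2"])
        assert site.observations["NT2"] == GenotypeObservation("het", 60)
        assert "Donor" not in site.observations

    def test_symbolic_and_star_alleles_skipped(self, tmp_path):
        path = write_text_vcf(
            tmp_path,
            "chr1\t10\t.\tA\t<DEL>\t.\t.\t.\tGT:DP\t0/1:50\t0/1:50\n"
            "chr1\t20\t.\tC\t*\t.\t.\t.\tGT:DP\t0/1:50\t0/1:50\n"
            "chr1\t30\t.\tG\tT\t.\t.\t.\tGT:DP\t0/1:50\t0/1:50\n",
        )
        sites = read_vcf(path)
        assert [(s.pos, s.alt) for s in sites] == [(30, "T")]

    def test_missing_genotype_and_absent_sample(self, tmp_path):
        path = write_text_vcf(
            tmp_path, "chr1\t5\t.\tA\tC\t.\t.\t.\tGT:DP\t./.:10\t1/1:30\n"
        )
        (site,) = read_vcf(path)
        assert site.observations["Donor"].gt == "missing"
        assert site.observations["NT2"].gt == "hom_alt"
        with pytest.raises(ConfigurationError):
            read_vcf(path, ["NT9"])

    def test_missing_file(self):
        with pytest.raises(InputError):
            read_vcf("/nonexistent/calls.vcf")

    def test_split_conserves_allele_count(self, tmp_path):
        body = (
            "chr1\t1\t.\tA\tC,G,T\t.\t.\t.\tGT:DP\t0/1:9\t0/2:9\n"
            "chr1\t2\t.\tC\tT\t.\t.\t.\tGT:DP\t0/1:9\t0/1:9\n"
        )
        sites = read_vcf(write_text_vcf(tmp_path, body))
        assert len(sites) == 3 + 1


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path, small_study):
        """Writing any site collection as VCF and re-reading preserves
        (chrom,pos,ref,alt,GT,DP) for every sample."""
        subset = small_study.variants[:200]
        samples = ["Donor", "NT2", "NT4"]
        path = tmp_path / "out.vcf"
        write_vcf(path, subset, samples, small_study.reference.lengths)
        back = read_vcf(path, samples)
        assert len(back) == len(subset)
        for a, b in zip(subset, back):
            assert a.key == b.key
            for s in samples:
                assert a.observations[s] == b.observations[s]

    def test_ann_survives_round_trip(self, tmp_path):
        site = VariantSite(
            "chr1", 10, "A", "G",
            observations={"Donor": GenotypeObservation("het", 30)},
            ann_raw="G|missense_variant|MODERATE|GENE1|g1||t1",
        )
        path = tmp_path / "ann.vcf"
        write_vcf(path, [site], ["Donor"], {"chr1": 100})
        (back,) = read_vcf(path)
        assert back.ann_raw == site.ann_raw


class TestVariantSite:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", pos=0, ref="A", alt="C"),
            dict(chrom="chr1", pos=1, ref="A", alt="A"),
            dict(chrom="chr1", pos=1, ref="", alt="C"),
            dict(chrom="chr1", pos=1, ref="A", alt="<DEL>"),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            VariantSite(**kwargs)


class TestReferenceGenome:
    def test_case_fold_and_full_span(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nacgt\n")
        ref = ReferenceGenome.from_fasta(path)
        assert ref.fetch("chr1", 1, 4) == "ACGT"

    def test_one_based_inclusive(self):
        ref = ReferenceGenome({"chr1": "ACGTA"})
        assert ref.fetch("chr1", 2, 4) == "CGT"
        assert ref.fetch("chr1", 1, 1) == "A"

    def test_range_errors(self):
        ref = ReferenceGenome({"chr1": "ACGTA"})
        with pytest.raises(CoordinateError):
            ref.fetch("chr1", 2, 6)
        with pytest.raises(CoordinateError):
            ref.fetch("chr2", 1, 1)

    def test_alphabet_guard(self):
        with pytest.raises(FormatError):
            ReferenceGenome({"chr1": "ACGU"})

    def test_fasta_round_trip(self, tmp_path, small_study):
        path = tmp_path / "ref.fa"
        small_study.reference.to_fasta(path)
        back = ReferenceGenome.from_fasta(path)
        assert back.sequences == small_study.reference.sequences

    def test_reverse_complement_involution(self):
        ref = ReferenceGenome({"chr1": "AACGTN"})
        assert ref.reverse_complemented().reverse_complemented().sequences == (
            ref.sequences
        )
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("TGG") == "CCA"


GTF_BODY = (
    'chr1\tsrc\tgene\t101\t1030\t.\t+\t.\tgene_id "X"; gene_name "Y";\n'
    'chr1\tsrc\ttranscript\t101\t1030\t.\t+\t.\tgene_id "X"; transcript_id "X.1";\n'
    'chr1\tsrc\texon\t101\t1030\t.\t+\t.\tgene_id "X"; transcript_id "X.1";\n'
    'chr1\tsrc\tCDS\t201\t500\t.\t+\t0\tgene_id "X"; transcript_id "X.1";\n'
)


class TestGeneModels:
    def test_span_length_and_gtf_attributes(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(GTF_BODY)
        (gene,) = read_gene_models(path)
        assert (gene.gene_id, gene.symbol) == ("X", "Y")
        assert gene.length == 1030 - 101 + 1 == 930
        assert gene.cds_segments == [(201, 500)]

    def test_longest_transcript_cds_kept(self, tmp_path):
        body = (
            "chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=g1;Name=G1\n"
            "chr1\tsrc\tmRNA\t1\t400\t.\t+\t.\tID=t_short;Parent=g1\n"
            "chr1\tsrc\tCDS\t10\t90\t.\t+\t0\tID=c1;Parent=t_short\n"
            "chr1\tsrc\tmRNA\t1\t900\t.\t+\t.\tID=t_long;Parent=g1\n"
            "chr1\tsrc\tCDS\t100\t300\t.\t+\t0\tID=c2;Parent=t_long\n"
            "chr1\tsrc\tCDS\t400\t600\t.\t+\t0\tID=c3;Parent=t_long\n"
        )
        path = tmp_path / "genes.gff3"
        path.write_text("##gff-version 3\n" + body)
        (gene,) = read_gene_models(path)
        assert gene.cds_segments == [(100, 300), (400, 600)]

    def test_simulated_gff3_round_trip(self, default_study):
        """Every simulated gene survives a write/read cycle with its span,
        strand and CDS intact, and all invariants hold."""
        back = read_gene_models(default_study.paths["genes"])
        assert len(back) == len(default_study.genes)
        by_id = {g.gene_id: g for g in back}
        for g in default_study.genes:
            b = by_id[g.gene_id]
            assert (b.chrom, b.start, b.end, b.strand) == (
                g.chrom, g.start, g.end, g.strand,
            )
            assert b.cds_segments == g.cds_segments
            assert b.length > 0

    def test_reversed_span_rejected(self):
        with pytest.raises(FormatError):
            GeneModel("g", "G", "chr1", 100, 50, "+")


class TestSignatureMatrix:
    def test_renormalization_tolerance(self, tmp_path):
        vec = np.full(96, 1 / 96)
        vec[0] += 5e-4  # column sums to 1.0005: accepted and renormalized
        path = tmp_path / "sig.tsv"
        with open(path, "w") as fh:
            fh.write("Type\tS1\n")
            for lab, v in zip(CHANNELS_96, vec):
                fh.write(f"{lab}\t{v:.10f}\n")
        sigs = read_signature_matrix(path)
        assert abs(sigs["S1"].sum() - 1.0) < 1e-9

    def test_wrong_channel_count_rejected(self, tmp_path):
        path = tmp_path / "sig95.tsv"
        with open(path, "w") as fh:
            fh.write("Type\tS1\n")
            for lab in CHANNELS_96[:95]:
                fh.write(f"{lab}\t{1/95:.10f}\n")
        with pytest.raises(FormatError):
            read_signature_matrix(path)

    def test_uniform_round_trips_exactly(self, tmp_path):
        sigset = ReferenceSignatureSet(
            channel_labels=CHANNELS_96,
            signatures={"uniform": np.full(96, 1 / 96)},
        )
        path = tmp_path / "u.tsv"
        write_signature_matrix(sigset, path)
        back = read_signature_matrix(path)
        assert np.allclose(back["uniform"], 1 / 96, atol=1e-12)

    def test_negative_proportion_rejected(self, tmp_path):
        vec = np.full(96, 1 / 96)
        vec[0], vec[1] = -0.01, 1 / 96 + 0.01
        path = tmp_path / "neg.tsv"
        with open(path, "w") as fh:
            fh.write("Type\tS1\n")
            for lab, v in zip(CHANNELS_96, vec):
                fh.write(f"{lab}\t{v:.10f}\n")
        with pytest.raises(FormatError):
            read_signature_matrix(path)
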