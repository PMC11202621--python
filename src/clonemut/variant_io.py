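"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive, matching the VCF/GFF3 source
conventions; there are no half-open intervals anywhere in the package.
Multi-allelic VCF records are split into biallelic :class:`VariantSite`
records on read, so downstream code only ever sees one ALT per site.

File parsing is delegated to the standard libraries (pysam for VCF,
pyfaidx for FASTA, gffutils for GFF3/GTF, pandas for tabular files); this
module adapts them to the shared domain types.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta, FastaIndexingError

from .errors import (
    ConfigurationError,
    CoordinateError,
    FormatError,
    InputError,
)

logger = logging.getLogger(__name__)

# -- SBS channel canon --------------------------------------------------------
# Substitution class major (COSMIC plotting convention), then 5' flank, then
# 3' flank, alphabetical.  The mutated base is always a pyrimidine.

SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)
CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS_96)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# -- Domain types -------------------------------------------------------------

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"
GENOTYPE_CLASSES = (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING)


@dataclass(frozen=True)
class GenotypeObservation:
    """One sample's call at a site: genotype class and total read depth (DP)."""

    gt: str
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.gt not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype class {self.gt!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative when present")


SiteKey = tuple[str, int, str, str]


@dataclass
class VariantSite:
    """One normalized biallelic variant with per-sample observations.

    ``ann_raw`` carries the unparsed SnpEff-style ANN INFO string (if any);
    :func:`clonemut.effect_annotation.parse_ann_field` turns it into
    structured annotations cached on ``ann``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    observations: dict[str, GenotypeObservation] = field(default_factory=dict)
    ann_raw: str | None = None
    ann: list | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"allele {allele!r} not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class GeneModel:
    """A gene span with optional CDS structure (1-based inclusive)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.cds_segments:
            if not (self.start <= s <= e <= self.end):
                raise FormatError(
                    f"gene {self.gene_id}: CDS segment ({s},{e}) outside span"
                )
        self.cds_segments.sort()

    @property
    def length(self) -> int:
        """Genomic span length, end - start + 1 (the Table-1 'Length')."""
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class ReferenceGenome:
    """Uppercase in-memory reference with 1-based inclusive queries."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise FormatError(f"{chrom}: non-ACGTN characters {bad}")
            self.sequences[chrom] = seq
        self.lengths: dict[str, int] = {c: len(s) for c, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        if not os.path.exists(path):
            raise InputError(f"FASTA not found: {path}")
        try:
            fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        except (FastaIndexingError, ValueError) as exc:
            raise FormatError(f"malformed FASTA {path}: {exc}") from exc
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring query, 1-based inclusive on both ends."""
        if chrom not in self.sequences:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if not (1 <= start <= end <= self.lengths[chrom]):
            raise CoordinateError(
                f"query {chrom}:{start}-{end} outside [1,{self.lengths[chrom]}]"
            )
        return self.sequences[chrom][start - 1 : end]

    def to_fasta(self, path: str | os.PathLike, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    def reverse_complemented(self) -> "ReferenceGenome":
        """Mirror genome used for strand-invariance checks."""
        return ReferenceGenome(
            {c: reverse_complement(s) for c, s in self.sequences.items()}
        )


@dataclass
class ReferenceSignatureSet:
    """A COSMIC-style set of 96-channel signatures in canonical channel order."""

    channel_labels: tuple[str, ...]
    signatures: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if tuple(self.channel_labels) != CHANNELS_96:
            raise FormatError("channel labels must be the canonical 96 labels")
        for name, vec in self.signatures.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (96,):
                raise FormatError(f"signature {name}: expected 96 channels")
            if (vec < 0).any():
                raise FormatError(f"signature {name}: negative proportion")
            total = vec.sum()
            if abs(total - 1.0) > 1e-6:
                raise FormatError(f"signature {name}: sums to {total}, not 1")
            self.signatures[name] = vec

    def names(self) -> list[str]:
        return list(self.signatures)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signatures[name]


# -- VCF ----------------------------------------------------------------------

_SYMBOLIC_CHARS = set("<>*[].")


def _classify_gt(gt: tuple | None, alt_index: int) -> str:
    """Genotype class of one split ALT: count of that allele in the call.

    A 1/2 call becomes het for each split alt; 0/1 becomes het for alt1 and
    hom_ref for alt2 — preserving 'heterozygous site' semantics per alternate
    allele.
    """
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return GT_MISSING
    n = sum(1 for a in gt if a == alt_index + 1)
    if n == 0:
        return GT_HOM_REF
    if n == len(gt):
        return GT_HOM_ALT
    return GT_HET


def read_vcf(
    path: str | os.PathLike, sample_names: Sequence[str] | None = None
) -> list[VariantSite]:
    """Read a VCF 4.x file into biallelic :class:`VariantSite` records.

    Multi-allelic records are split per ALT; symbolic, star and non-ACGT
    alleles are skipped with a logged count.  File order is preserved.
    """
    if not os.path.exists(path):
        raise InputError(f"VCF not found: {path}")
    sites: list[VariantSite] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if sample_names is None:
            sample_names = header_samples
        missing = [s for s in sample_names if s not in header_samples]
        if missing:
            raise ConfigurationError(
                f"samples {missing} absent from VCF header of {path}"
            )
        for rec in vf:
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
            ann_raw = None
            if "ANN" in rec.info:
                val = rec.info["ANN"]
                ann_raw = ",".join(val) if isinstance(val, tuple) else str(val)
            for alt_index, alt in enumerate(alts):
                alt = alt.upper()
                if (
                    not alt
                    or not ref
                    or set(alt) & _SYMBOLIC_CHARS
                    or set(alt) - set("ACGT")
                    or set(ref) - set("ACGT")
                ):
                    skipped += 1
                    continue
                obs = {}
                for name in sample_names:
                    samp = rec.samples[name]
                    depth = samp.get("DP")
                    obs[name] = GenotypeObservation(
                        gt=_classify_gt(samp.get("GT"), alt_index),
                        depth=int(depth) if depth is not None else None,
                    )
                sites.append(
                    VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        observations=obs,
                        ann_raw=ann_raw,
                    )
                )
    if skipped:
        logger.info("read_vcf(%s): skipped %d symbolic/non-ACGT alleles", path, skipped)
    return sites


def write_vcf(
    path: str | os.PathLike,
    sites: Iterable[VariantSite],
    sample_names: Sequence[str],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write sites as an uncompressed VCF 4.2 file with GT/DP (and ANN)."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Approximate read depth")
    header.info.add("ANN", ".", "String", "Functional annotations")
    for s in sample_names:
        header.add_sample(s)
    gt_tuples = {
        GT_HOM_REF: (0, 0),
        GT_HET: (0, 1),
        GT_HOM_ALT: (1, 1),
        GT_MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in sites:
            rec = vf.new_record(
                contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt)
            )
            if site.ann_raw:
                rec.info["ANN"] = tuple(site.ann_raw.split(","))
            for s in sample_names:
                ob = site.observations.get(s)
                if ob is None:
                    rec.samples[s]["GT"] = (None, None)
                    continue
                rec.samples[s]["GT"] = gt_tuples[ob.gt]
                if ob.depth is not None:
                    rec.samples[s]["DP"] = ob.depth
            vf.write(rec)


# -- Reference ----------------------------------------------------------------

def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Read a FASTA reference (optionally .fai-indexed), case-folded."""
    return ReferenceGenome.from_fasta(path)


# -- Gene models --------------------------------------------------------------

def _first_attr(feature, keys: Sequence[str], default: str | None = None) -> str | None:
    for k in keys:
        if k in feature.attributes:
            return feature.attributes[k][0]
    return default


def read_gene_models(path: str | os.PathLike, dialect: str = "auto") -> list[GeneModel]:
    """Parse gene models from GFF3 or GTF via gffutils.

    One :class:`GeneModel` per ``gene`` feature.  CDS segments are attached
    through transcript linkage; when a gene has several transcripts only the
    longest transcript's CDS is retained (logged).
    """
    import gffutils

    if not os.path.exists(path):
        raise InputError(f"gene model file not found: {path}")
    if dialect not in ("auto", "gff3", "gtf"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a zoo of types
        raise FormatError(f"could not parse gene models from {path}: {exc}") from exc

    models: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene_id = _first_attr(g, ("gene_id", "ID"), g.id)
        symbol = _first_attr(g, ("gene_name", "Name"), gene_id)
        transcripts = list(db.children(g, level=1, featuretype=("mRNA", "transcript")))
        if transcripts:
            transcripts.sort(key=lambda t: (-(t.end - t.start + 1), t.id))
            chosen = transcripts[0]
            if len(transcripts) > 1:
                logger.debug(
                    "gene %s: keeping longest transcript %s of %d",
                    gene_id, chosen.id, len(transcripts),
                )
            cds = [(c.start, c.end) for c in db.children(chosen, featuretype="CDS")]
        else:
            cds = [(c.start, c.end) for c in db.children(g, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in ("+", "-") else "+",
                cds_segments=sorted(cds),
            )
        )
    return models


# -- Signature matrices -------------------------------------------------------

def read_signature_matrix(path: str | os.PathLike) -> ReferenceSignatureSet:
    """Read a COSMIC-style 96-row signature TSV.

    The first column holds channel labels ("A[C>A]A" style); every remaining
    column is one signature.  Channels are re-ordered into canonical order and
    columns renormalized when their sum is within 1e-3 of 1.
    """
    if not os.path.exists(path):
        raise InputError(f"signature matrix not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("signature matrix needs a label column and >=1 signature")
    labels = df.iloc[:, 0].astype(str)
    if len(labels) != 96 or set(labels) != set(CHANNELS_96):
        raise FormatError(
            f"expected exactly the 96 canonical channels, got {len(labels)} rows"
        )
    df = df.set_index(labels.name or df.columns[0])
    df.index = labels.values
    df = df.loc[list(CHANNELS_96)]
    signatures: dict[str, np.ndarray] = {}
    for col in df.columns:
        vec = df[col].to_numpy(dtype=float)
        if (vec < 0).any():
            raise FormatError(f"signature {col}: negative proportion")
        total = vec.sum()
        if abs(total - 1.0) > 1e-3:
            raise FormatError(f"signature {col}: column sums to {total:.6g}, not 1")
        signatures[col] = vec / total
    return ReferenceSignatureSet(channel_labels=CHANNELS_96, signatures=signatures)


def write_signature_matrix(
    sigset: ReferenceSignatureSet, path: str | os.PathLike
) -> None:
    df = pd.DataFrame(
        {name: sigset.signatures[name] for name in sigset.signatures},
        index=list(CHANNELS_96),
    )
    df.index.name = "Type"
    df.to_csv(path, sep="\t", float_format="%.10g")


# -- Gene lists and set collections ------------------------------------------

def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Plain gene list, one symbol per line; blank lines and '#' comments skipped."""
    if not os.path.exists(path):
        raise InputError(f"gene list not found: {path}")
    out = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out


def read_gene_sets(path: str | os.PathLike) -> dict[str, set[str]]:
    """Gene-set collection as 2-column TSV (set_name, gene_symbol)."""
    if not os.path.exists(path):
        raise InputError(f"gene-set collection not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("gene-set collection must have 2 columns")
    sets: dict[str, set[str]] = {}
    for name, sym in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sets.setdefault(str(name), set()).add(str(sym))
    return sets
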