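"""96-channel single-base-substitution (SBS) spectrum construction.

Each SNV is classified by its substitution and trinucleotide context,
pyrimidine-normalized: when the mutated reference base is a purine, the
trinucleotide and both alleles are reverse-complemented so that the
central base is C or T. The 96 channels follow the COSMIC plotting
convention: substitution class major (C>A, C>G, C>T, T>A, T>C, T>G),
then 5' flank, then 3' flank, alphabetical.

A spectrum that matches a flat, clock-like reference profile (SBS5-like)
points to an aging-type mutational process; a C>T-dominant spectrum is
the UV-exposure pattern seen in melanomas and in the transmissible dog
tumor CTVT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DataConsistencyError, NormalizationError
from .variant_io import (
    CHANNELS_96,
    CHANNEL_INDEX,
    SUBSTITUTION_CLASSES,
    ReferenceGenome,
    ReferenceSignatureSet,
    VariantSite,
    reverse_complement,
)

#: substitution class of each canonical channel, by index
_CLASS_OF_CHANNEL = np.array(
    [CHANNELS_96[i][2:5] for i in range(96)], dtype=object
)


@dataclass
class Spectrum96:
    """Counts over the 96 canonical channels plus unclassifiable SNVs."""

    counts: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("expected 96 channel counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.dropped < 0:
            raise ValueError("dropped must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise NormalizationError("empty spectrum has no proportions")
        return self.counts / self.total


@dataclass
class Spectrum6:
    """Proportions over the six substitution classes."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.proportions) != SUBSTITUTION_CLASSES:
            raise ValueError("expected the six canonical substitution classes")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def sbs_channel(
    chrom: str, pos: int, ref: str, alt: str, reference: ReferenceGenome
) -> str | None:
    """Canonical channel label of one SNV, or None when unclassifiable.

    Unclassifiable means the trinucleotide context runs off the chromosome
    or contains N.  A REF that disagrees with the genome raises instead —
    that is a data-consistency problem, not a property of the site.
    """
    length = reference.lengths.get(chrom)
    if length is None:
        raise DataConsistencyError(f"unknown chromosome {chrom!r}")
    genome_base = reference.fetch(chrom, pos, pos)
    if genome_base != ref.upper():
        raise DataConsistencyError(
            f"{chrom}:{pos} REF {ref} != genome base {genome_base}"
        )
    if pos - 1 < 1 or pos + 1 > length:
        return None
    tri = reference.fetch(chrom, pos - 1, pos + 1)
    alt = alt.upper()
    if "N" in tri or alt == "N":
        return None
    if tri[1] in "AG":
        tri = reverse_complement(tri)
        alt = reverse_complement(alt)
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


def build_spectrum(
    snvs: Iterable[VariantSite], reference: ReferenceGenome
) -> Spectrum96:
    """Aggregate SNVs into a 96-channel spectrum.

    Non-SNV records are ignored (they are filtered upstream and do not count
    as dropped); SNVs with unusable context are tallied as dropped, so that
    total + dropped equals the number of SNVs submitted.
    """
    counts = np.zeros(96, dtype=np.int64)
    dropped = 0
    for site in snvs:
        if not site.is_snv:
            continue
        label = sbs_channel(site.chrom, site.pos, site.ref, site.alt, reference)
        if label is None:
            dropped += 1
        else:
            counts[CHANNEL_INDEX[label]] += 1
    return Spectrum96(counts=counts, dropped=dropped)


def collapse_to_six(spectrum: Spectrum96) -> Spectrum6:
    """Six-class proportions, ignoring flanking context."""
    if spectrum.total == 0:
        raise NormalizationError("cannot collapse an empty spectrum")
    props = spectrum.proportions()
    out = {
        sub: float(props[_CLASS_OF_CHANNEL == sub].sum())
        for sub in SUBSTITUTION_CLASSES
    }
    return Spectrum6(proportions=out)


def cosine_similarity(
    spectrum: Spectrum96 | np.ndarray, signature: np.ndarray
) -> float:
    """Cosine of the spectrum (as proportions) with a 96-vector signature."""
    a = spectrum.proportions() if isinstance(spectrum, Spectrum96) else np.asarray(
        spectrum, dtype=float
    )
    b = np.asarray(signature, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise NormalizationError("zero-norm vector in cosine similarity")
    return float(np.dot(a, b) / (na * nb))


def flatness(spectrum: Spectrum96) -> float:
    """Normalized Shannon entropy of channel proportions, in [0,1].

    1.0 for a perfectly uniform spectrum, 0.0 when all mass sits in one
    channel.  Quantifies the 'no pronounced substitution bias' statement.
    """
    props = spectrum.proportions()
    nz = props[props > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy / np.log(96.0)


def best_match(
    spectrum: Spectrum96, signatures: ReferenceSignatureSet
) -> list[tuple[str, float]]:
    """Signatures ranked by descending cosine similarity (ties by name)."""
    if not signatures.signatures:
        raise NormalizationError("empty signature set")
    scored = [
        (name, cosine_similarity(spectrum, vec))
        for name, vec in signatures.signatures.items()
    ]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def spectrum_frame(spectrum: Spectrum96) -> "pd.DataFrame":
    """96-row table: channel, count, proportion."""
    import pandas as pd

    total = spectrum.total
    return pd.DataFrame(
        {
            "channel": list(CHANNELS_96),
            "count": spectrum.counts,
            "proportion": spectrum.counts / total if total else np.zeros(96),
        }
    )
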