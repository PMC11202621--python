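"""Synthetic donor/clone study generator with a ground-truth manifest.

Generates every input the pipeline consumes, emulating the statistical
structure of a cloned-animal somatic-mutation study: a donor genotype
background shared with the clones, somatic heterozygous SNVs planted in
both clones (plus clone-private and low-depth decoys) under a chosen
96-channel substitution signature, per-site read depths, non-overlapping
gene models, a population allele-frequency panel, and aging/gene-set
lists with a controlled enrichment odds ratio.

The generator works at the post-calling VCF level: there is no read or
alignment model. Depths are Poisson around the configured means,
truncated so that a planted site is unambiguously on its intended side
of the depth filter — boundary flakiness is a property of real data that
the simulator deliberately does not emulate.

Determinism: every operation derives its random stream from
``(config.seed, fixed_op_tag)``, so one master seed reproduces every
emitted file byte-for-byte, regardless of which subset of operations is
invoked.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, SimulationError
from .somatic_filter import PopulationPanel
from .variant_io import (
    CHANNELS_96,
    GT_HET,
    GT_HOM_REF,
    GeneModel,
    GenotypeObservation,
    ReferenceGenome,
    ReferenceSignatureSet,
    SiteKey,
    VariantSite,
    reverse_complement,
    write_signature_matrix,
    write_vcf,
)

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I2B = "ACGT"

# rng stream tags, one per operation
_RNG_REFERENCE = 1
_RNG_GENES = 2
_RNG_PLANT = 3
_RNG_PANEL = 4
_RNG_SETS = 5
_RNG_CODING = 6


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard fixture.

    The somatic plant counts (300 shared, 200/150 clone-private, 40
    low-depth) and the germline background of 10,000 shared heterozygous
    sites set up a cascade whose ground truth is unambiguous: exactly the
    shared high-depth plants must survive.  ``aging_enrichment_odds``
    defaults to 2.0, the odds ratio implied by the study-scale 2x2 table
    this pipeline is built to test.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (1_500, 8_000)
    gene_spacing: int = 300
    minus_strand_fraction: float = 0.5
    n_germline_het: int = 10_000
    n_somatic_shared: int = 300
    n_somatic_private_per_clone: tuple[int, ...] = (200, 150)
    n_somatic_lowdepth: int = 40
    depth_mean: float = 80.0
    lowdepth_mean: float = 25.0
    depth_pass_min: int = 51
    signature: str = "SBS5like"
    donor_name: str = "Donor"
    clone_names: tuple[str, ...] = ("NT2", "NT4")
    aging_list_size: int = 12
    aging_enrichment_odds: float = 2.0
    n_null_sets: int = 20
    null_set_size: int = 12
    enriched_set_odds: float = 8.0
    panel_n_samples: int = 196
    panel_germline_fraction: float = 0.95
    panel_af_beta: tuple[float, float] = (2.0, 2.0)
    n_panel_rare_colliders: int = 5
    n_panel_missing_colliders: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.n_somatic_private_per_clone, int):
            self.n_somatic_private_per_clone = tuple(
                [self.n_somatic_private_per_clone] * len(self.clone_names)
            )
        if len(self.n_somatic_private_per_clone) != len(self.clone_names):
            raise ConfigurationError("one private count per clone required")
        counts = (
            self.n_germline_het,
            self.n_somatic_shared,
            self.n_somatic_lowdepth,
            *self.n_somatic_private_per_clone,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all plant counts must be >= 0")
        if self.n_chrom < 1 or self.chrom_length < 1000:
            raise ConfigurationError("need >=1 chromosome of >=1000 bp")

    def signature_vector(self) -> np.ndarray:
        if isinstance(self.signature, str):
            sigs = builtin_signatures()
            if self.signature not in sigs.signatures:
                raise ConfigurationError(
                    f"unknown builtin signature {self.signature!r}; "
                    f"available: {sigs.names()}"
                )
            return sigs[self.signature]
        vec = np.asarray(self.signature, dtype=float)
        if vec.shape != (96,) or (vec < 0).any():
            raise ConfigurationError("explicit signature must be 96 non-negatives")
        return vec / vec.sum()


@dataclass
class PlantedSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    channel: str
    kind: str  # shared | private | lowdepth
    clone: str | None = None  # for private plants
    genes: list[str] = field(default_factory=list)

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GroundTruthManifest:
    planted_somatic_shared: list[PlantedSite]
    planted_private: list[PlantedSite]
    planted_lowdepth: list[PlantedSite]
    germline_keys: list[SiteKey]
    planted_signature: np.ndarray
    signature_name: str
    expected_final_count: int
    enriched_sets: dict[str, float] = field(default_factory=dict)
    aging_genes: list[str] = field(default_factory=list)
    mutated_gene_ids: list[str] = field(default_factory=list)

    def shared_keys(self) -> set[SiteKey]:
        return {p.key for p in self.planted_somatic_shared}


# -- Built-in signatures ------------------------------------------------------

def builtin_signatures() -> ReferenceSignatureSet:
    """Three synthetic 96-channel signatures used as planting profiles.

    These are constructed profiles, not the COSMIC reference vectors:

    * ``uniform``: exactly 1/96 per channel.
    * ``SBS5like``: a flat, clock-like profile (uniform with a smooth
      +/-25% cosine modulation) emulating the featureless aging signature.
    * ``UVlike``: C>T-dominant with a strong pyrimidine-context bias
      (NpCpC / NpCpT sites), emulating a UV-exposure spectrum.
    """
    uniform = np.full(96, 1 / 96)

    k = np.arange(96)
    sbs5 = 1.0 + 0.25 * np.cos(2 * np.pi * k / 96)
    sbs5 /= sbs5.sum()

    uv = np.full(96, 0.10 / 80)
    hot = ["T[C>T]T", "T[C>T]C", "C[C>T]T", "C[C>T]C"]
    ct_idx = [i for i, lab in enumerate(CHANNELS_96) if lab[2:5] == "C>T"]
    for i in ct_idx:
        uv[i] = 0.10 / 12
    for lab in hot:
        uv[CHANNELS_96.index(lab)] = 0.20
    uv /= uv.sum()

    return ReferenceSignatureSet(
        channel_labels=CHANNELS_96,
        signatures={"SBS5like": sbs5, "UVlike": uv, "uniform": uniform},
    )


# -- Reference and gene models ------------------------------------------------

def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def simulate_reference(config: SimulationConfig) -> ReferenceGenome:
    """I.i.d. uniform A/C/G/T sequence per chromosome, seed-deterministic."""
    rng = np.random.default_rng([config.seed, _RNG_REFERENCE])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for i in range(config.n_chrom):
        draw = rng.integers(0, 4, size=config.chrom_length)
        seqs[_chrom_name(i)] = bases[draw].tobytes().decode()
    return ReferenceGenome(seqs)


def simulate_gene_models(
    config: SimulationConfig, reference: ReferenceGenome
) -> list[GeneModel]:
    """Non-overlapping gene spans with a single central CDS segment.

    The CDS covers ~60% of the span, trimmed to a codon multiple; a
    configured fraction of genes sit on the minus strand.
    """
    rng = np.random.default_rng([config.seed, _RNG_GENES])
    lo, hi = config.gene_length_range
    chroms = list(reference.sequences)
    cursors = {c: 200 + int(rng.integers(0, 400)) for c in chroms}
    models: list[GeneModel] = []
    ci = 0
    attempts = 0
    while len(models) < config.n_genes:
        if attempts > config.n_genes * 10 + len(chroms):
            raise SimulationError(
                f"cannot place {config.n_genes} genes in "
                f"{config.n_chrom} x {config.chrom_length} bp"
            )
        attempts += 1
        chrom = chroms[ci % len(chroms)]
        ci += 1
        length = int(rng.integers(lo, hi + 1))
        gap = config.gene_spacing + int(rng.integers(0, config.gene_spacing + 1))
        start = cursors[chrom] + gap
        end = start + length - 1
        if end > reference.lengths[chrom] - 200:
            continue
        cursors[chrom] = end
        idx = len(models) + 1
        cds_len = max(9, (int(0.6 * length) // 3) * 3)
        cds_start = start + (length - cds_len) // 2
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        models.append(
            GeneModel(
                gene_id=f"g{idx:04d}",
                symbol=f"GENE{idx:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                cds_segments=[(cds_start, cds_start + cds_len - 1)],
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tclonemut_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            tid = g.gene_id.replace("g", "t", 1)
            fh.write(
                f"{g.chrom}\tclonemut_sim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.cds_segments):
                fh.write(
                    f"{g.chrom}\tclonemut_sim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={tid}.cds{j};Parent={tid}\n"
                )


# -- Somatic planting ---------------------------------------------------------

def _encode_tri(tri: str) -> int:
    return 16 * _B2I[tri[0]] + 4 * _B2I[tri[1]] + _B2I[tri[2]]


def _trinuc_pools(
    reference: ReferenceGenome, rng: np.random.Generator
) -> dict[int, list]:
    """Per-trinucleotide-code shuffled position pools [(chrom, pos), ...]."""
    by_code: dict[int, list[np.ndarray]] = {}
    chrom_of: dict[int, list[str]] = {}
    for chrom, seq in reference.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(arr.shape, -1, dtype=np.int16)
        for b, v in zip(b"ACGT", range(4)):
            code[arr == b] = v
        valid = code >= 0
        tri = 16 * code[:-2] + 4 * code[1:-1] + code[2:]
        ok = valid[:-2] & valid[1:-1] & valid[2:]
        pos = np.nonzero(ok)[0] + 2  # 1-based center position
        tri = tri[ok]
        for t in range(64):
            sel = pos[tri == t]
            if sel.size:
                by_code.setdefault(t, []).append(sel)
                chrom_of.setdefault(t, []).append(chrom)
    pools: dict[int, list] = {}
    for t, arrays in by_code.items():
        entries = [
            (chrom, int(p)) for chrom, arr in zip(chrom_of[t], arrays) for p in arr
        ]
        order = rng.permutation(len(entries))
        pools[t] = [entries[i] for i in order]
    return pools


def _channel_codes() -> list[tuple[int, str, int, str]]:
    """Per canonical channel: (pyr-context code, alt, pur-context code, alt)."""
    out = []
    for label in CHANNELS_96:
        tri = label[0] + label[2] + label[6]
        alt = label[4]
        tri_rc = reverse_complement(tri)
        alt_rc = reverse_complement(alt)
        out.append((_encode_tri(tri), alt, _encode_tri(tri_rc), alt_rc))
    return out


_CHANNEL_CODES = _channel_codes()


def _truncated_poisson(
    rng: np.random.Generator, mean: float, low: int | None, high: int | None
) -> int:
    for _ in range(10_000):
        d = int(rng.poisson(mean))
        if (low is None or d >= low) and (high is None or d <= high):
            return d
    raise SimulationError(
        f"could not draw Poisson({mean}) in [{low},{high}] after 10000 tries"
    )


def plant_somatic_mutations(
    config: SimulationConfig,
    reference: ReferenceGenome,
    genes: Sequence[GeneModel],
) -> tuple[list[VariantSite], GroundTruthManifest]:
    """Plant germline background and somatic SNVs; return joint calls + truth.

    Somatic substitutions and their trinucleotide contexts are sampled from
    the configured 96-channel signature by drawing a channel and then a
    genome position whose local context matches it (possibly on the reverse
    strand).  Shared plants are heterozygous in every clone and
    homozygous-reference in the donor at passing depth; private plants sit
    in one clone; low-depth plants are shared but guaranteed to fail the
    depth filter in every clone.
    """
    rng = np.random.default_rng([config.seed, _RNG_PLANT])
    signature = config.signature_vector()
    pools = _trinuc_pools(reference, rng)
    cursors = {t: 0 for t in pools}

    def pop_position(channel_idx: int) -> tuple[str, int, str]:
        code_p, alt_p, code_r, alt_r = _CHANNEL_CODES[channel_idx]
        rem_p = len(pools.get(code_p, ())) - cursors.get(code_p, 0)
        rem_r = len(pools.get(code_r, ())) - cursors.get(code_r, 0)
        if rem_p <= 0 and rem_r <= 0:
            raise SimulationError(
                f"no genome positions left for channel {CHANNELS_96[channel_idx]}"
            )
        pick_p = rng.random() < rem_p / (rem_p + rem_r)
        code, alt = (code_p, alt_p) if pick_p and rem_p > 0 else (code_r, alt_r)
        if not pick_p and rem_r <= 0:
            code, alt = code_p, alt_p
        chrom, pos = pools[code][cursors[code]]
        cursors[code] += 1
        return chrom, pos, alt

    counts = [
        ("shared", None, config.n_somatic_shared),
        *[
            ("private", clone, n)
            for clone, n in zip(config.clone_names, config.n_somatic_private_per_clone)
        ],
        ("lowdepth", None, config.n_somatic_lowdepth),
    ]
    planted: dict[str, list[PlantedSite]] = {"shared": [], "private": [], "lowdepth": []}
    used: set[tuple[str, int]] = set()
    for kind, clone, n in counts:
        channels = rng.choice(96, size=n, p=signature)
        for ch in channels:
            chrom, pos, alt = pop_position(int(ch))
            used.add((chrom, pos))
            ref = reference.fetch(chrom, pos, pos)
            site = PlantedSite(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                channel=CHANNELS_96[int(ch)],
                kind=kind,
                clone=clone,
                genes=[g.gene_id for g in genes if g.chrom == chrom and g.contains(pos)],
            )
            planted[kind].append(site)

    # germline background: shared heterozygosity, donor and clones alike
    germline: list[tuple[str, int, str, str]] = []
    chroms = list(reference.sequences)
    lengths = np.array([reference.lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    guard = 0
    while len(germline) < config.n_germline_het:
        guard += 1
        if guard > config.n_germline_het * 50:
            raise SimulationError("could not place germline sites (genome too small)")
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        pos = int(rng.integers(2, reference.lengths[chrom]))
        if (chrom, pos) in used:
            continue
        ref = reference.fetch(chrom, pos, pos)
        if ref == "N":
            continue
        used.add((chrom, pos))
        alt = rng.choice([b for b in "ACGT" if b != ref])
        germline.append((chrom, pos, ref, str(alt)))

    # assemble joint multi-sample calls with depths
    donor = config.donor_name
    clones = list(config.clone_names)
    pass_min = config.depth_pass_min
    sites: list[VariantSite] = []

    def depth_pass() -> int:
        return _truncated_poisson(rng, config.depth_mean, pass_min, None)

    def depth_fail() -> int:
        return _truncated_poisson(rng, config.lowdepth_mean, 0, pass_min - 1)

    def depth_free() -> int:
        return int(rng.poisson(config.depth_mean))

    for chrom, pos, ref, alt in germline:
        obs = {donor: GenotypeObservation(GT_HET, depth_free())}
        for c in clones:
            obs[c] = GenotypeObservation(GT_HET, depth_free())
        sites.append(VariantSite(chrom, pos, ref, alt, observations=obs))
    for p in planted["shared"]:
        obs = {donor: GenotypeObservation(GT_HOM_REF, depth_free())}
        for c in clones:
            obs[c] = GenotypeObservation(GT_HET, depth_pass())
        sites.append(VariantSite(p.chrom, p.pos, p.ref, p.alt, observations=obs))
    for p in planted["private"]:
        obs = {donor: GenotypeObservation(GT_HOM_REF, depth_free())}
        for c in clones:
            if c == p.clone:
                obs[c] = GenotypeObservation(GT_HET, depth_pass())
            else:
                obs[c] = GenotypeObservation(GT_HOM_REF, depth_free())
        sites.append(VariantSite(p.chrom, p.pos, p.ref, p.alt, observations=obs))
    for p in planted["lowdepth"]:
        obs = {donor: GenotypeObservation(GT_HOM_REF, depth_free())}
        for c in clones:
            obs[c] = GenotypeObservation(GT_HET, depth_fail())
        sites.append(VariantSite(p.chrom, p.pos, p.ref, p.alt, observations=obs))
    sites.sort(key=lambda s: s.key)

    manifest = GroundTruthManifest(
        planted_somatic_shared=planted["shared"],
        planted_private=planted["private"],
        planted_lowdepth=planted["lowdepth"],
        germline_keys=[(c, p, r, a) for c, p, r, a in germline],
        planted_signature=signature,
        signature_name=str(config.signature),
        expected_final_count=config.n_somatic_shared,
    )
    return sites, manifest


# -- Population panel ---------------------------------------------------------

def simulate_panel(
    config: SimulationConfig, manifest: GroundTruthManifest
) -> PopulationPanel:
    """Population panel emulating a public cohort of unrelated animals.

    Most germline sites appear at common frequencies (Beta-distributed,
    quantized to the allele-count grid of ``panel_n_samples`` diploids);
    planted somatic sites are absent — except a configured handful of
    colliders: some at rare frequency (< 0.01) and some with a genotype
    missing rate above 10%, to exercise the annotation rules.
    """
    rng = np.random.default_rng([config.seed, _RNG_PANEL])
    two_n = 2 * config.panel_n_samples
    a, b = config.panel_af_beta
    lookup: dict[SiteKey, tuple[float, float]] = {}
    for key in manifest.germline_keys:
        if rng.random() > config.panel_germline_fraction:
            continue
        af = float(rng.beta(a, b))
        af = max(1, round(af * two_n)) / two_n
        miss = float(rng.uniform(0.0, 0.05))
        lookup[key] = (min(af, 1.0), miss)
    shared = manifest.planted_somatic_shared
    n_rare = min(config.n_panel_rare_colliders, len(shared))
    n_miss = min(config.n_panel_missing_colliders, max(0, len(shared) - n_rare))
    for p in shared[:n_rare]:
        lookup[p.key] = (1 / two_n, float(rng.uniform(0.0, 0.05)))
    for p in shared[n_rare : n_rare + n_miss]:
        lookup[p.key] = (float(rng.uniform(0.02, 0.2)), 0.2)
    return PopulationPanel(af_lookup=lookup, n_samples=config.panel_n_samples)


def write_panel_tsv(panel: PopulationPanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\tmissing_rate\n")
        for (chrom, pos, ref, alt) in sorted(panel.af_lookup):
            af, miss = panel.af_lookup[(chrom, pos, ref, alt)]
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{af:.6g}\t{miss:.6g}\n")


# -- Gene lists and set collections ------------------------------------------

def _membership_with_odds(
    rng: np.random.Generator,
    bearing: np.ndarray,
    target_size: int,
    odds: float,
) -> np.ndarray:
    """Bernoulli membership with P(member|bearing) at ``odds`` vs the rest.

    Solves for the non-bearing membership probability so the expected list
    size equals ``target_size``, then samples independently per gene.
    """
    n = bearing.size
    n_b = int(bearing.sum())
    n_nb = n - n_b
    if target_size > n:
        raise SimulationError("aging list larger than the gene universe")
    if odds <= 0:
        raise SimulationError("odds ratio must be positive")

    def expected(p_nb: float) -> float:
        p_b = odds * p_nb / (1 + (odds - 1) * p_nb)
        return n_b * p_b + n_nb * p_nb - target_size

    if expected(1.0 - 1e-12) < 0:
        raise SimulationError("target list size infeasible at this odds ratio")
    p_nb = brentq(expected, 1e-12, 1.0 - 1e-12)
    p_b = odds * p_nb / (1 + (odds - 1) * p_nb)
    probs = np.where(bearing, p_b, p_nb)
    return rng.random(n) < probs


def simulate_membership_study(
    seed_or_rng: int | np.random.Generator,
    n_background: int,
    n_query: int,
    list_size: int,
    odds: float,
) -> tuple[list[str], list[str], list[str]]:
    """Symbol-level study: background, query, and an odds-biased list.

    Used for statistical calibration/power checks of the enrichment engine
    at sizes the desk-scale genomic simulation cannot reach.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    background = [f"BG{i:05d}" for i in range(n_background)]
    query_idx = rng.choice(n_background, size=n_query, replace=False)
    bearing = np.zeros(n_background, dtype=bool)
    bearing[query_idx] = True
    member = _membership_with_odds(rng, bearing, list_size, odds)
    query = [background[i] for i in sorted(query_idx)]
    listed = [background[i] for i in np.nonzero(member)[0]]
    return background, query, listed


def simulate_null_sets(
    rng: np.random.Generator, background: Sequence[str], n_sets: int, set_size: int
) -> dict[str, set[str]]:
    """Null gene sets drawn uniformly without replacement from the background."""
    out = {}
    for i in range(n_sets):
        idx = rng.choice(len(background), size=set_size, replace=False)
        out[f"null_{i:03d}"] = {background[j] for j in idx}
    return out


def simulate_gene_sets(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    manifest: GroundTruthManifest,
) -> tuple[list[str], dict[str, set[str]]]:
    """Aging list plus a set collection over the simulated genes.

    The aging list is sampled so that mutation-bearing genes (those hit by
    a shared somatic plant) are over-represented at
    ``config.aging_enrichment_odds``; null sets are uniform; when
    ``enriched_set_odds`` differs from 1 one additional set is planted at
    that odds ratio.  Ground truth is recorded on the manifest.
    """
    if config.n_genes < config.aging_list_size:
        raise SimulationError("aging_list_size exceeds the number of genes")
    rng = np.random.default_rng([config.seed, _RNG_SETS])
    symbols = [g.symbol for g in genes]
    mutated_ids = {
        gid for p in manifest.planted_somatic_shared for gid in p.genes
    }
    bearing = np.array([g.gene_id in mutated_ids for g in genes])
    member = _membership_with_odds(
        rng, bearing, config.aging_list_size, config.aging_enrichment_odds
    )
    aging = [symbols[i] for i in np.nonzero(member)[0]]
    collection = simulate_null_sets(
        rng, symbols, config.n_null_sets, config.null_set_size
    )
    enriched: dict[str, float] = {}
    if config.enriched_set_odds != 1.0:
        member_e = _membership_with_odds(
            rng, bearing, config.null_set_size, config.enriched_set_odds
        )
        collection["enriched_set"] = {symbols[i] for i in np.nonzero(member_e)[0]}
        enriched["enriched_set"] = config.enriched_set_odds
    manifest.aging_genes = aging
    manifest.mutated_gene_ids = sorted(mutated_ids)
    manifest.enriched_sets = enriched
    return aging, collection


# -- Coding-effect fixture ----------------------------------------------------

_SO_OF_EFFECT = {
    "synonymous": "synonymous_variant",
    "missense": "missense_variant",
    "stop_gained": "stop_gained",
    "intergenic": "intergenic_region",
    "intronic": "intron_variant",
}

_IMPACT_OF_EFFECT = {
    "synonymous": "LOW",
    "missense": "MODERATE",
    "stop_gained": "HIGH",
    "intergenic": "MODIFIER",
    "intronic": "MODIFIER",
}


def plant_coding_variants(
    seed: int,
    reference: ReferenceGenome,
    genes: Sequence[GeneModel],
    counts: Mapping[str, int],
) -> list[tuple[VariantSite, str]]:
    """Plant SNVs with known effect classes; returns (site, effect) pairs.

    Coding plants are constructed forward from the genetic code: a codon is
    chosen, every single-base substitution is classified by translation,
    and one matching the requested class is converted back to genomic
    coordinates (strand-aware).  Sites carry a SnpEff-style ANN string so
    ANN-parsing and the internal classifier can be cross-checked.
    """
    from Bio.Data.CodonTable import standard_dna_table

    codon_aa = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        codon_aa[stop] = "*"

    rng = np.random.default_rng([seed, _RNG_CODING])
    coding_genes = [g for g in genes if g.cds_segments]
    used: set[tuple[str, int]] = set()
    out: list[tuple[VariantSite, str]] = []

    def genomic_of(gene: GeneModel, cds_offset: int) -> int:
        s, e = gene.cds_segments[0]
        if gene.strand == "+":
            return s + cds_offset
        return e - cds_offset

    for effect, n in counts.items():
        if effect not in _SO_OF_EFFECT:
            raise ConfigurationError(f"unsupported effect class {effect!r}")
        placed = 0
        guard = 0
        while placed < n:
            guard += 1
            if guard > 10_000 * max(1, n):
                raise SimulationError(f"could not place {n} {effect} plants")
            if effect == "intergenic":
                chrom = _chrom_name(int(rng.integers(0, len(reference.sequences))))
                pos = int(rng.integers(2, reference.lengths[chrom]))
                if (chrom, pos) in used or any(
                    g.chrom == chrom and g.contains(pos) for g in genes
                ):
                    continue
                ref = reference.fetch(chrom, pos, pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                site = _ann_site(chrom, pos, ref, alt, effect, "", "")
                out.append((site, effect))
                used.add((chrom, pos))
                placed += 1
                continue
            gene = coding_genes[int(rng.integers(0, len(coding_genes)))]
            s, e = gene.cds_segments[0]
            if effect == "intronic":
                # inside span, >2 bp away from the CDS boundaries
                candidates = list(range(gene.start, s - 2)) + list(
                    range(e + 3, gene.end + 1)
                )
                if not candidates:
                    continue
                pos = int(candidates[int(rng.integers(0, len(candidates)))])
                if (gene.chrom, pos) in used:
                    continue
                ref = reference.fetch(gene.chrom, pos, pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                site = _ann_site(gene.chrom, pos, ref, alt, effect, gene.symbol, gene.gene_id)
                out.append((site, effect))
                used.add((gene.chrom, pos))
                placed += 1
                continue
            n_codons = (e - s + 1) // 3
            if n_codons < 3:
                continue
            codon_idx = int(rng.integers(1, n_codons))  # skip the start codon
            cds_seq = reference.fetch(gene.chrom, s, e)
            if gene.strand == "-":
                cds_seq = reverse_complement(cds_seq)
            codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            aa_ref = codon_aa[codon]
            options = []
            for within in range(3):
                for alt_base in "ACGT":
                    if alt_base == codon[within]:
                        continue
                    mutated = codon[:within] + alt_base + codon[within + 1 :]
                    aa_alt = codon_aa[mutated]
                    if aa_ref == aa_alt:
                        cls = "synonymous"
                    elif aa_alt == "*":
                        cls = "stop_gained"
                    elif aa_ref == "*":
                        cls = "stop_lost"
                    else:
                        cls = "missense"
                    if cls == effect:
                        options.append((within, alt_base))
            if not options:
                continue
            within, alt_base = options[int(rng.integers(0, len(options)))]
            pos = genomic_of(gene, codon_idx * 3 + within)
            if (gene.chrom, pos) in used:
                continue
            ref = reference.fetch(gene.chrom, pos, pos)
            alt = alt_base if gene.strand == "+" else reverse_complement(alt_base)
            site = _ann_site(gene.chrom, pos, ref, alt, effect, gene.symbol, gene.gene_id)
            out.append((site, effect))
            used.add((gene.chrom, pos))
            placed += 1
    return out


def _ann_site(
    chrom: str, pos: int, ref: str, alt: str, effect: str, symbol: str, gene_id: str
) -> VariantSite:
    ann = "|".join(
        [alt, _SO_OF_EFFECT[effect], _IMPACT_OF_EFFECT[effect], symbol, gene_id, "", ""]
    )
    return VariantSite(chrom, pos, ref, alt, ann_raw=ann)


# -- End-to-end fixture -------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: ReferenceGenome
    genes: list[GeneModel]
    variants: list[VariantSite]
    panel: PopulationPanel
    signatures: ReferenceSignatureSet
    aging_genes: list[str]
    gene_sets: dict[str, set[str]]
    manifest: GroundTruthManifest
    paths: dict[str, str] = field(default_factory=dict)


def simulate_all(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> SimulationResult:
    """Run the full generator; optionally write every fixture file.

    Emits (when ``out_dir`` is given): reference.fa, genes.gff3, calls.vcf
    (multi-sample: donor + clones), panel.tsv, signatures.tsv,
    aging_genes.txt, gene_sets.tsv, manifest.tsv and manifest.json.
    """
    reference = simulate_reference(config)
    genes = simulate_gene_models(config, reference)
    variants, manifest = plant_somatic_mutations(config, reference, genes)
    panel = simulate_panel(config, manifest)
    aging, collection = simulate_gene_sets(config, genes, manifest)
    signatures = builtin_signatures()
    result = SimulationResult(
        config=config,
        reference=reference,
        genes=genes,
        variants=variants,
        panel=panel,
        signatures=signatures,
        aging_genes=aging,
        gene_sets=collection,
        manifest=manifest,
    )
    if out_dir is not None:
        out = str(out_dir)
        os.makedirs(out, exist_ok=True)
        paths = {
            "reference": os.path.join(out, "reference.fa"),
            "genes": os.path.join(out, "genes.gff3"),
            "calls": os.path.join(out, "calls.vcf"),
            "panel": os.path.join(out, "panel.tsv"),
            "signatures": os.path.join(out, "signatures.tsv"),
            "aging_genes": os.path.join(out, "aging_genes.txt"),
            "gene_sets": os.path.join(out, "gene_sets.tsv"),
            "manifest": os.path.join(out, "manifest.tsv"),
            "manifest_json": os.path.join(out, "manifest.json"),
        }
        reference.to_fasta(paths["reference"])
        write_gff3(genes, paths["genes"])
        write_vcf(
            paths["calls"],
            variants,
            [config.donor_name, *config.clone_names],
            reference.lengths,
        )
        write_panel_tsv(panel, paths["panel"])
        write_signature_matrix(signatures, paths["signatures"])
        with open(paths["aging_genes"], "w") as fh:
            fh.writelines(s + "\n" for s in aging)
        with open(paths["gene_sets"], "w") as fh:
            for name in sorted(collection):
                for sym in sorted(collection[name]):
                    fh.write(f"{name}\t{sym}\n")
        _write_manifest(manifest, paths["manifest"], paths["manifest_json"])
        result.paths = paths
    return result


def _write_manifest(
    manifest: GroundTruthManifest, tsv_path: str, json_path: str
) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tchannel\tkind\tclone\tgenes\n")
        for group in (
            manifest.planted_somatic_shared,
            manifest.planted_private,
            manifest.planted_lowdepth,
        ):
            for p in sorted(group, key=lambda p: p.key):
                fh.write(
                    f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.alt}\t{p.channel}\t"
                    f"{p.kind}\t{p.clone or ''}\t{','.join(p.genes)}\n"
                )
    summary = {
        "expected_final_count": manifest.expected_final_count,
        "n_shared": len(manifest.planted_somatic_shared),
        "n_private": len(manifest.planted_private),
        "n_lowdepth": len(manifest.planted_lowdepth),
        "n_germline": len(manifest.germline_keys),
        "signature_name": manifest.signature_name,
        "aging_genes": manifest.aging_genes,
        "mutated_gene_ids": manifest.mutated_gene_ids,
        "enriched_sets": manifest.enriched_sets,
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
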