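"""Candidate somatic-mutation filtering cascade.

A "somatic mutation" in the cloning setting is a variant that is
heterozygous in a cloned animal but homozygous-reference in the nuclear
donor: the donor and clone are expected to be genetically identical, so a
clone-specific heterozygous allele is a mutation acquired during or after
nuclear transfer.

The cascade mirrors the discovery design with one donor and two clones:

1. per clone, keep heterozygous sites specific to that clone
   (clone het AND donor hom_ref);
2. per clone, drop low-coverage calls (DP <= 50 by default);
3. keep only sites discovered in at least ``min_shared_clones`` clones
   (shared by both clones by default) — the candidate somatic mutations;
4. annotate (never remove) candidates with population-panel allele
   frequency and a rare-variant flag.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, InputError
from .variant_io import (
    GT_HET,
    GT_HOM_REF,
    SiteKey,
    VariantSite,
    read_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the cascade.

    min_depth: minimum clone-sample DP retained (default 51, i.e. calls with
        DP <= 50 are removed).
    min_shared_clones: sites must be discovered in at least this many clones.
    rare_af_max: panel allele frequency below which a candidate is "rare".
    panel_missing_max: panel sites with a higher genotype missing rate are
        treated as uninformative (AF undefined).
    """

    min_depth: int = 51
    min_shared_clones: int = 2
    rare_af_max: float = 0.01
    panel_missing_max: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ConfigurationError("min_depth must be >= 0")
        if not (0.0 <= self.rare_af_max <= 1.0):
            raise ConfigurationError("rare_af_max must be in [0,1]")
        if not (0.0 <= self.panel_missing_max <= 1.0):
            raise ConfigurationError("panel_missing_max must be in [0,1]")
        if self.min_shared_clones < 1:
            raise ConfigurationError("min_shared_clones must be >= 1")


@dataclass
class PopulationPanel:
    """Per-site population allele frequency and genotype missing rate."""

    af_lookup: dict[SiteKey, tuple[float, float]]
    n_samples: int = 0

    def __post_init__(self) -> None:
        for key, (af, miss) in self.af_lookup.items():
            if not (0.0 <= af <= 1.0 and 0.0 <= miss <= 1.0):
                raise FormatError(f"panel entry {key}: af/missing outside [0,1]")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, n_samples: int = 0) -> "PopulationPanel":
        """Load a panel TSV with columns chrom, pos, ref, alt, af, missing_rate."""
        if not os.path.exists(path):
            raise InputError(f"panel file not found: {path}")
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"chrom", "pos", "ref", "alt", "af", "missing_rate"}
        if not required.issubset(df.columns):
            raise FormatError(f"panel TSV must have columns {sorted(required)}")
        lookup = {
            (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper()):
            (float(r.af), float(r.missing_rate))
            for r in df.itertuples()
        }
        return cls(af_lookup=lookup, n_samples=n_samples)

    @classmethod
    def from_vcf(cls, path: str | os.PathLike) -> "PopulationPanel":
        """Build a panel from a population VCF with per-sample genotypes."""
        sites = read_vcf(path)
        lookup: dict[SiteKey, tuple[float, float]] = {}
        n_samples = 0
        for site in sites:
            obs = site.observations
            n_samples = max(n_samples, len(obs))
            called = [o for o in obs.values() if o.gt != "missing"]
            miss = 1.0 - len(called) / len(obs) if obs else 1.0
            if called:
                ac = sum({"hom_ref": 0, "het": 1, "hom_alt": 2}[o.gt] for o in called)
                af = ac / (2 * len(called))
            else:
                af = 0.0
            lookup[site.key] = (af, miss)
        return cls(af_lookup=lookup, n_samples=n_samples)


@dataclass
class SiteFlags:
    """Per-site provenance through the cascade."""

    clone_specific_in: set[str] = field(default_factory=set)
    depth_pass: bool | None = None
    shared: bool | None = None
    population_af: float | None = None
    rare: bool | None = None


@dataclass
class CandidateSet:
    """Surviving candidate somatic mutations plus per-stage counts."""

    sites: dict[SiteKey, VariantSite]
    stage_counts: dict[str, int]
    provenance: dict[SiteKey, SiteFlags]

    def __len__(self) -> int:
        return len(self.sites)

    def keys(self) -> list[SiteKey]:
        return list(self.sites)

    def snvs(self) -> list[VariantSite]:
        return [s for s in self.sites.values() if s.is_snv]


def _sorted_sites(sites: Iterable[VariantSite]) -> dict[SiteKey, VariantSite]:
    return {s.key: s for s in sorted(sites, key=lambda s: s.key)}


def clone_specific_hets(
    variants: Sequence[VariantSite], donor_name: str, clone_name: str
) -> dict[SiteKey, VariantSite]:
    """Sites heterozygous in the clone and homozygous-reference in the donor.

    Inherited heterozygosity (donor het) and donor-allele dropout events
    (donor hom_alt) are excluded: "clone-specific" means gain of an allele
    the donor does not carry.  Donor-missing calls are excluded as
    uninterpretable.
    """
    if donor_name == clone_name:
        raise ConfigurationError("donor and clone sample names must differ")
    out = []
    n_donor_hom_alt = 0
    for site in variants:
        donor = site.observations.get(donor_name)
        clone = site.observations.get(clone_name)
        if donor is None or clone is None:
            raise ConfigurationError(
                f"site {site.key} lacks observations for {donor_name}/{clone_name}"
            )
        if clone.gt != GT_HET:
            continue
        if donor.gt != GT_HOM_REF:
            if donor.gt == "hom_alt":
                n_donor_hom_alt += 1
            continue
        out.append(site)
    if n_donor_hom_alt:
        logger.info(
            "clone_specific_hets(%s): excluded %d donor-hom_alt sites",
            clone_name, n_donor_hom_alt,
        )
    return _sorted_sites(out)


def depth_filter(
    sites: Mapping[SiteKey, VariantSite],
    config: FilterConfig,
    sample_name: str,
) -> dict[SiteKey, VariantSite]:
    """Retain sites whose DP in ``sample_name`` is >= config.min_depth.

    Missing depth is treated as failing (removed).
    """
    out = {}
    for key, site in sites.items():
        ob = site.observations.get(sample_name)
        if ob is None or ob.depth is None:
            continue
        if ob.depth >= config.min_depth:
            out[key] = site
    return out


def intersect_clones(
    per_clone: Mapping[str, Mapping[SiteKey, VariantSite]],
    config: FilterConfig,
) -> tuple[dict[SiteKey, VariantSite], dict[SiteKey, set[str]]]:
    """Sites present (same chrom,pos,ref,alt) in >= min_shared_clones clones.

    Returns the surviving sites and, for every input site, the set of clones
    it was seen in (used for provenance).
    """
    if len(per_clone) < config.min_shared_clones:
        raise ConfigurationError(
            f"{len(per_clone)} clone sets < min_shared_clones={config.min_shared_clones}"
        )
    seen_in: dict[SiteKey, set[str]] = {}
    rep: dict[SiteKey, VariantSite] = {}
    for clone, sites in per_clone.items():
        for key, site in sites.items():
            seen_in.setdefault(key, set()).add(clone)
            rep.setdefault(key, site)
    shared = {
        key: rep[key]
        for key in sorted(seen_in)
        if len(seen_in[key]) >= config.min_shared_clones
    }
    return shared, seen_in


def annotate_population_frequency(
    sites: Mapping[SiteKey, VariantSite],
    panel: PopulationPanel,
    config: FilterConfig,
) -> dict[SiteKey, tuple[float | None, bool | None]]:
    """Per-site (population_af, rare) annotation; removes nothing.

    A site absent from the panel has AF 0 (hence rare).  A panel entry whose
    genotype missing rate exceeds the threshold is uninformative: AF and the
    rare flag are undefined (None).
    """
    out: dict[SiteKey, tuple[float | None, bool | None]] = {}
    for key in sites:
        entry = panel.af_lookup.get(key)
        if entry is None:
            af: float | None = 0.0
        else:
            af_val, missing_rate = entry
            af = None if missing_rate > config.panel_missing_max else af_val
        rare = None if af is None else (af < config.rare_af_max)
        out[key] = (af, rare)
    return out


def run_filter_cascade(
    variants: Sequence[VariantSite] | Mapping[str, Sequence[VariantSite]],
    donor_name: str,
    clone_names: Sequence[str],
    panel: PopulationPanel | None = None,
    config: FilterConfig | None = None,
) -> CandidateSet:
    """Full cascade: clone-specific hets -> depth -> intersection -> AF.

    ``variants`` is either one multi-sample collection (donor + clones called
    jointly) or a mapping clone -> per-clone paired calls; both layouts carry
    donor and clone observations for every record.
    """
    config = config or FilterConfig()
    if len(clone_names) < config.min_shared_clones:
        raise ConfigurationError("fewer clones than min_shared_clones")
    if isinstance(variants, Mapping):
        per_clone_input: dict[str, Sequence[VariantSite]] = dict(variants)
        missing = [c for c in clone_names if c not in per_clone_input]
        if missing:
            raise ConfigurationError(f"no variant input for clones {missing}")
    else:
        per_clone_input = {c: variants for c in clone_names}

    stage_counts: dict[str, int] = {}
    provenance: dict[SiteKey, SiteFlags] = {}
    depth_passed: dict[str, dict[SiteKey, VariantSite]] = {}

    for clone in clone_names:
        specific = clone_specific_hets(per_clone_input[clone], donor_name, clone)
        stage_counts[f"clone_specific[{clone}]"] = len(specific)
        for key in specific:
            provenance.setdefault(key, SiteFlags()).clone_specific_in.add(clone)
        passed = depth_filter(specific, config, clone)
        stage_counts[f"depth_pass[{clone}]"] = len(passed)
        depth_passed[clone] = passed

    shared, seen_in = intersect_clones(depth_passed, config)
    stage_counts["shared"] = len(shared)
    for key, flags in provenance.items():
        flags.depth_pass = key in seen_in  # passed depth in >=1 clone
        flags.shared = key in shared
    for key in shared:
        provenance[key].depth_pass = True

    if panel is not None:
        af_ann = annotate_population_frequency(shared, panel, config)
        for key, (af, rare) in af_ann.items():
            provenance[key].population_af = af
            provenance[key].rare = rare
    stage_counts["annotated"] = len(shared)

    return CandidateSet(sites=shared, stage_counts=stage_counts, provenance=provenance)


def stage_counts_frame(candidates: CandidateSet) -> pd.DataFrame:
    """Stage-by-stage survivor counts as a tidy table."""
    return pd.DataFrame(
        {"stage": list(candidates.stage_counts),
         "count": list(candidates.stage_counts.values())}
    )


def provenance_frame(candidates: CandidateSet) -> pd.DataFrame:
    """Per-candidate provenance flags for the final set."""
    rows = []
    for key, site in candidates.sites.items():
        flags = candidates.provenance[key]
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "clones": ",".join(sorted(flags.clone_specific_in)),
                "depth_pass": flags.depth_pass,
                "shared": flags.shared,
                "population_af": flags.population_af,
                "rare": flags.rare,
            }
        )
    return pd.DataFrame(rows)
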