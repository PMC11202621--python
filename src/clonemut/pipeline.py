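"""End-to-end orchestration: simulate/load -> filter -> annotate ->
spectrum -> rates -> enrichment, behind one configuration object.

Every threshold of the analysis is surfaced as a named configuration key
with the standard value as default: DP > 50, two clones shared, rare AF
< 0.01, panel missing rate <= 10%, per-gene minimum count 2, top 20
rates, enrichment alpha 0.01 with minimum overlap 2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import __version__
from .effect_annotation import annotate_candidates, effects_frame, select_moderate_high
from .enrichment import (
    aging_overlap_test,
    enrich_gene_sets,
    enrichment_frame,
)
from .errors import CloneMutError, ConfigurationError, DegenerateTableError
from .gene_rates import assign_to_genes, mutation_rates, rates_frame, top_n
from .signature_spectrum import (
    best_match,
    build_spectrum,
    collapse_to_six,
    flatness,
    spectrum_frame,
)
from .somatic_filter import (
    FilterConfig,
    PopulationPanel,
    provenance_frame,
    run_filter_cascade,
    stage_counts_frame,
)
from .synthetic_data import SimulationConfig, simulate_all
from .variant_io import (
    read_gene_list,
    read_gene_models,
    read_gene_sets,
    read_reference,
    read_signature_matrix,
    read_vcf,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run of the full flow; either simulated or file-based inputs."""

    out_dir: str = "clonemut_run"
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    donor_name: str = "Donor"
    clone_names: tuple[str, ...] = ("NT2", "NT4")
    filter: FilterConfig = field(default_factory=FilterConfig)
    rate_min_count: int = 2
    rate_top_n: int = 20
    enrich_alpha: float = 0.01
    enrich_min_overlap: int = 2
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim_raw = dict(raw["simulate"])
            if "seed" not in sim_raw and "seed" in raw:
                sim_raw["seed"] = raw["seed"]
            sim = SimulationConfig(**sim_raw)
        samples = raw.get("samples", {})
        donor = samples.get("donor", sim.donor_name if sim else "Donor")
        clones = tuple(samples.get("clones", sim.clone_names if sim else ("NT2", "NT4")))
        cfg = cls(
            out_dir=raw.get("out_dir", "clonemut_run"),
            simulate=sim,
            inputs=dict(raw.get("inputs", {})),
            donor_name=donor,
            clone_names=clones,
            filter=FilterConfig(**raw.get("filter", {})),
            rate_min_count=raw.get("rates", {}).get("min_count", 2),
            rate_top_n=raw.get("rates", {}).get("top_n", 20),
            enrich_alpha=raw.get("enrichment", {}).get("alpha", 0.01),
            enrich_min_overlap=raw.get("enrichment", {}).get("min_overlap", 2),
            log_level=raw.get("log_level", "INFO"),
        )
        if cfg.simulate is None and "calls_vcf" not in cfg.inputs:
            raise ConfigurationError(
                "config needs either a 'simulate' block or inputs.calls_vcf"
            )
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage in order; returns (and writes) the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.simulate.seed if config.simulate else None,
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except CloneMutError as exc:
                raise CloneMutError(f"stage {name!r} failed: {exc}") from exc
        return deco

    manifest = None
    if config.simulate is not None:
        fixtures = os.path.join(config.out_dir, "fixtures")
        sim = stage("simulate")(lambda: simulate_all(config.simulate, fixtures))
        config.inputs = {
            "calls_vcf": sim.paths["calls"],
            "reference": sim.paths["reference"],
            "genes": sim.paths["genes"],
            "panel": sim.paths["panel"],
            "signatures": sim.paths["signatures"],
            "aging_genes": sim.paths["aging_genes"],
            "gene_sets": sim.paths["gene_sets"],
        }
        manifest = sim.manifest
        report["manifest_expected_final_count"] = manifest.expected_final_count

    inputs = config.inputs
    reference = stage("read_reference")(lambda: read_reference(inputs["reference"]))
    genes = stage("read_genes")(lambda: read_gene_models(inputs["genes"]))
    sample_names = [config.donor_name, *config.clone_names]
    variants = stage("read_vcf")(lambda: read_vcf(inputs["calls_vcf"], sample_names))
    panel = None
    if "panel" in inputs:
        panel = stage("read_panel")(
            lambda: PopulationPanel.from_tsv(inputs["panel"])
            if not inputs["panel"].endswith(".vcf")
            else PopulationPanel.from_vcf(inputs["panel"])
        )

    candidates = stage("filter")(
        lambda: run_filter_cascade(
            variants, config.donor_name, config.clone_names, panel, config.filter
        )
    )
    report["stage_counts"] = dict(candidates.stage_counts)
    report["final_candidates"] = len(candidates)
    stage_counts_frame(candidates).to_csv(
        os.path.join(config.out_dir, "stage_counts.tsv"), sep="\t", index=False
    )
    provenance_frame(candidates).to_csv(
        os.path.join(config.out_dir, "provenance.tsv"), sep="\t", index=False
    )
    write_vcf(
        os.path.join(config.out_dir, "candidates.vcf"),
        candidates.sites.values(),
        sample_names,
        reference.lengths,
    )

    stage("annotate")(lambda: annotate_candidates(candidates, genes, reference))
    effects_frame(candidates).to_csv(
        os.path.join(config.out_dir, "effects.tsv"), sep="\t", index=False
    )
    mod_high = select_moderate_high(candidates)
    report["moderate_high"] = len(mod_high)
    report["moderate_high_rare"] = sum(
        1
        for key in mod_high.sites
        if mod_high.provenance[key].rare is True
    )

    spectrum = stage("spectrum")(lambda: build_spectrum(candidates.snvs(), reference))
    spectrum_frame(spectrum).to_csv(
        os.path.join(config.out_dir, "spectrum96.tsv"), sep="\t", index=False
    )
    report["spectrum_total"] = spectrum.total
    report["spectrum_dropped"] = spectrum.dropped
    if spectrum.total:
        six = collapse_to_six(spectrum)
        with open(os.path.join(config.out_dir, "spectrum6.tsv"), "w") as fh:
            fh.write("class\tproportion\n")
            for cls, p in six.proportions.items():
                fh.write(f"{cls}\t{p:.6g}\n")
        report["spectrum6"] = {k: round(v, 6) for k, v in six.proportions.items()}
        report["flatness"] = round(flatness(spectrum), 6)
        sigset = read_signature_matrix(inputs["signatures"])
        ranked = best_match(spectrum, sigset)
        with open(os.path.join(config.out_dir, "similarity.tsv"), "w") as fh:
            fh.write("signature\tcosine\n")
            for name, sim_ in ranked:
                fh.write(f"{name}\t{sim_:.6f}\n")
        report["best_signature"] = {"name": ranked[0][0], "cosine": round(ranked[0][1], 6)}

    assignment, intergenic = assign_to_genes(candidates, genes)
    report["intergenic_candidates"] = intergenic
    mutated = [g for g, sites in assignment.items() if sites]
    report["mutation_bearing_genes"] = len(mutated)
    records = mutation_rates(assignment, genes, min_count=config.rate_min_count)
    report["genes_with_min_count"] = len(records)
    top = top_n(records, config.rate_top_n)
    rates_frame(top).to_csv(
        os.path.join(config.out_dir, "rates_top.tsv"), sep="\t", index=False
    )
    rates_frame(records).to_csv(
        os.path.join(config.out_dir, "rates_all.tsv"), sep="\t", index=False
    )

    if "aging_genes" in inputs:
        aging = read_gene_list(inputs["aging_genes"])
        by_id = {g.gene_id: g for g in genes}
        mutated_symbols = {by_id[g].symbol.casefold() for g in mutated}
        aging_cf = {a.casefold() for a in aging}
        all_symbols = {g.symbol.casefold() for g in genes}
        n_set = len(aging_cf & all_symbols)
        overlap = len(mutated_symbols & aging_cf)
        try:
            table, chi, pct = aging_overlap_test(
                len(genes), n_set, len(mutated), overlap
            )
            report["aging_test"] = {
                "table": [table.a, table.b, table.c, table.d],
                "chi2": round(chi.statistic, 3),
                "df": chi.df,
                "p": chi.p_value,
                "overlap_percent": round(pct, 1),
            }
        except DegenerateTableError:
            report["aging_test"] = {"error": "degenerate 2x2 table"}

    if "gene_sets" in inputs:
        collection = read_gene_sets(inputs["gene_sets"])
        by_id = {g.gene_id: g for g in genes}
        query = [by_id[g].symbol for g in mutated]
        background = [g.symbol for g in genes]
        results = enrich_gene_sets(
            query,
            collection,
            background,
            alpha=config.enrich_alpha,
            min_overlap=config.enrich_min_overlap,
        )
        enrichment_frame(results).to_csv(
            os.path.join(config.out_dir, "enrichment.tsv"), sep="\t", index=False
        )
        report["significant_sets"] = [r.set_name for r in results if r.significant]

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %d final candidates", report["final_candidates"])
    return report
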