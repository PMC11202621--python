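# Methods

## Somatic-mutation model

An SCNT clone shares its donor's nuclear genome, so the package defines
a candidate somatic mutation operationally: a biallelic variant at which
a clone is heterozygous and the donor is homozygous-reference. Two other
donor/clone genotype patterns are deliberately excluded from that
definition:

* donor het / clone het — inherited heterozygosity, not somatic;
* donor hom-alt / clone het — loss of a donor allele, a different event
  class (counted and logged, never admitted as a somatic gain).

Donor-missing genotypes are excluded as uninterpretable. Multi-allelic
VCF records are split per ALT on read; a `1/2` genotype is het for each
split alt and a `0/1` is het for alt1 and hom-ref for alt2, preserving
per-allele heterozygosity semantics. All coordinates are 1-based
inclusive throughout (VCF/GFF3 convention); no half-open intervals
exist anywhere in the package.

## Filter cascade

Stages, in order, with their tunable parameters (`FilterConfig`):

| stage | rule | parameter (default) |
|---|---|---|
| clone-specific | clone het AND donor hom-ref, per clone | — |
| depth | clone-sample DP ≥ `min_depth` | `min_depth = 51` (DP ≤ 50 removed) |
| intersection | site present in ≥ `min_shared_clones` clones | `min_shared_clones = 2` |
| population AF | annotate AF and `rare` flag; removes nothing | `rare_af_max = 0.01`, `panel_missing_max = 0.10` |

Notes on choices that were genuinely open:

* **Depth threshold.** The operational rule is "DP of 50 or less is
  removed", i.e. survivors have DP ≥ 51. Depth is evaluated on the
  clone sample in each per-clone set; donor depth is not thresholded
  (which sample's depth governs the filter is not specified by the
  source protocol — the clone's call is the one being trusted, so its
  depth is the one demanded). Missing DP fails the filter.
* **Population frequency is annotation, not filtration.** The panel
  lookup attaches AF (0 for sites absent from the panel) and a
  `rare = AF < 0.01` flag; entries whose genotype missing rate exceeds
  10% are treated as uninformative (AF and rare undefined). No site is
  removed, so the stage is count-preserving.
* Indels pass the cascade (they are variants) but are excluded from
  spectrum construction, which is SNV-only by definition.

The cascade is deterministic, order-invariant (the final set is sorted
by (chrom, pos, ref, alt)), monotone non-increasing per stage, and
idempotent on its own output.

## Effect annotation

When a VCF carries SnpEff-style `ANN` entries they are parsed as-is
(unknown effect terms degrade to other/MODIFIER with a warning). Bare
SNVs fall back to an internal classifier: position outside every gene
span → intergenic; inside a span but outside CDS → intronic (or
splice_region when within ±2 bp of a CDS segment boundary); inside CDS →
the affected codon is translated before and after substitution on the
coding strand (reverse-complemented for minus-strand genes) under the
standard nuclear genetic code, giving synonymous / missense /
stop_gained / stop_lost / start_lost. Impact follows the fixed SnpEff
mapping (missense→MODERATE, stop/start changes and splice_region→HIGH,
synonymous→LOW, intergenic/intronic→MODIFIER). A site's impact is the
maximum over its annotations; the functional subset keeps MODERATE and
HIGH. The classifier intentionally covers nothing subtler (no UTR
classes, no regulatory features, no canonical-transcript database).

Gene models use the genomic span length (end − start + 1), not summed
exon length; when a gene has several transcripts only the longest
transcript's CDS is kept (logged) — transcript selection is otherwise
arbitrary and this choice is deterministic.

## SBS spectrum

Channels follow the COSMIC plotting convention: substitution class
major (C>A, C>G, C>T, T>A, T>C, T>G), then 5′ flank, then 3′ flank,
alphabetical. Purine-centered SNVs are reverse-complemented into the
pyrimidine frame. SNVs whose context runs off the chromosome or
contains N are tallied as `dropped`, so `total + dropped` always equals
the number of SNVs submitted; a REF/genome disagreement raises instead
(data inconsistency, not a site property). No genome trinucleotide-
frequency normalization is applied — spectra are raw proportions
(matching how such spectra are usually displayed); similarity is plain
cosine on the 96-vectors, and `flatness` is Shannon entropy of the
channel proportions divided by ln 96. Signature ranking breaks ties by
name for determinism.

## Per-gene rates

A candidate is assigned to *every* gene whose span contains its
position (overlap double-counts by design: span-based annotation
conserves per-gene evidence); sites outside all genes are tallied as
intergenic. The rate is count/length kept at full precision internally
and formatted to 3 significant figures (`%.2e`, round-half-even) for
reporting. Genes need ≥ `min_count` (default 2) mutations to be ranked;
ordering is rate-descending with symbol as the deterministic tie-break.

## Enrichment statistics

* **2×2 chi-squared with Yates correction.** The correction is clamped
  at |O−E| — `(|O−E| − min(0.5, |O−E|))²/E` — so a table already at its
  expectation yields exactly 0 rather than a manufactured positive
  statistic. This matches mainstream statistical software on all tables
  with |O−E| ≥ 0.5 (verified against `scipy.stats.chi2_contingency` in
  the tests) and differs only where scipy over-corrects. Zero margins
  raise a degenerate-table error.
* **Over-representation.** Hypergeometric upper tail
  P(X ≥ k | N, K, n) via `scipy.stats.hypergeom.sf` (stable tail
  evaluation), validated against exhaustive subset enumeration for all
  feasible tables with N ≤ 12. BH adjustment wraps
  `statsmodels.multipletests(method="fdr_bh")`. Gene identity is
  case-insensitive symbol match after whitespace trimming; sets are
  intersected with the background before testing; significance requires
  adjusted p < `alpha` (default 0.01) *and* overlap ≥ `min_overlap`
  (default 2).

## Synthetic-data generator

The generator emulates the post-calling VCF level of a donor + two-clone
study; it is where validation ground truth comes from.

* **Reference**: i.i.d. uniform A/C/G/T per chromosome (default
  2 × 300 kb). Uniform composition means every trinucleotide context is
  abundant, so signature-constrained planting cannot starve.
* **Genes**: default 60 non-overlapping spans of 1.5–8 kb, single
  central CDS (~60% of span, codon-multiple length), half on the minus
  strand.
* **Plants**: 300 shared somatic SNVs (het in both clones, hom-ref in
  donor), 200/150 clone-private, 40 shared-but-low-depth decoys, on a
  background of 10,000 germline heterozygous sites shared by donor and
  clones. Each somatic site's channel is drawn from the configured
  96-channel signature and matched to a genome position with that
  context (possibly reverse-strand); pools are pre-shuffled so no
  position repeats. Expected final candidate count is therefore exactly
  the number of shared high-depth plants.
* **Depths**: Poisson around `depth_mean = 80` for passing sites
  (truncated to ≥ 51) and `lowdepth_mean = 25` for failing sites
  (truncated to ≤ 50). The truncation removes boundary flakiness on
  purpose: a plant is unambiguously on its intended side of the filter.
* **Panel**: 95% of germline sites at Beta(2,2) frequencies quantized
  to the allele-count grid of 196 diploids; planted somatic sites are
  absent except 5 rare colliders (AF < 0.01) and 5 high-missing-rate
  colliders (missing rate 0.2) that exercise the annotation rules.
* **Gene lists**: the aging list is sampled per gene with membership
  odds `aging_enrichment_odds` (default 2.0, the odds ratio implied by
  the study-scale 2×2 table this package tests) conditional on whether
  the gene carries a shared plant; null sets are uniform; one extra set
  is planted at `enriched_set_odds` (default 8). The odds bias is
  applied on the list-membership side only — mutation placement stays
  uniform given the signature — which realizes the intended 2×2 odds
  ratio with a single mechanism and leaves the spectrum unbiased.
* **Built-in signatures** (synthetic constructions, not COSMIC
  vectors): `uniform`; `SBS5like`, uniform with a smooth ±25% cosine
  modulation (flat/clock-like); `UVlike`, 80% of mass on the four
  NpCpC/NpCpT C>T channels (C>T-dominant, low entropy).
* **Determinism**: every operation derives its stream from
  `(seed, op_tag)` with numpy's `default_rng`; one seed reproduces all
  emitted files byte-for-byte.

What the generator does **not** model: sequencing error, mapping
artifacts, read-level evidence, indel/SV processes, linkage in the
panel, realistic demography, or genome composition bias. Passing tests
therefore demonstrate correctness of the *computational pipeline* under
its own definitions, not calling accuracy on real sequencing data.

Symbol-level helpers (`simulate_membership_study`,
`simulate_null_sets`) generate enrichment studies at sizes the genomic
fixture cannot reach (e.g. 400-gene queries on a 2,000-gene background)
for calibration and power checks of the statistical engine.

## Problem sizes used in tests

The default fixture (above) backs the exact-recovery checks. Repeated
studies (20-seed monotonicity/idempotence) use a reduced configuration
(2 × 100 kb, 20 genes, 1,000 germline, 60/40/30/10 plants) so each
replicate is cheap while exercising every stage. Signature-recovery
runs plant 5,000 SNVs with no germline background. Null-calibration
uses 200 uniform sets of 60 genes against a 400-gene query in a
2,000-gene background, where the hypergeometric null is close enough to
continuous for the p < 0.05 fraction to sit near its nominal level.

## Known limitations

* The clone-specific definition cannot distinguish a true somatic
  mutation from a systematic genotyping error replicated in both
  clones; with a single donor and two clones that ambiguity is
  inherent to the design.
* Gene span (not coding footprint) is the rate denominator, so rates
  are not comparable between genes of very different intron content.
* The internal effect classifier assumes in-frame, single-segment-clean
  CDS annotations and the standard genetic code.
* The enrichment engine tests user-supplied set files; it does not
  reproduce any hosted database's curation, GO graph propagation, or
  expression-based analyses.
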