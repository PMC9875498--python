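# Methods

This note documents the models, rules and numerical choices behind
`lakemeta`, the assumptions of the synthetic-data generator, and the
places where a design decision was genuinely open.

## Scope and data model

The package operates strictly downstream of assembly, binning and the
external QC/annotation tools. Its inputs are their tabular summaries:
hmmsearch-style marker hits, per-(entity, sample) mean coverage +
breadth, genome metadata (taxonomy, completeness, redundancy, lineage
flags), sample metadata (depth, compartment), a pathway-definition
table with manually curated per-model bit-score thresholds, viral QC
reports (viral/host gene counts, provirus and completeness flags),
protein-family membership tables, and nucleotide FASTA for the
genetic-code tests. Read mapping, binning engines, external classifiers
and tree inference are deliberately out of scope; where the original
analysis used a phylogenetic curation step (pmoA-vs-amoA, RuBisCO
reference placement, III-a/III-b sub-forms), the package exposes
configurable allow/deny or label tables instead.

Units: every fraction (breadth, relative coverage, coding density) is
stored in [0, 1]; percentages appear only at reporting boundaries.
Completeness/redundancy stay in [0, 100] because upstream tools report
them that way. All score/threshold comparisons are inclusive (≥) — the
upstream conventions mix "≥" and "a threshold of", so one documented
convention is used throughout. Coordinates are 0-based half-open.

## Community profiling

Marker proteins (ribosomal protein S3) pass at HMM bit score ≥ 40.
Species groups are built by greedy centroid clustering, longest
sequence first: a sequence joins the first centroid with pairwise
identity ≥ 0.99, else founds a group. Pairwise identity is exact
matches over total alignment columns of a global alignment scored
match +1 / mismatch 0 / gap −1; the scoring only picks the alignment.
The identity function is an injection point because dedicated
clustering tools define identity subtly differently. Representatives
are the longest member; when two members share a scaffold (assembly
fragmentation) only the longer fragment remains a candidate.
Representatives shorter than mean − 1 SD are dropped; the SD is the
sample SD (n − 1), configurable, since the prose convention is
ambiguous. With fewer than two sequences everything is retained.

Taxonomy uses three evidence lines — bin taxonomy, best reference hit,
scaffold protein consensus (hits at query coverage ≥ 0.70 and E ≤
1e-10, modal phylum) — and a two-of-three agreement rule. Modal ties
and two-way disagreements return "unresolved" rather than an arbitrary
pick, mirroring escalation to manual curation.

Detection requires breadth ≥ 0.5 (boundary inclusive); relative
coverage divides an entity's mean depth by the summed depth of detected
entities in the sample, so columns sum to 1 wherever anything is
detected. Genomes are gated at completeness ≥ 70% and dereplicated by
single-linkage clustering at ANI ≥ 95% (representative: highest
completeness, then lowest redundancy, then id; ANI entries given in
both orientations must agree within 0.1 percentage points).

Bray-Curtis is computed from the definition `1 − 2Σmin/(Σu + Σv)`;
the distance between two all-zero profiles is defined as 0 so empty
samples do not inject NaN into the ordination. PCoA is classical
scaling (double-centering, symmetric eigendecomposition); negative
eigenvalues (semimetric distortion) are dropped from the embedding and
logged, and explained variance is eigenvalue over the sum of positive
eigenvalues. An optional minimum-abundance filter before ordination
exists but defaults to off.

## Pathway inference

Order of operations matters and is fixed as: E-value screen (≤ 1e-6),
then best hit per protein (highest bit score, model id as deterministic
tie-break), then per-model thresholds. A protein whose best hit fails
its model threshold contributes nothing even if a weaker hit to a laxer
model would have passed. `min_markers` counts *distinct* marker models,
not hit multiplicity; the default is 1, with 2/3/2 for formate
oxidation, CO oxidation and Wood-Ljungdahl to suppress false positives.
Presence calling is therefore monotone in the hit set. Methanogen
flagging is `mcr` presence OR membership in a configurable methanogenic
lineage list (incomplete bins of known methanogen lineages lack `mcr`).

Pathway abundance is presence × detection: the summed relative coverage
of encoding genomes per sample, hence bounded by 1. Phylum/compartment
aggregation sums per (pathway, phylum, sample), then takes the
arithmetic mean over a compartment's samples. The 1% phylum floor is
applied jointly across pathways by default (a phylum surviving for any
pathway is kept everywhere it occurs); a per-pathway variant is a flag.

RuBisCO forms are assigned per scaffold as the highest-scoring form
whose bit score meets its threshold; the form III threshold defaults to
380.3 bits, a deliberately lowered cutoff that admits the divergent
III-a enzymes of methanogens. III-a/III-b refinement requires a
reference label table; without one the call stays "III". Calvin-cycle
capacity derives from form I/II presence, not from a marker-count rule.
Cluster representatives prefer binned members (ties by length), else
the longest. Abundance fractions are normalized within each sample over
present (breadth ≥ 0.5) RuBisCO scaffolds only; deny-listed (e.g.
eukaryotic) scaffolds leave numerator and denominator alike; a
breadth-failed scaffold is reported with fraction 0.

## Phage triage and genetic codes

The triage cascade applies to scaffolds ≥ 50 kb and evaluates, in
order, first match wins (h = host genes, v = viral genes, p = provirus):

| rule | condition | status |
|------|-----------|--------|
| R1 | h = 0 ∧ v ≥ 5 | likely_virus |
| R2 | h ≥ 1 ∧ v > h ∧ ¬p | likely_virus |
| R3 | h ≥ 5v ∧ ¬p | discard |
| R4 | h ≥ 5v ∧ p | likely_provirus |
| R5 | v < 5h | manual_curation |
| R6 | v = 0 ∧ h < 4 | manual_curation |
| fallback | — | manual_curation |

The source prose reads as a sequential cascade with overlapping
predicates and leaves some cells (e.g. h = 0, v ∈ 1..4) undefined; the
explicit fallback makes the mapping total and `rule_fired` makes every
call auditable, flagging fallback cells rather than guessing intent.
The test suite checks the engine against an independently coded
sentence-by-sentence oracle over the full grid of counts ≤ 30.

The eukaryote filter discards a scaffold when ≥ 25% of its *annotated*
proteins are eukaryotic; with zero annotated proteins there is no
evidence and the scaffold is kept.

Coding density is the union length of gene intervals (strand collapsed)
over sequence length. An alternate code (15 or 4) is selected when its
density is ≥ 1.10 × the standard-code density — the "≥10% increase" is
read as *relative*; the absolute (+10 points) reading is available as a
flag because the phrasing is genuinely ambiguous. Among qualifying
alternates the denser wins, ties to code 15. When the standard code
yields no genes at all, any alternate with positive density is taken
(the relative rule would otherwise admit density 0). Selection is
scale-invariant. Gene intervals are an injection point: real pipelines
pass intervals from a dedicated gene caller per code; the bundled
scanner (six frames, starts ATG/GTG/TTG, stops per code table, minimum
ORF 300 nt) is a simple self-contained caller used by the synthetic
tests.

Host assignments resolve by method priority — CRISPR targeting, then
prophage flanking-region taxonomy, then gene taxonomic profile — with
conflicting taxa inside the winning method yielding an explicit
unassigned-with-conflict result. Size classes default to ≥ 50 kb and
≥ 100 kb; 100% completeness (terminal repeats) is reported as circular.

## Enrichment statistics

Families with more than 5 member proteins (≥ 6, read strictly) are
tested. A genome "has" a family iff ≥ 1 member protein; genomes
detected in several compartments count inside each and outside only
where undetected (the source is silent here; the choice is recorded in
the output metadata). Occurrence is binary per compartment, not
weighted by per-sample detection.

The two-sided Fisher p-value follows the point-probability convention
of mainstream statistics libraries: sum the hypergeometric
probabilities of all tables, margins fixed, no more likely than the
observed one. It is computed with exact integer numerators over the
common binomial denominator and one final correctly-rounded float
division, so equiprobable-table ties are decided exactly rather than to
floating-point tolerance; degenerate margins give p = 1. The suite
verifies exact agreement with rational enumeration for every table with
N ≤ 40 and cross-checks scipy. BH correction (via statsmodels, oracle-
tested against the textbook step-up formula) pools all
(family × compartment) comparisons of a run; the enrichment call is
adjusted p ≤ 0.05 — the adjusted value, since correction was applied to
all comparisons — and ratio ≥ 3 or exclusivity.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for each stage under one integer
seed, sub-seeded per stage (CRC of the stage name), so stages are
independently reproducible. Default conditions: 4 compartments ×
30 genomes × 3 samples, adjacent-compartment overlap fraction 0.2.
Abundances are log-normal (μ = 1, σ = 1) per present (genome, sample) —
the standard neutral choice for community profiles; absent pairs get
low residual coverage (μ − 3, σ = 0.5) emulating cross-mapping noise.
Breadths are drawn from [0.6, 1.0] when present and [0.0, 0.3] when
absent, deliberately avoiding (0.3, 0.6) so ground truth is unambiguous
under the 0.5 rule. Marker hits give each planted pathway at least
`min_markers` above-threshold models (E ≤ 1e-8) and add spurious
strictly-sub-threshold hits at a configurable per-(genome, model) rate.
Family tables use inclusion probability ratio × base_freq inside the
target compartment and base_freq outside (defaults 5 × 0.15), padding
non-empty families to ≥ 6 proteins so the size filter keeps them.
Phage QC records are rejection-sampled until the triage cascade, run
as oracle, returns the requested class. Coded scaffolds interleave
planted ORFs (450–900 nt, start ATG, stop TAA, read-through TAG/TGA
every 20–40 codons for codes 15/4, plus one clean ORF keeping
standard-code density positive) with TTAA-repeat spacers that stop all
six frames under every code, so background calls essentially nothing.

What it does not emulate: real read noise, assembly error, chimeric
bins, compositional covariance between taxa, genuine depth-profile
shapes, or any real taxon. Passing the recovery tests shows the
inference rules are implemented correctly and have the designed
operating characteristics under clean planted signal — not that the
pipeline is robust to upstream artifacts.

Desk-scale problem sizes were chosen so the full suite runs in seconds
while keeping the statistical checks meaningful: 20 replicate seeds for
the stochastic recovery rates (pathway recovery, enrichment recall /
false-discovery proportion, null-control), 30 scaffolds per genetic
code, the full 1,922-cell triage grid, and all 135,751 Fisher tables
with N ≤ 40.

## Known limitations

- Greedy clustering is order-dependent by design (longest-first,
  deterministic); it reproduces the behavior of centroid-based tools,
  not an optimal partition.
- The bundled ORF scanner is intentionally minimal (no RBS model, no
  overlapping-gene resolution) and is not a substitute gene caller for
  real data; inject intervals from a dedicated caller per code.
- `unresolved` taxonomy and `manual_curation` triage statuses are
  terminal here; the original workflow resolves them by hand.
- Fisher tables with very large margins (tens of thousands) would make
  exact integer arithmetic slower than a log-space approximation;
  genome counts in this setting are hundreds at most, where it is
  effectively instant.
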