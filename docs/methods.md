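# Methods

This note documents the models and procedures implemented in `splicemaps`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic study conditions do and do not show about real data.

## Positional model

Coding exons are selected from a GENCODE-dialect GTF by feature type
(`CDS`), biotype (`gene_type` and `transcript_type` both
`protein_coding`), annotation evidence (level ≠ 3) and curated support (at
least one of the tags CCDS, appris_principal_1, appris_candidate_longest,
appris_candidate, exp_conf). Sex chromosomes are excluded by default
(`autosomes_only=True`); duplicate features sharing coordinates and strand
can be collapsed on request.

Internally every interval is 0-based half-open; GTF input/output converts
from 1-based closed coordinates explicitly. This makes junction arithmetic
unambiguous: on a plus-strand exon `[s, e)`, acceptor 0 is `s` and donor 0
is `e − 1`.

Near-splice windows cover acceptor −25..+10 and donor −10..+10, offsets
defined in transcript orientation (on the minus strand, donor +1 has the
lower genomic coordinate than donor 0). Windows are emitted only at exon
ends that abut an intron: the transcript's first CDS start and last CDS end
get none, because near-splice offsets are defined relative to introns.
Exonic window positions are truncated at the exon's other junction. Any
genomic base that collects more than one distinct (site, offset, strand)
label — across transcripts, or within a short exon where the donor and
acceptor exonic windows overlap — is removed entirely; identical labels
from multiple transcripts deduplicate to one (smallest transcript ID, for
determinism). Conflict removal is idempotent. Two consequences worth
knowing: an internal exon emits the full 57 labels whenever it is ≥ 11 bp
(both exonic windows fit), but yields 57 distinct conflict-free bases only
when ≥ 22 bp (at 21 bp the two exonic windows still share one base, which
the conflict rule removes).

Branchpoints are not predicted here: per-intron score tracks (one score per
position 1–70 bp upstream of each acceptor, LaBranchoR-style) are consumed,
and the highest-scoring position per intron is taken as the branchpoint.
Ties — rare with continuous scores — break toward the 5′-most position.
Scores above 0.85 flag a high-confidence subset. Branchpoint windows span
−5..+5 with +1 pointing toward the acceptor.

SNV enumeration emits all three alternates per position with the
trinucleotide context read from the reference strand; positions whose
reference base is not A/C/G/T are skipped and counted. Positional weight
matrices are computed strand-aware (minus-strand bases complemented), so
columns describe transcript-orientation motifs.

## SpliceAI aggregation and conservation summaries

The four delta scores (acceptor gain/loss, donor gain/loss) are combined as
the probability of at least one event under independence,
`P = 1 − Π(1 − DS)`. The function validates its inputs: a missing
annotation must be an absent record, never zeros, because zero-filling
biases per-position means downward. When one variant carries several
records (multi-gene annotations), the record whose gene matches the
variant's annotated gene wins, else the maximum-probability record.

Per-(site, offset) summaries are arithmetic means over distinct SNVs with a
95% CI. The default CI is the normal approximation mean ± 1.96·SE (the
usual error-bar convention and cheap at millions of variants); a
nonparametric bootstrap option exists. Variants without a score are
excluded from numerator and denominator. Conservation tracks (bigWig or
bedGraph) are summarised the same way per base; a position beyond a bigWig
chromosome's length raises an error naming the chromosome, since that
indicates a track/assembly mismatch rather than missing data.

## MAPS

Let `S_v ∈ {0,1}` indicate that variant `v` is a singleton (allele count
exactly 1) and `μ_v` the relative mutation rate of its trinucleotide
context and alternate allele (strand-collapsed table; any positive rate
table is accepted and MAPS is invariant to its overall scale, because the
calibration refit absorbs it). The calibration is fitted on synonymous
variants only, aggregated by (context, alt): weighted least squares of the
group singleton proportion on the group rate, weights equal to group
counts. This is numerically identical to variant-level least squares of
`S` on `μ` (same normal equations), a fact the bootstrap exploits.
Predictions are clamped to [0, 1] before summation, since a straight line
can stray outside the probability range at extreme mutabilities. With all
training variants in one context the fit is unidentifiable and raises; with
several contexts sharing one rate the slope is set to 0, the intercept to
the pooled proportion, and `slope_identifiable_` is cleared.

Class assignment follows a strict precedence. Synonymous variants inside a
near-splice window become near-splice variants and leave the calibration
set; missense variants inside a window are excluded altogether (their
constraint mixes coding and splicing effects); nonsense variants stay
nonsense. A variant carrying both near-splice and branchpoint labels keeps
only the near-splice one. High-confidence branchpoints support a parallel
analysis on the flagged subset.

MAPS is `(Σ S_v − Σ clamp(α̂ + β̂ μ_v)) / n`. On the training set it is zero
to round-off — an identity, since the WLS residuals are count-weighted to
zero — which the tests assert at 1e−10.

**Confidence intervals.** The CI method is a genuine design choice. A
per-class bootstrap that holds the calibration fixed understates the
variance: the calibration is itself estimated, and its error is shared
across all classes. `maps_table` therefore uses a joint bootstrap: each of
the (default 1000) replicates resamples the synonymous set, refits the line
via moment arrays, then resamples the class and recomputes MAPS under the
refitted line. The synonymous class is evaluated on its own training
resample, preserving the zero identity per replicate. Empirically this
brings coverage of the generator's true selection effects from ~78% (fixed
calibration) to ~95%. `compute_maps` retains the simpler fixed-calibration
bootstrap for standalone use on one class.

**Significance.** Following the corrected two-cell recipe: all MAPS scores
are shifted by the synonymous unadjusted proportion of singletons `c` so
the baseline expectation is a real count; observed `= n(MAPS_V + c)` vs
expected `= n(MAPS_syn + c)` on the {singleton, non-singleton} table, 1 df,
no continuity correction, two-sided p. Bonferroni controls the family-wise
rate (79 tests at α = 0.05 give 6.3 × 10⁻⁴ in the full design of 57
near-splice offsets plus 11 all-branchpoint and 11 high-confidence
branchpoint offsets). A known property: this one-sample test treats the
expected count as fixed, so it is calibrated only when the tested class is
small relative to the synonymous set (the regime of per-offset classes). If
a class approaches or exceeds the calibration set's size, shared
calibration noise inflates the statistic and the test over-rejects; the
null-calibration test pins the small-class regime (~600-variant classes vs
~7300 synonymous), where the empirical rejection rate is ~5.5% at nominal
5% (400 replicates).

## Trio de novo filters and prioritisation

The stringent filter encodes, rule by rule: heterozygous offspring,
homozygous-reference parents, each parent independently ≤ 1 alternate read,
offspring allele balance within [0.3, 0.7] (bounds inclusive — literal
reading of "between"), depth strictly > 20 in offspring and both parents,
offspring depth strictly < 98, no locus-control-region or assembly-patch
overlap, and no other DNV of the same individual within 20 bp (inclusive,
absolute genomic distance, counted regardless of the neighbour's own
verdict — making the rule symmetric). Evaluation never short-circuits: the
verdict lists every failed rule, and missing read evidence fails with
`incomplete_evidence`. Upstream "global"/"base" calling filters are an
input contract, not re-implemented.

Prioritisation keeps filter-passing SNVs on near-splice or branchpoint
positions of panel genes restricted to monoallelic, loss-of-function,
confirmed/probable entries. Near-splice annotation takes precedence over
branchpoint; one candidate row per (individual, variant). The aggregate
SpliceAI probability is attached for reporting but never thresholded —
prediction scores do not gate candidacy.

Phenotype terms are abstracted by one step up the HPO is-a hierarchy (e.g.
"Tetralogy of Fallot" → "Conotruncal defect"); with multiple parents the
lexicographically smallest ID is chosen for determinism, and the root
returns itself with a warning.

## Synthetic study conditions

The generator emits every input the pipeline reads, all driven by one seed
(byte-identical files on re-run). Defaults: ~100 genes of 3–5 exons
(60–120 bp) and introns of 120–300 bp on four autosomes plus two
X-chromosome genes, canonical GT/AG dinucleotides at every intron in
transcript orientation, decoy transcripts planted to violate each CDS
filter criterion, a 96-row log-normal rate table (σ = 0.4) with CpG
transitions boosted ×6 then renormalised to mean 1, and 50 trios. This
yields ~17,000 conflict-free near-splice positions (~51,000 near-splice
SNVs; ~150,000 possible SNVs including coding and branchpoint positions)
and ~50,000 observed cohort variants — large enough for per-class
constraint estimation, small enough that a full pipeline run takes a few
seconds.

The observation model deliberately matches the calibration's functional
form: each possible SNV is observed with probability `min(1, 0.35 μ)`, and
an observed variant is a singleton with probability
`clamp(a + b μ + s_class)` with a = 0.55, b = −0.05 (higher mutability →
more recurrence → fewer singletons), and `s_class` a configured selection
effect. MAPS of a class then has expectation `s_class` exactly, making
parameter recovery a sharp end-to-end test; a warning fires if more than
20% of probabilities clamp (parameters implausible). Default selection
effects mirror the qualitative ordering seen in large cohorts: canonical
splice sites 0.12–0.13, nonsense 0.12, donor +5 0.06, donor 0 0.05,
missense 0.04, branchpoint 0/−2 small positive, everything else 0.
Allele counts for non-singletons are a shifted geometric — arbitrary and
irrelevant to MAPS, which depends only on the singleton indicator. Coding
consequences are drawn at fixed proportions (25% synonymous, 70% missense,
5% nonsense) rather than translated from codons, since no downstream
statistic depends on codon structure. For controlled recovery experiments a
partition mode reassigns intronic SNVs uniformly to named classes with
specified effects, leaving the synonymous calibration set untouched.

SpliceAI-like deltas are Beta-distributed with class-dependent means (high
loss scores at canonical sites, moderate at donor +5, mild at branchpoint
0/−2, near-zero background), with 1.8% of SNVs lacking a record by default.
The conservation track spikes at canonical sites (mean ≈ 6.3), donor 0
(≈ 5.0) and the known intronic hierarchy (D+5 3.4, D+4 2.4, D+3 2.0, A−3
1.7, D+6 1.3), with acceptor −4 deliberately weak. Trio tables plant clean
passing DNVs — a subset on splice positions of filtered panel genes — plus
one dedicated violator per stringent rule, with the generator's intent
recorded per record.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the method relies on (mutability-dependent
observation and singleton processes, class-dependent selection, planted
filter truth) but not the biology it abstracts: no demography or realistic
site-frequency spectrum, no linkage, no codon structure, no sequencing
noise, and singleton probability exactly linear in rate (a nonlinear
stress mode can be had by post-transforming the table's rates). Passing
therefore demonstrates correctness of the implementation and calibration
identities — not that real cohorts satisfy the linearity assumption.

## Numerical choices and limitations

- All randomness flows from `numpy.random.Generator` seeded per component;
  bootstrap resample counts and CI levels are configurable.
- Chi-squared expected cells below 1 emit an "unreliable" warning rather
  than an error.
- Branchpoint-score ties break 5′-most; transcript deduplication keeps the
  smallest transcript ID; multi-parent HPO abstraction keeps the smallest
  parent ID — all for determinism, none with a biological claim.
- The packaged mutability table is synthetic (clearly labelled); analyses
  of real cohorts should load an empirically estimated table. MAPS itself
  is scale-invariant to this choice, but per-context calibration quality is
  not.
- Genome-scale printed counts (hundreds of thousands of CDS features,
  millions of near-splice positions) require the full GENCODE annotation
  and genome-wide branchpoint scores; the desk-scale suite validates the
  same code paths on the synthetic annotation instead.
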