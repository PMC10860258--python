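# Methods

`mtbkit` implements the computational core of a molecular-guided-therapy
(MGT) workflow for relapsed/refractory pediatric solid tumors: a tumor is
profiled (somatic variants, copy-number segments, fusions, RNA
expression), scored against reference panels, matched against a drug–gene
knowledge base through three tiers of evidence, and assembled into an
up-to-four-drug combination plan; at cohort level the package computes
the landscape (arm-level CNV recurrence, TMB, mutational signatures,
oncoprint) and the trial-style outcome statistics (RECIST v1.1 best
response, clinical benefit rate, feasibility milestones).

## Expression scoring

**Normalization.** Raw counts are normalized with median-of-ratios size
factors (the geometric-mean reference restricted to genes with
all-positive counts) followed by `log2(count/sf + pseudocount)`,
pseudocount 1. This is a deliberate approximation: the full regularized
log transform shrinks per-gene dispersion and is an off-the-shelf
preprocessing step, not the method of interest here; matrices normalized
elsewhere are accepted via the explicit `scale` flag on
`ExpressionMatrix`, which also makes the scale ambiguity of any external
reference visible rather than implicit.

**NRZ.** The normal reference summarises a whole-body panel of normal
tissues (22 in the reference design) into per-gene mean μ_g and sample
SD σ_g (n−1 denominator). A tumor gene scores z_g = (x_g − μ_g)/σ_g and
is flagged `over` when z ≥ τ, `under` when z ≤ −τ. τ defaults to 2 and
the boundary is inclusive ("Z-score of 2" is actionable); both are
configurable. σ is floored at `sd_floor` (default 0.1 on the log2
scale) so degenerate reference genes cannot produce infinite scores —
with 22 reference samples a zero sample SD essentially only occurs for
unexpressed genes.

**CRC.** The cancer-reference statistic is the mid-rank empirical-CDF
percentile of the tumor's value within a reference cohort of
relapsed/refractory childhood tumors: p_g = 100·(#{ref < x} +
0.5·#{ref = x})/n. The mid-rank convention makes p invariant under any
strictly monotone joint transform and symmetric for ties. The precise
statistic used operationally by the original reporting system is not
public; this definition is the package's documented choice.

## Somatic landscape

**Arm-level CNV events.** Segments qualify when they contain ≥ 50 genes
and |log2 tumor/normal| ≥ 0.5 (both inclusive; gain and loss handled by
sign). Qualifying segments are intersected with chromosome arms, the
overlaps **unioned** per (subject, arm, direction) — so overlapping
segment calls cannot push the covered fraction above 1 — and an event is
emitted when the union covers ≥ 50% of the arm. Arm length is taken from
the arm map as-is (no centromeric-gap exclusion). Arm maps can be built
from UCSC cytoBand files (p = bands before the centromere, q = after,
converted from 0-based half-open to the package-wide 1-based inclusive
convention).

**Recurrence.** An (arm, direction) pair enters the cohort oncoprint when
≥ 15 *distinct subjects* carry it; longitudinal biopsies of one subject
count once.

**TMB.** Somatic point mutations (SNVs only; indels excluded) per
megabase. The callable footprint is assay-specific and never inferable
from a variant list, so `callable_mb` is an explicit parameter with a
documented default of 30 (a typical exome); reports echo the value used.

## Mutational signatures

SNVs with trinucleotide context are binned into the canonical 96 classes
(substitution type major — C>A, C>G, C>T, T>A, T>C, T>G — then 5′ and 3′
flank lexicographic). Purine-strand calls are reverse-complemented; the
192→96 collapse is enumerated exhaustively in tests. A catalog m is
decomposed against a signature matrix W (96 × S, columns on the simplex)
by unregularized non-negative least squares, e = argmin_{e≥0}‖We − m‖₂,
matching the linear-combination-decomposition approach of signature
refitting tools under default settings; an optional per-signature
proportion cutoff (default 0, i.e. off) re-fits after dropping small
exposures. Proportions π = e/Σe are averaged **unweighted** within tumor
types for cohort tables. The canonical COSMIC matrix is a user-supplied
input, not embedded data: tests and simulations use synthetic,
well-separated signatures so no external database version is baked in.

## Drug matching

Three tiers, matched per subject:

1. **direct** — a somatic variant, or either partner of a fusion, in a
   gene with a `direct` rule;
2. **inferred** — a variant in gene G, one curated hop G→T in the
   inference map, and a `direct`/`inferred` rule on T. Exactly one hop;
   chains are never followed. The map is a curated stand-in for the
   "computational impact" prediction of the original system, which is
   unspecified;
3. **expression** — an NRZ `over`/`under` flag agreeing with an
   `expression` rule's direction.

Rules whose mode is `resistance` are **hard vetoes** for the matched
drug — the conservative machine-checkable reading of
sensitivity/resistance annotation. Gene-level CNV→drug matching is not
implemented: copy-number segments carry a gene count, not gene
identities, so there is no sound channel from a segment to a rule gene;
arm-level events feed the landscape views instead.

**Ranking.** The original decision is a human tumor-board deliberation;
software needs a deterministic surrogate. Candidates rank by
(tier ascending, score descending, drug name). Expression candidates
score by |z| of their best supporting gene; variant candidates by a
fixed, configurable event-class weight (fusion 4 > protein-change SNV 3 >
other variant 2 > CNV 1).

**Assembly.** A greedy cycle mirrors the "repeat until a three- or
four-drug combination" loop: optionally seed with the first priority
regimen fully contained in the candidate pool and internally
conflict-free (modeling "previously established and tested regimens were
given priority"), then repeatedly add the best-ranked drug that neither
duplicates a plan drug nor pairs with one in the interaction blacklist,
stopping at `max_drugs` (default 4) or exhaustion. Exhaustion of all
candidates by vetoes raises a distinct "no plan" condition. Reports are
deterministic JSON (sorted keys, no timestamps) validated against a
shipped structural schema.

## Outcomes

Best response is computed from target-lesion diameter sums only; the
confirmation-scan, non-target and new-lesion machinery of full RECIST is
out of scope. Classes: NED (post-surgical, no measurable disease), CR
(sum reaches 0), PR (best baseline-referenced change ≤ −30%), PD (before
any PR/CR, some timepoint ≥ +20% over the running nadir **and** ≥ 5 mm
absolute increase), SD otherwise. Two reference conventions coexist
deliberately: PD is nadir-referenced per RECIST 1.1, while waterfall
percent change is baseline-referenced (pre-cycle-1 to best scan) as
reported clinically. The −30% boundary classifies as PR ("at least 30%
decrease"); a strictness knob flips the boundary to SD since the trial's
central-review convention at exactly −30% is not recoverable.

Benefit rate = (CR+PR+SD+NED)/(CR+PR+SD+NED+PD), reported as a half-up
rounded percent. Cycle-start and waterfall percentages round half-up to
two decimals, matching clinical-report precision. Feasibility summaries
(mean/median/range of days from biopsy per milestone) exclude missing
milestones per-statistic.

## Synthetic cohorts

`simulate.generate_cohort` emits a full bundle plus ground truth, all
randomness through one seeded generator. Defaults are the package's
study conditions, chosen once:

- **Cohort**: 28 subjects (6 neuroblastoma, 8 CNS, 14 rare), roughly the
  trial's stratum proportions at desk scale; 400 genes; 22 normal
  tissues.
- **Expression**: per-gene location Uniform(2,10) and scale
  Uniform(0.2,0.6) on the log2 scale, Gaussian noise per tissue/tumor —
  positive, heavy-tailed on the natural scale like normalized RNA-seq. A
  spike adds k·σ_g (k = 4) to 8 over- and subtracts from 4 under-genes
  per tumor, always including a few knowledge-base rule genes so a
  tier-3 plan exists.
- **Signatures**: 5 synthetic block-concentrated signatures;
  type-specific Dirichlet mixtures; mutation counts per subject
  (Poisson means 120/30/50 for NB/CNS/rare) span the trial's qualitative
  TMB ordering without imitating its distribution.
- **Arm events**: type-characteristic gains/losses (e.g. 17q gain and
  11q loss for neuroblastoma-like subjects) planted at fractions
  0.6–0.95 with |log2| 0.7 and 100-gene segments, over neutral
  background segments.
- **Outcomes**: lesion trajectories constructed to classify exactly as
  intended under the documented rules, with class frequencies near the
  trial's per-stratum best-response mix; milestone days centered on the
  trial's means (10/17/23/38 from biopsy).

What passing closed-loop tests show — and don't: recovery holds under
Gaussian log-scale noise, independent genes, exact rule wiring and
clean segment calls. Real tumors add correlation structure, purity and
batch effects, annotation noise and caller disagreement, so these tests
validate the algorithms' contracts, not clinical performance.

## Numerical choices

- All coordinates in memory are 1-based inclusive; dialects convert at
  the I/O boundary.
- Thresholds (τ, log2, gene count, arm fraction, −30%/+20%/5 mm) are
  inclusive throughout, matching the ≥/≤ phrasing of the rules they
  implement.
- Ties in candidate ranking break by drug name; ties in oncoprint gene
  ordering break alphabetically — determinism over cleverness.
- Percent rounding is half-up (Decimal), not banker's, to match printed
  clinical tables.
- Degenerate inputs fail loudly: all-zero expression samples, all-zero
  catalogs, empty gene intersections, zero baselines and empty candidate
  pools all raise typed errors rather than propagating NaN.

## Known limitations

- No purity/ploidy correction, allele-specific CN, or segmentation — the
  caller consumes segments.
- The tier-2 inference map is single-hop and curated; no pathway
  propagation.
- Best response ignores non-target/new lesions and confirmation scans.
- The per-subject exposure fit is unregularized NNLS; at very low
  mutation counts (tens) proportions are noisy, which is inherent to the
  catalog size, and cohort statistics should prefer subjects with larger
  catalogs. Recovery at catalog size 1000 is the tested operating point;
  at trial-like counts only the dominant signature is reliably
  identified.
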