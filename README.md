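# mtbkit

Molecular-guided therapy (MGT) analytics for pediatric precision
oncology. `mtbkit` implements the computational pipeline behind a
molecular tumor board (MTB) for relapsed/refractory childhood solid
tumors — neuroblastoma, CNS tumors and rare solid tumors — where therapy
is chosen from a tumor's genomic and transcriptomic profile rather than
histology alone, as a combination of up to four targeted agents.

It is written for computational biologists and trialists who need the
decision pipeline and cohort analytics as reusable, tested code:

- **Expression outlier scoring.** Median-of-ratios normalization, then
  the *normal reference Z-score* (NRZ): per gene,
  `z_g = (x_g − μ_g)/σ_g` against a whole-body panel of 22 normal
  tissues, flagged over/under at |z| ≥ 2; plus a mid-rank ECDF
  percentile (CRC) against a cancer-reference cohort.
- **Somatic landscape.** Arm-level CNV calling (segments with ≥ 50 genes
  and |log2 T/N| ≥ 0.5 covering ≥ 50% of an arm), cohort recurrence
  (≥ 15 distinct subjects), TMB (somatic point mutations per Mb), and
  oncoprint assembly.
- **Mutational signatures.** 96-trinucleotide-context catalogs and
  non-negative least-squares decomposition
  `e = argmin_{e≥0} ‖We − m‖₂` against a signature matrix, with
  per-tumor-type exposure averaging.
- **Tiered drug–gene matching.** Tier 1: direct variant/fusion ↔ drug
  rules; tier 2: single-hop inferred matches (altered gene → drug
  target); tier 3: NRZ expression flags vs over/under rules. Resistance
  rules veto their drug; a greedy, deterministic loop assembles a 1–4
  drug plan honoring an interaction blacklist and priority regimens, and
  emits a reproducible drug-prediction report.
- **Outcomes.** RECIST v1.1 best-response classification (CR/PR/SD/PD,
  plus NED), clinical benefit rate
  `(CR+PR+SD+NED)/(CR+PR+SD+NED+PD)`, waterfall tables of best percent
  tumor-burden change, feasibility milestone summaries, and cycle-start
  statistics.
- **Longitudinal analysis.** Shared/unique event partitions across 2–3
  serial biopsies and targetable-gene Z matrices with plan-drug flags.
- **Synthetic cohorts.** A fully seeded generator producing bundles with
  planted spikes, signature mixtures, arm events, drivers and lesion
  trajectories — with ground truth — so the whole pipeline is testable
  with no protected data.

## Worked example

Generate a synthetic cohort and run one subject end to end:

```python
from mtbkit.simulate import generate_cohort, SimulationConfig
from mtbkit import pipeline

bundle, truth = generate_cohort(SimulationConfig(seed=11))
result = pipeline.run_subject(bundle, "CNS001")
print(result.report["plan"]["drugs"])
```

prints

```
['trametinib', 'bortezomib', 'sorafenib', 'vorinostat']
```

a four-drug plan for a CNS-type subject: `trametinib` is a tier-2 match
(an NF1 variant inferred to impact its target MAP2K1, event-class score
3.0), and the other three are tier-3 expression matches whose targets
(PSMB5, PDGFRA, HDAC2) were flagged overexpressed with z-scores 4.44,
3.85 and 2.40 against the 22-tissue normal reference. Cohort summaries:

```python
summary = pipeline.run_cohort(bundle)
print(summary["benefit"])          # {'proportion': 0.679, 'percent': 68.0}
print(summary["benefit_by_type"])  # {'CNS': 63.0, 'neuroblastoma': 67.0, 'rare': 71.0}
print(summary["waterfall"])        # {'n': 25, 'n_decrease': 15, ... 'percent_decrease': 60.0}
```

i.e. 68% of this synthetic cohort's subjects show clinical benefit (best
response better than progressive disease), and 60% of
measurable-disease subjects show a tumor-burden decrease.

The same flows are available from the shell:

```bash
mtb simulate --seed 11 --out run/
mtb run --manifest run/manifest.yaml --subject CNS001
mtb outcomes --lesions run/lesions.tsv --milestones run/milestones.tsv
mtb cnv-arms --seg run/segments.tsv --arms run/arms.tsv
```

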