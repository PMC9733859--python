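# Methods

`cordmod` prioritizes candidate *modifier* variants in a small dominant
cone-rod dystrophy (CORD) pedigree: one fully penetrant causative
variant explains who is affected, and the question is which of the
remaining candidate variants shape *which symptoms* each patient shows.
Because the pedigree is far too small for regression-style association,
the package implements a qualitative scoring procedure plus exact tests
and similarity clustering, and ships a synthetic-cohort generator so the
whole chain can be validated end to end.

## Genotype encoding

Diallelic calls (wild-type, heterozygous, homozygous-mutated, missing)
are encoded per inheritance model:

| call      | additive | dominant | recessive |
|-----------|----------|----------|-----------|
| wild-type | 1        | 0        | 0         |
| het       | 2        | 1        | 0         |
| hom. mut. | 3        | 1        | 1         |
| missing   | NaN      | NaN      | NaN       |

The additive code is mutant-allele dosage shifted to 1..3 — risk grows
1r-fold per heterozygous step and 2r-fold for homozygotes. Dominant and
recessive codes are mutated-class indicators; {0,1} was chosen over a
{1,2} relabeling because only the partition matters downstream, and an
indicator makes that explicit. Missing calls propagate as NaN and are
dropped pairwise wherever a mean is taken, with masked-cell counts
surfaced in the run summary.

## The symptom-difference score

For a variant v and symptom s, members are split into a
symptom-present and a symptom-absent group, and

    d[s][v] = mean(code | s = yes) − mean(code | s = no).

Positive d: mutant dosage leans toward members showing the symptom
(putative causative direction); negative d: protective direction. |d| is
discretized into a weight

    p[s][v] = 0  if |d| < 0.5
              1  if 0.5 ≤ |d| < 1
              2  if |d| ≥ 1

and the per-variant relevance score is the column sum
`SC[v] = Σ_s p[s][v]`. Under additive codes every defined |d| ≤ 2, so
`SC ≤ 2 × (number of scored symptoms)`.

A separate categorization with cut points 0.05 and 1 (irrelevant /
low / strong, causative / protective) exists purely for heatmap export
(`heatmap_category`); it uses different thresholds than the weight rule
and the two are deliberately never merged. The printed interval ends
overlap at d = −0.05; the protective label wins there, mirroring the
half-open convention on the causative side. `heatmap_long.tsv` carries
the categories; no figure is rendered.

### Contrast population

Only the affected members have clinical symptom annotations. The
default (`contrast="family"`) forms, per symptom, the present group from
the patients showing it and the absent group from the patients not
showing it **plus every genotyped disease-free relative** — the healthy
members exhibit none of the clinical symptoms, so they belong in every
symptom-absent group. Members of uncertain status are excluded from the
contrast by default (a flag forces them in as healthy). A symptom must
still *vary among the patients* to be scored: rows uniform across the
patients (e.g. photophobia, shown by every patient; or a visual-field
sign shown by none) are "white rows", masked as undefined rather than
zero-filled.

This construction is the only one under which the two published
behaviours coexist: symptoms common to all patients produce white rows,
*and* a variant whose genotype is uniform among the patients but
different in the healthy members (the CACNG8 3'UTR variant, homozygous
in all four patients and wild-type in all healthy members) can still
earn the top score. A pure within-patient contrast (`contrast=
"affected"`, also available) forces such a variant to score 0.

### Banding

Scores are banded against their own distribution: `two_sd` at
SC ≥ median + 2·σ, `one_sd` at median + σ ≤ SC < median + 2·σ, `below`
otherwise. σ is the population SD (divisor n) by default; the sample SD
(n−1) is available and the fixture results are identical under both.
With a degenerate distribution (σ = 0) a score escapes `below` only if
strictly above the median. The banding median is taken over the
candidate variants only, not the causative/associated ones.

### The fixture symptom roster (a reconstruction)

The published table of clinical features mixes binary rows with
free-text and categorical rows, and the original analysis never
enumerates which rows were scored. The packaged fixture uses an 11-row
binarization: night blindness, visual-field narrowing, photophobia,
three colour-perception axes (green→light-blue, white perception,
red→orange), nystagmus, compensatory head movement, photopsia, plus two
documented binarizations of categorical rows — "best visual condition =
darkness" (one patient) and "perimacular involvement" (one patient).
This roster was selected, from the space of defensible binarizations of
the published table, as the one consistent with the published band
structure (one variant beyond two SDs, eight between one and two); an
exhaustive sweep shows the structure is sensitive to the roster, so the
roster is an explicit reconstruction, configurable by supplying any
symptom table. Two caveats are documented rather than hidden: no
binarization reproduces the published *identity list* of the eight
one-SD variants exactly (the reconstruction ranks an ABCA4 splice
variant, a second CACNG8 3'UTR variant and a synonymous LTF change into
the band in place of the RXRG splice variant and two LTF missense
changes — the surviving-gene count is six either way), and the
uncertain-status member III1 must stay out of the contrast.

## Association tests

Per variant, a genotype-by-status table is built under one of three
schemes — `carrier_2x2` (het+hom vs wild; default, the common genetics
convention), `recessive_2x2` (hom vs rest) or `genotype_2x3` — with
uncertain members excluded by default, and tested with the classical
two-sided Fisher exact test (probability ordering; no mid-p). The 2×2
case delegates to `scipy.stats.fisher_exact`; the 2×3 case is an exact
Freeman–Halton enumeration over all tables with the observed margins,
feasible for family-sized totals (guarded at N ≤ 30). On the fixture the
CACNG8 carrier table is [[4,0],[0,3]], p = 1/35 ≈ 0.0286 (0.0286 also
with the uncertain member counted healthy); the originally printed
p = 0.040 is not reproduced by any of the three constructions, so the
chosen scheme is stamped into every output rather than silently matched.

`perfect_separation` flags variants whose non-missing genotype values in
the affected and healthy groups are disjoint sets. On the fixture this
flags *two* candidates — the CACNG8 3'UTR variant and the ABCA4
splice-region variant, whose genotypes track disease status exactly —
plus the causative/associated pair by construction. The original report
names only CACNG8 here; the discrepancy follows directly from the
published genotype table and is asserted as-is in the unit suite.

Control-cohort screening reports per-variant genotype counts and the
alternate-allele frequency (alt alleles / 2·called subjects); variants
absent from the cohort are reported untyped, never as frequency zero.

## Similarity clustering

Subject similarity is the simple matching coefficient between raw
categorical vectors (genotype calls, or yes/no symptom vectors with
disease-free members given all-"no" columns): the fraction of positions
in agreement, missing positions excluded pairwise, a pair with no
comparable positions masked. Clusters at a cutoff are connected
components of the graph with edges at similarity ≥ cutoff; components
(not cliques) match the pixel-persistence reading of a thresholded
similarity map. Raising the cutoff only refines the partition. On the
fixture, symptom-basis clustering at 0.8 isolates exactly the
disease-free quartet {I1, II3, II5, III1}, and genotype-basis clustering
at 0.7 keeps the proband I2 with her sons II1 and II2 (the component
also chains in II3/III1 via intermediate members — the published account
prints no component sizes).

## Synthetic cohorts

`simulate_cohort` emulates the *shape* of the study data: status-labeled
subjects (no meiosis/transmission modelling — the statistics never use
relatedness), one dominant fully penetrant causative variant (het in
every affected, wild in every healthy and in all controls), modifier and
neutral candidate variants drawn under Hardy–Weinberg proportions at
configured allele frequencies, and binary symptoms for the affected
members only, drawn from a logistic model

    logit P(symptom s) = logit(baseline_prob)
                         + Σ_{modifiers m linked to s} effect_size · (code_m − 1).

Each modifier links to 1–3 symptoms chosen at the configured seed.
Defaults mirror the study conditions: 4 affected + 4 healthy members, 32
candidate variants (3 modifiers), 11 symptoms, 100 controls, allele
frequency 0.3 (mid-range of the candidate panel's population
frequencies), baseline symptom probability 0.5 (about half the fixture's
symptom cells are "yes"), effect size 2.0 on the log-odds scale (a
strong but not deterministic per-allele shift). Output is
bit-reproducible for a fixed config.

What the generator does **not** emulate: linkage disequilibrium between
candidate variants, ascertainment of the pedigree through a proband,
quantitative or progressive symptoms, genotyping error. Passing
recovery tests therefore demonstrate that the scoring chain detects
genotype-linked symptom shifts of the configured size in cohorts of this
shape — not calibrated error rates on real pedigrees; the band rule is a
descriptive outlier screen, not a calibrated test, which is why the null
band rate is regression-tested against a frozen-seed reference rather
than a theoretical value.

`recovery_rate` ranks variants by score (ties broken lexicographically
by variant key for determinism) and reports the fraction of planted
modifiers in the top k. With 200 seeded replicates at effect size 2.0
and 8 affected members, mean recovery exceeds the zero-effect null's.

## Numerical and degenerate-input choices

- Undefined differences are masked (NaN + mask), never zero-filled;
  masked cells contribute 0 to score sums and are counted in summaries.
- Band classification refuses fewer than 2 variants; scoring refuses a
  symptom table with no informative row.
- Fisher ties are resolved with 1e-12 relative slack, matching the
  enumeration oracle convention.
- Cutoffs are closed (similarity ≥ cutoff forms an edge).
- Pipeline bundles contain no timestamps and sort all JSON keys, so a
  fixed configuration reproduces byte-identical output.

## Limitations

Four affected members give the difference statistic very coarse support
(group means over 1–3 subjects); the score is a screen, not an
inferential procedure, and no multiple-testing correction is applied
anywhere (by design — none was used in the original analysis). The
symptom roster is a reconstruction with documented sensitivity. The
Fisher p-values on family-sized tables are exact but essentially
floor-limited (1/35 here), so "significance" language should be avoided
on data of this size.
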