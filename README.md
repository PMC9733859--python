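# cordmod

Family-based modifier-variant prioritization for a cone-rod dystrophy
(CORD) pedigree.

In small dominant retinopathy pedigrees a single fully penetrant variant
often explains *who* is affected, but not why affected relatives show
very different symptoms. `cordmod` implements a qualitative
genotype–phenotype screen for exactly that setting: given a pedigree, a
variant-by-subject table of diallelic calls (one causative variant plus
a panel of candidate modifier variants) and per-patient binary symptoms,
it ranks candidates by how well their genotype pattern separates
symptomatic from asymptomatic members. It is aimed at analysts working
with single-family NGS candidate panels who need a transparent,
reproducible screen rather than a powered association test.

## The statistic

Genotypes are encoded additively (1 = wild-type, 2 = heterozygous,
3 = homozygous mutated; dominant/recessive indicator codings are also
available). For variant *v* and symptom *s*,

    d_s,v = mean(code | s present) − mean(code | s absent)

where the symptom-absent group also contains the genotyped disease-free
relatives, and symptoms uniform across the patients are masked ("white
rows"). |d| is discretized into weights p ∈ {0, 1, 2} at cut points 0.5
and 1, and each variant's relevance score is the column sum
SC_v = Σ_s p_s,v. Variants are banded against the score distribution:
`two_sd` at SC ≥ median + 2σ, `one_sd` from median + σ. Around the score
sit a two-sided Fisher exact disease-association test per variant
(carrier/recessive/genotypic tables; exact Freeman–Halton enumeration
for 2×3), perfect-separation screening, control-cohort allele
frequencies, simple-matching similarity clustering of subjects, and a
synthetic-cohort generator with planted modifiers for validation.
See `docs/methods.md` for assumptions and design choices.

## Worked example

The tables of the motivating study ship as packaged fixtures:

```python
import cordmod as cm

genotypes = cm.load_fixture("table2")          # 34 variants x 8 members
candidates = genotypes.select_role("modifier-candidate")  # 32 in 10 genes
symptoms = cm.load_fixture("table1")           # 11 symptoms x 4 patients
pedigree = cm.load_fixture("pedigree")         # 4 affected, 3 healthy, 1 uncertain

encoded = cm.encode_matrix(candidates, cm.InheritanceModel.ADDITIVE)
result = cm.score_matrix(encoded, symptoms, pedigree=pedigree)
print(result.median, round(result.sd, 3))
for key, sc in result.scores.sort_values(ascending=False).head(5).items():
    print(key, sc, result.bands[key])
```

prints

```
2.0 3.716
CACNG8:c.*6819A>T 16 two_sd
PAX2:c.-375C>A 9 one_sd
ABCA4:c.6730-3T>C 8 one_sd
CACNG8:c.*6802G>A 8 one_sd
CCDC175:c.-79C>G 6 one_sd
```

i.e. the CACNG8 3'UTR variant scores 16 — more than two standard
deviations (σ = 3.72) above the median score of 2 — and is the single
`two_sd` outlier; eight further variants land between one and two SDs,
giving nine surviving variants across six genes. The disease
association of the top variant:

```python
t = cm.contingency_table(genotypes, pedigree, "CACNG8:c.*6819A>T")
print(t.counts.tolist(), cm.fisher_exact(t))   # [[4, 0], [0, 3]] 0.02857...
```

Every affected member is a carrier and no healthy member is; the exact
two-sided p is 1/35 ≈ 0.029, the smallest value attainable with these
margins.

The same pipeline runs from the shell:

```
cordmod fixtures --outdir inputs
cordmod report --genotypes inputs/table2.tsv --symptoms inputs/table1.tsv \
    --pedigree inputs/pedigree.ped --outdir out
```

which writes encoded matrices (all three models), difference/weight/
score tables with bands, the association table, similarity matrices and
clusters on both bases, and a JSON summary naming every configuration
choice. `cordmod simulate --seed 7 --outdir sim` generates a synthetic
cohort (PED/TSV/VCF plus a planted-truth JSON) with the same dialects
the readers consume.

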