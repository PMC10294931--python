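# aquarisk

Quantitative risk assessment of aquatic animal introduction, built on the
analytic hierarchy process (AHP).

Importing a non-native aquatic animal — for aquaculture, the ornamental
trade, or research — carries two coupled risks: the ecological risk of the
species itself (invasiveness, impact on native fauna and habitats) and the
epidemiological risk of the pathogens it may carry (entry, exposure and
consequence of disease introduction). `aquarisk` implements a fully
quantitative scoring model for this decision, aimed at risk analysts,
fisheries and biosecurity agencies, and researchers comparing candidate
introductions.

## The model

Risk is organised as a three-layer weighted criterion tree beneath a single
total value *R*:

- 4 **primary indices** *R1–R4*: hazard of the introduced species, entry
  assessment, exposure assessment, consequence assessment;
- 12 **secondary indices** *P1–P12* beneath them;
- 60 **tertiary indices** *p11…p126*, each scored by experts on an integer
  scale 0 (negligible) … 5 (extremely high risk) against a published rubric.

All relationships are cumulative, so every aggregate is a weighted sum of
its children:

```
P_k = Σ_j w_kj · p_kj        R_i = Σ_k w_ik · P_k        R = Σ_i w_i · R_i
```

with each sibling weight group summing to 1 — *R* therefore stays on the
same 0–5 scale as the raw scores. The bundled default model ships the full
published coefficient set, e.g. `R = 0.3873·R1 + 0.1397·R2 + 0.2748·R3 +
0.1982·R4`.

Weights come from AHP: for each sibling group, experts fill a pairwise
comparison matrix `a[i][j]` (Saaty 1–9 scale, reciprocal), the weight vector
is the principal eigenvector of the matrix, and judgement coherence is
checked with

```
CI = (λmax − n)/(n − 1),    CR = CI/RI(n),    accept when CR < 0.1.
```

The total value maps to five grades, each with a policy recommendation:
negligible (0, 1], low (1, 2], medium (2, 3], high (3, 4], extremely high
(4, 5].

## Worked example

The package embeds a five-species case study (armored catfish
*Pterygoplichthys pardalis*, giant river prawn *Macrobrachium rosenbergii*,
Pacific oyster *Crassostrea gigas*, red-eared slider *Trachemys scripta
elegans*, axolotl *Ambystoma mexicanum*) with all 300 tertiary scores:

```python
from aquarisk import assess, builtin_case_study, default_hierarchy

case = builtin_case_study()
result = assess(case.score_sheet, default_hierarchy())
for s in result.ranking:
    print(f"{s}: R = {result.total(s):.4f} -> {result.grades[s]}")
```

prints

```
Pterygoplichthys pardalis: R = 3.6971 -> high
Macrobrachium rosenbergii: R = 2.9622 -> medium
Crassostrea gigas: R = 2.7073 -> medium
Trachemys scripta elegans: R = 2.5947 -> medium
Ambystoma mexicanum: R = 1.9742 -> low
```

i.e. the armored catfish is the only high-risk introduction (introduction
not recommended), the prawn, oyster and slider are medium (limited
introduction under strict management), and the axolotl is low risk.

The same pipeline is available from the shell:

```bash
aquarisk demo --out demo/               # write the case study + its report
aquarisk assess --scores demo/scores.tsv --out report/
aquarisk weights --matrix my_matrix.csv # AHP weights + consistency report
aquarisk check-consistency --matrix my_matrix.csv
```

Score sheets are plain CSV/TSV tables (rows = tertiary index ids, columns =
subjects); custom models are YAML documents bundling the hierarchy, weights,
rubric and grade thresholds — see `src/aquarisk/data/default_model.yaml`.

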