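# needlestoich

Within-branch C:N:P stoichiometry and nutrient-reallocation analysis for
conifer needles and layered soils.

## The problem

In nutrient-poor sandy-land plantations, pine trees often show a striking
within-branch pattern: basal needles turn chlorotic while apical needles on
the same branch stay green. Whether that chlorosis is passive soil
starvation or an active survival strategy — the tree withdrawing nitrogen
and phosphorus from old needles to protect apical growth — can be read off
elemental stoichiometry alone. This package implements that analysis for
ecophysiologists working with the standard design: per tree, one composite
needle sample per branch position (apical/basal) and one composite soil
sample per 20 cm depth layer down to 1 m, with total C, N and P in mg/g
dry mass.

## What it computes

For each sample the mass ratios C:N, C:P and N:P, and on top of them five
indices:

- **Homeostatic Index** — HI = 1/CV = x̄/SD of a ratio within a group;
  high HI means tight stoichiometric regulation.
- **Nutrient Stress Index** — NSI = Z(C:N) + Z(C:P), z-scores taken across
  all needle samples of the run; more positive = more jointly N- and
  P-depleted tissue.
- **Nutrient Resorption Efficiency** — NRE = (C_apical − C_basal)/C_apical
  × 100 % per tree and nutrient; the fraction withdrawn from basal tissue.
- **Resorption Priority Index** — RPI = NRE_N / NRE_P; above 1 nitrogen is
  withdrawn preferentially, below 1 phosphorus, near 1 both together.
- **Stoichiometric Deviation Index** — SDI = |needle ratio − soil
  ratio| / soil ratio against the same tree's soil at each depth layer;
  large SDI = needle chemistry decoupled from the soil.

The inferential chain mirrors field practice: Levene's test gates between
classical one-way ANOVA + Tukey HSD and Welch's ANOVA + Games–Howell,
pairwise significance is condensed into compact letter displays, RPI and
NRE are compared between conditions with Welch's t, needle–soil coupling
is screened with a Pearson grid (4 groups × 5 layers × 3 ratios), and a
PCA of the standardized ratios summarizes group separation. A synthetic
generator reproduces the study design with known ground truth, including a
mechanistic mode that moves a known fraction of the basal N/P pool apically
so resorption estimates can be validated in closed form.

## Worked example

```bash
python examples/01_resorption_indices.py
```

```
group  C:N     C:P     N:P
AH     20.45   53.95   2.64
BH     37.64  112.05   2.98
AC     18.68   58.41   3.13
BC     65.61  295.25   4.50

healthy    NRE_N = 41.55%   NRE_P = 48.19%   RPI = 0.862 (coupled/P-leaning)
chlorotic  NRE_N = 70.85%   NRE_P = 79.75%   RPI = 0.888 (coupled/P-leaning)
```

The basal chlorotic group (BC) shows C:N and C:P far above every other
group — carbon left behind as N and P were withdrawn. Chlorotic trees
resorb 70–80 % of both nutrients versus ~40–50 % in healthy trees, and RPI
near 1 says N and P move together: the signature of active reallocation
rather than passive starvation. The other examples generate a full
synthetic study and run the pipeline (`02`), validate parameter recovery
against the mechanistic ground truth (`03`), and demo the gated comparison
with letters (`04`).

From Python, the high-level surface is:

```python
from needlestoich import GeneratorConfig, generate_study, analyze

report = analyze(generate_study(GeneratorConfig(seed=42)))
report.resorption_condition_means
# {'healthy': {'nre_n': 51.6, 'nre_p': 51.4, 'rpi': 1.09},
#  'chlorotic': {'nre_n': 70.9, 'nre_p': 80.2, 'rpi': 0.88}}
```

A thin CLI wraps the same pipeline: `needlestoich generate`,
`needlestoich analyze`, `needlestoich benchmark` (the last compares a
mapped external deposit against the published reference values).

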