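# hisbench

Benchmark-anchored AHP–TOPSIS scoring of a city's health sustainability.

Most multi-criteria sustainability assessments rank a city against *other
cities*, which says little when the comparison set shares the same problems.
`hisbench` instead scores a single city against **published health indicator
standards (HIS)** — WHO world averages, UN targets, ministry policy
thresholds — organised in a hierarchy of dimensions (health, environment,
social, economic) → elements (e.g. *Health Status*) → indicators (e.g. life
expectancy, per-100,000 mortality rates). It is aimed at public-health
analysts and city policymakers who need to know *which* elements fall short
of standard, not who their neighbours are.

## Method

**Weights — Analytic Hierarchy Process.** For each indicator group an expert
pairwise comparison matrix $A = (a_{ij})$ on Saaty's 1–9 scale is
column-normalized and row-averaged to a priority vector $w$. The judgments
are gated by the consistency ratio

$$\lambda_{\max} = \tfrac1n\sum_i \frac{(Aw)_i}{w_i},\qquad
C.I. = \frac{\lambda_{\max}-n}{n-1},\qquad
C.R. = \frac{C.I.}{R.I.(n)} < 0.1,$$

with $R.I.$ a size-dependent random consistency index. A group failing the
gate aborts the run: inconsistent judgments produce meaningless weights.

**Scores — TOPSIS with standards as the ideal rows.** Each indicator $j$
contributes a three-row column $x = (\text{city},\ PI_j,\ NI_j)$: the city's
value plus the positive and negative ideal from the published standard.
After vector normalization $r = x/\lVert x\rVert_2$ and weighting
$v = w_j r$, the orientation-aware best and worst of the three entries
become $v_j^+$ and $v_j^-$ (so a city that beats its standard defines its
own ideal). Squared deviations of the city row pool over an element's (or a
dimension's) members:

$$S^+ = \sqrt{\textstyle\sum_j (v_{j,\text{city}}-v_j^+)^2},\qquad
S^- = \sqrt{\textstyle\sum_j (v_{j,\text{city}}-v_j^-)^2},\qquad
c^* = \frac{S^-}{S^+ + S^-} \in [0,1].$$

$c^* = 1$ means the city sits on every positive ideal, $0$ on every
negative one. Elements are ranked within their dimension and dimensions
against each other. A three-level strategy classifier then maps each
indicator to *growth-maintaining* (at/above standard), *monitoring*
(between the standards) or *improvement* (below standard), and an IOC
(index of item-objective congruence) helper screens candidate indicators by
expert panel votes in $\{-1, 0, +1\}$.

## Worked example

The package bundles a complete fixture: a 45-indicator / 15-element /
4-dimension framework with its HIS ideals, nine consensus expert judgment
matrices, and the 2019 observation for Khon Kaen province, Thailand.
`--weight-decimals 2` carries two-decimal weights into the scoring stage,
matching how the benchmark weight table is published.

```sh
hisbench evaluate --fixture khon_kaen_2019 --weight-decimals 2 \
    --out report.json --tables tables/
```

prints

```
dimension closeness: ECDm=0.57(rank 1)  SODm=0.55(rank 2)  HEDm=0.51(rank 3)  ENDm=0.28(rank 4)
```

— the economic dimension is closest to standard, the environment dimension
(c\* = 0.28) furthest from it, so environmental elements are where
improvement effort should go first. `tables/closeness.csv` breaks this down
per element; for the environment dimension:

```
ENDm,ERM,VR23,0.04,0.03,0.42,1
ENDm,APM,VR24,0.13,0.04,0.23,4
ENDm,PNA,VR25,0.33,0.13,0.28,3
ENDm,WM,VR26,0.07,0.04,0.34,2
ENDm,-,VR23-VR26,0.37,0.14,0.28,4
```

Air-pollution management (APM, c\* = 0.23) is the weakest environmental
element. The same library surface is available in Python:

```python
import hisbench as hb

fw, obs, pcms, overrides = hb.bundled_fixture("khon_kaen_2019")
weights = hb.weights_for_framework(fw, pcms, decimals=2)
result = hb.evaluate_city(fw, obs, weights)
result.dimension("ENDm").closeness   # 0.2818...
```

Synthetic inputs for experimentation come from `hisbench synth` (or
`hisbench.generate_framework` / `generate_pcm` / `generate_city`), which
produce seeded random frameworks, near-consistent Saaty matrices and city
observations positioned anywhere between the negative and positive ideals.

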