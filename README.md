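# viosna

Diagnosis co-occurrence network analysis for recognizing gender-based
violence in emergency-department (ED) visit histories.

## The problem

Most women victims of violence never contact support services, but many do
reach an ED — often repeatedly, and often with diagnoses that are only
indirectly related to abuse (substance use, pregnancy complications,
genitourinary disease, ill-defined symptoms). `viosna` implements a
network-based screening pipeline for administrative ED data: given the visit
histories of women who sought at least one ED visit for aggression, it asks
which *patterns* of diagnoses and traumas travel together with the nine
explicit violence diagnosis codes (ICD9-CM 995.80–995.85, V15.41, V15.42,
V61.11), and turns those patterns into a bedside risk chart.

The intended users are epidemiologists and health-services researchers
working with ED registry extracts, and anyone who wants a tested, seeded
re-implementation of this class of co-occurrence-network + risk-score
analysis.

## The method

Each woman's **ED history** is the set of diagnoses and traumas recorded in
the 3 years up to and including her latest aggression visit, collapsed to 29
binary indicators: 9 violence codes, 13 diagnostic groups, other-diagnoses,
missing-diagnosis (left the ED before being examined) and 5 trauma groups
(repeated aggression + unintentional trauma by place). A woman is **WVV**
(victim of violence) if any violence code appears in her history.

1. **Co-occurrence network.** `X` is the symmetric 29×29 matrix with
   `x_ij` = number of women whose history contains both categories *i* and
   *j*. Iterative proportional fitting (IPF) rescales `X` so every node has
   marginal frequency 1 (`X* = D X D`, diagonal scaling, which preserves
   symmetry and all cross-product ratios), removing the dominance of common
   diagnoses. Edges are the pairs whose normalized joint frequency (NJF)
   strictly exceeds the 95th percentile of the 406 off-diagonal values, and
   only edges confirmed in **all** of 10 equal-size WVV-stratified subsets
   are kept.
2. **Graph analysis.** Three community algorithms (exact optimal modularity,
   edge betweenness, fast greedy) are run and the partition with the highest
   Newman–Girvan modularity `Q = Σ_c (e_c/m − (d_c/2m)²)` is selected;
   degree, closeness and betweenness describe each node's role.
3. **Validation.** A 75/25 proportional WVV-stratified split, a multivariate
   logistic model of WVV membership on the 12 key diagnosis/trauma
   indicators plus age group, residence and nationality, and a stratified
   10-fold cross-validated AUROC.
4. **Risk chart.** For a profile (community pattern × age × nationality) the
   risk score is the sum of the active coefficients and the risk percentage
   is `100·e^s/(1+e^s)`; the chart is color-banded by the quartiles of its
   own percentage distribution.

Because the source registry is not public, the package ships a seeded
synthetic-cohort generator (`viosna.synthetic`) that emulates the study
population — 124,691 women, 0.47 % WVV prevalence, four planted
co-occurrence communities each anchored to a violence code, and a logistic
link between the key categories and violence status — so every stage is
testable end to end.

## Worked example

```python
from viosna import synthetic as syn
from viosna.network import CooccurrenceNetwork
from viosna.graph_analysis import CommunityDetector
from viosna.model import stratified_split, fit_logistic, cross_validated_auroc

cfg = syn.planted_recovery_config(n_women=20_000)   # strong-signal cohort
hist = syn.generate_histories(cfg, seed=17)

net = CooccurrenceNetwork(percentile=95, k=10, seed=17).fit(hist)
det = CommunityDetector().fit(net.network_)
dev, val = stratified_split(hist, 0.75, seed=17)
cv = cross_validated_auroc(dev, k=10, seed=17)
```

prints (via the obvious `print` calls):

```
women: 20000  WVV: 1013
robust edges: 12  density: 0.0296
algorithm: optimal  Q = 0.737
  community: ['adult_emotional_abuse', 'alcohol_substance_abuse', 'circulatory', 'infectious']
  community: ['adult_sexual_abuse', 'digestive', 'pregnancy_related']
  community: ['adult_neglect', 'respiratory', 'symptoms_ill_defined', 'trauma_other']
  community: ['genitourinary', 'partner_abuse_counseling', 'psychoses', 'trauma_road']
CV AUROC: 0.965 (0.960; 0.969)
```

Each detected community is one planted violence pattern: a violence code
plus the categories whose occurrence the generator elevated for that latent
profile. The robust network keeps 12 of 406 possible edges (density 0.030),
exactly the within-pattern associations; the exact modularity optimum
(Q = 0.74) separates the four patterns; and the cross-validated AUROC shows
the logistic model recovering the planted signal. On the default
(realistic, weak-signal) configuration the same pipeline yields a CV AUROC
around 0.70 and odds ratios scattered around their generating values.

The same stages are available from the shell:

```bash
viosna simulate --seed 17 --out sim/
viosna cohort  --visits sim/visits.csv --out histories.csv
viosna network --histories histories.csv --k 10 --seed 17 --out net/
viosna graph   --network net/ --out analysis/
viosna model   --histories histories.csv --folds 10 --seed 17 --out model/
viosna chart   --model model/ --partition analysis/ --out chart/
```

## Documentation

`docs/methods.md` describes the model, the generator, every tunable
parameter, the numerical choices (symmetric IPF variant, percentile
definition, deficient-row handling, tie-breaks) and the known limitations.
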