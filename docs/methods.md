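# Methods

This note documents the models and procedures implemented in `viosna`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## 1. Cohort and history reconstruction (`viosna.cohort`)

**Unit of analysis.** The woman, not the visit. The cohort is every woman
with ≥ 1 ED visit for aggression at age 15–70; her *history* is the closed
window `[index − lookback, index]` around the **latest** aggression visit
(the index visit contributes its own diagnoses). `lookback_years` defaults
to 3. A visit dated exactly `lookback` calendar years before the index is
inside the window; one day earlier is outside.

**Categories.** 29 indicators: 9 violence diagnosis codes matched exactly
(995.80–995.85, V15.41, V15.42, V61.11); 13 diagnostic groups assigned by
ICD9-CM numeric ranges from a versioned config file
(`viosna/data/icd9_groups.yaml`) — the alcohol/substance ranges (291–292,
303–305) take precedence inside the psychoses chapter, and a configurable
head/face code list takes precedence over the traumatic/musculoskeletal
ranges ("head and face involved independently of the traumatic origin");
`other_diagnoses` is the fallback for any unmatched code;
`missing_diagnosis` marks visits where the woman left before being examined
(such visits contribute no codes); 5 trauma groups are repeated aggression
(≥ 2 aggression visits in the window; a config switch widens the scope to
the whole record) and unintentional trauma by place (work/school, road,
home, other), taken from non-aggression visits only. The shipped range
table is a defensible default, not a canonical standard; users holding an
authoritative grouping should substitute their own file.

**Summary table.** Percentages are `100·count/N` with N the column total
(women or visits in the WVV / non-WVV group — not the block sum, because a
block may omit a missing-data stratum), rounded to 2 decimals half away
from zero. Zero denominators report 0 with a flag.

## 2. Co-occurrence network (`viosna.network`)

**Counting.** `x_ij` counts *women* whose history contains both categories
(presence/presence). Once-per-woman counting treats the history as the unit
of relational information; a per-visit-pair variant would over-weight
frequent attenders.  The diagonal is zero: self-pairs carry no relational
information and the graph has no self-loops.

**IPF normalization.** All nodes are constrained to marginal frequency 1,
so rare-but-specific associations (a violence code with its pattern) are
not drowned out by frequent diagnoses. The implementation is the symmetric
variant: per iteration `X ← diag(s) X diag(s)` with
`s_i = sqrt(target/rowsum_i)` — the geometric mean of the row and column
factors — which keeps the matrix exactly symmetric at every step and has
the same limit as classic alternating row/column scaling on symmetric
input (asserted against a brute-force alternating-scaling oracle to 1e-8
in the tests). Diagonal scalings preserve every cross-product ratio, i.e.
the "relationships between nodes". Convergence: max |marginal − 1| < 1e-10,
cap 10,000 iterations.

Two kinds of rows are excluded from the constraint and reported:
*structurally zero* rows (a category never co-occurring) and *deficient*
rows, whose zero pattern admits no unit-marginal limit. The canonical
deficient case — common in small stratified subsets — is a rare violence
code that co-occurred with exactly one partner: forcing its marginal to 1
would force the partner's entire remaining row to 0, and the scaling
iteration stalls sublinearly instead of converging. Such rows are released
from the constraint (detected a priori for single-partner rows, and by a
stall monitor — deviation not halving per 1000 iterations — for deeper
deficiencies) and keep their partner-scaled values. This is the analogue,
for marginal constraints, of retaining isolated nodes.

**Threshold.** The NJF distribution is the multiset of the 406 off-diagonal
upper-triangle entries; edges are the pairs **strictly above** its 95th
percentile, computed with linear interpolation between order statistics
(the definition is recorded in the network provenance since several
percentile conventions exist). Strict inequality means an all-equal matrix
yields no edges (warned).

**Robustness.** Women are split into k = 10 equal-size subsets stratified
on WVV status; the full pipeline runs per subset; the robust network keeps
the pairs that pass the threshold in **all** k subsets, weighted by the
full-data NJF. An m-of-k relaxation is deliberately *not* the default: the
all-k intersection is the conservative reading of "confirmed within the
ten subsets". Note the robust edge set is not necessarily a subset of the
full-data threshold set. At the default weak-signal configuration
(0.47 % prevalence) the all-10 intersection at n ≈ 10⁵ is typically empty —
with ~58 WVV women per subset the violence-code rows are too noisy for any
pair to win ten times — which is itself informative: the robustness filter
is honest about what that sample size supports. The strong-signal regime
(below) is where the filter isolates exactly the planted structure.

## 3. Communities and centralities (`viosna.graph_analysis`)

Three algorithms run on the thresholded robust graph: exact modularity
maximization (integer programming, feasible at 29 nodes; guarded by a
30-node ceiling and skipped with a warning above it), edge-betweenness
(divisive) and fast-greedy (agglomerative). Modularity is the standard
Newman–Girvan `Q = Σ_c (e_c/m − (d_c/2m)²)`, weighted by the NJF edge
weights by default (an unweighted switch exists). All three candidates are
re-scored with this same weighted Q — for the divisive/agglomerative
dendrograms every cut level is scored and the best kept — so the selection
criterion is identical across algorithms; ties go to fewer communities,
then to the algorithm order optimal → edge-betweenness → fast-greedy.
For edge-betweenness the NJF weights (affinities) are inverted to act as
distances in the path computations. Isolated nodes are appended as
singleton communities.

Centralities are computed on the thresholded robust network — printed
closeness values in the 0.3–0.5 range are implausible on a near-complete
graph — and unweighted by default: degree is the incident-edge count,
closeness is component-normalized `(n_reachable − 1)/Σd` (isolated nodes:
0, flagged), betweenness is the unnormalized pair-summed intermediation
fraction. Weighted mode uses distance = 1/weight for the path measures.

## 4. Logistic validation (`viosna.model`)

**Split.** Validation size is `⌊(1−f)·N⌋` overall, apportioned to the WVV
strata by largest remainder; at f = 0.75 on 124,691 women with 580 WVV this
gives exactly 93,519 development / 31,172 validation (145 WVV held out).

**Model.** WVV status on the 12 key indicators (infectious, symptoms,
other-diagnoses, psychoses, alcohol/substance, circulatory,
pregnancy-related, genitourinary, respiratory, road-traffic accident, other
accident, repeated aggression) plus age group (reference 15–24), residence
(reference outside Rome) and nationality (reference foreign). Maximum
likelihood via Newton iterations; Wald 95 % intervals (standard
epidemiological reporting; profile likelihood would differ only in tiny
strata); odds ratios by exponentiation. Separation or non-convergence
raises an error naming the most extreme term — expect this below roughly
50 events with the full 17-term model. A nationality-missing level is added
automatically when present; the synthetic generator emits no missingness by
default.

**Cross-validated AUROC.** Stratified 10-fold on the development set; each
fold scored by a model fitted on the rest; AUROC is the Mann–Whitney
probability (ties half). The interval `mean ± 1.96·SE(folds)` is a
reporting convention, not an exact coverage statement. The fitted model is
reported on the development set and evaluated on the validation set; both
are emitted.

## 5. Risk chart (`viosna.risk_chart`)

Score = intercept + Σ active coefficients; percentage = `100·e^s/(1+e^s)`
(round trip `logit(p/100) = s` to 1e-12). A community activates exactly its
member categories that are model predictors; the community → predictor
mapping is emitted as an editable artifact. Residence is fixed at a
configurable reference (default inside Rome) since the chart varies
community, age and nationality. Bands are the quartiles of the grid's own
percentages, green → red; a degenerate (all-equal) grid falls entirely in
the lowest band. With the published sign pattern (age ORs < 1, Italian
OR < 1) risk decreases across age bands and foreign cells dominate Italian
cells in every row — properties the tests assert for any coefficient set
with that sign pattern.

## 6. Synthetic cohort generator (`viosna.synthetic`)

**What it emulates.** The study cohort: 124,691 women aged 15–70 with ≥ 1
aggression visit; 0.47 % WVV prevalence; four age bands with probabilities
(0.147, 0.257, 0.477, 0.119); 30.9 % foreign; 51.9 % resident in the Rome
metropolitan area; mean 3.21 visits per woman over the 3-year look-back
(the 400,369 visits / 124,691 women ratio), overdispersed as 1 + negative
binomial (dispersion 1.0); per-extra-visit aggression probability 0.076,
giving ~16 % repeated aggression; per-visit category probabilities ordered
like the reported visit mix (ill-defined symptoms and
traumatic/musculoskeletal most frequent at 0.25, psychoses and substance
abuse rarest at 0.01, unintentional trauma mostly in an "other" place).
Four latent community profiles, each a set of categories with elevated
per-visit probability anchored to one violence code (psychological abuse →
alcohol/circulatory/infectious; partner abuse → psychoses/genitourinary/
road accident + a raised repeat-aggression probability; maltreatment →
respiratory/symptoms/other trauma; sexual abuse → pregnancy-related),
together covering 20 % of women by default.

**Generative model.** The canonical unit is the per-woman indicator vector:
given profile and visit count `v`, each emittable category is present with
probability `1 − (1 − p_c)^v` (independent across categories given profile
and `v`); repeated aggression is `1 − (1 − a)^(v−1)`. Violence status is
logistic: `logit P(WVV) = β₀ + Σ β·indicators + β·demographics`, with
default `β` the natural logs of the published odds ratios (config values,
not claims). The intercept is calibrated at run time by root-finding on a
fixed-seed Monte-Carlo sample of 200,000 linear predictors so the marginal
prevalence equals `baseline_prevalence` — the generator takes the marginal
prevalence as the primary quantity and treats the intercept as derived.
Flag ⇔ violence-code presence exactly: flagged women emit their profile's
code (uniform over the nine codes when profile-less); unflagged women never
emit one. `expected_cooccurrence` gives the closed-form expected joint-count
matrix (mixture over profiles and the visit-count distribution) for
non-violence pairs and a fixed-seed Monte-Carlo estimate for pairs
involving violence codes; it is the oracle for the generator tests.

**Visit materialization.** Visits realize the drawn indicators exactly:
diagnosis categories occur on a ≥ 1 truncated-binomial number of visits,
each trauma place occupies one dedicated non-aggression visit, the missing
category occupies one dedicated left-without-visit row with no codes, and
violence codes are emitted at the index aggression visit; extra visits are
appended when a woman's presences need more hosts than her drawn count.
Dates are uniform over the look-back window (no temporal model is implied
by the emulated design); 365-day years keep every offset inside the
calendar window wherever the leap days fall. The round trip
generate → write CSV → cohort builder reproduces the truth indicators
bit-exactly (tested).

**Strong-signal regime.** `planted_recovery_config()` defines the regime in
which downstream recovery is checked: equal per-visit baselines (0.02),
ten-fold elevation (well above the 5× floor), every woman in one of the
four profiles, 5 % prevalence, and generating coefficients concentrated on
profile categories so each violence code attaches firmly to its community.
The parameters were fixed from the closed-form co-occurrence separation
analysis. At 20,000 women the robust network contains almost exactly the
within-profile edges and modularity clustering recovers the four planted
profiles (partition equality up to labels on the planted nodes present in
the network) in ≥ 9/10 seeds.

**What the generator does not emulate — and what passing tests show.**
One representative ICD9 code per category (no within-group code-frequency
structure); no temporal disease progression or care pathways; no
nationality missingness (the real summary table has a large missing class);
category independence given profile and visit count (real comorbidity
correlates beyond the planted communities); exact flag ⇔ code equivalence
(real registries misclassify). Passing tests therefore demonstrate that the
pipeline's mathematics and bookkeeping are correct and that it recovers
structure *when the generating assumptions hold*; they do not validate the
screening tool on real ED data, where the published real-data network
statistics remain out of reach without the registry.

## 7. Problem sizes and determinism

All randomness flows through explicit integer seeds (numpy `default_rng`;
generator calibration uses its own fixed stream so the intercept does not
depend on the cohort seed). The test suite and the acceptance script use:
study-scale cohorts (124,691 women) for split arithmetic and parameter
recovery (100 replicates; Wald-interval coverage of every generating
coefficient asserted within [89 %, 99 %]); 20,000 women × 10 seeds for
planted recovery; 100 random positive matrices for the IPF oracle suite;
100 random 12-node graphs for the exhaustive shortest-path oracle suite.

## 8. Known limitations

* The ICD9 group ranges are a reconstruction; the authoritative grouping
  of the emulated study is not public. The mapping is a config file
  precisely so it can be replaced.
* The all-10 robustness intersection is conservative: at realistic
  prevalence it returns an empty network at desk-scale n (see §2); analyses
  at that scale should use the full-data threshold network (`k=1`) or the
  m-of-k relaxation, and interpret accordingly.
* Closeness is reported as 0 for isolated nodes (flagged) rather than
  undefined; betweenness is unnormalized by design, so its scale grows with
  the graph.
* Exact optimal modularity is exponential in the worst case; above 30 nodes
  only the two heuristics run.
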