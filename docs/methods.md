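# Methods

## The model

`glycopath` treats a glycosylation pathway as a directed graph whose nodes
are glycan structures (composition-level, SNFG-coded) and whose edges are
enzymatic reactions.  Each reaction carries a boolean *gene requirement*:
isoenzyme alternatives combine with OR, obligate complex subunits with AND,
arbitrarily nested (e.g. lactose synthase is `B4GALT1&LALBA`; class-I
mannosidase trimming is `MAN1A1|MAN1A2|MAN1C1`).  Reactions whose
catalyzing gene has not been identified carry no requirement and form a
distinct *unknown* class throughout the engine — they are never silently
treated as inactive.

Given a sample's TPM profile, a reaction's **score** is the aggregated
expression of its requirement tree: leaves evaluate to the gene's TPM
(genes missing from the upload count as 0 — absence of evidence is modelled
as no expression, the same as present-at-zero), OR nodes take the maximum
(the most capable isoenzyme carries the reaction) and AND nodes the minimum
(the scarcest subunit limits the complex).  Both rules can be switched to
mean/min/max per run.  Because every aggregation rule returns a value
between the smallest and largest leaf, scores are always sandwiched by the
leaf TPMs — a property the test suite checks against a brute-force
evaluator on random trees.

### Classification and rendering

Scores are classified against a TPM threshold, default **1 TPM** per
required gene:

| score                | class     | arrow                |
|----------------------|-----------|----------------------|
| ≥ threshold          | expressed | black, width scaling |
| floor < s < threshold| limited   | red                  |
| ≤ floor (0.1 TPM)    | absent    | pink                 |
| unknown gene         | unknown   | gray, dashed         |

The limited/absent split is not a published constant; the floor of 0.1 TPM
was chosen because sub-0.1 TPM signal is conventionally indistinguishable
from background in bulk RNA-seq.  Expressed arrow widths follow
`1 + 1.5·log10(score/threshold + 1)` capped at 8 px — the published maps
state only that thickness tracks expression, so any strictly increasing,
bounded map is admissible; the log keeps 1–10 000 TPM visually separable.

### Two-sample comparison

Comparison operates on reaction scores *after* aggregation, so an
isoenzyme switch (gene A down, gene B up) correctly reports no net change.
The fold is `(score_b + ε)/(score_a + ε)` with pseudocount ε = 0.1, which
avoids infinite folds on silent reactions while leaving the
double/half semantics intact at expressed levels (at 10 TPM the distortion
is < 1%).  A reaction is *increased* when fold > 2 (strictly), *decreased*
below 1/2, *undefined* when its gene is unknown or when both scores sit
below ε (no resolvable signal in either sample).  Swapping the samples
inverts every fold; the product of the two folds is 1 up to one ulp
(IEEE division is correctly rounded, but `x/y · y/x` is not guaranteed to
round to exactly 1, so tests assert reciprocity at 1e-12).

### Presence estimation

Presence is a three-state reachability call.  Edge ranks are
expressed = 2, limited = unknown = 1, absent = 0; each structure receives
the best (max over root-to-structure paths) bottleneck (min over path
edges) rank: 2 → *present*, 1 → *rare*, 0 → *absent*; roots are always
present.  Limited edges propagate "rare" rather than blocking, so a
pathway with one weak step reports its downstream products as scarce, not
impossible.  The implementation is a monotone fixpoint iteration (it
therefore also terminates on cyclic pathways); tests verify it against an
exhaustive simple-path enumeration on 200 random pathways of ≤ 12 nodes
and check the monotone-repair property (upgrading one reaction never
downgrades any call).

### Threshold calibration

`roc_curve` sweeps "predict present iff score ≥ t" over the midpoints
between consecutive distinct scores plus ∓∞ sentinels — exhaustive for all
step-function metrics and deterministic under ties.  The AUC is
accumulated from integer confusion counts, which makes it *exactly* the
Mann–Whitney concordance `(#(pos>neg) + ½·ties)/(n₊·n₋)`; tests assert
bitwise equality against a pairwise oracle and against
`sklearn.metrics.roc_auc_score`.  The operating point maximizes Youden's
J = sensitivity + specificity − 1 or the F1 score (harmonic mean of
precision and sensitivity); ties break toward the smaller threshold,
favoring sensitivity, which matches the permissive default of 1 TPM.
Precision at thresholds with no positive prediction is reported as 1.0 (no
false positives) with F1 = 0.

`calibrate_on_synthetic` is the end-to-end recovery harness: it draws
random profiles over the pathway's gene universe, labels each non-root
structure per sample by whether its continuous bottleneck score reaches
the generating threshold, flips each label independently with probability
`label_noise`, and returns the ROC of bottleneck scores against the noisy
labels.  With zero noise the recovered Youden threshold is the midpoint of
the empty score interval containing the generating value (one sweep step).
A note on flip noise: flipping a fraction p of perfectly separated labels
bounds the expected AUC by 1 − p (attained at balanced classes) — at
p = 0.4 the harness measures ≈ 0.58, far above chance but necessarily
close to 0.6.

### Absorbing Markov chain

For quantitative output profiles the scored pathway becomes an absorbing
Markov chain: a glycan at transient structure *i* moves along outgoing
reaction *j* with probability `s_ij / (Σ_j s_ij + exit_weight)` —
transition probabilities proportional to expression scores, the minimal
law that integrates the expression profile into the stochastic model.
Terminal structures absorb; structures whose outgoing reactions all score
zero are converted to absorbing with a warning (expression data silences
branches; product accumulates).  With `exit_weight > 0` the remainder of
each row flows to a synthetic absorbing state `exited@i` modelling
premature secretion/transport; with `exit_weight = 0` the chain is
invariant under global rescaling of the TPM vector.  Unknown-requirement
reactions carry no flux.

Absorption probabilities and expected visit counts come from the
fundamental matrix N = (I − Q)⁻¹ via linear solves of (I − Q)ᵀy = e_src
(never explicit inversion); a condition number above 1e10 logs a warning,
and transient components with no route to absorption are detected by
reachability and reported by name instead of surfacing as a singular
solve.  Construction renormalizes each row, keeping [Q | R] row-stochastic
to 1e-12; absorption masses sum to 1 within 1e-9.  Tests compare exact
distributions against a seeded 10⁵-walk Monte-Carlo simulation within 3
binomial standard errors per state on 20 random models.

`knockdown_scan` rescales one gene's TPM by factors in [0, 1], rebuilds
the chain and reports the profile series — factor 1 reproduces the
baseline exactly, and on the toy N-glycan map the bisecting-product mass
is non-increasing in MGAT3 knockdown strength.

## Packaged pathways

* **`n_glycan_toy`** — 21 structures / 20 reactions of N-glycan
  processing: glucose trimming (including the glucosidase-II complex
  `GANAB&PRKCSH`), mannose trimming, GlcNAc branching with the bisecting
  step ("Step 15", `MGAT3`), core fucosylation, galactosylation,
  sialylation.  Covers branch, merge, AND-complex and OR-isoenzyme
  features.
* **`hmo`** — human milk oligosaccharide biosynthesis with 39 core
  structures, 6 terminal modifications and 30 distinct genes.  The
  published map prints only these counts, not the wiring; this fixture is
  *reconstructed* from standard HMO biosynthesis knowledge (lactose
  synthase complex, type-1/type-2 chain elongation, α1-2/3/4
  fucosylation, α2-3/6 sialylation, β1-6 branching) and is flagged as such
  in its description.  Two reactions (fucosyl-DSLNT, the uncharacterized
  cap) have no identified enzyme and carry the unknown marker.
* **`queuosine_trna`** — 5-reaction stub: the tRNA-guanine
  transglycosylase complex `QTRT1&QTRT2`, queuosine galactosylation
  (`QTGAL`) and mannosylation (`QTMAN`), plus a salvage branch with one
  unknown step.

Fixtures without explicit layout get a deterministic longest-path layering
(BFS depth under cycles) with alphabetical stacking inside each layer —
determinism matters more than aesthetics for diffable output.

## Synthetic data

`generate_synthetic_pathway(n, branching, seed)` emits a single-root
acyclic pathway in which every non-root structure has one guaranteed
incoming reaction from an earlier structure plus
`round((branching−1)(n−1))` extra edges, random OR/AND requirement trees
over a synthetic gene universe, and terminal flags on sinks.
`generate_synthetic_expression` marks each gene active with probability
0.8 and draws active TPMs from log-normal(μ = 2, σ = 1) (median ≈ 7.4 TPM,
a typical level for robustly expressed enzymes) and inactive genes
uniformly from [0, 0.1].  These generators emulate the *topology* and
*marginal expression levels* of curated maps and bulk RNA-seq, not
gene–gene correlation, isoform structure, compartmentalization or
measurement error models — so passing tests demonstrate algorithmic
correctness under realistic scales, not biological fidelity of any
specific tissue.

## Numerical and design choices

* All iteration orders are sorted and all randomness flows through a
  single seed, so every artifact (JSON, TSV, SVG) is byte-reproducible.
* Requirement trees are kept in canonical flattened form (no OR directly
  under OR, no AND under AND), which makes serialize → parse the identity;
  a 1000-example property test covers this.
* Duplicate gene rows in expression tables collapse to the per-sample
  maximum (consistent with the max-isoenzyme default); the collapse is
  logged, not fatal.
* Problem sizes in the test and acceptance runs — 200 random ≤ 12-node
  pathways for the path-enumeration oracle, 100 ROC instances, 20 Markov
  models at 10⁵ Monte-Carlo walks, 200-sample calibration runs — were
  chosen so the full suite completes in well under a minute while keeping
  every binomial check at ≥ 3σ resolution.

## Known limitations

* Glycans are modelled at composition level; linkage isomers sharing a
  composition are distinct nodes only if the pathway definition names them
  separately.  No GlycoCT/WURCS parsing.
* The Markov chain is single-compartment: Golgi sub-compartments,
  sugar-nucleotide availability and protein carriers are deliberately out
  of the model.
* Comparison is a fold-change highlight, not a differential-expression
  test; no replicate handling or statistics.
* Human HGNC-style symbols are assumed; there is no cross-species
  aliasing.
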