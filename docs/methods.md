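# Methods

## The model

`probjudge` implements a dual-process account of how people attach
probabilities to unique events and their conjunctions.

**Intuitive system.** Evidence for an event is held as a small *mental
model*: a set of individuals, each with or without the relevant property,
whose proportion encodes a quantifier.  "Most incumbent US Presidents are
re-elected" is represented canonically as 4 individuals of whom 3 are
re-elected.  Sampling a model yields a *belief icon* — an analog magnitude in
[0, 1], conceptually the length of a line between impossibility and
certainty.  The intuitive system has no working memory; it can hold one icon
and apply only primitive operations to a pair of them:

- *split the difference*: move to the (weighted) midpoint,
  (1−w)·a + w·b, with optional Gaussian jitter for "roughly" halving;
- *primitive multiplication*: quantize one icon to g equal steps
  (round to the nearest multiple of 1/g) and take that proportion of the
  other.  g is capped at 16 by default — the system can repeat an operation
  only a small finite number of times — and the quantization error is
  bounded by b/(2g), so the operation converges to the exact product as g
  grows.

**Deliberative system.** A separate system with working memory maps icons
onto response scales: onto 0–100 integers with additive Gaussian conversion
error (sd `noise_sd`, proportion units), or onto a 7-point verbal scale
(*Impossible* … *Certain*) by nearest anchor.  It can also multiply exactly;
`SimParams(granularity=None)` selects this exact product for the
multiplicative mechanism.

**Conjunctions.** On each trial the model estimates P(A&B) by primitive/exact
multiplication with probability `w_mult` and by split-the-difference
otherwise (an independent Bernoulli choice per trial; the mechanism-selection
process itself is not modeled).  Split-the-difference typically places the
conjunction *above* min(P(A), P(B)), so the implied JPD acquires a negative
cell on almost every unequal pair — the signature incoherence the analysis
side detects.  Dependence between the conjuncts (P(B|A) ≠ P(B)) is not
modeled.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| `w_mult` | probability | 0.3 | multiplication-strategy trials were observed on roughly a quarter to a third of trials; not fitted |
| `noise_sd` | proportion | 0.05 | ≈5-point conversion error; the simplest jitter consistent with the coarse/fine-scale argument |
| `granularity` | steps | 7 | a small step count for the intuitive product; `None` = exact |
| `split_weight` | proportion | 0.5 | "splitting the distance roughly halves it" |
| quantifier bands | — | all=1, most/many∈(0.5,1), some∈(0,1), few∈(0,0.5), none=0 | symmetric bands consistent with the canonical 3-of-4 diagram; canonical points most→¾, few→¼ |
| verbal anchors | proportion | 0, 1/6, …, 1 | equally spaced; the scale's labels carry no published numeric anchors, so the mapping is configurable and ties resolve to the lower category |

## Coherence criteria

A triplet's JPD is derived by the additive identities; a *violation* is a
strictly negative cell (a zero cell is coherent), and at most two cells can
be negative (if both marginal-difference cells are negative, the fourth cell
exceeds zero).  Two criteria are exposed side by side:

- `full_jpd`: no negative cell, i.e. pConj ≤ min(pA,pB) **and**
  pConj ≥ pA+pB−100;
- `conjunction_bound`: only pConj ≤ min(pA,pB), ties coherent.

The printed coarse-vs-fine rates (about 40% on a 7-point scale, 33% on
0–100) are reproduced exactly by the *conjunction bound* — enumeration gives
140/343 ≈ 40.8% and the continuous closed form is 1/3 — whereas the full-JPD
criterion gives 84/343 ≈ 24.5% and ≈17% respectively.  The package defaults
to the criterion that reproduces the printed figures for the scale
simulation and reports both, leaving the discrepancy visible rather than
resolved.

## Competitor predictors

Both published competitor formula strings are typographically ambiguous.
The averaging model is read as (P(A)+P(B))/2.  The averaging-plus-product
model defaults to ((pA+pB)/2 + pA·pB/100)/2 — the face-value reading
pA + pB/2 + pA·pB/100 exceeds 100 for moderate inputs and cannot be a
probability, so it is retained only behind the `literal` flag for auditing.
Fits report R² as the squared Pearson correlation (matching regression-plane
usage) and RMSE on the proportion scale.  Kendall's W uses midranks with the
standard tie correction.  The two-mechanism *mixture* predictor,
w·(pA·pB/100) + (1−w)·(pA+pB)/2 with w taken from the strategy classifier,
is the conditional mean of the generative model and therefore attains the
highest population R² of any predictor that is a function of (pA, pB) alone.

## Synthetic data: what it emulates and what it does not

The raw participant data were never deposited, so the generators target the
two experiments' *structure*, not their empirical histograms:

- **Experiment-1 structure** (default 39 participants × 16 trials): every
  participant sees each of the 16 contents once (8 per dependence
  direction), with question order balanced 8/8 and randomized.  True
  conjunct probabilities are the published per-content mean estimates plus
  truncated-Gaussian jitter (default sd 10 points).  Participant
  heterogeneity — some individuals never split, others always do — is
  modeled by drawing each participant's `w_mult` from a Beta distribution
  with mean `params.w_mult` and concentration 5.
- **Experiment-2 structure** (default 18 participants × 16 trials): two
  blocks (verbal, numeric; order counterbalanced across participants), each
  crossing the four problem forms (plain and negated) with both dependence
  directions; each trial also records the fourth judgment, the conjunction
  of the negations.  Verbal responses are generated icon-first (the icon,
  jittered by the same conversion noise, is mapped straight to the nearest
  verbal anchor, never through a number) and are stored as both the label
  and its anchor-mapped percentage.

Passing tests on these data therefore show that the pipeline's *inferences*
(violation rates, strategy recovery, model ordering) are correct under the
stated generative assumptions; they cannot show that real respondents follow
those assumptions, and the generators make no attempt to reproduce order or
content effects on strategy choice.

## Numerical choices and degenerate inputs

- Integer inputs stay exact through the JPD identities (sums and differences
  of integers are exact in double precision); the discrete scale-consistency
  enumeration runs on integer indices to avoid floating-point ties at the
  boundary.
- Rounding to the 0–100 integer scale is itself a conversion error: even
  exact products can acquire a −1 cell after rounding (e.g. 99.6 and 99.6
  both round up while their product rounds down).  Algebraic zero-violation
  guarantees therefore hold on the continuous reporting scale
  (`integer_scale=False` in `run_batch`).
- Nearest-anchor verbal mapping resolves exact midpoints to the lower
  category; `icon_to_number` rounds half away from zero.
- Mental-model construction picks the admissible property count closest to
  the quantifier's canonical proportion; (quantifier, size) pairs with no
  representable proportion (e.g. "most" of 2) raise a degenerate-model
  error rather than silently widening the band.
- Strategy classification gives multiplication precedence when both rules
  match (possible only for small, nearly equal conjuncts); the 5-point
  split tolerance is a package convention chosen for symmetry with the
  published 5-point multiplication tolerance.
- Zero-variance series make the correlation-based R² undefined and raise
  rather than return NaN.

## Problem sizes

Simulated batches default to 2000 runs (the size used for the scatterplot
simulation) and recovery checks use 2000 trials; the fine-scale Monte Carlo
uses 10⁶ samples, giving a standard error below 0.0005.  The full test suite
runs in a few seconds.

## Known limitations

- No model of conjunct dependence, response latencies, or order effects on
  mechanism choice; the generators hold `w_mult` fixed within participant.
- The verbal-scale anchor mapping used when scoring verbal violations is a
  convention (equally spaced anchors); empirical anchor placements would
  change verbal violation rates.
- The pointer-shifting dynamics of splitting are represented only by their
  endpoint (the weighted midpoint), not as a process.
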