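# probjudge

Dual-process simulation and coherence auditing of subjective probability
judgments about unique events ("What is the chance that Obama is re-elected?")
and their conjunctions.

People readily put numbers on one-off possibilities, yet their estimates of a
conjunction P(A&B) often *split the difference* between P(A) and P(B) instead
of staying below both.  Even without an outright conjunction fallacy, a
triplet of judgments can be incoherent: by additivity the triplet fixes the
full joint probability distribution (JPD)

    P(A&B)   = pConj
    P(A&¬B)  = pA − pConj
    P(¬A&B)  = pB − pConj
    P(¬A&¬B) = 100 − pA − pB + pConj,

and any negative cell is a violation of the probability calculus (a Dutch
book can be made against it).  For example pA=70, pB=75, pConj=40 yields
P(¬A&¬B) = −5%.

`probjudge` implements a dual-process generative model of such judgments and
the analysis machinery around it:

- **icons** — the intuitive system: mental models of quantified evidence
  ("Most incumbent US Presidents are re-elected" → 3 of 4 model individuals),
  analog belief icons in [0,1], split-the-difference, a primitive quantized
  multiplication, and noisy deliberative mappings to the 0–100 scale and a
  7-point verbal scale (*Impossible* … *Certain*).
- **jpd** — JPD derivation from plain or negated problem forms, violation
  counting, and two coherence criteria (`full_jpd`, `conjunction_bound`).
- **strategies** — the hard classification rule: *multiplicative* when
  pConj ≤ min(pA,pB) and within 5 points of pA·pB/100, else *split* when
  within 5 points of the midpoint, else *other*.
- **simulator** — batch simulation of conjunction trials with a per-trial
  Bernoulli(w_mult) choice between the two mechanisms.
- **evaluation** — competitor conjunction predictors (the averaging model
  (pA+pB)/2; an averaging-plus-product model), R²/RMSE fits, Kendall's W
  concordance, and grouped violation summaries.
- **scale_mc** — enumeration/Monte Carlo of how often randomly assigned
  triplets cohere on coarse vs fine scales (≈40% on a 7-point scale vs ≈33%
  on 0–100 under the conjunction bound).
- **synthetic_data** — generators for datasets with the structure of the two
  behavioral experiments (39×16 numeric trials; 18×16 verbal/numeric trials
  with masked negated forms), seeded from the 16 published mean conjunct
  estimates, plus the trial-CSV reader/writer.

## Worked example

```python
from probjudge import EstimateTriplet, jpd_from_triplet, count_violations

jpd = jpd_from_triplet(EstimateTriplet(pA=70, pB=75, pConj=40))
print(jpd.cells())          # (40, 30, 35, -5.0)
print(count_violations(jpd))  # 1
```

The four cells sum to 100 but the fourth is −5: the judgments are incoherent
even though 40 ≤ min(70, 75).  Running
`python examples/simulate_and_classify.py` prints:

```
simulated 2000 trials with w_mult = 0.3
classifier rates: {'multiplicative': 0.304, 'split': 0.696, 'other': 0.0}
recovered w_mult = 0.304  (truth 0.3)
coherence violations: 68.6% of trials
pure-split regression pConj ~ pA + pB: coefficients (0.500, 0.500)
```

i.e. the strategy classifier recovers the generating mechanism mixture, and
pure split-the-difference data regress on the conjuncts with weights (½, ½).
The other scripts in `examples/` walk through the JPD worked example, the
coarse-vs-fine scale simulation, and full synthetic-experiment analyses.

A thin CLI mirrors the pipeline:

```sh
probjudge generate --experiment 1 --n 39 --seed 7 --out trials.csv
probjudge jpd --in trials.csv --criterion full_jpd --out jpd.csv
probjudge classify --in trials.csv --out labeled.csv
probjudge mc-scale --points 7,101 --out rates.json
```

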