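"""Derive the joint probability distribution implied by one triplet of judgments.

A respondent judges P(A) = 70, P(B) = 75 and P(A&B) = 40.  No conjunction
fallacy is committed (40 is below both conjuncts), yet additivity forces the
fourth cell P(notA & notB) to be negative — an incoherent set of estimates
that a Dutch book could exploit.  The same information can be elicited in a
masked, negated form and fixes the identical distribution.
"""

from probjudge import EstimateTriplet, count_violations, jpd_from_form, jpd_from_triplet

triplet = EstimateTriplet(pA=70, pB=75, pConj=40)
jpd = jpd_from_triplet(triplet)
print("P(A)=70, P(B)=75, P(A&B)=40 implies the JPD (percentage scale):")
print(f"  P(A&B)         = {jpd.cell_AB}")
print(f"  P(A & notB)    = {jpd.cell_AnotB}")
print(f"  P(notA & B)    = {jpd.cell_notAB}")
print(f"  P(notA & notB) = {jpd.cell_notAnotB}   <- negative: incoherent")
print(f"violations (negative cells): {count_violations(jpd)}")

masked = EstimateTriplet(pA=30, pB=75, pConj=35, form="notA_B")
print("\nSame beliefs elicited as P(notA)=30, P(B)=75, P(notA&B)=35:")
print(f"  cells = {jpd_from_form(masked).cells()}  (identical JPD)")
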