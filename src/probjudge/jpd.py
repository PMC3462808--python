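"""Joint probability distributions implied by estimate triplets, and their violations.

A triplet of judgments P(A), P(B), P(A&B) fixes all four cells of the joint
probability distribution (JPD) over two events by additivity:

    P(A&B)   = pConj
    P(A&¬B)  = pA − pConj
    P(¬A&B)  = pB − pConj
    P(¬A&¬B) = 100 − pA − pB + pConj     (percentage scale)

Coherent judgments leave every cell nonnegative; a negative cell is a
*violation* of the probability calculus (e.g. pA=70, pB=75, pConj=40 implies
P(¬A&¬B) = −5).  Negated problem forms such as (P(¬A), P(B), P(¬A&B)) fix the
same JPD after complement relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import FormMismatchError, UnknownFormError

__all__ = [
    "EstimateTriplet",
    "JPD",
    "FORMS",
    "jpd_from_triplet",
    "jpd_from_form",
    "count_violations",
    "is_consistent",
]

#: form label -> (first marginal is negated A?, second marginal is negated B?)
FORMS: dict[str, tuple[bool, bool]] = {
    "AB": (False, False),
    "notA_B": (True, False),
    "A_notB": (False, True),
    "notA_notB": (True, True),
}

_SCALES = ("numeric", "verbal")
_ORDERS = ("conjunction_first", "conjunction_last")


@dataclass(frozen=True)
class EstimateTriplet:
    """One trial's three probability judgments plus design metadata.

    ``pA`` and ``pB`` hold the two reported marginals and ``pConj`` the
    reported conjunction *as given*; ``form`` says which (possibly negated)
    events they concern, e.g. for form ``notA_B`` the slots hold P(¬A), P(B)
    and P(¬A&B).
    """

    pA: float
    pB: float
    pConj: float
    form: str = "AB"
    scale: str = "numeric"
    order: str = "conjunction_last"
    participant_id: str = ""
    content_id: str = ""
    dependence: str = ""

    def __post_init__(self) -> None:
        for name in ("pA", "pB", "pConj"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.form not in FORMS:
            raise UnknownFormError(f"unknown problem form: {self.form!r}")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.order not in _ORDERS:
            raise ValueError(f"unknown order: {self.order!r}")


@dataclass(frozen=True)
class JPD:
    """The four joint cells on the percentage scale; cells may be negative."""

    cell_AB: float
    cell_AnotB: float
    cell_notAB: float
    cell_notAnotB: float

    def __post_init__(self) -> None:
        if abs(sum(self.cells()) - 100.0) > 1e-9:
            raise ValueError(f"JPD cells must sum to 100, got {sum(self.cells())}")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.cell_AB, self.cell_AnotB, self.cell_notAB, self.cell_notAnotB)


def jpd_from_triplet(t: EstimateTriplet, reinterpret_marginal: bool = False) -> JPD:
    """Derive the JPD from a plain-form triplet (P(A), P(B), P(A&B)).

    With ``reinterpret_marginal`` the reported P(A) is instead read as
    P(A&¬B) — the reinterpretation under which a respondent who has just
    judged the conjunction takes the conjunct question to exclude it.

    Raises
    ------
    FormMismatchError
        If the triplet is not in the plain ``AB`` form (use
        :func:`jpd_from_form` for negated forms).
    """
    if t.form != "AB":
        raise FormMismatchError(f"jpd_from_triplet requires form 'AB', got {t.form!r}")
    if reinterpret_marginal:
        return JPD(
            cell_AB=t.pConj,
            cell_AnotB=t.pA,
            cell_notAB=t.pB - t.pConj,
            cell_notAnotB=100.0 - t.pA - t.pB,
        )
    return JPD(
        cell_AB=t.pConj,
        cell_AnotB=t.pA - t.pConj,
        cell_notAB=t.pB - t.pConj,
        cell_notAnotB=100.0 - t.pA - t.pB + t.pConj,
    )


def jpd_from_form(t: EstimateTriplet) -> JPD:
    """Derive the JPD from a triplet in any of the four problem forms.

    The reported marginals X, Y and conjunction P(X&Y) fix the four cells in
    (X, Y) space by the additive identities; complement relabeling then maps
    them onto the canonical (A, B) cells.  For form ``AB`` this coincides
    with :func:`jpd_from_triplet`.
    """
    if t.form not in FORMS:
        raise UnknownFormError(f"unknown problem form: {t.form!r}")
    x, y, c = t.pA, t.pB, t.pConj
    xy_cells = {
        (True, True): c,
        (True, False): x - c,
        (False, True): y - c,
        (False, False): 100.0 - x - y + c,
    }
    neg_a, neg_b = FORMS[t.form]
    ab_cells = {}
    for (x_holds, y_holds), v in xy_cells.items():
        a = (not x_holds) if neg_a else x_holds
        b = (not y_holds) if neg_b else y_holds
        ab_cells[(a, b)] = v
    return JPD(
        cell_AB=ab_cells[(True, True)],
        cell_AnotB=ab_cells[(True, False)],
        cell_notAB=ab_cells[(False, True)],
        cell_notAnotB=ab_cells[(False, False)],
    )


def complement_relabel(t: EstimateTriplet) -> EstimateTriplet:
    """Relabel a triplet so both events are negated (an involution on forms).

    Applying it twice returns the original triplet.  Useful for auditing the
    form identities; note the relabeled conjunction P(¬X&¬Y) = 100 − x − y + c
    must itself land in [0, 100] to be a representable triplet.
    """
    x, y, c = t.pA, t.pB, t.pConj
    neg_a, neg_b = FORMS[t.form]
    inv = {v: k for k, v in FORMS.items()}
    return replace(
        t,
        pA=100.0 - x,
        pB=100.0 - y,
        pConj=100.0 - x - y + c,
        form=inv[(not neg_a, not neg_b)],
    )


def count_violations(j: JPD) -> int:
    """Number of strictly negative JPD cells (0, 1, or 2; never more)."""
    return sum(1 for c in j.cells() if c < 0)


def is_consistent(t: EstimateTriplet, criterion: str = "full_jpd") -> bool:
    """Whether a triplet is coherent under the given criterion.

    ``full_jpd``: no cell of the implied JPD is negative (cells equal to zero
    are coherent).  ``conjunction_bound``: the weaker requirement that the
    reported conjunction does not exceed either reported conjunct,
    pConj ≤ min(pA, pB); every full_jpd-consistent triplet also satisfies it.
    """
    if criterion == "full_jpd":
        return count_violations(jpd_from_form(t)) == 0
    if criterion == "conjunction_bound":
        return t.pConj <= min(t.pA, t.pB)
    raise ValueError(f"unknown consistency criterion: {criterion!r}")
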