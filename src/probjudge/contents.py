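"""The 16 conjunction problems about real unique events, with mean-estimate seeds.

Each content pairs two real possibilities (drawn from sports, science,
economics, politics, and entertainment) whose conjunction participants judged;
in half of them event A was normed to decrease the probability of event B and
in half to increase it.  ``seed_pA``/``seed_pB`` are the published mean
percentage estimates of the two conjuncts and serve as seed values for the
synthetic-data generators; ``seed_pConj`` is the mean conjunction estimate,
kept for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ContentFixture", "CONTENTS", "load_content_fixture"]


@dataclass(frozen=True)
class ContentFixture:
    content_id: str
    description: str
    dependence: str  # A_increases_B | A_decreases_B
    seed_pA: float
    seed_pB: float
    seed_pConj: float


CONTENTS: tuple[ContentFixture, ...] = (
    # Event A decreases the likelihood of event B
    ContentFixture(
        "kyoto-warming",
        "US signs the Kyoto Protocol and global temperatures reach a point of no return",
        "A_decreases_B", 47, 42, 44,
    ),
    ContentFixture(
        "web-ads-nyt",
        "US companies focus advertising on the Web and the New York Times becomes more profitable",
        "A_decreases_B", 69, 41, 42,
    ),
    ContentFixture(
        "ip-law-russia",
        "US intellectual property law is updated and Russia becomes the world center for software",
        "A_decreases_B", 54, 24, 27,
    ),
    ContentFixture(
        "nuclear-terror-decline",
        "a nuclear weapon is used in a terrorist attack and terrorist activity substantially decreases",
        "A_decreases_B", 39, 27, 26,
    ),
    ContentFixture(
        "open-border-english",
        "US adopts an open border policy and English is legally declared the official language",
        "A_decreases_B", 15, 46, 26,
    ),
    ContentFixture(
        "greece-recovery-exit",
        "Greece makes a full economic recovery and Greece is forced to leave the EU",
        "A_decreases_B", 33, 33, 25,
    ),
    ContentFixture(
        "parkinsons-cure-triple",
        "a cure for Parkinson's disease is found and the number of Parkinson's patients triples",
        "A_decreases_B", 39, 32, 25,
    ),
    ContentFixture(
        "honda-ford-bankrupt",
        "Honda goes bankrupt and Ford goes bankrupt",
        "A_decreases_B", 19, 23, 15,
    ),
    # Event A increases the likelihood of event B
    ContentFixture(
        "synthetic-drug-decriminalize",
        "a new synthetic drug becomes popular and the decriminalization movement doubles its numbers",
        "A_increases_B", 58, 48, 49,
    ),
    ContentFixture(
        "graphics-markers-esports",
        "3-D graphics require unreality markers and competitive video gaming achieves mainstream acceptance",
        "A_increases_B", 41, 52, 45,
    ),
    ContentFixture(
        "gay-marriage-president",
        "the Supreme Court rules on gay marriage and a gay person is elected president",
        "A_increases_B", 65, 40, 38,
    ),
    ContentFixture(
        "economy-obama",
        "a significant upturn in the economy occurs and Obama is re-elected President",
        "A_increases_B", 36, 55, 38,
    ),
    ContentFixture(
        "centenarians-organs",
        "millions live past 100 and genetics ends the shortage of replacement organs",
        "A_increases_B", 36, 38, 37,
    ),
    ContentFixture(
        "space-tourism-antigravity",
        "space tourism achieves widespread popularity and anti-gravity materials are developed",
        "A_increases_B", 34, 40, 36,
    ),
    ContentFixture(
        "assassination-nato",
        "a head of state is assassinated and NATO grants military support to Arab Spring movements",
        "A_increases_B", 39, 36, 32,
    ),
    ContentFixture(
        "alien-life-funding",
        "intelligent alien life is found and world governments dedicate more resources to contact",
        "A_increases_B", 20, 18, 17,
    ),
)


def load_content_fixture() -> list[ContentFixture]:
    """The 16 contents with their mean conjunct estimates as seed values."""
    return list(CONTENTS)
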