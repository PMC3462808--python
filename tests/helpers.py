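"""Small shared helpers for building in-memory trial tables."""

import pandas as pd


def make_table(triples):
    """Build a minimal schema-complete trial table from (pA, pB, pConj) triples."""
    return pd.DataFrame(
        [
            {
                "participant_id": f"P{i}",
                "content_id": f"c{i}",
                "form": "AB",
                "scale": "numeric",
                "order": "conjunction_last",
                "dependence": "",
                "pA": a,
                "pB": b,
                "pConj": c,
            }
            for i, (a, b, c) in enumerate(triples)
        ]
    )
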