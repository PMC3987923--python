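"""Synthetic stand-in gene lists shared across tests.

These emulate the two nomination inputs -- a 29-gene over-expressed
kinase list and a 95-gene screen hit list -- built so that their
overlap is exactly the six known G2-M candidates (AURKA, WEE1, TTK,
AURKB, CDK2, PLK1).  All distractor identifiers are invented; the
lists are synthetic, not the study's supplementary tables.
"""

SIX_CANDIDATES = ["AURKA", "WEE1", "TTK", "AURKB", "CDK2", "PLK1"]

SYNTHETIC_OVEREXPRESSED = SIX_CANDIDATES + [f"FAKEK{i:02d}" for i in range(1, 24)]

SYNTHETIC_SCREEN_HITS = SIX_CANDIDATES + [f"FAKEH{i:02d}" for i in range(1, 90)]

assert len(SYNTHETIC_OVEREXPRESSED) == 29
assert len(SYNTHETIC_SCREEN_HITS) == 95
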