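"""Build a response matrix from a long-format outcome table.

Writes a tiny screening outcome table to disk, reads it back, rolls the
records up into a compound × assay matrix in {1, -1, 0}, and classifies
the compounds' LD50 endpoints into toxic / marginal / nontoxic.
"""
import tempfile
from pathlib import Path

import pandas as pd

from toxprofile import build_matrix, classify_ld50, read_outcomes

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "outcomes.tsv"
    path.write_text(
        "compound_id\tassay_id\toutcome\n"
        "CID100\tAID1\tActive\n"
        "CID100\tAID2\tInactive\n"
        "CID200\tAID1\tInconclusive\n"
        "CID200\tAID2\tActive\n"
        "CID300\tAID1\tInactive\n"
        "CID300\tAID2\tUntested\n"
        # a second deposit for the same pair: any active response wins
        "CID300\tAID1\tActive\n"
    )
    records = read_outcomes(path)

matrix = build_matrix(records)
print("Response matrix (1 active, -1 inactive, 0 untested/inconclusive):")
print(matrix.data, end="\n\n")

endpoints = pd.Series({"CID100": 4.1, "CID200": 2.6, "CID300": 0.9})
print("-log10 LD50 (mol/kg) endpoints and their classes")
print("(> 3.00 toxic, < 2.00 nontoxic, in between marginal):")
for cid, value in endpoints.items():
    print(f"  {cid}: {value:.1f} -> {classify_ld50(value).value}")
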