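"""Build a kinase→peptide target map from a phosphosite score table.

Candidate targets need a prediction score strictly above 300; the top 12 by
score are kept at ranks 1..12, and in-vitro confirmed substrates join at
rank 0 without consuming the top-12 budget.
"""

import pandas as pd

import phoskin as pk

scores = pk.ScoreTable(pd.DataFrame(
    [("PKG1", f"pep{i:02d}", 280 + 10 * i) for i in range(16)]  # 290..430
    + [("PKACA", "pep01", 505), ("PKACA", "pep07", 450), ("PKACA", "pep03", 299)],
    columns=["kinase", "peptide_id", "score"],
))
invitro = pk.InVitroTargets(pd.DataFrame(
    {"kinase": ["PKG1", "PKG1"], "peptide_id": ["pep00", "off_chip_pep"]}
))
chip = {f"pep{i:02d}" for i in range(16)}

kmap = pk.build_map(scores, invitro, chip_peptides=chip)
print(kmap.frame.to_string(index=False))
print(f"\nPKG1 keeps {len(kmap.peptides_for('PKG1'))} targets: "
      "scores of 300 and below are dropped (strict threshold), only the 12 "
      "best survivors are ranked, and the in-vitro substrate pep00 enters at "
      "rank 0 (its off-chip partner was dropped with a warning).")
print("PKACA keeps only targets scoring >300; pep03 at 299 is excluded.")
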