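"""Who removes the phosphorus in full-scale EBPR plants?

Loads the bundled eight-plant survey (qFISH biovolume fractions,
per-cell poly-P in the aerobic tank, total P per g of suspended solids),
recomputes each genus's percentage contribution, and closes the
four-pool P mass balance per plant.
"""

import ramanfish as rf
from ramanfish.plants import accounts_from_survey

df = rf.survey_contributions()
print("plant           Acc %   Tet %   combined")
for row in df.itertuples():
    print(f"{row.plant:<15} {row.contrib_acc_recomputed:5.1f}  "
          f"{row.contrib_tet_recomputed:6.1f}   {row.contrib_combined:6.1f}")

lead = (df.contrib_tet_recomputed > df.contrib_acc_recomputed).sum()
print(f"\nTetrasphaera out-contributes Ca. Accumulibacter in {lead} of 8 plants;"
      f" together the two PAO hold {df.contrib_combined.min():.0f}-"
      f"{df.contrib_combined.max():.0f}% of the sludge P.")

account = accounts_from_survey()[0]  # Hjoerring
balance = rf.mass_balance(account)
print(f"\nP pools, {account.name} (total {account.total_p} mg P/gSS):")
print(balance[["pool", "mgP_per_gSS", "percent"]].to_string(index=False))
print("The remainder pool lumps chemically precipitated P with poly-P in "
      "PAO that current probes do not target.")
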