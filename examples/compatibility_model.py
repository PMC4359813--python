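"""The static blood-type model: compatibility, fallback order, values.

Prints the receiver x donor compatibility matrix, each receiver's
cross-match preference order (own type first, O- always last), and the
per-type numeric values (receivable-donor count / 27) the optimizer uses.
"""

from bloodassign import BloodType, compatible_donors, type_value
from bloodassign.blood_types import compatibility_table, values_table, rhesus_split

print("Compatibility matrix (rows = receiver, columns = donor):")
print(compatibility_table().replace({True: "YES", False: "."}))

print("\nCross-match preference order per receiver:")
for t in BloodType:
    chain = " > ".join(d.label for d in compatible_donors(t))
    print(f"  {t.label:>3}: {chain}")

print("\nType values and population proportions:")
print(values_table())

pos, neg = rhesus_split()
print(f"\nRh-positive shares sum to {pos}%, Rh-negative to {neg}% "
      "(printed proportions total 101%; they are normalized internally).")
print("Values sum to", sum(type_value(t) for t in BloodType),
      "- each value is the type's receivable-donor count out of the 27 "
      "compatible pairs.")
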