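"""Dimension the littered lying area for the eight study groups.

The Swiss welfare rules prescribe a minimal littered area per horse by
withers-height category; a group's minimum is the sum over its members.
The treatments scale the littered part to 0, 0.5, 1 and 1.5 times that
minimum inside a fixed 1.5x footprint (the rest is rubber mats).
"""

from equirest.housing import STUDY_GROUPS, pony_count, treatment_table

table = treatment_table(STUDY_GROUPS)
print(table.to_string(index=False))
print(f"\ntotal horses: {sum(c.group_size for c in STUDY_GROUPS.values())}, "
      f"of which ponies (withers <=148 cm): {pony_count(STUDY_GROUPS)}")
print("littered_T* columns are m2 of bedded area under each treatment; "
      "T0 offers none, T1 the legal minimum, T1.5 one and a half times it.")
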