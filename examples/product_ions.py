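"""Check an enzymatic product identity by negative-mode ion arithmetic.

The glucose ester of gallic acid (beta-glucogallin, C13H16O10) should
ionise at m/z 331 and fragment to gallate (C7H6O5, m/z 169) by losing
an anhydrohexose (162 Da).
"""

from ugtfam.product_identity import deprotonated_mz, neutral_loss, nominal_mass

parent_formula, fragment_formula = "C13H16O10", "C7H6O5"

print(f"beta-glucogallin {parent_formula}: nominal mass "
      f"{nominal_mass(parent_formula)} Da, [M-H]- at m/z "
      f"{deprotonated_mz(parent_formula)}")
print(f"gallic acid {fragment_formula}: [M-H]- at m/z "
      f"{deprotonated_mz(fragment_formula)}")

for fragment in (169, 211, 271):
    loss = neutral_loss(deprotonated_mz(parent_formula), fragment)
    print(f"fragment m/z {fragment}: neutral loss {loss.delta} "
          f"({loss.annotation})")
# the 162 Da loss to m/z 169 is the anhydrohexose signature of a
# glucosylated product; unassigned differences stay labelled as such
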