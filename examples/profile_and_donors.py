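"""Profile PSPG boxes and predict each enzyme's preferred sugar donor.

Generates two groups with opposite terminal residues (Q vs H), builds
the per-position consensus profile, checks it against the conserved
PSPG positions, and calls the donor preference from position 44.
"""

from ugtfam.motif_mining import PSPGBox
from ugtfam.pspg_profile import (
    build_profile, check_consensus, identity_summary, predict_donor,
)
from ugtfam.synthetic_data import FamilySpec, make_family

spec = FamilySpec(
    n_groups=2, members_per_group=6, terminal_residues=("Q", "H"), seed=5,
)
records, truth = make_family(spec)
boxes = [
    PSPGBox(r.id, r.sequence[truth[r.id].box_start:][:44]) for r in records
]

profile = build_profile(boxes)
report = check_consensus(profile)
passed = int(report["passed"].sum())
print(f"profile over {profile.n_boxes} boxes: {passed}/{len(report)} "
      "conserved positions pass at the 0.9 frequency threshold")
# position 44 carries the Q/H donor dimorphism, so it splits 50/50 here
print(f"position 44 frequencies: Q={profile.frequency(44, 'Q'):.2f}, "
      f"H={profile.frequency(44, 'H'):.2f}")

mean_id, min_id = identity_summary(boxes)
print(f"pairwise box identity: mean {mean_id:.1f}%, min {min_id:.1f}%")

calls = [predict_donor(b) for b in boxes[:4]]
for p in calls:
    print(f"{p.record_id}: residue44={p.residue} -> {p.call} "
          f"({p.confidence})")
# Q-terminal enzymes are called UDP-glucose-preferring, H-terminal ones
# UDP-galactose-preferring; the call is a sequence rule of thumb
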