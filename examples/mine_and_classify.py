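"""Mine a synthetic protein set for PSPG motifs and classify the hits.

Builds a family of four groups (plus decoys and truncated partials),
scans it with the two gapped PSPG patterns, removes partials, builds a
bootstrapped NJ tree on the 44-residue boxes and assigns every query to
a group from two references per group.
"""

from ugtfam.motif_mining import default_patterns, extract_pspg, filter_partials, mine
from ugtfam.phylogeny import Alignment, assign_groups, bootstrap_support
from ugtfam.synthetic_data import FamilySpec, make_family

spec = FamilySpec(
    n_groups=4, members_per_group=6, decoy_count=10, partial_fraction=0.25,
    seed=7,
)
records, truth = make_family(spec)
print(f"input: {len(records)} records "
      f"({sum(1 for t in truth.values() if t.group)} family members, "
      f"{spec.decoy_count} decoys)")

result = mine(records, default_patterns())
kept, removed = filter_partials([e.record for e in result.candidates])
print(f"mined {len(result.candidates)} candidates; "
      f"removed {len(removed)} partials (< 250 aa); kept {len(kept)}")

kept_ids = {r.id for r in kept}
boxes = [
    extract_pspg(e.best_hit())
    for e in result.candidates
    if e.record.id in kept_ids
]
tree = bootstrap_support(Alignment.from_boxes(boxes), n_replicates=200, seed=7)

refs = {f"G{g}_M0{m}": f"G{g}" for g in range(1, 5) for m in (1, 2)
        if f"G{g}_M0{m}" in kept_ids}
assignments = assign_groups(tree, refs)
correct = sum(
    a.group == truth[a.label].group for a in assignments if not a.is_reference
)
queries = sum(1 for a in assignments if not a.is_reference)
print(f"group assignment: {correct}/{queries} queries recovered their "
      "generating group")
# every count above is exact because the generator records ground truth:
# mined == planted members, removed == planted partials, and assignments
# are checked against the generating group labels
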