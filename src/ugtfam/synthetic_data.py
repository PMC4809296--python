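"""Synthetic inputs with known ground truth for every pipeline stage.

`make_family` emulates the *structure* of a translated transcriptome
protein set containing a glycosyltransferase family: group-structured
sequences built as random flanks around a mutated copy of a group
ancestor's 44-residue PSPG box, plus decoy sequences with no planted
box and truncated partials (shorter than 250 residues, box retained).
It emulates structure only — flank composition is uniform over the 20
amino acids, mutations are uniform residue exchanges, and there are no
indels inside the box.

Divergence is controlled on three axes:

* ``within_divergence`` — per-position substitution probability of a
  member relative to its group ancestor, at non-anchor box positions;
* ``between_divergence`` — same, for a group ancestor relative to the
  family root box (default 3x the within rate, so groups form clean
  clades);
* ``motif_conservation`` — probability that each mining-pattern literal
  (anchor) position is left intact in a member; at 1.0 every member
  carries a perfectly minable motif.

Each group is assigned a terminal residue (Q or H, alternating by
default), held fixed in all its members: it is the ground-truth label
for sugar-donor prediction.

`simulate_assay` produces Michaelis–Menten rate observations with
multiplicative Gaussian noise.  Everything is reproducible from the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import ProteinRecord
from .kinetics import KineticDataset
from .motif_mining import PSPG_SPAN, default_patterns

__all__ = [
    "FamilySpec",
    "SyntheticTruth",
    "FamilySpecError",
    "ROOT_PSPG_BOX",
    "make_family",
    "simulate_assay",
    "random_additive_tree",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: family root box: satisfies the default consensus spec and carries
#: every literal of both mining patterns (Q-terminal form)
ROOT_PSPG_BOX = "WAPQVLILSHCGFGSFTKHCGWNSTLESLVAGVPMITWPLFAEQ"
assert len(ROOT_PSPG_BOX) == PSPG_SPAN

TERMINAL_OFFSET = PSPG_SPAN - 1


def _anchor_offsets() -> frozenset[int]:
    """Union of both default patterns' literal offsets, minus the
    terminal position (which is governed by the group's donor label)."""
    offsets = {
        off
        for pattern in default_patterns()
        for off, _ in pattern.literal_offsets()
    }
    offsets.discard(TERMINAL_OFFSET)
    return frozenset(offsets)


ANCHOR_OFFSETS = _anchor_offsets()
NON_ANCHOR_OFFSETS = tuple(
    off
    for off in range(PSPG_SPAN)
    if off not in ANCHOR_OFFSETS and off != TERMINAL_OFFSET
)


class FamilySpecError(ValueError):
    """Raised for a contradictory family specification."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic motif-bearing protein family."""

    n_groups: int = 4
    members_per_group: int = 8
    within_divergence: float = 0.05
    between_divergence: float = 0.15
    motif_conservation: float = 1.0
    flank_length: tuple[int, int] = (110, 160)
    decoy_count: int = 0
    partial_fraction: float = 0.0
    terminal_residues: tuple[str, ...] | None = None
    group_sizes: tuple[int, ...] | None = None
    ancestors: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise FamilySpecError("n_groups must be >= 1")
        if self.members_per_group < 1:
            raise FamilySpecError("members_per_group must be >= 1")
        for name in ("within_divergence", "between_divergence",
                     "motif_conservation", "partial_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise FamilySpecError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.flank_length
        if not 0 <= lo <= hi:
            raise FamilySpecError("flank_length must satisfy 0 <= min <= max")
        if self.decoy_count < 0:
            raise FamilySpecError("decoy_count must be >= 0")
        if self.group_sizes is not None:
            if len(self.group_sizes) != self.n_groups:
                raise FamilySpecError("group_sizes length must equal n_groups")
            if any(s < 1 for s in self.group_sizes):
                raise FamilySpecError("group sizes must be >= 1")
        if self.terminal_residues is not None:
            if len(self.terminal_residues) != self.n_groups:
                raise FamilySpecError("terminal_residues length must equal n_groups")
            bad = set("".join(self.terminal_residues).upper()) - set(AA20)
            if bad or any(len(t) != 1 for t in self.terminal_residues):
                raise FamilySpecError("terminal residues must be single amino acids")
        if self.ancestors is not None:
            if len(self.ancestors) != self.n_groups:
                raise FamilySpecError("ancestors length must equal n_groups")
            if any(len(a) != PSPG_SPAN for a in self.ancestors):
                raise FamilySpecError(f"ancestor boxes must be {PSPG_SPAN} residues")

    def sizes(self) -> tuple[int, ...]:
        return self.group_sizes or (self.members_per_group,) * self.n_groups

    def terminals(self) -> tuple[str, ...]:
        if self.terminal_residues is not None:
            return tuple(t.upper() for t in self.terminal_residues)
        return tuple("Q" if g % 2 == 0 else "H" for g in range(self.n_groups))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated record."""

    group: str | None
    box_start: int | None
    terminal: str | None
    is_partial: bool = False

    @property
    def is_decoy(self) -> bool:
        return self.group is None


def _mutate(box: list[str], offsets, prob: float, rng: np.random.Generator) -> None:
    # uniform exchange to a different residue, i.i.d. per position
    for off in offsets:
        if prob > 0 and rng.random() < prob:
            current = box[off]
            choices = [a for a in AA20 if a != current]
            box[off] = choices[int(rng.integers(len(choices)))]


def _random_flank(length: int, rng: np.random.Generator) -> str:
    return "".join(
        AA20[i] for i in rng.integers(0, len(AA20), size=length)
    )


def make_family(
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], dict[str, SyntheticTruth]]:
    """Generate a family with per-record ground truth.

    Members are ``flank + mutated ancestor box + flank``; the chosen
    partials get short flanks so the whole record stays below 250
    residues while the box survives intact (mirroring fragmentary
    assemblies that still cover the conserved C-terminal region).
    Decoys contain no planted box.  Byte-identical output for equal
    seeds.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    terminals = spec.terminals()

    if spec.ancestors is not None:
        ancestors = [list(a.upper()) for a in spec.ancestors]
    else:
        ancestors = []
        for g in range(spec.n_groups):
            anc = list(ROOT_PSPG_BOX)
            _mutate(anc, NON_ANCHOR_OFFSETS, spec.between_divergence, rng)
            ancestors.append(anc)
    for g, anc in enumerate(ancestors):
        anc[TERMINAL_OFFSET] = terminals[g]

    total_members = sum(sizes)
    n_partials = int(round(spec.partial_fraction * total_members))
    partial_idx = set(
        int(i) for i in rng.choice(total_members, size=n_partials, replace=False)
    ) if n_partials else set()

    lo, hi = spec.flank_length
    records: list[ProteinRecord] = []
    truth: dict[str, SyntheticTruth] = {}
    member_counter = 0
    motif_mutation = 1.0 - spec.motif_conservation
    for g in range(spec.n_groups):
        group_label = f"G{g + 1}"
        for m in range(sizes[g]):
            box = list(ancestors[g])
            _mutate(box, NON_ANCHOR_OFFSETS, spec.within_divergence, rng)
            _mutate(box, sorted(ANCHOR_OFFSETS), motif_mutation, rng)
            box[TERMINAL_OFFSET] = terminals[g]
            is_partial = member_counter in partial_idx
            if is_partial:
                left = int(rng.integers(10, 61))
                total = int(rng.integers(left + PSPG_SPAN + 10, 250))
                right = total - left - PSPG_SPAN
            else:
                left = int(rng.integers(lo, hi + 1))
                right = int(rng.integers(lo, hi + 1))
            seq = _random_flank(left, rng) + "".join(box) + _random_flank(right, rng)
            rid = f"{group_label}_M{m + 1:02d}"
            records.append(ProteinRecord(rid, seq))
            truth[rid] = SyntheticTruth(
                group=group_label,
                box_start=left,
                terminal=terminals[g],
                is_partial=is_partial,
            )
            member_counter += 1

    for d in range(spec.decoy_count):
        length = int(rng.integers(250, 401))
        rid = f"DECOY_{d + 1:02d}"
        records.append(ProteinRecord(rid, _random_flank(length, rng)))
        truth[rid] = SyntheticTruth(group=None, box_start=None, terminal=None)

    return records, truth


def simulate_assay(
    km: float,
    vmax: float,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
    enzyme: str = "synthetic-enzyme",
    substrate: str = "synthetic-substrate",
) -> KineticDataset:
    """Michaelis–Menten observations with multiplicative Gaussian noise.

    v = Vmax·S/(Km+S) × (1 + ε), ε ~ N(0, noise_cv) truncated at −0.99
    so rates stay positive.  Replicates are pooled with a replicate
    index; seeded and reproducible.
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    s = np.tile(np.asarray(concentrations, dtype=float), replicates)
    rep_idx = np.repeat(np.arange(1, replicates + 1), len(concentrations))
    ideal = vmax * s / (km + s)
    if noise_cv > 0:
        factor = np.maximum(1.0 + rng.normal(0.0, noise_cv, size=s.size), 0.01)
    else:
        factor = np.ones_like(s)
    return KineticDataset(
        enzyme=enzyme,
        substrate=substrate,
        concentrations_uM=tuple(s),
        rates=tuple(ideal * factor),
        replicate=tuple(int(i) for i in rep_idx),
    )


def random_additive_tree(
    n_taxa: int,
    seed: int | np.random.Generator | None = None,
    length_range: tuple[float, float] = (0.05, 0.5),
) -> TreeNode:
    """A random unrooted binary tree with positive branch lengths.

    Its tip-to-tip path lengths form an additive distance matrix — the
    standard oracle for distance-based reconstruction: NJ run on
    ``tree.tip_tip_distances()`` must recover this topology exactly.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lo, hi = length_range

    def draw() -> float:
        return float(rng.uniform(lo, hi))

    tips = [TreeNode(name=f"T{i + 1}") for i in range(n_taxa)]
    root = TreeNode(children=tips[:3])
    for t in tips[:3]:
        t.length = draw()
    attachable = list(tips[:3])  # nodes with a parent edge that can be split
    for tip in tips[3:]:
        edge_node = attachable[int(rng.integers(len(attachable)))]
        parent = edge_node.parent
        joint = TreeNode(length=draw())
        parent.remove(edge_node)
        parent.append(joint)
        joint.append(edge_node)
        tip.length = draw()
        joint.append(tip)
        attachable.extend([joint, tip])
    return root
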