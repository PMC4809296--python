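"""PSPG-box conservation profiling and sugar-donor prediction.

A set of 44-residue PSPG boxes is summarised into per-position residue
frequencies, checked against the expected conserved-position profile of
plant secondary-product glycosyltransferases (W1, Q4, L8, H10, HCGWNS at
19-24, E27, P39, E/D43, Q44), and the terminal residue is used to
predict the preferred UDP-sugar donor: a terminal Gln (Q) marks
UDP-glucose-preferring enzymes and a terminal His (H) marks
UDP-galactose-preferring ones.

The donor call is a sequence rule of thumb, not a mechanistic model:
swapping the terminal residue of a galactosyltransferase experimentally
does not always flip its specificity, so every prediction carries
confidence ``"rule-of-thumb"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .motif_mining import PSPGBox, PSPG_SPAN

__all__ = [
    "ConsensusProfile",
    "ConsensusSpec",
    "DonorPrediction",
    "DEFAULT_CONSENSUS_SPEC",
    "GLC_PREFERRING",
    "GAL_PREFERRING",
    "UNKNOWN_DONOR",
    "build_profile",
    "check_consensus",
    "pairwise_identity",
    "identity_summary",
    "predict_donor",
]

GLC_PREFERRING = "UDP-glucose-preferring"
GAL_PREFERRING = "UDP-galactose-preferring"
UNKNOWN_DONOR = "unknown"


@dataclass(frozen=True)
class ConsensusSpec:
    """Allowed residues at conserved PSPG positions (1-based)."""

    positions: Mapping[int, frozenset[str]]

    def __post_init__(self) -> None:
        norm = {}
        for pos, residues in dict(self.positions).items():
            if not 1 <= pos <= PSPG_SPAN:
                raise ValueError(f"position {pos} outside 1..{PSPG_SPAN}")
            norm[int(pos)] = frozenset(str(r).upper() for r in residues)
        object.__setattr__(self, "positions", norm)


#: conserved positions of the plant PSPG box; 43 tolerates E or D, and
#: position 44 is the Q/H donor dimorphism handled by predict_donor
DEFAULT_CONSENSUS_SPEC = ConsensusSpec(
    {
        1: "W",
        4: "Q",
        8: "L",
        10: "H",
        19: "H",
        20: "C",
        21: "G",
        22: "W",
        23: "N",
        24: "S",
        27: "E",
        39: "P",
        43: "ED",
        44: "Q",
    }
)


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-position residue frequencies of a PSPG box collection.

    ``frequencies`` is a DataFrame indexed by position 1..44 with one
    column per observed residue; each row sums to 1.
    """

    frequencies: pd.DataFrame
    counts: pd.DataFrame
    n_boxes: int

    def frequency(self, position: int, residues: Iterable[str]) -> float:
        """Summed frequency of ``residues`` at a 1-based position."""
        row = self.frequencies.loc[position]
        return float(sum(row.get(r.upper(), 0.0) for r in residues))

    def modal(self) -> pd.DataFrame:
        """Position, modal residue and its frequency (ties: alphabetical)."""
        rows = []
        for pos in self.frequencies.index:
            series = self.frequencies.loc[pos]
            top = series[series == series.max()].index.min()
            rows.append((pos, top, float(series[top])))
        return pd.DataFrame(rows, columns=["position", "residue", "frequency"])


def build_profile(boxes: Iterable[PSPGBox]) -> ConsensusProfile:
    """Exact per-position residue counts, normalised to frequencies."""
    boxes = list(boxes)
    if not boxes:
        raise ValueError("at least one PSPG box is required")
    residues = sorted({ch for b in boxes for ch in b.residues})
    counts = pd.DataFrame(
        0, index=range(1, PSPG_SPAN + 1), columns=residues, dtype=int
    )
    for box in boxes:
        for pos, ch in enumerate(box.residues, start=1):
            counts.at[pos, ch] += 1
    freqs = counts / len(boxes)
    return ConsensusProfile(frequencies=freqs, counts=counts, n_boxes=len(boxes))


def check_consensus(
    profile: ConsensusProfile,
    spec: ConsensusSpec = DEFAULT_CONSENSUS_SPEC,
    min_freq: float = 0.9,
) -> pd.DataFrame:
    """Per-position pass/fail against a conserved-position spec.

    A position passes iff the summed frequency of its allowed residues
    is >= ``min_freq`` (default 0.9, operationalising "highly
    conserved").
    """
    rows = []
    for pos in sorted(spec.positions):
        allowed = spec.positions[pos]
        observed = profile.frequency(pos, allowed)
        rows.append(
            (pos, "/".join(sorted(allowed)), observed, observed >= min_freq)
        )
    return pd.DataFrame(
        rows, columns=["position", "allowed", "observed_frequency", "passed"]
    )


def pairwise_identity(box_a: PSPGBox, box_b: PSPGBox) -> float:
    """Percent identity over the 44 box positions (0..100)."""
    matches = sum(a == b for a, b in zip(box_a.residues, box_b.residues))
    return 100.0 * matches / PSPG_SPAN


def identity_summary(boxes: Iterable[PSPGBox]) -> tuple[float, float]:
    """(mean, minimum) pairwise identity over all unordered box pairs."""
    boxes = list(boxes)
    if len(boxes) < 2:
        raise ValueError("identity summary needs at least 2 boxes")
    idents = [
        pairwise_identity(a, b) for a, b in itertools.combinations(boxes, 2)
    ]
    return sum(idents) / len(idents), min(idents)


@dataclass(frozen=True)
class DonorPrediction:
    """Sugar-donor call from the terminal PSPG residue (position 44)."""

    record_id: str
    residue: str
    call: str
    confidence: str = "rule-of-thumb"


def predict_donor(box: PSPGBox) -> DonorPrediction:
    """Q -> UDP-glucose-preferring, H -> UDP-galactose-preferring.

    Any other terminal residue yields ``unknown``.  Pure function of
    position 44, case-insensitive.
    """
    residue = box.terminal.upper()
    if residue == "Q":
        call = GLC_PREFERRING
    elif residue == "H":
        call = GAL_PREFERRING
    else:
        call = UNKNOWN_DONOR
    return DonorPrediction(record_id=box.record_id, residue=residue, call=call)
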