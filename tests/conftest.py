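import numpy as np
import pytest

from ugtfam.motif_mining import PSPGBox, default_patterns
from ugtfam.synthetic_data import FamilySpec, ROOT_PSPG_BOX, make_family


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture()
def root_box():
    return PSPGBox("root", ROOT_PSPG_BOX)


@pytest.fixture()
def small_family():
    """2 groups x 3 members, perfectly conserved motifs, no decoys."""
    spec = FamilySpec(
        n_groups=2, members_per_group=3, within_divergence=0.0,
        between_divergence=0.0, seed=42,
    )
    return make_family(spec)


def build_window(pattern, gap_char="A"):
    """A minimal window matching ``pattern``: literals at their offsets,
    ``gap_char`` everywhere else.  Independent of the scanner."""
    window = [gap_char] * pattern.span
    for off, residue in pattern.literal_offsets():
        window[off] = residue
    return "".join(window)


def brute_force_scan(sequence, pattern, allow_x=True):
    """Position-by-position oracle matcher (no regex)."""
    literals = pattern.literal_offsets()
    span = pattern.span
    hits = []
    for start in range(len(sequence) - span + 1):
        ok = True
        for off, residue in literals:
            ch = sequence[start + off]
            if ch != residue and not (allow_x and ch == "X"):
                ok = False
                break
        if ok:
            hits.append(start)
    return hits


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWYX"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
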