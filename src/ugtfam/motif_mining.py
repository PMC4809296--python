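"""Gapped PSPG-motif mining.

Plant UDP-glycosyltransferases carry a conserved ~44-residue signature
near the C-terminus, the PSPG box (Plant Secondary Product
Glycosyltransferase motif).  Family members can be pulled out of large
translated transcriptome sets with *gapped patterns*: short runs of
anchored literal residues separated by fixed-length wildcard gaps, e.g.
``W-2x-Q-11x-F-2x-H-1x-GW-1x-S-9x-P-9x-Q``.  Both default patterns span
exactly 44 residues, so every hit window is directly a PSPG box.

The module compiles such patterns, scans protein records (reporting all
overlapping hits), applies the partial-sequence length filter (sequences
shorter than 250 residues are set aside as assembly fragments), and
extracts 44-residue PSPG boxes from hits.

Coordinates are 0-based half-open internally and 1-based in tabular
reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .io_formats import ProteinRecord, STANDARD_AA

__all__ = [
    "GappedPattern",
    "MotifHit",
    "PSPGBox",
    "MiningEntry",
    "MiningResult",
    "PatternParseError",
    "PatternSpanError",
    "PartitionResult",
    "parse_pattern",
    "scan",
    "mine",
    "filter_partials",
    "extract_pspg",
    "default_patterns",
    "PATTERN_TEXTS",
    "PSPG_SPAN",
    "DEFAULT_MIN_LENGTH",
]

#: the two mining motifs; pspg-1 anchors the Q-terminal (glucosylating)
#: form, pspg-2 tolerates the divergent C-terminal half
PATTERN_TEXTS = {
    "pspg-1": "W-2x-Q-11x-F-2x-H-1x-GW-1x-S-9x-P-9x-Q",
    "pspg-2": "W-2x-Q-3x-L-10x-H-1x-G-5x-E-17x",
}

PSPG_SPAN = 44
DEFAULT_MIN_LENGTH = 250

_GAP_RE = re.compile(r"^(\d+)x$")


class PatternParseError(ValueError):
    """Raised for a token that is neither a residue run nor ``<n>x``."""


class PatternSpanError(ValueError):
    """Raised when an operation requires a 44-residue window."""


@dataclass(frozen=True)
class GappedPattern:
    """A compiled gapped mining motif.

    ``tokens`` is an ordered tuple of ``("literal", residues)`` and
    ``("gap", n)`` entries; ``span`` is the total window length.
    """

    name: str
    source_text: str
    tokens: tuple[tuple[str, object], ...]

    @property
    def span(self) -> int:
        return sum(
            len(val) if kind == "literal" else val for kind, val in self.tokens
        )

    def literal_offsets(self) -> tuple[tuple[int, str], ...]:
        """(0-based window offset, residue) for every anchored literal."""
        out = []
        off = 0
        for kind, val in self.tokens:
            if kind == "literal":
                for ch in val:
                    out.append((off, ch))
                    off += 1
            else:
                off += val
        return tuple(out)

    def to_regex(self, allow_x: bool = True) -> re.Pattern:
        """Overlap-reporting regex (lookahead capture of the window)."""
        parts = []
        for kind, val in self.tokens:
            if kind == "literal":
                parts.extend(f"[{ch}X]" if allow_x else ch for ch in val)
            else:
                parts.append(f".{{{val}}}")
        return re.compile(f"(?=({''.join(parts)}))")


def parse_pattern(text: str, name: str | None = None) -> GappedPattern:
    """Compile a dash-separated gapped pattern string.

    Tokens are either runs of amino-acid letters (``GW``) or fixed gaps
    ``<n>x`` with ``n >= 1``.  Unknown tokens raise
    :class:`PatternParseError` naming the offending position.
    """
    tokens: list[tuple[str, object]] = []
    for i, tok in enumerate(text.split("-")):
        m = _GAP_RE.match(tok)
        if m:
            n = int(m.group(1))
            if n < 1:
                raise PatternParseError(
                    f"token {i + 1} ({tok!r}): gap length must be >= 1"
                )
            tokens.append(("gap", n))
        elif tok and set(tok) <= STANDARD_AA:
            tokens.append(("literal", tok))
        else:
            raise PatternParseError(f"token {i + 1} ({tok!r}): not a residue run or '<n>x'")
    return GappedPattern(name=name or text, source_text=text, tokens=tuple(tokens))


def default_patterns() -> list[GappedPattern]:
    """The two built-in PSPG mining patterns (each spans 44 residues)."""
    return [parse_pattern(text, name) for name, text in PATTERN_TEXTS.items()]


@dataclass(frozen=True)
class MotifHit:
    """A located pattern window inside one record (0-based start)."""

    record_id: str
    pattern_id: str
    start: int
    window: str

    @property
    def span(self) -> int:
        return len(self.window)

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass(frozen=True)
class PSPGBox:
    """A 44-residue PSPG box; positions are numbered 1..44 in reports."""

    record_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != PSPG_SPAN:
            raise PatternSpanError(
                f"PSPG box for {self.record_id!r} must be {PSPG_SPAN} residues, "
                f"got {len(self.residues)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def position(self, pos: int) -> str:
        """Residue at 1-based position ``pos`` (1..44)."""
        if not 1 <= pos <= PSPG_SPAN:
            raise IndexError(f"PSPG position must be in 1..{PSPG_SPAN}, got {pos}")
        return self.residues[pos - 1]

    @property
    def terminal(self) -> str:
        """Position-44 residue (the sugar-donor indicator)."""
        return self.residues[-1]


def scan(
    record: ProteinRecord, pattern: GappedPattern, allow_x: bool = True
) -> list[MotifHit]:
    """Report every window where all pattern literals match.

    ``X`` in the scanned sequence matches any literal iff ``allow_x``.
    Overlapping hits are all reported, in ascending start order; a
    sequence shorter than the pattern span simply yields no hits.
    """
    seq = record.sequence
    if len(seq) < pattern.span:
        return []
    rx = pattern.to_regex(allow_x=allow_x)
    return [
        MotifHit(record.id, pattern.name, m.start(), m.group(1))
        for m in rx.finditer(seq)
    ]


@dataclass(frozen=True)
class MiningEntry:
    """One record's mining outcome: all hits, ordered (start, pattern)."""

    record: ProteinRecord
    hits: tuple[MotifHit, ...]

    @property
    def matched(self) -> bool:
        return bool(self.hits)

    def best_hit(self, span: int = PSPG_SPAN) -> MotifHit | None:
        """The first hit of the requested span (left-most, then pattern
        order as given to :func:`mine`)."""
        for hit in self.hits:
            if hit.span == span:
                return hit
        return None


@dataclass
class MiningResult:
    """Per-record mining outcomes, in input order."""

    entries: list[MiningEntry]
    pattern_ids: tuple[str, ...]

    @property
    def candidates(self) -> list[MiningEntry]:
        return [e for e in self.entries if e.matched]

    def to_frame(self) -> pd.DataFrame:
        """Hit table: record_id, length, pattern_id, start (1-based), window."""
        rows = [
            (e.record.id, len(e.record), h.pattern_id, h.start + 1, h.window)
            for e in self.candidates
            for h in e.hits
        ]
        return pd.DataFrame(
            rows, columns=["record_id", "length", "pattern_id", "start", "window"]
        )


def mine(
    records: Iterable[ProteinRecord], patterns: Sequence[GappedPattern],
    allow_x: bool = True,
) -> MiningResult:
    """Scan every record with every pattern.

    A record is a candidate iff at least one pattern hits it; a record
    matched by several patterns is listed once carrying all its hits.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("at least one pattern is required")
    order = {p.name: i for i, p in enumerate(patterns)}
    entries = []
    for record in records:
        hits = [h for p in patterns for h in scan(record, p, allow_x=allow_x)]
        hits.sort(key=lambda h: (h.start, order[h.pattern_id]))
        entries.append(MiningEntry(record, tuple(hits)))
    return MiningResult(entries, tuple(p.name for p in patterns))


class PartitionResult(NamedTuple):
    kept: list[ProteinRecord]
    removed: list[ProteinRecord]


def filter_partials(
    records: Iterable[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> PartitionResult:
    """Partition records into (kept, removed) by length.

    Records *fewer than* ``min_length`` residues are removed as assembly
    partials, so a record of exactly ``min_length`` is kept.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept, removed = [], []
    for r in records:
        (kept if len(r) >= min_length else removed).append(r)
    return PartitionResult(kept, removed)


def extract_pspg(hit: MotifHit) -> PSPGBox:
    """Turn a 44-residue hit window into a PSPG box (positions 1..44)."""
    if hit.span != PSPG_SPAN:
        raise PatternSpanError(
            f"cannot extract a PSPG box from a span-{hit.span} hit "
            f"(pattern {hit.pattern_id!r}); a {PSPG_SPAN}-residue window is required"
        )
    return PSPGBox(record_id=hit.record_id, residues=hit.window)
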