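"""Marker identifiers and panel handling.

Eight tumor markers exist: each of the four analytes CEA, CA19-9, CA125 and
CA15-3 measured in pleural effusion fluid (``PE``) and in peripheral blood
(``PB``).  A *panel* is any non-empty subset of the eight; panels are the
unit everything downstream (pricing, model evaluation, cost-effectiveness
scoring) operates on.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

FLUIDS = ("PE", "PB")
ANALYTES = ("CEA", "CA19-9", "CA125", "CA15-3")

#: The eight valid marker identifiers, "<fluid>.<analyte>".
ALL_MARKERS: tuple[str, ...] = tuple(f"{f}.{a}" for f in FLUIDS for a in ANALYTES)

_MARKER_SET = frozenset(ALL_MARKERS)

#: The single marker whose absence characterizes the low-AUC outlier panels.
ANCHOR_MARKER = "PE.CEA"


def validate_marker(marker: str) -> str:
    """Return ``marker`` if it is one of the eight valid identifiers."""
    if marker not in _MARKER_SET:
        raise ValueError(
            f"unknown marker {marker!r}; valid markers are {sorted(_MARKER_SET)}"
        )
    return marker


def marker_fluid(marker: str) -> str:
    return validate_marker(marker).split(".", 1)[0]


def marker_analyte(marker: str) -> str:
    return validate_marker(marker).split(".", 1)[1]


def canonical_panel(markers: Iterable[str]) -> tuple[str, ...]:
    """Validate a collection of markers and return the canonical panel.

    Canonical form is the lexicographically sorted tuple of marker strings;
    duplicates and empty panels are rejected.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("a marker panel must be non-empty")
    if len(set(markers)) != len(markers):
        raise ValueError(f"duplicate markers in panel: {markers}")
    for m in markers:
        validate_marker(m)
    return tuple(sorted(markers))


def panel_str(markers: Iterable[str]) -> str:
    """Canonical serialized form: sorted, ``+``-joined marker strings."""
    return "+".join(canonical_panel(markers))


def parse_panel(text: str) -> tuple[str, ...]:
    """Parse a ``+``-joined panel string (any order) into canonical form."""
    return canonical_panel(part.strip() for part in text.split("+"))


def enumerate_panels(markers: Iterable[str] = ALL_MARKERS) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``markers``, each exactly once.

    Ordered by panel size, then lexicographically; over the full marker set
    this yields the 255 combinations the pricing and evaluation stages score.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("marker set must be non-empty")
    if len(set(markers)) != len(markers):
        raise ValueError(f"duplicate markers: {markers}")
    for m in markers:
        validate_marker(m)
    base = sorted(markers)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(base) + 1):
        out.extend(combinations(base, size))
    return out
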