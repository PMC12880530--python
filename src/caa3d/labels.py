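"""Segment depth labels for vascular units.

Segments of a vascular unit are labeled by branch order counted from the
cortical entry point: ``D0`` is the stretch from parenchymal entry to the
first branch, ``D1`` the stretch from that branch to the next, and so on.
The short arc surrounding the branch node between depths ``d`` and ``d+1``
is its own segment, ``D0-D1`` etc.  The leptomeningeal portion above the
entry point is ``LMA``; branch orders beyond 6 are pooled as ``DEEPER``.

Labels carry a total *superficiality* order::

    LMA < D0 < D0-D1 < D1 < D1-D2 < ... < D6 < DEEPER
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

MAX_DEPTH = 6  # depths beyond this pool into DEEPER


@total_ordering
@dataclass(frozen=True)
class SegmentLabel:
    """One depth label; ``depth`` is None for LMA and DEEPER."""

    kind: str  # "LMA" | "DEPTH" | "BIFURCATION" | "DEEPER"
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("LMA", "DEPTH", "BIFURCATION", "DEEPER"):
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.kind in ("DEPTH", "BIFURCATION"):
            if self.depth is None or not 0 <= self.depth <= MAX_DEPTH:
                raise ValueError(f"depth out of range for {self.kind}: {self.depth}")

    @property
    def order(self) -> float:
        """Superficiality rank (smaller = more superficial)."""
        if self.kind == "LMA":
            return -1.0
        if self.kind == "DEPTH":
            return float(self.depth)
        if self.kind == "BIFURCATION":
            return self.depth + 0.5
        return MAX_DEPTH + 1.0  # DEEPER

    def __lt__(self, other: "SegmentLabel") -> bool:
        return self.order < other.order

    def __str__(self) -> str:
        if self.kind == "LMA":
            return "LMA"
        if self.kind == "DEPTH":
            return f"D{self.depth}"
        if self.kind == "BIFURCATION":
            return f"D{self.depth}-D{self.depth + 1}"
        return "DEEPER"

    @classmethod
    def parse(cls, text: str) -> "SegmentLabel":
        text = text.strip()
        if text == "LMA":
            return LMA
        if text == "DEEPER":
            return DEEPER
        if "-" in text:
            a, b = text.split("-")
            d = int(a[1:])
            if int(b[1:]) != d + 1:
                raise ValueError(f"malformed bifurcation label {text!r}")
            return cls("BIFURCATION", d)
        return cls("DEPTH", int(text[1:]))

    @classmethod
    def for_depth(cls, depth: int) -> "SegmentLabel":
        """Depth label for a branch order, pooling > MAX_DEPTH into DEEPER."""
        return cls("DEPTH", depth) if depth <= MAX_DEPTH else DEEPER

    @classmethod
    def for_bifurcation(cls, depth: int) -> "SegmentLabel":
        """Label of the branch-node arc between ``depth`` and ``depth+1``."""
        return cls("BIFURCATION", depth) if depth < MAX_DEPTH else DEEPER


LMA = SegmentLabel("LMA")
DEEPER = SegmentLabel("DEEPER")
D = SegmentLabel.for_depth  # shorthand used throughout

#: labels D0..D6 in superficial-to-deep order (no LMA, no bifurcations)
DEPTH_LABELS = tuple(SegmentLabel("DEPTH", d) for d in range(MAX_DEPTH + 1))

#: full ordered chain LMA, D0, D0-D1, ..., D6, DEEPER
LABEL_CHAIN = (
    (LMA,)
    + sum(
        (
            (SegmentLabel("DEPTH", d), SegmentLabel("BIFURCATION", d))
            for d in range(MAX_DEPTH)
        ),
        (),
    )
    + (SegmentLabel("DEPTH", MAX_DEPTH), DEEPER)
)
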