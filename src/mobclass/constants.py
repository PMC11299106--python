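"""Shared constants: the fixed MOB class order and fragment length ranges.

Every module that emits or consumes per-class score vectors uses
:data:`CLASS_ORDER`; output columns, model class ordering and tie-breaking
all refer to this single tuple.
"""

from __future__ import annotations

#: Fixed 11-class order used everywhere: ten relaxase (MOB) families plus the
#: nonmobilizable category.  Output score columns follow this order.
CLASS_ORDER: tuple[str, ...] = (
    "MOBB",
    "MOBC",
    "MOBF",
    "MOBH",
    "MOBL",
    "MOBM",
    "MOBP",
    "MOBQ",
    "MOBT",
    "MOBV",
    "non-MOB",
)

MOB_CLASSES: tuple[str, ...] = CLASS_ORDER[:-1]
NON_MOB: str = "non-MOB"

#: Training length bins: each is served by its own random-forest model.
#: Fragments shorter than 100 bp fall back to B1.
LENGTH_BINS: dict[str, tuple[int, int]] = {
    "B1": (100, 400),
    "B2": (401, 800),
    "B3": (801, 1200),
    "B4": (1201, 1600),
}

#: Test length groups used for benchmarking, including long-fragment groups
#: that exercise segmentation.
TEST_GROUPS: dict[str, tuple[int, int]] = {
    "A": (801, 1200),
    "B": (1201, 1600),
    "C": (3000, 4000),
    "D": (5000, 10000),
}

#: Fragments longer than this are segmented before classification.
SEGMENT_LENGTH: int = 1600

#: Sentinel predicted class for fragments that cannot be featurized
#: (e.g. shorter than k or all-ambiguous).
UNCLASSIFIED: str = "unclassified"
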