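"""Class labels, display names and the overlay palette.

The five recognised states of cultured cells are, in fixed order:
apoptosis, autophagy, ferroptosis, healthy and necroptosis.  Every module
indexes classes by position in :data:`CLASSES`; ties in argmax decisions are
broken toward the lowest index in this order.
"""

from __future__ import annotations

CLASSES: tuple[str, ...] = ("apo", "aut", "fer", "hea", "nec")

LABEL_TO_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CLASSES)}

FULL_NAMES: dict[str, str] = {
    "apo": "Apoptosis",
    "aut": "Autophagy",
    "fer": "Ferroptosis",
    "hea": "Healthy",
    "nec": "Necroptosis",
}

# RGB in [0, 1]; healthy is gray, each death mode gets a distinct hue.
PALETTE: dict[str, tuple[float, float, float]] = {
    "apo": (0.85, 0.20, 0.20),  # red
    "aut": (0.95, 0.65, 0.10),  # orange
    "fer": (0.55, 0.25, 0.75),  # purple
    "hea": (0.55, 0.55, 0.55),  # gray
    "nec": (0.15, 0.45, 0.85),  # blue
}


def check_label(label: str) -> str:
    if label not in LABEL_TO_INDEX:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return label
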