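"""The closed enumeration of MRI sequence types handled by the pipeline.

Fifteen acquisition types are recognised; the tuple order below is the
canonical order used everywhere a deterministic ordering over sequences is
needed (manifest validation, subset enumeration, report columns).
"""

from __future__ import annotations

SEQUENCE_TYPES: tuple[str, ...] = (
    "ADC",
    "DWI",
    "dynamicaxi",
    "dynamicsag",
    "fsT1axi",
    "fsT1CEaxi",
    "fsT1CEcor",
    "fsT1CEsag",
    "fsT1sag",
    "fsT2axi",
    "T1axi",
    "T1sag",
    "T2axi",
    "T2cor",
    "T2sag",
)

SEQUENCE_INDEX: dict[str, int] = {s: i for i, s in enumerate(SEQUENCE_TYPES)}


def validate_sequence(name: str) -> str:
    if name not in SEQUENCE_INDEX:
        raise ValueError(
            f"unknown sequence type {name!r}; allowed: {', '.join(SEQUENCE_TYPES)}"
        )
    return name
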