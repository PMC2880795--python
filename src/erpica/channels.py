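"""Canonical 19-channel 10-20 electrode montage.

The 10-20 system names the electrodes but prescribes no serialization
order, so a fixed order is frozen here for all file round-trips and
matrix row conventions.
"""

from __future__ import annotations

CANONICAL_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


def channel_index(name: str, channel_order: tuple[str, ...] = CANONICAL_19) -> int:
    """Index of an electrode in the canonical row order."""
    try:
        return channel_order.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; expected one of {channel_order}") from None
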