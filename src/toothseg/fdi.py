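"""FDI two-digit tooth numbering and its mapping onto mask channels.

The FDI (Fédération Dentaire Internationale) system divides the permanent
dentition into four quadrants (1 upper right, 2 upper left, 3 lower left,
4 lower right) with positions 1 (central incisor) through 8 (third molar)
inside each quadrant, giving 32 codes such as 17 = upper-right second molar.

A :class:`FDILabelMap` fixes the bijection between the 32 mask channels of a
:class:`~toothseg.synthetic.ToothMaskStack` and the FDI codes.  The canonical
channel order is quadrant 1 from the third molar inward (18..11), then
quadrant 2 outward (21..28), then quadrant 3 (31..38), then quadrant 4 from
the third molar inward (48..41).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FDILabelMap",
    "build_fdi_label_map",
    "fdi_flip_permutation",
    "CANONICAL_FDI_ORDER",
]

#: Channel-ordered FDI codes: one row per quadrant, read left-to-right as a
#: clinician reads a panoramic film (patient's right appears on the left).
CANONICAL_FDI_ORDER: tuple[int, ...] = (
    18, 17, 16, 15, 14, 13, 12, 11,
    21, 22, 23, 24, 25, 26, 27, 28,
    31, 32, 33, 34, 35, 36, 37, 38,
    48, 47, 46, 45, 44, 43, 42, 41,
)


@dataclass(frozen=True)
class FDILabelMap:
    """Bijection between mask-channel indices 0..31 and FDI tooth codes."""

    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.codes) != 32 or len(set(self.codes)) != 32:
            raise ValueError("label map must contain 32 distinct FDI codes")
        for code in self.codes:
            q, p = divmod(code, 10)
            if q not in (1, 2, 3, 4) or p not in range(1, 9):
                raise ValueError(f"invalid FDI code {code}")

    def __len__(self) -> int:
        return 32

    def channel_of(self, fdi_code: int) -> int:
        """Channel index carrying the given FDI code."""
        try:
            return self.codes.index(fdi_code)
        except ValueError:
            raise KeyError(f"FDI code {fdi_code} not in label map") from None

    def code_of(self, channel: int) -> int:
        return self.codes[channel]

    def quadrant_of(self, channel: int) -> int:
        return self.codes[channel] // 10

    def position_of(self, channel: int) -> int:
        return self.codes[channel] % 10

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {"channels": {str(i): c for i, c in enumerate(self.codes)}}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FDILabelMap":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"label-map sidecar not found: {path}")
        payload = json.loads(path.read_text())
        channels = payload.get("channels")
        if channels is None or len(channels) != 32:
            raise ValueError(f"malformed label-map sidecar {path}: expected 32 channels")
        codes = tuple(int(channels[str(i)]) for i in range(32))
        return cls(codes)


def build_fdi_label_map() -> FDILabelMap:
    """Return the canonical 32-entry channel/FDI map."""
    return FDILabelMap(CANONICAL_FDI_ORDER)


def fdi_flip_permutation(label_map: FDILabelMap | None = None) -> np.ndarray:
    """Channel permutation induced by mirroring the image left-right.

    A horizontal flip swaps the patient's left and right sides, i.e.
    quadrant 1 <-> 2 and quadrant 4 <-> 3 at equal position (FDI 11 <-> 21,
    48 <-> 38, ...).  Returns ``perm`` such that flipped-mask channel ``k``
    should carry original channel ``perm[k]``; the permutation is an
    involution.
    """
    if label_map is None:
        label_map = build_fdi_label_map()
    mirror = {1: 2, 2: 1, 3: 4, 4: 3}
    perm = np.empty(32, dtype=np.intp)
    for k, code in enumerate(label_map.codes):
        q, p = divmod(code, 10)
        perm[k] = label_map.channel_of(mirror[q] * 10 + p)
    return perm
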