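"""FDI two-digit tooth codes and their geometric arch ordering.

FDI World Dental Federation notation assigns each permanent tooth a two-digit
code: the first digit is the quadrant (1 upper right, 2 upper left, 3 lower
left, 4 lower right), the second the position from the central incisor (1) to
the third molar (8), giving 32 codes per dentition.

Raw FDI numerals are *not* monotone along the arch: within the upper jaw the
codes run 18, 17, ..., 11 across the right quadrant and then 21, 22, ..., 28
across the left.  The combinatorial labeling stages need a per-jaw index that
increases monotonically with the patient's left-right (x) axis, so this module
defines the *arch index*: position 0-15 along one jaw from one end of the arch
to the other (upper: 18..11, 21..28; lower: 48..41, 31..38).
"""

from __future__ import annotations

import numpy as np

UPPER = "upper"
LOWER = "lower"

#: Canonical column order of the N x 32 assignment matrix.
FDI_CODES: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)
)

#: Arch-ordered codes per jaw: arch index 0..15 runs across the arch.
ARCH_ORDER: dict[str, tuple[int, ...]] = {
    UPPER: tuple(range(18, 10, -1)) + tuple(range(21, 29)),
    LOWER: tuple(range(48, 40, -1)) + tuple(range(31, 39)),
}

CODE_TO_COLUMN: dict[int, int] = {c: i for i, c in enumerate(FDI_CODES)}

_JAW_OF_QUADRANT = {1: UPPER, 2: UPPER, 3: LOWER, 4: LOWER}

#: Assignment-matrix column indices belonging to each jaw, in arch order.
JAW_COLUMNS: dict[str, np.ndarray] = {
    jaw: np.array([CODE_TO_COLUMN[c] for c in order])
    for jaw, order in ARCH_ORDER.items()
}

_ARCH_INDEX: dict[int, int] = {
    c: i for order in ARCH_ORDER.values() for i, c in enumerate(order)
}


def is_valid_code(code: int) -> bool:
    return code in CODE_TO_COLUMN


def jaw_of(code: int) -> str:
    """Jaw ('upper'/'lower') a code belongs to."""
    if code not in CODE_TO_COLUMN:
        raise ValueError(f"not an FDI permanent-dentition code: {code}")
    return _JAW_OF_QUADRANT[code // 10]


def arch_index(code: int) -> int:
    """Position 0-15 of a code along its jaw's arch."""
    if code not in _ARCH_INDEX:
        raise ValueError(f"not an FDI permanent-dentition code: {code}")
    return _ARCH_INDEX[code]


def code_at(jaw: str, index: int) -> int:
    """Inverse of (jaw_of, arch_index)."""
    return ARCH_ORDER[jaw][index]


#: arch index of each assignment-matrix column (jaw-local, 0..15).
ARCH_INDEX_OF_COLUMN: np.ndarray = np.array(
    [arch_index(c) for c in FDI_CODES]
)

#: jaw of each assignment-matrix column.
JAW_OF_COLUMN: tuple[str, ...] = tuple(jaw_of(c) for c in FDI_CODES)
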