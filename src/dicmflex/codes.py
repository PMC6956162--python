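"""Frequency bands, frequency codes, and estimator identities.

The analysis decomposes each channel into 8 canonical frequency bands and
labels every coupling candidate with an integer *frequency code*:

* codes 1-8  — within-band coupling (delta ... gamma, in band order),
* codes 9-36 — the 28 ordered low<high band pairs, lexicographic by
  (low band index, high band index),
* code 0     — reserved for "no significant coupling".

Five coupling estimators are identified by integer ids 1-5.
"""

from __future__ import annotations

import itertools
from enum import IntEnum

#: (name, low edge Hz, high edge Hz); edges are half-open [lo, hi).
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha1", 8.0, 10.0),
    ("alpha2", 10.0, 13.0),
    ("beta1", 13.0, 15.0),
    ("beta2", 15.0, 19.0),
    ("beta3", 20.0, 29.0),
    ("gamma", 30.0, 45.0),
)

N_BANDS = len(BANDS)
BAND_NAMES = tuple(b[0] for b in BANDS)
BAND_INDEX = {name: i for i, name in enumerate(BAND_NAMES)}

#: Ordered low<high band-index pairs, lexicographic — the 28 cross-band pairs.
CROSS_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(N_BANDS), 2)
)
N_CROSS_PAIRS = len(CROSS_PAIRS)

#: Total number of non-null frequency codes (8 within + 28 cross).
N_CODES = N_BANDS + N_CROSS_PAIRS

_CROSS_CODE = {pair: N_BANDS + 1 + i for i, pair in enumerate(CROSS_PAIRS)}


class Estimator(IntEnum):
    """Integer identities of the five coupling estimators."""

    AEC = 1     # amplitude envelope correlation
    IPLV = 2    # same-frequency imaginary phase-locking value
    PAC = 3     # phase-amplitude coupling (cross-frequency iPLV)
    DSTE = 4    # delay symbolic transfer entropy
    DPLI = 5    # directed phase-lag index


#: Frequency codes each estimator may report.  Same-frequency iPLV is
#: within-band only; PAC is cross-band only; the rest cover both.
ADMISSIBLE_CODES: dict[int, tuple[int, ...]] = {
    int(Estimator.AEC): tuple(range(1, N_CODES + 1)),
    int(Estimator.IPLV): tuple(range(1, N_BANDS + 1)),
    int(Estimator.PAC): tuple(range(N_BANDS + 1, N_CODES + 1)),
    int(Estimator.DSTE): tuple(range(1, N_CODES + 1)),
    int(Estimator.DPLI): tuple(range(1, N_CODES + 1)),
}


def within_code(band: int | str) -> int:
    """Frequency code of within-band coupling in ``band`` (index or name)."""
    i = BAND_INDEX[band] if isinstance(band, str) else int(band)
    if not 0 <= i < N_BANDS:
        raise ValueError(f"band index out of range: {i}")
    return i + 1


def cross_code(low: int | str, high: int | str) -> int:
    """Frequency code of cross-band coupling between ``low`` and ``high``."""
    i = BAND_INDEX[low] if isinstance(low, str) else int(low)
    j = BAND_INDEX[high] if isinstance(high, str) else int(high)
    if i >= j:
        raise ValueError(f"low band must precede high band, got ({i}, {j})")
    return _CROSS_CODE[(i, j)]


def bands_of_code(code: int) -> tuple[int, int | None]:
    """Inverse of the code table: (low band index, high band index or None).

    ``None`` in the second slot marks a within-band code.
    """
    if not 1 <= code <= N_CODES:
        raise ValueError(f"frequency code out of range: {code}")
    if code <= N_BANDS:
        return code - 1, None
    return CROSS_PAIRS[code - N_BANDS - 1]


def is_cross(code: int) -> bool:
    return code > N_BANDS
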