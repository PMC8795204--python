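"""Static conference matrices used to build definitive screening designs.

A conference matrix C of order n has zero diagonal, off-diagonal entries in
{-1, +1}, and satisfies C Cᵀ = (n-1) I.  Stacking [C; -C; 0] gives a
three-level screening design whose non-center runs come in mirror pairs and
whose main-effect columns are mutually orthogonal.

Matrices below were constructed by Paley's method (orders 6, 8, 12, 14 from
primes 5, 7, 11, 13; order 10 over GF(9)) and, for order 16, by subtracting
the identity from a doubled skew-Hadamard matrix.  Each was verified to
satisfy C Cᵀ = Cᵀ C = (n-1) I before being frozen here.
"""

from __future__ import annotations

import numpy as np

_ENC = {"+": 1, "-": -1, "0": 0}

_MATRICES: dict[int, tuple[str, ...]] = {
    6: (
        "0+++++",
        "+0+--+",
        "++0+--",
        "+-+0+-",
        "+--+0+",
        "++--+0",
    ),
    8: (
        "0+++++++",
        "-0--+-++",
        "-+0--+-+",
        "-++0--+-",
        "--++0--+",
        "-+-++0--",
        "--+-++0-",
        "---+-++0",
    ),
    10: (
        "0+++++++++",
        "+0+++--+--",
        "++0+-+--+-",
        "+++0--+--+",
        "++--0+++--",
        "+-+-+0+-+-",
        "+--+++0--+",
        "++--+--0++",
        "+-+--+-+0+",
        "+--+--+++0",
    ),
    12: (
        "0+++++++++++",
        "-0-+---+++-+",
        "-+0-+---+++-",
        "--+0-+---+++",
        "-+-+0-+---++",
        "-++-+0-+---+",
        "-+++-+0-+---",
        "--+++-+0-+--",
        "---+++-+0-+-",
        "----+++-+0-+",
        "-+---+++-+0-",
        "--+---+++-+0",
    ),
    14: (
        "0+++++++++++++",
        "+0+-++----++-+",
        "++0+-++----++-",
        "+-+0+-++----++",
        "++-+0+-++----+",
        "+++-+0+-++----",
        "+-++-+0+-++---",
        "+--++-+0+-++--",
        "+---++-+0+-++-",
        "+----++-+0+-++",
        "++----++-+0+-+",
        "+++----++-+0+-",
        "+-++----++-+0+",
        "++-++----++-+0",
    ),
    16: (
        "0+++++++++++++++",
        "-0--+-++-+--+-++",
        "-+0--+-+-++--+-+",
        "-++0--+--+++--+-",
        "--++0--+--+++--+",
        "-+-++0---+-+++--",
        "--+-++0---+-+++-",
        "---+-++0---+-+++",
        "-+++++++0-------",
        "----+-+++0++-+--",
        "-+---+-++-0++-+-",
        "-++---+-+--0++-+",
        "--++---+++--0++-",
        "-+-++---+-+--0++",
        "--+-++--++-+--0+",
        "---+-++-+++-+--0",
    ),
}

AVAILABLE_ORDERS: tuple[int, ...] = tuple(sorted(_MATRICES))


def conference_matrix(order: int) -> np.ndarray:
    """Return the stored conference matrix of the given order as an int array."""
    if order not in _MATRICES:
        raise KeyError(f"no conference matrix stored for order {order}; "
                       f"available orders: {AVAILABLE_ORDERS}")
    rows = _MATRICES[order]
    return np.array([[_ENC[c] for c in row] for row in rows], dtype=int)
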