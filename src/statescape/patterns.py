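"""Binary activity-pattern codes.

An activity pattern of ``N`` binary units, each either active (+1) or
inactive (−1), is stored as an integer code in ``[0, 2**N)``.  Bit ``i``
of the code (least-significant bit = unit 0) is 1 when unit ``i`` is
active.  This encoding is fixed package-wide so that energies, basin
assignments and trajectories can be exchanged as plain integer arrays.
"""

from __future__ import annotations

import numpy as np

#: Largest unit count for which exhaustive 2**N enumeration is allowed.
MAX_ENUM_NODES = 20


def check_enumerable(n_nodes: int) -> None:
    """Raise if ``2**n_nodes`` patterns are too many to enumerate."""
    if n_nodes > MAX_ENUM_NODES:
        raise ValueError(
            f"n_nodes={n_nodes} exceeds the exhaustive-enumeration guard "
            f"({MAX_ENUM_NODES}); pattern enumeration would need 2**{n_nodes} states"
        )


def pattern_matrix(n_nodes: int) -> np.ndarray:
    """All ``2**n_nodes`` patterns as a ``(2**N, N)`` array of ±1 (int8).

    Row ``k`` is the pattern with code ``k``.
    """
    check_enumerable(n_nodes)
    codes = np.arange(2**n_nodes, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n_nodes)) & 1
    return (2 * bits - 1).astype(np.int8)


def code_to_pattern(code: int, n_nodes: int) -> np.ndarray:
    """Decode an integer code into a length-``N`` ±1 vector."""
    bits = (int(code) >> np.arange(n_nodes)) & 1
    return (2 * bits - 1).astype(np.int8)


def pattern_to_code(pattern: np.ndarray) -> int:
    """Encode a length-``N`` ±1 vector into its integer code."""
    pattern = np.asarray(pattern)
    bits = (pattern > 0).astype(np.int64)
    return int(bits @ (1 << np.arange(pattern.shape[-1], dtype=np.int64)))


def series_to_codes(values: np.ndarray) -> np.ndarray:
    """Vectorized encoding of a ``(T, N)`` ±1 matrix into T codes."""
    values = np.asarray(values)
    bits = (values > 0).astype(np.int64)
    weights = 1 << np.arange(values.shape[1], dtype=np.int64)
    return bits @ weights


def neighbor_codes(n_nodes: int) -> np.ndarray:
    """``(2**N, N)`` array: entry ``[k, i]`` is code ``k`` with bit ``i`` flipped.

    Two patterns are adjacent when they differ at exactly one unit, so row
    ``k`` lists the N Hamming-distance-1 neighbours of pattern ``k``.
    """
    check_enumerable(n_nodes)
    codes = np.arange(2**n_nodes, dtype=np.int64)
    return codes[:, None] ^ (1 << np.arange(n_nodes, dtype=np.int64))
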