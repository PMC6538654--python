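"""Compiled inner loops for k-mer counting over shuffled sequence windows.

Sequences are encoded as int8 arrays with A,C,G,T -> 0..3 and any other
(ambiguity) letter -> 4. K-mers touching a code >= 4 are skipped, in the
observed sequence and in every shuffle alike.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def count_codes(codes: np.ndarray, k: int, out: np.ndarray) -> None:
    """Accumulate overlapping k-mer counts of one encoded sequence into ``out``.

    ``out`` must have length 4**k. Rolling 2-bit code; a run counter
    resets whenever a non-ACGT letter interrupts the window.
    """
    L = codes.shape[0]
    mask = (1 << (2 * k)) - 1
    code = 0
    run = 0
    for j in range(L):
        b = codes[j]
        if b < 4:
            code = ((code << 2) | b) & mask
            run += 1
        else:
            code = 0
            run = 0
        if run >= k:
            out[code] += 1


@nb.njit(cache=True)
def shuffle_count(
    letters: np.ndarray, jmat: np.ndarray, k: int, counts: np.ndarray
) -> None:
    """Fisher-Yates shuffle + k-mer count for a block of permutations.

    ``jmat`` holds pre-drawn swap targets: row r, column t is the swap
    index for position i = L-1-t (an integer in [0, i]). Each row of
    ``counts`` (shape n_rows x 4**k) receives the k-mer counts of one
    permuted copy of ``letters``.
    """
    n = jmat.shape[0]
    L = letters.shape[0]
    mask = (1 << (2 * k)) - 1
    buf = np.empty(L, np.int8)
    for r in range(n):
        buf[:] = letters
        for i in range(L - 1, 0, -1):
            j = jmat[r, L - 1 - i]
            t = buf[i]
            buf[i] = buf[j]
            buf[j] = t
        code = 0
        run = 0
        for j in range(L):
            b = buf[j]
            if b < 4:
                code = ((code << 2) | b) & mask
                run += 1
            else:
                code = 0
                run = 0
            if run >= k:
                counts[r, code] += 1
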