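"""Banded semi-global (free-end-gap) alignment.

Reads are aligned to reference amplicons with a linear-gap DP under the
scheme match +1 / mismatch -1 / gap -2.  End gaps on either sequence are
free, so a query hanging off a target end is clipped rather than penalised
(BLAST-like qcov semantics): coverage is the fraction of the query inside
the aligned core, identity the fraction of matching columns (gap columns
count as non-matches).

The DP is restricted to a diagonal band.  The band is centred on the
length-difference-corrected diagonal window ``[min(0, n-m) - band,
max(0, n-m) + band]``, so a band of ``b`` tolerates ``b`` net indels
regardless of how much longer the target is than the query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_NEG = -(2**28)

_ENCODE = np.full(256, 4, dtype=np.uint8)  # N / unknown -> 4, matches nothing
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class AlignmentBandError(ValueError):
    """The requested band cannot hold any alignment."""


@dataclass
class AlignmentResult:
    """Outcome of one query-vs-target alignment.

    ``identity`` = matches / alignment columns (gaps are columns);
    ``coverage`` = aligned query bases / query length.  ``q_start..q_end``
    and ``t_start..t_end`` delimit the aligned core (0-based, half-open);
    ``n_gap_columns`` counts indel columns inside it.
    """

    score: int
    identity: float
    coverage: float
    matches: int
    columns: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_gap_columns: int
    strand: str = "+"
    accession: str | None = None


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _overlap_align(q, t, band):  # pragma: no cover - exercised via wrapper
    m, n = q.shape[0], t.shape[0]
    lo = min(0, n - m) - band
    hi = max(0, n - m) + band
    H = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    for j in range(n + 1):
        H[0, j] = 0
    for i in range(m + 1):
        H[i, 0] = 0
    for i in range(1, m + 1):
        j0 = max(1, i + lo)
        j1 = min(n, i + hi)
        for j in range(j0, j1 + 1):
            qi = q[i - 1]
            tj = t[j - 1]
            s = 1 if (qi == tj and qi < 4) else -1
            best = H[i - 1, j - 1] + s
            v = H[i - 1, j] - 2
            if v > best:
                best = v
            v = H[i, j - 1] - 2
            if v > best:
                best = v
            H[i, j] = best
    # endpoint: free trailing gaps -> max over last row and last column
    bi, bj, bscore = 0, 0, _NEG
    for j in range(n + 1):
        if H[m, j] > bscore:
            bscore = H[m, j]
            bi, bj = m, j
    for i in range(m + 1):
        if H[i, n] > bscore:
            bscore = H[i, n]
            bi, bj = i, n
    # traceback (diagonal > up > left preference, fixed for determinism)
    i, j = bi, bj
    matches = 0
    columns = 0
    gapcols = 0
    while i > 0 and j > 0:
        qi = q[i - 1]
        tj = t[j - 1]
        s = 1 if (qi == tj and qi < 4) else -1
        if H[i, j] == H[i - 1, j - 1] + s:
            columns += 1
            if s == 1:
                matches += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - 2:
            columns += 1
            gapcols += 1
            i -= 1
        elif H[i, j] == H[i, j - 1] - 2:
            columns += 1
            gapcols += 1
            j -= 1
        else:  # boundary zero reached away from edges cannot happen
            break
    return bscore, matches, columns, i, bi, j, bj, gapcols


def align_semi_global(query: str, target: str, band: int = 16) -> AlignmentResult:
    """Align the query within the target, end gaps free on both sequences.

    Deterministic: ties in the DP are broken by a fixed move preference
    (diagonal, then query-consuming gap, then target-consuming gap) and the
    endpoint by scanning the last row before the last column.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    if band < 1:
        raise AlignmentBandError(f"band must be >= 1, got {band}")
    q = encode(query)
    t = encode(target)
    score, matches, columns, qs, qe, ts, te, gapcols = _overlap_align(q, t, band)
    if score <= _NEG // 2:
        raise AlignmentBandError("no alignment endpoint reachable within band")
    identity = matches / columns if columns else 0.0
    coverage = (qe - qs) / len(query)
    return AlignmentResult(
        score=int(score),
        identity=identity,
        coverage=coverage,
        matches=int(matches),
        columns=int(columns),
        q_start=int(qs),
        q_end=int(qe),
        t_start=int(ts),
        t_end=int(te),
        n_gap_columns=int(gapcols),
    )
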