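"""Numba-accelerated global alignment kernel used by the homology module.

The kernel maximises the global alignment score ``match*M + mismatch*X +
gap*G`` (M matched columns, X mismatched columns, G gap columns) and, among
score-optimal alignments, minimises the number of gap columns.  Preferring
substitutions over indels is the conventional tie-break and makes the match
count of the reported alignment unique: with aligned pairs
``P = (len_a + len_b - G) / 2``, the identities follow from the score as
``M = (S - gap*G - mismatch*P) / (match - mismatch)``.

Scores must be integers (the defaults are +1/0/-1) so that score and gap
count can be packed into one int64 for a single-comparison DP.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Fixed residue order used to encode sequences as uint8 arrays.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Gap counts fit below _SCALE, so packed = score*_SCALE - gaps compares
# (score, -gaps) lexicographically in one integer comparison.
_SCALE = 1 << 20


def encode_residues(seq: str) -> np.ndarray:
    """Encode an amino-acid string as a uint8 index array."""
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal amino-acid letter {exc.args[0]!r}") from exc


@njit(cache=True)
def _packed_kernel(a, b, match, mismatch, gap, scale):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    gap_step = gap * scale - 1
    prev = np.empty(m + 1, dtype=np.int64)
    cur = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):
        prev[j] = gap_step * j
    for i in range(1, n + 1):
        cur[0] = gap_step * i
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                best = prev[j - 1] + match * scale
            else:
                best = prev[j - 1] + mismatch * scale
            up = prev[j] + gap_step
            if up > best:
                best = up
            left = cur[j - 1] + gap_step
            if left > best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _batch_packed_kernel(a, bcat, starts, ends, match, mismatch, gap, scale):  # pragma: no cover - jit
    n_targets = starts.shape[0]
    out = np.empty(n_targets, dtype=np.int64)
    for t in range(n_targets):
        out[t] = _packed_kernel(a, bcat[starts[t]:ends[t]], match, mismatch, gap, scale)
    return out


def batch_align_stats(
    a: np.ndarray,
    targets: "list[np.ndarray]",
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> "list[tuple[int, int, int]]":
    """Vector of ``(score, n_matches, n_gaps)`` for one query vs many targets.

    Semantically identical to calling :func:`align_stats` per pair; one jit
    call amortises the per-call dispatch overhead.
    """
    if match == mismatch:
        raise ValueError("match and mismatch scores must differ")
    if not targets:
        return []
    lengths = np.fromiter((t.shape[0] for t in targets), dtype=np.int64,
                          count=len(targets))
    ends = np.cumsum(lengths)
    starts = ends - lengths
    bcat = np.concatenate(targets)
    n = a.shape[0]
    if n + int(lengths.max()) >= _SCALE:
        raise ValueError("sequences too long for the packed DP kernel")
    packed = _batch_packed_kernel(
        a, bcat, starts, ends, int(match), int(mismatch), int(gap), _SCALE
    )
    results = []
    for t, p in enumerate(packed):
        p = int(p)
        gaps = -(p % _SCALE) % _SCALE
        score = (p + gaps) // _SCALE
        pairs = (n + int(lengths[t]) - gaps) // 2
        matches = (score - gap * gaps - mismatch * pairs) // (match - mismatch)
        results.append((score, matches, gaps))
    return results


@njit(cache=True)
def _traceback_kernel(a, b, match, mismatch, gap, scale):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    gap_step = gap * scale - 1
    dp = np.empty((n + 1, m + 1), dtype=np.int64)
    for j in range(m + 1):
        dp[0, j] = gap_step * j
    for i in range(1, n + 1):
        dp[i, 0] = gap_step * i
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                best = dp[i - 1, j - 1] + match * scale
            else:
                best = dp[i - 1, j - 1] + mismatch * scale
            up = dp[i - 1, j] + gap_step
            if up > best:
                best = up
            left = dp[i, j - 1] + gap_step
            if left > best:
                best = left
            dp[i, j] = best
    mapping = np.full(n, -1, dtype=np.int64)
    i, j = n, m
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1]:
            diag = dp[i - 1, j - 1] + match * scale
        else:
            diag = dp[i - 1, j - 1] + mismatch * scale
        if dp[i, j] == diag:
            mapping[i - 1] = j - 1
            i -= 1
            j -= 1
        elif dp[i, j] == dp[i - 1, j] + gap_step:
            i -= 1
        else:
            j -= 1
    return mapping


def alignment_map(
    a: np.ndarray,
    b: np.ndarray,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> np.ndarray:
    """Positions of ``b`` aligned to each position of ``a`` (-1 where gapped).

    Follows one optimal alignment under the same (score, fewest-gaps)
    objective as :func:`align_stats`, preferring aligned pairs during the
    traceback.
    """
    if match == mismatch:
        raise ValueError("match and mismatch scores must differ")
    if a.shape[0] + b.shape[0] >= _SCALE:
        raise ValueError("sequences too long for the packed DP kernel")
    return _traceback_kernel(a, b, int(match), int(mismatch), int(gap), _SCALE)


def align_stats(
    a: np.ndarray,
    b: np.ndarray,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> tuple[int, int, int]:
    """Return ``(score, n_matches, n_gaps)`` of the optimal global alignment.

    Ties in score are broken toward the fewest gap columns.
    """
    if match == mismatch:
        raise ValueError("match and mismatch scores must differ")
    n, m = a.shape[0], b.shape[0]
    if n + m >= _SCALE:
        raise ValueError("sequences too long for the packed DP kernel")
    packed = int(_packed_kernel(a, b, int(match), int(mismatch), int(gap), _SCALE))
    gaps = -(packed % _SCALE) % _SCALE
    score = (packed + gaps) // _SCALE
    pairs = (n + m - gaps) // 2
    matches = (score - gap * gaps - mismatch * pairs) // (match - mismatch)
    return score, matches, gaps
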