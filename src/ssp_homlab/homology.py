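"""Pairwise sequence identity and homology reduction.

Identity between two proteins is the number of identical aligned positions
in an optimal global alignment (match +1, mismatch 0, linear gap -1 by
default; ties broken toward the fewest gaps) divided by the length of the
shorter sequence — the CD-HIT convention.  On top of that sit three
reduction procedures:

``reduce_within``
    greedy incremental clustering (longest-first), keeping a sequence only
    if it stays below the cutoff against everything already kept;
``reduce_between``
    one-way removal from dataset B of everything at/above the cutoff to
    dataset A;
``reduce_two_way``
    B' = B - A followed by A' = A - B', which guarantees that no cross-pair
    at/above the cutoff survives and that repeating the procedure removes
    nothing further.

An O(n^2) all-pairs scan (:func:`max_cross_identity`,
:func:`verify_inner_cutoff`) acts as the post-condition oracle for all of
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from ._align import align_stats, batch_align_stats
from .seq import LabeledSequence, SequenceDataset

#: Chunk width for batched scans that still want between-chunk early exit.
_CHUNK = 48


@dataclass(frozen=True)
class ScoringScheme:
    """Integer alignment scores; defaults follow the package convention."""

    match: int = 1
    mismatch: int = 0
    gap: int = -1


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    identity: float
    n_matches: int
    denominator: int


class IdentityCache:
    """Memoises identities between records of a fixed sequence universe.

    Keyed by unordered id pair; safe as long as ids are stable, which the
    synthetic universe guarantees.
    """

    def __init__(self, scoring: ScoringScheme = DEFAULT_SCORING) -> None:
        self.scoring = scoring
        self._store: dict[Tuple[str, str], float] = {}

    def __len__(self) -> int:
        return len(self._store)

    def identity(self, a: LabeledSequence, b: LabeledSequence) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        hit = self._store.get(key)
        if hit is None:
            hit = pairwise_identity(a, b, self.scoring).identity
            self._store[key] = hit
        return hit

    def identities(
        self, a: LabeledSequence, others: Sequence[LabeledSequence]
    ) -> "list[float]":
        """Identities of ``a`` against many records, batching cache misses."""
        out: list[Optional[float]] = []
        miss_idx: list[int] = []
        for i, b in enumerate(others):
            key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
            hit = self._store.get(key)
            out.append(hit)
            if hit is None:
                miss_idx.append(i)
        if miss_idx:
            stats = batch_align_stats(
                a.codes,
                [others[i].codes for i in miss_idx],
                self.scoring.match,
                self.scoring.mismatch,
                self.scoring.gap,
            )
            for i, (_, matches, _) in zip(miss_idx, stats):
                b = others[i]
                value = matches / min(a.length, b.length)
                key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
                self._store[key] = value
                out[i] = value
        return out  # type: ignore[return-value]


def pairwise_identity(
    a: LabeledSequence,
    b: LabeledSequence,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> IdentityResult:
    """Identity = matched positions / length of the shorter sequence."""
    if a.length == 0 or b.length == 0:
        raise ValueError("cannot align an empty sequence")
    _, matches, _ = align_stats(
        a.codes, b.codes, scoring.match, scoring.mismatch, scoring.gap
    )
    denom = min(a.length, b.length)
    return IdentityResult(
        id_a=a.id,
        id_b=b.id,
        identity=matches / denom,
        n_matches=matches,
        denominator=denom,
    )


def _check_cutoff(cutoff: float) -> None:
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")


def _greedy_order(records: Sequence[LabeledSequence]) -> list[LabeledSequence]:
    return sorted(records, key=lambda r: (-r.length, r.id))


def _below_cutoff_all(
    rec: LabeledSequence,
    others: Sequence[LabeledSequence],
    cutoff: float,
    cache: Optional[IdentityCache],
) -> bool:
    """True iff rec stays below the cutoff against every record in others.

    With a cache the scan runs in chunks through the batched kernel while
    still allowing an early exit once a violation is found.
    """
    if cache is None:
        return all(
            pairwise_identity(rec, other).identity < cutoff for other in others
        )
    for start in range(0, len(others), _CHUNK):
        chunk = others[start:start + _CHUNK]
        if any(v >= cutoff for v in cache.identities(rec, chunk)):
            return False
    return True


def reduce_within(
    dataset: SequenceDataset,
    cutoff: float,
    cache: Optional[IdentityCache] = None,
    max_kept: Optional[int] = None,
) -> SequenceDataset:
    """Greedy incremental non-redundancy clustering at the given cutoff.

    Records are visited longest-first (ties by id); a record is kept iff its
    identity to every already-kept record is below the cutoff.  ``max_kept``
    truncates the scan once enough representatives have been collected; the
    all-pairs post-condition holds for the truncated output as well.
    """
    _check_cutoff(cutoff)
    kept: list[LabeledSequence] = []
    for rec in _greedy_order(dataset.records):
        if _below_cutoff_all(rec, kept, cutoff, cache):
            kept.append(rec)
            if max_kept is not None and len(kept) >= max_kept:
                break
    out = SequenceDataset(
        name=f"{dataset.name}~nr{cutoff:g}",
        role=dataset.role,
        records=kept,
        declared_inner_cutoff=cutoff,
        provenance=list(dataset.provenance),
    )
    out.note(
        f"reduce_within cutoff={cutoff:g}: kept {len(kept)}/{len(dataset)}"
        + (f" (truncated at {max_kept})" if max_kept is not None else "")
    )
    return out


def reduce_between(
    b: SequenceDataset,
    a: SequenceDataset,
    cutoff: float,
    cache: Optional[IdentityCache] = None,
) -> SequenceDataset:
    """B minus every record at/above the cutoff to any record of A."""
    _check_cutoff(cutoff)
    survivors = [
        rb for rb in b.records
        if _below_cutoff_all(rb, a.records, cutoff, cache)
    ]
    out = SequenceDataset(
        name=b.name,
        role=b.role,
        records=survivors,
        declared_inner_cutoff=b.declared_inner_cutoff,
        provenance=list(b.provenance),
    )
    out.note(
        f"reduce_between vs {a.name!r} cutoff={cutoff:g}: "
        f"kept {len(survivors)}/{len(b)}"
    )
    return out


def reduce_two_way(
    a: SequenceDataset,
    b: SequenceDataset,
    cutoff: float,
    cache: Optional[IdentityCache] = None,
) -> Tuple[SequenceDataset, SequenceDataset]:
    """Two-way inter-dataset reduction: B' = B - A, then A' = A - B'.

    The returned pair has no cross-pair at/above the cutoff, so re-applying
    the procedure is a no-op.
    """
    b_prime = reduce_between(b, a, cutoff, cache)
    a_prime = reduce_between(a, b_prime, cutoff, cache)
    return a_prime, b_prime


# ---------------------------------------------------------------------------
# All-pairs post-condition oracle (used by tests and fail-fast layout checks)

def max_inner_identity(
    dataset: SequenceDataset, cache: Optional[IdentityCache] = None
) -> float:
    """Largest pairwise identity within a dataset (0.0 if < 2 records)."""
    best = 0.0
    recs = dataset.records
    for i in range(1, len(recs)):
        if cache is not None:
            best = max(best, max(cache.identities(recs[i], recs[:i])))
        else:
            for j in range(i):
                best = max(best, pairwise_identity(recs[i], recs[j]).identity)
    return best


def max_cross_identity(
    a: SequenceDataset | Iterable[LabeledSequence],
    b: SequenceDataset | Iterable[LabeledSequence],
    cache: Optional[IdentityCache] = None,
) -> float:
    """Largest identity across two datasets (0.0 if either is empty)."""
    best = 0.0
    b_list = list(b)
    if not b_list:
        return best
    for ra in a:
        if cache is not None:
            best = max(best, max(cache.identities(ra, b_list)))
        else:
            for rb in b_list:
                best = max(best, pairwise_identity(ra, rb).identity)
    return best


def verify_inner_cutoff(
    dataset: SequenceDataset,
    cutoff: float,
    cache: Optional[IdentityCache] = None,
) -> bool:
    return max_inner_identity(dataset, cache) < cutoff
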