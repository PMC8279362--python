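"""Experimental dataset layouts and the multi-repeat sampling protocol.

One :class:`LayoutSpec` fully describes a design point: the reference
set(s) that profiles are built against, the training and testing query sets
with their inner/inter homology cutoffs, the query-reference cutoff, and an
independent query set drawn from families withheld from every other role.
:func:`build_layout` realises one random instance of a spec from the
synthetic universe and verifies every declared homology constraint with the
all-pairs oracle before returning.  :func:`run_repeats` re-samples the whole
layout ``n_repeats`` times (fresh reference and query draws each time, with
per-repeat seeds derived from the master seed) and aggregates each measure
as mean and sample standard deviation.

Cutoff fields accept a number in (0, 1], the string ``"All"`` (no
constraint) or — for the train/test relation — ``"NR100"`` (exact-duplicate
removal only).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .homology import (
    IdentityCache,
    _below_cutoff_all,
    max_cross_identity,
    max_inner_identity,
    reduce_within,
)
from .seq import LabeledSequence, SequenceDataset

Cutoff = Union[float, str]  # a fraction, "All", or "NR100"


class SizeExhaustionError(RuntimeError):
    """The universe cannot satisfy a layout constraint at the needed size."""


def _is_all(cutoff: Cutoff) -> bool:
    return isinstance(cutoff, str) and cutoff.lower() == "all"


def _is_nr100(cutoff: Cutoff) -> bool:
    return isinstance(cutoff, str) and cutoff.upper() == "NR100"


def _check_cutoff_field(name: str, value: Cutoff, allow_nr100: bool = False) -> None:
    if isinstance(value, str):
        if _is_all(value) or (allow_nr100 and _is_nr100(value)):
            return
        raise ValueError(f"{name}: unknown cutoff keyword {value!r}")
    if not 0.0 < float(value) <= 1.0:
        raise ValueError(f"{name}: numeric cutoff must be in (0, 1]")


@dataclass
class LayoutSpec:
    """Full description of one experimental design point."""

    reference_size: int = 500
    n_reference_sets: int = 1
    train_size: int = 60
    test_size: int = 60
    independent_size: int = 40
    inner_cutoff_query: Cutoff = 0.9
    inter_cutoff_train_test: Cutoff = "All"
    query_reference_cutoff: Cutoff = "All"
    reference_inner_cutoff: Cutoff = 0.9
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reference_size", "train_size", "test_size", "independent_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_reference_sets not in (1, 2, 3):
            raise ValueError("n_reference_sets must be 1, 2 or 3")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        _check_cutoff_field("inner_cutoff_query", self.inner_cutoff_query)
        _check_cutoff_field(
            "inter_cutoff_train_test", self.inter_cutoff_train_test, allow_nr100=True
        )
        _check_cutoff_field("query_reference_cutoff", self.query_reference_cutoff)
        _check_cutoff_field("reference_inner_cutoff", self.reference_inner_cutoff)


@dataclass
class Layout:
    """One realised layout: reference set(s) plus the three query roles."""

    reference_sets: list[SequenceDataset]
    train: SequenceDataset
    test: SequenceDataset
    independent: SequenceDataset
    withheld_families: set[str] = field(default_factory=set)

    def reference_for(self, group: str) -> SequenceDataset:
        """Reference assignment when references are isolated per role.

        With one set everybody shares it; with two, training keeps its own
        and testing/independent share the second; with three, each role has
        its own.
        """
        order = {"train": 0, "test": 1, "independent": 2}
        idx = min(order[group], len(self.reference_sets) - 1)
        return self.reference_sets[idx]

    @property
    def all_datasets(self) -> list[SequenceDataset]:
        return [*self.reference_sets, self.train, self.test, self.independent]


class PoolCache:
    """Caches non-redundant pools of a fixed universe per cutoff.

    Pool construction is the expensive O(kept^2) step, so pools are shared
    across repeats and across experiments on the same universe.  A pool may
    be truncated (``max_kept``); requesting a larger target rebuilds it.
    """

    def __init__(
        self,
        universe: SequenceDataset,
        cache: Optional[IdentityCache] = None,
        default_target: Optional[int] = None,
    ):
        self.universe = universe
        self.identity_cache = cache or IdentityCache()
        #: Cap on pool sizes when no explicit target is given.  One shared
        #: pool per cutoff keeps layout construction consistent across the
        #: levels of a ladder: per-level pool sizes would slice different
        #: family strata out of the length-ordered greedy sequence.
        self.default_target = default_target
        self._pools: dict[float, tuple[SequenceDataset, Optional[int]]] = {}
        self._families: dict[str, list[LabeledSequence]] = {}
        for rec in universe:
            self._families.setdefault(rec.family_id, []).append(rec)

    @property
    def families(self) -> dict[str, list[LabeledSequence]]:
        return self._families

    def pool(self, cutoff: Cutoff, target: Optional[int] = None) -> SequenceDataset:
        """First ``target`` non-redundant representatives at the cutoff.

        Greedy clustering has a prefix property (the first k kept records do
        not depend on how far the scan ran), so a request is served from any
        cached pool that reaches far enough, sliced to exactly ``target``.
        This keeps pool contents independent of cache history, which seeded
        layout construction relies on.
        """
        if _is_all(cutoff):
            return self.universe
        if target is None:
            target = self.default_target
        cutoff = float(cutoff)
        cached = self._pools.get(cutoff)
        pool = None
        if cached is not None:
            cached_pool, truncated_at = cached
            if truncated_at is None or (
                target is not None and len(cached_pool) >= target
            ):
                pool = cached_pool
        if pool is None:
            max_kept = None if target is None else max(target, 1)
            pool = reduce_within(
                self.universe, cutoff, cache=self.identity_cache, max_kept=max_kept
            )
            truncated = (
                max_kept if (max_kept is not None and len(pool) >= max_kept) else None
            )
            self._pools[cutoff] = (pool, truncated)
        if target is not None and len(pool) > target:
            prefix = SequenceDataset(
                name=pool.name,
                role=pool.role,
                records=pool.records[:target],
                declared_inner_cutoff=pool.declared_inner_cutoff,
            )
            return prefix
        return pool


def _exact_duplicate(candidate: LabeledSequence, chosen: list[LabeledSequence]) -> bool:
    return any(candidate.residues == c.residues for c in chosen)


def build_layout(
    universe: SequenceDataset,
    spec: LayoutSpec,
    rng: np.random.Generator,
    pools: Optional[PoolCache] = None,
    verify: bool = True,
) -> Layout:
    """Realise one random instance of a layout spec.

    Order of construction: withheld families and the independent set first,
    then the reference set(s) from the reference pool, then training and
    testing queries from the query pool subject to the query-reference and
    train-test constraints.  All roles are disjoint by id; a constraint that
    cannot be satisfied raises :class:`SizeExhaustionError` naming it.
    """
    pools = pools or PoolCache(universe)
    ident = pools.identity_cache

    # --- independent set: ancestors of withheld families -------------------
    family_ids = sorted(pools.families)
    if len(family_ids) < spec.independent_size + 2:
        raise SizeExhaustionError(
            "independent set: not enough families in the universe"
        )
    withheld = list(rng.choice(family_ids, size=spec.independent_size, replace=False))
    independent_records = []
    for fam in withheld:
        members = sorted(pools.families[fam], key=lambda r: r.id)
        founders = [r for r in members if r.is_ancestor]
        independent_records.append(founders[0] if founders else members[0])
    independent = SequenceDataset(
        name="independent", role="independent", records=independent_records
    )
    withheld_set = set(withheld)

    n_ref_needed = spec.reference_size * spec.n_reference_sets
    qr_numeric = (
        None if _is_all(spec.query_reference_cutoff)
        else float(spec.query_reference_cutoff)
    )
    tt_cutoff = spec.inter_cutoff_train_test

    def sample_references(excluded_ids: set[str]) -> list[SequenceDataset]:
        ref_pool = pools.pool(spec.reference_inner_cutoff)
        candidates = [
            r for r in ref_pool
            if r.family_id not in withheld_set and r.id not in excluded_ids
        ]
        if len(candidates) < n_ref_needed:
            raise SizeExhaustionError(
                f"reference sets: need {n_ref_needed} sequences at inner "
                f"cutoff {spec.reference_inner_cutoff!r}, pool has "
                f"{len(candidates)}"
            )
        picked = rng.choice(len(candidates), size=n_ref_needed, replace=False)
        sets = []
        for k in range(spec.n_reference_sets):
            recs = [
                candidates[i]
                for i in picked[k * spec.reference_size:(k + 1) * spec.reference_size]
            ]
            sets.append(
                SequenceDataset(
                    name=f"reference-{k + 1}",
                    role="reference",
                    records=recs,
                    declared_inner_cutoff=(
                        None if _is_all(spec.reference_inner_cutoff)
                        else float(spec.reference_inner_cutoff)
                    ),
                )
            )
        return sets

    def sample_queries(
        excluded_ids: set[str],
        reference_records: list[LabeledSequence],
    ) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
        query_pool = pools.pool(spec.inner_cutoff_query)
        candidates = [
            r for r in query_pool
            if r.family_id not in withheld_set and r.id not in excluded_ids
        ]
        order = rng.permutation(len(candidates))
        train_records: list[LabeledSequence] = []
        test_records: list[LabeledSequence] = []
        for idx in order:
            rec = candidates[idx]
            if qr_numeric is not None and not _below_cutoff_all(
                rec, reference_records, qr_numeric, ident
            ):
                continue
            if len(train_records) < spec.train_size:
                train_records.append(rec)
                continue
            if _is_nr100(tt_cutoff):
                if _exact_duplicate(rec, train_records):
                    continue
            elif not _is_all(tt_cutoff):
                if not _below_cutoff_all(
                    rec, train_records, float(tt_cutoff), ident
                ):
                    continue
            test_records.append(rec)
            if len(test_records) >= spec.test_size:
                break
        if len(train_records) < spec.train_size:
            raise SizeExhaustionError(
                f"training set: only {len(train_records)}/{spec.train_size} "
                f"queries satisfy inner cutoff {spec.inner_cutoff_query!r} and "
                f"query-reference cutoff {spec.query_reference_cutoff!r}"
            )
        if len(test_records) < spec.test_size:
            raise SizeExhaustionError(
                f"testing set: only {len(test_records)}/{spec.test_size} "
                f"queries satisfy the train-test cutoff "
                f"{spec.inter_cutoff_train_test!r}"
            )
        return train_records, test_records

    # Without a query-reference constraint, queries are drawn first so the
    # query sets do not depend on how many reference sequences were removed
    # from the pool — reference-axis ladders then vary only the reference.
    if qr_numeric is None:
        train_records, test_records = sample_queries(set(), [])
        query_ids = {r.id for r in train_records} | {r.id for r in test_records}
        reference_sets = sample_references(query_ids)
    else:
        reference_sets = sample_references(set())
        reference_ids = {r.id for ds in reference_sets for r in ds}
        all_reference_records = [r for ds in reference_sets for r in ds]
        train_records, test_records = sample_queries(
            reference_ids, all_reference_records
        )

    inner_declared = (
        None if _is_all(spec.inner_cutoff_query) else float(spec.inner_cutoff_query)
    )
    train = SequenceDataset(
        name="train", role="train", records=train_records,
        declared_inner_cutoff=inner_declared,
    )
    test = SequenceDataset(
        name="test", role="test", records=test_records,
        declared_inner_cutoff=inner_declared,
    )
    layout = Layout(
        reference_sets=reference_sets,
        train=train,
        test=test,
        independent=independent,
        withheld_families=withheld_set,
    )
    for ds in layout.all_datasets:
        ds.note(f"sampled under spec {spec}")
    if verify:
        verify_layout(layout, spec, ident)
    return layout


def verify_layout(layout: Layout, spec: LayoutSpec, cache: IdentityCache) -> None:
    """Fail-fast all-pairs re-verification of every declared constraint."""
    ids_seen: set[str] = set()
    for ds in layout.all_datasets:
        overlap = ids_seen & set(ds.ids)
        if overlap:
            raise AssertionError(f"role overlap on ids: {sorted(overlap)[:5]}")
        ids_seen |= set(ds.ids)

    for ds in (*layout.reference_sets, layout.train, layout.test):
        if ds.declared_inner_cutoff is not None:
            worst = max_inner_identity(ds, cache)
            if worst >= ds.declared_inner_cutoff:
                raise AssertionError(
                    f"{ds.name}: inner identity {worst:.3f} >= declared cutoff "
                    f"{ds.declared_inner_cutoff}"
                )
    tt = spec.inter_cutoff_train_test
    if not _is_all(tt) and not _is_nr100(tt):
        worst = max_cross_identity(layout.train, layout.test, cache)
        if worst >= float(tt):
            raise AssertionError(
                f"train-test identity {worst:.3f} >= declared cutoff {tt}"
            )
    qr = spec.query_reference_cutoff
    if not _is_all(qr):
        for ds in (layout.train, layout.test):
            for ref in layout.reference_sets:
                worst = max_cross_identity(ds, ref, cache)
                if worst >= float(qr):
                    raise AssertionError(
                        f"{ds.name}-{ref.name} identity {worst:.3f} >= "
                        f"declared cutoff {qr}"
                    )
    # Independent queries come from withheld families by construction.
    for ds in (*layout.reference_sets, layout.train, layout.test):
        leaked = {r.family_id for r in ds} & layout.withheld_families
        if leaked:
            raise AssertionError(f"withheld families leaked into {ds.name}: {leaked}")


@dataclass
class RepeatResult:
    """Per-repeat measure dictionaries plus their aggregates."""

    per_repeat: list[dict]
    mean: dict
    sd: dict  # sample standard deviation; absent measures -> None

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)


def run_repeats(
    universe: SequenceDataset,
    spec: LayoutSpec,
    experiment_fn: Callable[[Layout, np.random.Generator, int], dict],
    pools: Optional[PoolCache] = None,
) -> RepeatResult:
    """Execute the sample-train-evaluate protocol ``n_repeats`` times.

    Each repeat gets a fresh layout drawn with the derived seed
    ``spec.seed + repeat_index`` and is scored by ``experiment_fn``, which
    returns a flat measure dictionary.  Aggregation is per measure: mean and
    sample standard deviation (undefined for a single repeat).
    """
    pools = pools or PoolCache(universe)
    per_repeat = []
    for i in range(spec.n_repeats):
        rng = np.random.default_rng(spec.seed + i)
        try:
            layout = build_layout(universe, spec, rng, pools)
        except SizeExhaustionError as exc:
            raise SizeExhaustionError(f"repeat {i}: {exc}") from exc
        measures = experiment_fn(layout, rng, i)
        per_repeat.append(dict(measures))
    keys = sorted({k for m in per_repeat for k in m})
    mean = {k: statistics.fmean(m[k] for m in per_repeat if k in m) for k in keys}
    sd = {
        k: (
            statistics.stdev([m[k] for m in per_repeat if k in m])
            if sum(k in m for m in per_repeat) > 1
            else None
        )
        for k in keys
    }
    return RepeatResult(per_repeat=per_repeat, mean=mean, sd=sd)


def expand_ladder(base: LayoutSpec, field_name: str, levels) -> list[LayoutSpec]:
    """One spec per ladder level, varying a single LayoutSpec field."""
    return [replace(base, **{field_name: level}) for level in levels]
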