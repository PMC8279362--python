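"""Core sequence containers: labelled proteins and role-tagged datasets.

A :class:`LabeledSequence` couples an amino-acid sequence with per-residue
8-state secondary-structure labels (and the derived 3-state labels).  A
:class:`SequenceDataset` is an ordered, uniquely-keyed collection of such
records carrying a role (reference / train / test / independent / universe),
an optional declared non-redundancy cutoff and a free-text provenance trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from . import alphabet
from ._align import encode_residues

ROLES = ("reference", "train", "test", "independent", "universe")


@dataclass(frozen=True)
class LabeledSequence:
    """One protein: residues plus aligned 8-state and 3-state labels."""

    id: str
    residues: str
    ss8: str
    family_id: str = ""
    #: Marks the family's founding sequence in synthetic universes; member
    #: ids carry no rank information, so this is the only centrality marker.
    is_ancestor: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) == 0:
            raise ValueError(f"{self.id}: empty sequence")
        if len(self.residues) != len(self.ss8):
            raise ValueError(
                f"{self.id}: residue/label length mismatch "
                f"({len(self.residues)} vs {len(self.ss8)})"
            )
        alphabet.validate_residues(self.residues)
        alphabet.validate_ss8(self.ss8)

    @property
    def ss3(self) -> str:
        """3-state labels, derived from ss8 under the fixed mapping."""
        return alphabet.ss8_to_ss3(self.ss8)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """Residues encoded as a uint8 index array (cached)."""
        cached = _CODE_CACHE.get(self.residues)
        if cached is None:
            cached = encode_residues(self.residues)
            cached.setflags(write=False)
            _CODE_CACHE[self.residues] = cached
        return cached


# Residue encoding is needed by every alignment; keyed by the string itself
# so equal sequences in different records share one array.
_CODE_CACHE: dict[str, np.ndarray] = {}


@dataclass
class SequenceDataset:
    """A named, role-tagged, uniquely-keyed collection of proteins."""

    name: str
    role: str = "universe"
    records: list[LabeledSequence] = field(default_factory=list)
    declared_inner_cutoff: Optional[float] = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise ValueError(f"duplicate ids in dataset {self.name!r}: {sorted(dup)[:5]}")
        self._index = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> LabeledSequence:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def note(self, message: str) -> None:
        self.provenance.append(message)

    def subset(
        self,
        ids: Iterable[str],
        name: Optional[str] = None,
        role: Optional[str] = None,
    ) -> "SequenceDataset":
        """New dataset with the given records, preserving this one's order."""
        wanted = set(ids)
        missing = wanted - set(self._index)
        if missing:
            raise KeyError(f"ids not in dataset {self.name!r}: {sorted(missing)[:5]}")
        out = SequenceDataset(
            name=name or self.name,
            role=role or self.role,
            records=[r for r in self.records if r.id in wanted],
            declared_inner_cutoff=self.declared_inner_cutoff,
            provenance=list(self.provenance),
        )
        out.note(f"subset of {self.name!r}: {len(out)}/{len(self)} records")
        return out

    def with_role(self, role: str, name: Optional[str] = None) -> "SequenceDataset":
        out = SequenceDataset(
            name=name or self.name,
            role=role,
            records=list(self.records),
            declared_inner_cutoff=self.declared_inner_cutoff,
            provenance=list(self.provenance),
        )
        return out
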