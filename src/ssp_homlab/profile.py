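"""Sequence profiles: homolog search, PSSM construction and entropy.

The profile stage mirrors what a PSI-BLAST pass provides to a secondary
structure predictor, reduced to its desk-scale essentials: an exhaustive
pairwise-alignment search of the reference set (hit list capped like
PSI-BLAST's default of 500), a single-pass position-specific probability
matrix with background pseudocounts, log-odds columns in bits, and the
per-position Shannon entropy

    S = -sum_s p_s log2 p_s

whose length-weighted mean over a query set quantifies how much diversity
the reference set injected into the profiles.  HMM-style integer scores can
be converted to probabilities with ``hmm_to_prob`` (p = 2^(-h/1000)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._align import AA_ORDER, align_stats, alignment_map
from .homology import IdentityCache, ScoringScheme, DEFAULT_SCORING, pairwise_identity
from .seq import LabeledSequence, SequenceDataset

LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class Hit:
    """One reference sequence aligned to the query."""

    record: LabeledSequence
    identity: float
    #: query index -> hit index or -1 where the query position is gapped.
    query_to_hit: np.ndarray


@dataclass
class ProfileMatrix:
    """Per-query PSSM: probabilities, log-odds, per-position entropy."""

    query_id: str
    probs: np.ndarray          # L x 20, rows sum to 1
    log_odds: np.ndarray       # L x 20, bits relative to background
    position_entropy: np.ndarray  # length L
    n_hits: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("profile columns must sum to 1")
        if np.any(self.position_entropy < -1e-12) or np.any(
            self.position_entropy > LOG2_20 + 1e-12
        ):
            raise ValueError("entropy out of [0, log2 20]")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def mean_entropy(self) -> float:
        return float(self.position_entropy.mean())


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of one probability column; 0*log2(0) := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("input must be a probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def hmm_to_prob(h: float) -> float:
    """Convert a non-negative HMM integer score to a probability."""
    if h < 0:
        raise ValueError("HMM scores are non-negative")
    return float(2.0 ** (-h / 1000.0))


def _alignment_map(query: LabeledSequence, hit: LabeledSequence,
                   scoring: ScoringScheme) -> np.ndarray:
    """Map query positions to hit positions along one optimal alignment.

    Synthetic homologs carry no indels, so the common case is the identity
    map; unequal lengths fall back to a full DP traceback.
    """
    if query.length == hit.length:
        # Gapless alignment is optimal whenever it achieves the DP score.
        score, _, gaps = align_stats(
            query.codes, hit.codes, scoring.match, scoring.mismatch, scoring.gap
        )
        if gaps == 0:
            return np.arange(query.length)
    return alignment_map(
        query.codes, hit.codes, scoring.match, scoring.mismatch, scoring.gap
    )


def search_homologs(
    query: LabeledSequence,
    reference: SequenceDataset,
    max_hits: int = 500,
    min_identity: float = 0.25,
    cache: Optional[IdentityCache] = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[Hit]:
    """Exhaustive identity search of the reference set.

    Hits at/above ``min_identity`` are sorted by identity descending (ties
    by id) and truncated to ``max_hits`` — the same cap PSI-BLAST applies to
    its hit list, which is what couples reference-set diversity to profile
    entropy.
    """
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    records = [rec for rec in reference if rec.id != query.id]
    if cache is not None:
        identities = cache.identities(query, records)
    else:
        identities = [
            pairwise_identity(query, rec, scoring).identity for rec in records
        ]
    scored = [
        (identity, rec)
        for identity, rec in zip(identities, records)
        if identity >= min_identity
    ]
    scored.sort(key=lambda t: (-t[0], t[1].id))
    hits = []
    for identity, rec in scored[:max_hits]:
        hits.append(
            Hit(
                record=rec,
                identity=identity,
                query_to_hit=_alignment_map(query, rec, scoring),
            )
        )
    return hits


def build_pssm(
    query: LabeledSequence,
    hits: Sequence[Hit],
    pseudocount_weight: float = 1.0,
    background: Optional[np.ndarray] = None,
) -> ProfileMatrix:
    """Single-pass profile with background pseudocounts.

    Per position, observed counts accumulate the query residue plus every
    hit residue aligned there (gapped hits contribute nothing); then
    ``p = (c + beta*b) / (sum(c) + beta)`` and log-odds are log2(p/b).
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or np.any(background <= 0) or abs(
        background.sum() - 1.0
    ) > 1e-9:
        raise ValueError("background must be a positive 20-state probability vector")
    length = query.length
    counts = np.zeros((length, 20))
    counts[np.arange(length), query.codes] += 1.0
    for hit in hits:
        mapped = hit.query_to_hit
        valid = mapped >= 0
        counts[np.where(valid)[0], hit.record.codes[mapped[valid]]] += 1.0
    beta = float(pseudocount_weight)
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + beta * background) / (totals + beta)
    if beta == 0.0:
        probs = counts / totals
    with np.errstate(divide="ignore"):
        log_odds = np.where(probs > 0, np.log2(np.maximum(probs, 1e-300) / background), -np.inf)
    nz = np.where(probs > 0, probs, 1.0)
    position_entropy = -(nz * np.log2(nz) * (probs > 0)).sum(axis=1)
    position_entropy = np.clip(position_entropy, 0.0, LOG2_20)
    return ProfileMatrix(
        query_id=query.id,
        probs=probs,
        log_odds=log_odds,
        position_entropy=position_entropy,
        n_hits=len(hits),
    )


def weighted_mean_entropy(profiles: Sequence[ProfileMatrix]) -> float:
    """Length-weighted mean of per-profile mean entropies."""
    if not profiles:
        raise ValueError("empty profile collection")
    total_len = sum(p.length for p in profiles)
    return sum(p.length * p.mean_entropy for p in profiles) / total_len


def write_pssm_ascii(profile: ProfileMatrix, query: LabeledSequence, path) -> None:
    """PSI-BLAST-style ASCII matrix: 20 log-odds then 20 percentage columns."""
    header = "            " + "   ".join(AA_ORDER) + "    " + "   ".join(AA_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(header + "\n")
        for i in range(profile.length):
            odds = " ".join(
                f"{0 if np.isinf(v) else v:5.1f}" for v in profile.log_odds[i]
            )
            pcts = " ".join(f"{100 * v:5.1f}" for v in profile.probs[i])
            fh.write(f"{i + 1:5d} {query.residues[i]} {odds}  {pcts}\n")


def write_pssm_csv(profile: ProfileMatrix, path) -> None:
    """Tabular CSV export: position, entropy, 20 probabilities, 20 log-odds."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pos", "entropy"]
            + [f"p_{aa}" for aa in AA_ORDER]
            + [f"lo_{aa}" for aa in AA_ORDER]
        )
        for i in range(profile.length):
            writer.writerow(
                [i + 1, f"{profile.position_entropy[i]:.6f}"]
                + [f"{v:.6f}" for v in profile.probs[i]]
                + [f"{v:.4f}" for v in profile.log_odds[i]]
            )
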