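"""Exact k-best peptide enumeration over an additive scoring model.

Because the score is a sum of independent per-position weights, the best-k
peptides of the full combinatorial universe (|alphabet|^length sequences) can
be enumerated exactly with a best-first search over the Cartesian product of
score-sorted residue lists, without ever materialising the universe.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

from .landscape import ScoringModel, score_peptide

__all__ = [
    "RankedPeptide",
    "SearchConstraints",
    "top_k",
    "brute_force_top_k",
    "annotate_shared",
    "hamming_distance",
]

BRUTE_FORCE_LIMIT = 10**6


@dataclass(frozen=True)
class RankedPeptide:
    """One entry of a ranked candidate list (rank 1 = best)."""

    sequence: str
    score: float
    rank: int
    shared_mask: tuple[bool, ...] | None = None


@dataclass(frozen=True)
class SearchConstraints:
    """Optional restrictions on the search universe."""

    fixed_positions: dict[int, str] = field(default_factory=dict)
    excluded_sequences: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "excluded_sequences", frozenset(self.excluded_sequences)
        )


def _validate_constraints(model: ScoringModel, constraints: SearchConstraints) -> None:
    for pos, residue in constraints.fixed_positions.items():
        if not 0 <= pos < model.length:
            raise ValueError(f"fixed position {pos} outside 0..{model.length - 1}")
        if residue not in model.alphabet:
            raise ValueError(f"fixed residue {residue!r} not in model alphabet")
    for seq in constraints.excluded_sequences:
        if len(seq) != model.length:
            raise ValueError(f"excluded sequence {seq!r} has wrong length")


def _sorted_residues(
    model: ScoringModel, constraints: SearchConstraints
) -> list[list[str]]:
    """Per-position residue lists sorted by (-weight, residue)."""
    choices: list[list[str]] = []
    for i in range(model.length):
        fixed = constraints.fixed_positions.get(i)
        if fixed is not None:
            choices.append([fixed])
            continue
        order = sorted(
            model.alphabet, key=lambda a: (-model.weights[i, model.residue_index(a)], a)
        )
        choices.append(order)
    return choices


def _score(model: ScoringModel, sequence: str) -> float:
    # Same accumulation order as score_peptide so best-first and brute-force
    # scores are bit-identical, keeping tie detection exact.
    return score_peptide(model, sequence)


def top_k(
    model: ScoringModel,
    k: int,
    constraints: SearchConstraints | None = None,
    index_peptide: str | None = None,
) -> list[RankedPeptide]:
    """Exact top-k peptides of the (constrained) combinatorial universe.

    Sequences are returned in non-increasing score order; exact score ties
    are ordered lexicographically ascending. Identical, sequence for
    sequence, to :func:`brute_force_top_k` wherever the latter is feasible.

    The frontier state is the tuple of per-position indices into
    score-sorted residue lists; successors increment one coordinate and a
    visited set prevents duplicates, so the search is O(k * L * log(k * L)).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    constraints = constraints or SearchConstraints()
    _validate_constraints(model, constraints)
    choices = _sorted_residues(model, constraints)

    def build(state: tuple[int, ...]) -> str:
        return "".join(choices[i][j] for i, j in enumerate(state))

    start = (0,) * model.length
    start_seq = build(start)
    heap: list[tuple[float, str, tuple[int, ...]]] = [
        (-_score(model, start_seq), start_seq, start)
    ]
    visited = {start}
    results: list[RankedPeptide] = []
    while heap and len(results) < k:
        neg_score, sequence, state = heapq.heappop(heap)
        if sequence not in constraints.excluded_sequences:
            rank = len(results) + 1
            mask = (
                annotate_shared(sequence, index_peptide)
                if index_peptide is not None
                else None
            )
            results.append(
                RankedPeptide(
                    sequence=sequence, score=-neg_score, rank=rank, shared_mask=mask
                )
            )
        for i in range(model.length):
            j = state[i] + 1
            if j >= len(choices[i]):
                continue
            nxt = state[:i] + (j,) + state[i + 1 :]
            if nxt in visited:
                continue
            visited.add(nxt)
            seq = build(nxt)
            heapq.heappush(heap, (-_score(model, seq), seq, nxt))
    if not results:
        raise ValueError("constraints empty the search universe")
    return results


def brute_force_top_k(
    model: ScoringModel,
    k: int,
    constraints: SearchConstraints | None = None,
    index_peptide: str | None = None,
) -> list[RankedPeptide]:
    """Testing oracle: full enumeration, sorted by (-score, sequence)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    constraints = constraints or SearchConstraints()
    _validate_constraints(model, constraints)
    choices = _sorted_residues(model, constraints)
    universe = 1
    for c in choices:
        universe *= len(c)
    if universe > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"universe of {universe} sequences exceeds brute-force bound "
            f"{BRUTE_FORCE_LIMIT}"
        )
    scored = []
    for combo in itertools.product(*choices):
        seq = "".join(combo)
        if seq in constraints.excluded_sequences:
            continue
        scored.append((-_score(model, seq), seq))
    scored.sort()
    if not scored:
        raise ValueError("constraints empty the search universe")
    results = []
    for rank, (neg, seq) in enumerate(scored[:k], start=1):
        mask = (
            annotate_shared(seq, index_peptide) if index_peptide is not None else None
        )
        results.append(
            RankedPeptide(sequence=seq, score=-neg, rank=rank, shared_mask=mask)
        )
    return results


def annotate_shared(sequence: str, index_peptide: str) -> tuple[bool, ...]:
    """Per-position mask: True where the candidate matches the index epitope."""
    if len(sequence) != len(index_peptide):
        raise ValueError("sequence and index peptide lengths differ")
    return tuple(a == b for a, b in zip(sequence, index_peptide))


def hamming_distance(sequence: str, index_peptide: str) -> int:
    """Number of positions at which the candidate differs from the index."""
    return sum(not same for same in annotate_shared(sequence, index_peptide))
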