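"""In-silico mutational scanning: the L x 20 significance map.

Every position of a sequence is substituted by every amino acid and each
mutant is scored by the level-0 ensemble's soft score (the mean of the
three component models' ROSes probabilities — a hard vote would give a
two-valued map and destroy the continuous structure).  Entry (i, a) is the
probability that the sequence with residue i replaced by amino acid a is a
ROSes; the wild-type cell of every row equals the wild-type probability.

Conserved sites are positions where mutation hurts: the conservation score
of position i is the wild-type probability minus the mean probability over
the 19 non-wild-type substitutions, and positions whose score lies strictly
above a configurable quantile of all positional scores are flagged.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .config import ALPHABET, AA_INDEX, N_AA, validate_sequence


class SequenceScorer(Protocol):
    """Anything exposing batch ROSes probabilities (e.g. Level0Ensemble)."""

    def positive_proba(self, sequences: Sequence[str]) -> np.ndarray: ...


@dataclasses.dataclass
class SignificanceMap:
    sequence_id: str
    wild_type: str
    matrix: np.ndarray  # (L, 20), columns in ALPHABET order

    def __post_init__(self) -> None:
        L = len(self.wild_type)
        if self.matrix.shape != (L, N_AA):
            raise ValueError(f"matrix must be {L} x {N_AA}, got {self.matrix.shape}")

    @property
    def wild_type_probability(self) -> float:
        return float(self.matrix[0, AA_INDEX[self.wild_type[0]]])

    def conservation_scores(self) -> np.ndarray:
        """Per-position wild-type-minus-mean-mutant probability drop."""
        L = len(self.wild_type)
        wt_idx = np.array([AA_INDEX[a] for a in self.wild_type])
        wt_prob = self.matrix[np.arange(L), wt_idx]
        mutant_sum = self.matrix.sum(axis=1) - wt_prob
        return wt_prob - mutant_sum / (N_AA - 1)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("position\twild_type\t" + "\t".join(ALPHABET) + "\n")
        for i in range(len(self.wild_type)):
            vals = "\t".join(f"{v:.6f}" for v in self.matrix[i])
            buf.write(f"{i + 1}\t{self.wild_type[i]}\t{vals}\n")
        return buf.getvalue()


@dataclasses.dataclass
class ConservationCall:
    position: int  # 1-based
    conservation_score: float
    is_conserved: bool


def apply_mutation(sequence: str, position: int, new_residue: str) -> str:
    """Substitute the residue at a 1-based position."""
    if new_residue not in AA_INDEX:
        raise ValueError(f"invalid residue {new_residue!r}")
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    i = position - 1
    return sequence[:i] + new_residue + sequence[i + 1:]


def build_significance_map(
    sequence: str,
    scorer: SequenceScorer,
    *,
    sequence_id: str = "seq",
) -> SignificanceMap:
    """Score all L x 20 single-residue substitutions with the level-0 scorer.

    The wild-type probability is computed once and broadcast into every
    row's wild-type cell; the 19 L true mutants are scored in one batch.
    """
    validate_sequence(sequence, context=f"sequence {sequence_id!r}")
    L = len(sequence)
    mutants: list[str] = []
    slots: list[tuple[int, int]] = []
    for i in range(L):
        for a, residue in enumerate(ALPHABET):
            if residue == sequence[i]:
                continue
            mutants.append(apply_mutation(sequence, i + 1, residue))
            slots.append((i, a))
    probs = scorer.positive_proba([sequence] + mutants)
    wt_prob = float(probs[0])
    matrix = np.empty((L, N_AA))
    wt_idx = np.array([AA_INDEX[c] for c in sequence])
    matrix[np.arange(L), wt_idx] = wt_prob
    for (i, a), p in zip(slots, probs[1:]):
        matrix[i, a] = float(p)
    return SignificanceMap(sequence_id, sequence, matrix)


def call_conserved_sites(
    smap: SignificanceMap,
    quantile: float = 0.95,
) -> list[ConservationCall]:
    """Flag positions whose conservation score exceeds the given quantile.

    The threshold is the ``quantile`` of all positional scores; positions
    strictly above it are flagged (so a uniform map flags nothing), and any
    tie above the threshold is kept.
    """
    if len(smap.wild_type) < 2:
        raise ValueError("need at least 2 positions to define a quantile threshold")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    scores = smap.conservation_scores()
    threshold = float(np.quantile(scores, quantile))
    return [
        ConservationCall(i + 1, float(s), bool(s > threshold))
        for i, s in enumerate(scores)
    ]
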