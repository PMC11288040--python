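"""Global conventions shared by every rosmine module.

One alphabet, one category list, one column order.  Every one-hot encoding,
k-mer index and probability matrix in the package uses ``ALPHABET`` order;
keeping the convention in a single place prevents cross-module index bugs.
"""

from __future__ import annotations

import numpy as np

# The 20 standard amino acids, fixed order.  All feature matrices and the
# L x 20 significance maps use columns in this order.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}
N_AA: int = 20

# The 26-type ROS-scavenging enzyme (ROSes) taxonomy.  The first twelve are
# the family names commonly reported for gut-microbial antioxidant systems;
# the remainder are plausible antioxidant-enzyme family names used as
# configurable stand-ins — callers may supply their own 26-name list wherever
# a ``categories`` argument is accepted.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "thioredoxin_1",
    "thioredoxin reductase",
    "glutathione peroxidase",
    "thiol peroxidase",
    "NADH peroxidase",
    "Mn-containing catalase",
    "catalase",
    "alkyl hydroperoxide reductase",
    "alkyl hydroperoxide reductase 1",
    "superoxide dismutase",
    "superoxide dismutase 2",
    "monothiol glutaredoxin",
    "glutaredoxin",
    "peroxiredoxin",
    "rubrerythrin",
    "superoxide reductase",
    "glutathione reductase",
    "glutathione S-transferase",
    "methionine sulfoxide reductase A",
    "methionine sulfoxide reductase B",
    "cytochrome c peroxidase",
    "DyP-type peroxidase",
    "ferroxidase",
    "organic hydroperoxide resistance protein",
    "bacterioferritin comigratory protein",
    "hydrogen peroxide-inducible regulator",
)
N_CATEGORIES: int = 26

# Gut-microbiota phyla used as default genome metadata labels.
DEFAULT_PHYLA: tuple[str, ...] = (
    "Firmicutes",
    "Bacteroidota",
    "Actinobacteria",
    "Proteobacteria",
    "Fusobacteria",
    "Verrucomicrobia",
    "Synergistota",
    "Spirochaetota",
)


def validate_sequence(seq: str, *, context: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first residue outside the 20-letter alphabet."""
    for pos, ch in enumerate(seq):
        if ch not in AA_INDEX:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos + 1} in {context}; "
                f"allowed alphabet is {ALPHABET}"
            )


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode a protein string in ALPHABET order (no validation)."""
    return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
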