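"""Synthetic data generators.

Everything the pipeline consumes can be generated here with seeded
reproducibility: motif-defined reference enzyme families, multi-genome
proteomes with planted ROSes genes and phylum labels, codon-sequence pairs
evolved under a controlled nonsynonymous/synonymous rate ratio (omega), and
benchmark graphs for the network analyses.

The generators emulate the shape of real inputs, not their biology: family
members share a planted motif and a family-specific residue composition,
planted genes are point-mutated copies of reference members (motif
positions protected by default so the truth labels stay recoverable), and
codon pairs diverge by an accept/reject substitution process whose
nonsynonymous acceptance probability is scaled by omega.  No indels, no
site-rate heterogeneity.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .config import ALPHABET, DEFAULT_CATEGORIES, DEFAULT_PHYLA, N_AA

# ---------------------------------------------------------------------------
# reference families
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FamilySpec:
    """One synthetic enzyme family: a planted motif on a biased background."""

    category_label: str
    motif: str
    background_composition: np.ndarray  # 20-vector, sums to 1
    length_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not (8 <= len(self.motif) <= 15):
            raise ValueError("motif length must be in [8, 15]")
        if any(c not in ALPHABET for c in self.motif):
            raise ValueError("motif must use the 20 standard amino acids")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (N_AA,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("background_composition must be a nonnegative 20-vector summing to 1")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range min must be <= max")


@dataclasses.dataclass
class ReferenceSet:
    """Labeled reference sequences defining the 26-category label space."""

    records: list[tuple[str, str]]  # (id, sequence)
    labels: dict[str, str]  # id -> category
    families: list[FamilySpec]

    @property
    def categories(self) -> list[str]:
        return [f.category_label for f in self.families]

    def to_fasta(self) -> str:
        buf = io.StringIO()
        for rid, seq in self.records:
            buf.write(f">{rid}\n{seq}\n")
        return buf.getvalue()

    def to_label_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("id\tcategory\n")
        for rid, _ in self.records:
            buf.write(f"{rid}\t{self.labels[rid]}\n")
        return buf.getvalue()


def _random_sequence(rng: np.random.Generator, length: int, comp: np.ndarray) -> str:
    idx = rng.choice(N_AA, size=length, p=comp)
    return "".join(ALPHABET[i] for i in idx)


def _plant_motif(rng: np.random.Generator, seq: str, motif: str) -> tuple[str, int]:
    """Insert ``motif`` at a random position, returning (sequence, 0-based start)."""
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):], pos


def gen_reference_families(
    n_categories: int,
    members_per_family: int,
    seed: int,
    *,
    motif_length: int = 10,
    length_range: tuple[int, int] = (80, 150),
    category_names: Sequence[str] | None = None,
    composition_concentration: float = 5.0,
    member_divergence: float = 0.25,
) -> ReferenceSet:
    """Generate ``n_categories`` motif-defined families of labeled sequences.

    Each family is a cluster of diverged homologs, the way a curated enzyme
    family is: a family consensus sequence is drawn on a family-specific
    residue composition (symmetric Dirichlet) with a distinct random motif
    (default length 10 — long enough that cross-family motif collisions are
    vanishingly rare) planted once, and every member is a copy of the
    consensus with uniform point substitutions at ``member_divergence``
    (default 0.25, i.e. ~75 % within-family identity), motif positions
    protected.  Every member therefore contains its family motif exactly
    once.
    """
    names = list(category_names) if category_names is not None else list(DEFAULT_CATEGORIES)
    if not 1 <= n_categories <= len(names):
        raise ValueError(
            f"n_categories must be between 1 and {len(names)} (the fixed label space)"
        )
    if members_per_family < 2:
        raise ValueError("members_per_family must be >= 2")
    rng = np.random.default_rng(seed)
    families: list[FamilySpec] = []
    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    motifs: set[str] = set()
    for k in range(n_categories):
        while True:
            motif = "".join(ALPHABET[i] for i in rng.integers(0, N_AA, size=motif_length))
            if motif not in motifs:
                motifs.add(motif)
                break
        comp = rng.dirichlet(np.full(N_AA, composition_concentration))
        fam = FamilySpec(names[k], motif, comp, length_range)
        families.append(fam)
        while True:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            background = _random_sequence(rng, length - motif_length, comp)
            consensus, motif_start = _plant_motif(rng, background, motif)
            if consensus.count(motif) == 1:
                break
        span = (motif_start, motif_start + motif_length)
        for m in range(members_per_family):
            while True:
                seq = _mutate_protein(rng, consensus, member_divergence, span)
                if seq.count(motif) == 1:
                    break
            rid = f"ref_{k:02d}_{m:04d}"
            records.append((rid, seq))
            labels[rid] = fam.category_label
    return ReferenceSet(records, labels, families)


# ---------------------------------------------------------------------------
# genomes with planted genes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticGenome:
    """One synthetic proteome: planted ROSes genes among random background."""

    genome_id: str
    phylum: str
    proteins: list[tuple[str, str, str]]  # (protein_id, sequence, truth_label or "NONE")


def _mutate_protein(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: tuple[int, int] | None,
) -> str:
    """Uniform point substitutions at ``rate``; ``protected`` span untouched."""
    chars = list(seq)
    for i in range(len(chars)):
        if protected is not None and protected[0] <= i < protected[1]:
            continue
        if rng.random() < rate:
            choices = [a for a in ALPHABET if a != chars[i]]
            chars[i] = choices[int(rng.integers(0, 19))]
    return "".join(chars)


def gen_genomes(
    n_genomes: int,
    phyla: Sequence[str],
    planted_per_genome: int | tuple[str, float] | Callable[[np.random.Generator], int],
    background_per_genome: int,
    ref: ReferenceSet,
    seed: int,
    *,
    substitution_rate: float = 0.10,
    protect_motif: bool = True,
    background_length_range: tuple[int, int] = (80, 150),
) -> tuple[list[SyntheticGenome], pd.DataFrame]:
    """Generate genomes with planted (mutated) reference genes plus background.

    ``planted_per_genome`` may be a constant, ``("poisson", mean)``, or a
    callable drawing a count from the supplied RNG.  Planted genes are copies
    of randomly chosen reference members with uniform point substitutions at
    ``substitution_rate``; the family-motif span is protected from mutation
    by default so a motif scan recovers every truth label.

    Returns the genomes and a truth table with columns
    ``id, genome_id, phylum, category``.
    """
    if not phyla:
        raise ValueError("phyla must be nonempty")
    if not ref.records:
        raise ValueError("reference set is empty; cannot plant genes")
    rng = np.random.default_rng(seed)

    if callable(planted_per_genome):
        draw = planted_per_genome
    elif isinstance(planted_per_genome, tuple):
        kind, param = planted_per_genome
        if kind != "poisson":
            raise ValueError(f"unknown planted_per_genome distribution {kind!r}")
        draw = lambda r: int(r.poisson(param))
    else:
        draw = lambda r, k=int(planted_per_genome): k

    # precompute motif spans of reference members for protection
    fam_by_label = {f.category_label: f for f in ref.families}
    spans: dict[str, tuple[int, int]] = {}
    for rid, seq in ref.records:
        motif = fam_by_label[ref.labels[rid]].motif
        start = seq.find(motif)
        spans[rid] = (start, start + len(motif)) if start >= 0 else None

    uniform = np.full(N_AA, 1.0 / N_AA)
    genomes: list[SyntheticGenome] = []
    truth_rows: list[dict] = []
    for g in range(n_genomes):
        gid = f"genome_{g:03d}"
        phylum = phyla[int(rng.integers(0, len(phyla)))]
        proteins: list[tuple[str, str, str]] = []
        n_planted = draw(rng)
        for p in range(n_planted):
            src_idx = int(rng.integers(0, len(ref.records)))
            rid, src_seq = ref.records[src_idx]
            label = ref.labels[rid]
            protected = spans[rid] if protect_motif else None
            seq = _mutate_protein(rng, src_seq, substitution_rate, protected)
            pid = f"{gid}_p{p:04d}"
            proteins.append((pid, seq, label))
            truth_rows.append(
                {"id": pid, "genome_id": gid, "phylum": phylum, "category": label}
            )
        for b in range(background_per_genome):
            length = int(rng.integers(background_length_range[0], background_length_range[1] + 1))
            seq = _random_sequence(rng, length, uniform)
            proteins.append((f"{gid}_b{b:04d}", seq, "NONE"))
        genomes.append(SyntheticGenome(gid, phylum, proteins))
    truth = pd.DataFrame(truth_rows, columns=["id", "genome_id", "phylum", "category"])
    return genomes, truth


def genomes_to_fasta(genomes: Sequence[SyntheticGenome]) -> str:
    buf = io.StringIO()
    for g in genomes:
        for pid, seq, _ in g.proteins:
            buf.write(f">{pid}\n{seq}\n")
    return buf.getvalue()


def genome_metadata(genomes: Sequence[SyntheticGenome]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"genome_id": g.genome_id, "phylum": g.phylum} for g in genomes]
    )


# ---------------------------------------------------------------------------
# codon pairs under controlled omega
# ---------------------------------------------------------------------------

_STOPS = set(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)  # sense codons only
_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class CodonPairSpec:
    """Parameters for one diverged codon-sequence pair."""

    n_codons: int
    omega: float  # target Ka/Ks ratio
    t: float  # expected substitutions per codon
    seed: int

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    sense = sorted(_CODON_AA)
    return [sense[int(rng.integers(0, len(sense)))] for _ in range(n_codons)]


def gen_codon_pair(spec: CodonPairSpec) -> tuple[str, str, dict]:
    """Generate a CDS pair diverged under a controlled Ka/Ks ratio.

    One sequence is a random stop-free CDS; the other accumulates exactly
    ``round(t * n_codons)`` accepted single-base substitutions.  Proposed
    changes that create a stop codon are rejected outright; synonymous
    proposals are accepted with probability min(1, 1/omega) and nonsynonymous
    proposals with probability min(1, omega), so the realized
    nonsynonymous:synonymous substitution odds — and hence the NG86-estimable
    ratio — are scaled by omega relative to neutral divergence.

    Returns ``(cds_a, cds_b, info)`` where ``info`` records the generator's
    own bookkeeping: accepted synonymous/nonsynonymous change counts
    (``n_syn``, ``n_nonsyn``), usable as an oracle for estimator tests.
    """
    rng = np.random.default_rng(spec.seed)
    codons_a = _random_cds(rng, spec.n_codons)
    codons_b = list(codons_a)
    target = int(round(spec.t * spec.n_codons))
    p_nonsyn = min(1.0, spec.omega)
    p_syn = min(1.0, 1.0 / spec.omega) if spec.omega > 1 else 1.0
    n_syn = n_nonsyn = 0
    accepted = 0
    # At omega = 0 every codon receives at most one hit: stacked synonymous
    # hits in one codon can otherwise compose into codon pairs whose
    # mutational pathways pass through nonsynonymous intermediates, which a
    # pathway-averaging estimator counts as fractional nonsynonymous signal.
    one_hit_per_codon = spec.omega == 0
    hit: set[int] = set()
    if one_hit_per_codon and target > spec.n_codons // 2:
        raise ValueError("t too large for omega=0 (needs t <= 0.5)")
    attempts = 0
    while accepted < target:
        attempts += 1
        if attempts > 1000 * max(target, 1):
            raise RuntimeError("substitution sampling failed to converge")
        ci = int(rng.integers(0, spec.n_codons))
        if one_hit_per_codon and ci in hit:
            continue
        pos = int(rng.integers(0, 3))
        codon = codons_b[ci]
        old_base = codon[pos]
        new_base = _BASES[int(rng.integers(0, 4))]
        if new_base == old_base:
            continue
        new_codon = codon[:pos] + new_base + codon[pos + 1:]
        if new_codon in _STOPS:
            continue
        synonymous = _CODON_AA[new_codon] == _CODON_AA[codon]
        p_accept = p_syn if synonymous else p_nonsyn
        if rng.random() < p_accept:
            codons_b[ci] = new_codon
            accepted += 1
            hit.add(ci)
            if synonymous:
                n_syn += 1
            else:
                n_nonsyn += 1
    info = {"n_syn": n_syn, "n_nonsyn": n_nonsyn, "n_substitutions": accepted}
    return "".join(codons_a), "".join(codons_b), info


# ---------------------------------------------------------------------------
# benchmark graphs
# ---------------------------------------------------------------------------

_GRAPH_KINDS = ("path", "star", "complete", "barbell", "scale_free", "erdos_renyi")


def gen_test_graph(kind: str, n: int, seed: int = 0, **kwargs) -> nx.Graph:
    """Deterministic simple undirected benchmark graphs.

    ``scale_free`` is a Barabasi-Albert preferential-attachment graph
    (m defaults to 2); ``erdos_renyi`` is G(n, p) with p defaulting to 0.1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "path":
        return nx.path_graph(n)
    if kind == "star":
        return nx.star_graph(n - 1)
    if kind == "complete":
        return nx.complete_graph(n)
    if kind == "barbell":
        k = max(n // 2, 3)
        return nx.barbell_graph(k, max(n - 2 * k, 0))
    if kind == "scale_free":
        m = kwargs.get("m", 2)
        return nx.barabasi_albert_graph(n, m, seed=seed)
    if kind == "erdos_renyi":
        p = kwargs.get("p", 0.1)
        return nx.gnp_random_graph(n, p, seed=seed)
    raise ValueError(f"unknown graph kind {kind!r}; choose from {_GRAPH_KINDS}")


def graph_to_edge_tsv(g: nx.Graph) -> str:
    buf = io.StringIO()
    buf.write("u\tv\tweight\n")
    for u, v, data in g.edges(data=True):
        buf.write(f"{u}\t{v}\t{data.get('weight', 1.0)}\n")
    return buf.getvalue()
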