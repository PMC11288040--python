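"""Similarity screening: the mining workflow's first gate.

Candidate proteins are aligned against the labeled reference set and kept
when the best reference hit clears the mining thresholds — percent identity
>= 10 and E-value <= 1e-3, both inclusive.

Two alignment engines sit behind the same contract:

* ``builtin`` — exact Smith-Waterman with affine gaps (BLOSUM62, open 11 /
  extend 1) via Biopython's PairwiseAligner.  Bit scores use the published
  ungapped BLOSUM62 Karlin-Altschul constants (lambda = 0.3176, K = 0.134)
  applied to the gapped raw score; this overstates the significance of
  gapped alignments slightly, which is conservative for a screening gate.
  E = m * n * 2**(-bitscore) with search space m * n = query length times
  summed reference length.
* ``blastp`` — NCBI blastp run through a temporary database, parsed from
  12-column tabular output.  Used for large runs; results flow through the
  identical keep rule.
"""

from __future__ import annotations

import dataclasses
import math
import shutil
import subprocess
import tempfile
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import validate_sequence

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# ungapped Karlin-Altschul parameters for BLOSUM62
_LAMBDA = 0.3176
_K = 0.134


@dataclasses.dataclass
class ScreenHit:
    """One alignment hit in BLAST tabular terms."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    raw_score: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")

    def to_row(self) -> dict:
        return {c: getattr(self, a) for c, a in zip(
            OUTFMT6_COLUMNS,
            ["query_id", "subject_id", "percent_identity", "alignment_length",
             "mismatch", "gapopen", "qstart", "qend", "sstart", "send",
             "evalue", "bitscore"],
        )}


@dataclasses.dataclass
class ScreenConfig:
    """Thresholds and alignment parameters for the screening gate."""

    min_identity: float = 10.0  # percent, inclusive
    max_evalue: float = 1e-3  # inclusive
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # how the m*n search space for E-values is computed: "pairwise" uses
    # len(q)*len(s); "database" uses len(q) * summed reference length
    db_size_policy: str = "database"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


def _make_aligner(config: ScreenConfig, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    aligner.open_gap_score = -(config.gap_open)
    aligner.extend_gap_score = -(config.gap_extend)
    return aligner


def bitscore_from_raw(raw_score: float) -> float:
    """Karlin-Altschul bit score: (lambda*S - ln K) / ln 2."""
    return (_LAMBDA * raw_score - math.log(_K)) / math.log(2.0)


def evalue_from_bitscore(bitscore: float, search_space: float) -> float:
    return search_space * 2.0 ** (-bitscore)


def align_local(
    query: str,
    subject: str,
    config: ScreenConfig | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: float | None = None,
) -> ScreenHit:
    """Optimal local alignment of two proteins, reported as a ScreenHit.

    ``search_space`` overrides the m*n term of the E-value (used when the
    subject is one member of a larger database); the default is
    len(query) * len(subject).
    """
    config = config or ScreenConfig()
    if not query or not subject:
        raise ValueError("sequences must be nonempty")
    validate_sequence(query, context=f"query {query_id!r}")
    validate_sequence(subject, context=f"subject {subject_id!r}")
    aligner = _make_aligner(config)
    alignment = aligner.align(query, subject)[0]
    raw = float(alignment.score)
    aligned_q, aligned_s = alignment[0], alignment[1]
    identities = mismatches = gaps = gapopens = 0
    in_gap = False
    for a, b in zip(aligned_q, aligned_s):
        if a == "-" or b == "-":
            gaps += 1
            if not in_gap:
                gapopens += 1
                in_gap = True
        else:
            in_gap = False
            if a == b:
                identities += 1
            else:
                mismatches += 1
    length = len(aligned_q)
    pident = 100.0 * identities / length if length else 0.0
    coords = alignment.coordinates
    qstart, qend = int(coords[0][0]) + 1, int(coords[0][-1])
    sstart, send = int(coords[1][0]) + 1, int(coords[1][-1])
    bits = bitscore_from_raw(raw)
    space = search_space if search_space is not None else len(query) * len(subject)
    ev = evalue_from_bitscore(bits, space)
    return ScreenHit(
        query_id, subject_id, pident, length, mismatches, gapopens,
        int(qstart), int(qend), int(sstart), int(send), ev, bits, raw,
    )


def passes_gate(hit: ScreenHit, config: ScreenConfig) -> bool:
    """Inclusive thresholds: identity >= min_identity and E <= max_evalue."""
    return hit.percent_identity >= config.min_identity and hit.evalue <= config.max_evalue


def hits_to_frame(hits: Iterable[ScreenHit]) -> pd.DataFrame:
    return pd.DataFrame([h.to_row() for h in hits], columns=OUTFMT6_COLUMNS)


# ---------------------------------------------------------------------------
# candidate screening
# ---------------------------------------------------------------------------


def _builtin_best_hits(
    candidates: Sequence[tuple[str, str]],
    reference: Sequence[tuple[str, str]],
    config: ScreenConfig,
) -> list[ScreenHit]:
    """Best reference hit per candidate by exact Smith-Waterman.

    A score-only pass finds the best subject; the full alignment (identity,
    coordinates) is computed only for that one.
    """
    aligner = _make_aligner(config)
    total_ref_len = sum(len(s) for _, s in reference)
    best: list[ScreenHit] = []
    for qid, qseq in candidates:
        validate_sequence(qseq, context=f"candidate {qid!r}")
        best_score, best_idx = -math.inf, -1
        for i, (_, sseq) in enumerate(reference):
            score = aligner.score(qseq, sseq)
            if score > best_score:
                best_score, best_idx = score, i
        sid, sseq = reference[best_idx]
        space = (
            len(qseq) * total_ref_len
            if config.db_size_policy == "database"
            else len(qseq) * len(sseq)
        )
        best.append(
            align_local(qseq, sseq, config, query_id=qid, subject_id=sid,
                        search_space=space)
        )
    return best


def _blastp_best_hits(
    candidates: Sequence[tuple[str, str]],
    reference: Sequence[tuple[str, str]],
    config: ScreenConfig,
) -> list[ScreenHit]:
    """Best reference hit per candidate via NCBI blastp (tabular output)."""
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        ref_fa = tmpdir / "ref.fa"
        ref_fa.write_text("".join(f">{i}\n{s}\n" for i, s in reference))
        q_fa = tmpdir / "query.fa"
        q_fa.write_text("".join(f">{i}\n{s}\n" for i, s in candidates))
        db = tmpdir / "refdb"
        subprocess.run(
            ["makeblastdb", "-in", str(ref_fa), "-dbtype", "prot", "-out", str(db)],
            check=True, capture_output=True,
        )
        out = tmpdir / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(q_fa), "-db", str(db), "-outfmt", "6",
             "-evalue", str(max(config.max_evalue, 10.0)), "-max_target_seqs", "5",
             "-out", str(out), "-num_threads", "1"],
            check=True, capture_output=True,
        )
        hits = ingest_tabular_hits(out)
    best_by_query: dict[str, ScreenHit] = {}
    for h in hits:
        cur = best_by_query.get(h.query_id)
        if cur is None or h.bitscore > cur.bitscore:
            best_by_query[h.query_id] = h
    return [best_by_query[qid] for qid, _ in candidates if qid in best_by_query]


def blastp_available() -> bool:
    return shutil.which("blastp") is not None and shutil.which("makeblastdb") is not None


def screen_candidates(
    candidates: Sequence[tuple[str, str]],
    reference: Sequence[tuple[str, str]] | "ReferenceSet",
    config: ScreenConfig | None = None,
    *,
    engine: str = "builtin",
) -> pd.DataFrame:
    """Keep candidates whose best reference hit clears the screening gate.

    Returns the kept best hits as a BLAST-tabular DataFrame sorted by
    query id then ascending E-value.  ``engine`` is ``builtin`` (exact
    Smith-Waterman) or ``blastp``.
    """
    config = config or ScreenConfig()
    ref_records = getattr(reference, "records", reference)
    if not ref_records:
        raise ValueError("reference set is empty")
    if not candidates:
        warnings.warn("empty candidate set; returning empty screen output")
        return pd.DataFrame(columns=OUTFMT6_COLUMNS)
    if engine == "builtin":
        best = _builtin_best_hits(candidates, ref_records, config)
    elif engine == "blastp":
        if not blastp_available():
            raise RuntimeError("blastp/makeblastdb not found on PATH")
        best = _blastp_best_hits(candidates, ref_records, config)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    kept = [h for h in best if passes_gate(h, config)]
    frame = hits_to_frame(kept)
    return frame.sort_values(["qseqid", "evalue"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tabular ingestion (BLAST/DIAMOND "outfmt 6")
# ---------------------------------------------------------------------------


def ingest_tabular_hits(path: str | Path, *, strict: bool = True) -> list[ScreenHit]:
    """Parse a 12-column BLAST tabular ("outfmt 6") file into ScreenHits.

    In strict mode a malformed row raises ``ValueError`` naming its line
    number; in lenient mode malformed rows are reported as warnings and
    skipped.
    """
    hits: list[ScreenHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) != 12:
                    raise ValueError(f"expected 12 columns, found {len(fields)}")
                hits.append(ScreenHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                ))
            except ValueError as exc:
                msg = f"malformed tabular hit at line {lineno}: {exc}"
                if strict:
                    raise ValueError(msg) from None
                warnings.warn(msg)
    return hits


def all_pairs_hits(
    records: Sequence[tuple[str, str]],
    config: ScreenConfig | None = None,
    *,
    engine: str = "builtin",
) -> list[ScreenHit]:
    """All-vs-all hits among ``records`` (both directions collapsed later by
    the network builder; self-hits excluded)."""
    config = config or ScreenConfig()
    if engine == "blastp":
        if not blastp_available():
            raise RuntimeError("blastp/makeblastdb not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            fa = tmpdir / "all.fa"
            fa.write_text("".join(f">{i}\n{s}\n" for i, s in records))
            db = tmpdir / "alldb"
            subprocess.run(
                ["makeblastdb", "-in", str(fa), "-dbtype", "prot", "-out", str(db)],
                check=True, capture_output=True,
            )
            out = tmpdir / "hits.tsv"
            subprocess.run(
                ["blastp", "-query", str(fa), "-db", str(db), "-outfmt", "6",
                 "-evalue", "10", "-max_target_seqs", str(len(records)),
                 "-out", str(out), "-num_threads", "1"],
                check=True, capture_output=True,
            )
            return [h for h in ingest_tabular_hits(out) if h.query_id != h.subject_id]
    hits: list[ScreenHit] = []
    for i, (qid, qseq) in enumerate(records):
        for sid, sseq in records[i + 1:]:
            hits.append(align_local(qseq, sseq, config, query_id=qid, subject_id=sid))
    return hits
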