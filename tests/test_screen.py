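"""Screening gate: exact alignment scores, E-value behaviour, thresholds."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import rosmine as rm
from rosmine.config import ALPHABET
from rosmine.screen import ScreenConfig, ScreenHit, hits_to_frame, passes_gate
from rosmine.synth import _random_sequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_bruteforce(q: str, s: str, gap_open: float = 11.0,
                         gap_extend: float = 1.0) -> float:
    """Independent Smith-Waterman with affine gaps (Gotoh three-matrix DP).

    Opening a gap of length k costs gap_open + k * gap_extend, matching the
    BLAST convention used by the screen module.
    """
    n, m = len(q), len(s)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in s (consume q)
    Y = np.full((n + 1, m + 1), NEG)  # gap in q (consume s)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = BLOSUM62[q[i - 1], s[j - 1]]
            M[i, j] = max(0.0, sub + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestAlignLocal:
    def test_identical_sequences_full_identity(self):
        seq = "MKVLATNDEWQRSTYPHGCI" * 3  # 60-mer, alls tandard residues
        hit = rm.align_local(seq[:50], seq[:50])
        assert hit.percent_identity == 100.0
        assert hit.alignment_length == 50

    def test_score_matches_bruteforce_oracle(self):
        """On 100 random 8-mer pairs the optimal local score equals an
        independent Gotoh dynamic-programming implementation exactly."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            q = "".join(rng.choice(list(ALPHABET), 8))
            s = "".join(rng.choice(list(ALPHABET), 8))
            hit = rm.align_local(q, s)
            assert hit.raw_score == pytest.approx(sw_affine_bruteforce(q, s))

    def test_score_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            q = _random_sequence(rng, 30, np.full(20, 0.05))
            s = _random_sequence(rng, 30, np.full(20, 0.05))
            assert rm.align_local(q, s).raw_score == rm.align_local(s, q).raw_score

    def test_invalid_residue_named(self):
        with pytest.raises(ValueError, match="'B'"):
            rm.align_local("ACDB", "ACDE")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            rm.align_local("", "ACDE")


class TestEvalueCalibration:
    def test_decoy_hit_counts_scale_with_threshold(self):
        """Against shuffled decoys the number of hits with E <= t stays
        within a small constant multiple of t * N (the ungapped-lambda
        approximation overstates significance, hence the slack)."""
        rng = np.random.default_rng(0)
        query = _random_sequence(rng, 100, np.full(20, 0.05))
        base = list(_random_sequence(rng, 100, np.full(20, 0.05)))
        N = 150
        evalues = []
        for _ in range(N):
            decoy = "".join(rng.permutation(base))
            evalues.append(rm.align_local(query, decoy).evalue)
        for t in (0.1, 1.0):
            count = sum(e <= t for e in evalues)
            assert count <= 10 * t * N


def make_hit(pident: float, evalue: float, qid="q", sid="s") -> ScreenHit:
    return ScreenHit(qid, sid, pident, 100, 0, 0, 1, 100, 1, 100, evalue, 50.0)


class TestGate:
    @pytest.mark.parametrize("pident,evalue,kept", [
        (9.9, 1e-9, False),   # identity below 10 %
        (50.0, 1e-2, False),  # E above 1e-3
        (10.0, 1e-3, True),   # both thresholds inclusive
        (90.0, 1e-20, True),
        (9.99, 1e-20, False),
    ])
    def test_boundary_rule(self, pident, evalue, kept):
        assert passes_gate(make_hit(pident, evalue), ScreenConfig()) is kept

    def test_filtering_monotone(self):
        """Lowering max_evalue or raising min_identity never adds hits."""
        rng = np.random.default_rng(2)
        hits = [make_hit(float(rng.uniform(0, 100)), float(10 ** rng.uniform(-30, 1)),
                         qid=f"q{i}") for i in range(200)]
        base = {h.query_id for h in hits if passes_gate(h, ScreenConfig())}
        for cfg in [ScreenConfig(min_identity=30), ScreenConfig(max_evalue=1e-6),
                    ScreenConfig(min_identity=30, max_evalue=1e-6)]:
            stricter = {h.query_id for h in hits if passes_gate(h, cfg)}
            assert stricter <= base


class TestScreenCandidates:
    def test_planted_copy_kept_background_gated(self, small_reference):
        genomes, truth = rm.gen_genomes(
            1, ["Firmicutes"], 4, 0, small_reference, seed=11, substitution_rate=0.1
        )
        candidates = [(pid, s) for g in genomes for pid, s, _ in g.proteins]
        kept = rm.screen_candidates(candidates, small_reference)
        assert set(kept["qseqid"]) == {pid for pid, _ in candidates}
        assert (kept["pident"] >= 10).all()
        assert (kept["evalue"] <= 1e-3).all()

    def test_sorted_by_query_then_evalue(self, small_reference):
        genomes, _ = rm.gen_genomes(2, ["Firmicutes"], 3, 2, small_reference, seed=12)
        candidates = [(pid, s) for g in genomes for pid, s, _ in g.proteins]
        kept = rm.screen_candidates(candidates, small_reference)
        assert list(kept["qseqid"]) == sorted(kept["qseqid"])

    def test_empty_candidates_warns_not_fails(self, small_reference):
        with pytest.warns(UserWarning, match="empty candidate"):
            out = rm.screen_candidates([], small_reference)
        assert len(out) == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            rm.screen_candidates([("q", "ACDE")], [])

    @pytest.mark.skipif(not rm.screen.blastp_available(), reason="blastp not on PATH")
    def test_blastp_engine_agrees_on_clear_cases(self, small_reference):
        """Planted near-copies must be kept by both engines."""
        genomes, _ = rm.gen_genomes(1, ["Firmicutes"], 5, 0, small_reference,
                                    seed=13, substitution_rate=0.05)
        candidates = [(pid, s) for g in genomes for pid, s, _ in g.proteins]
        kept_builtin = rm.screen_candidates(candidates, small_reference)
        kept_blast = rm.screen_candidates(candidates, small_reference, engine="blastp")
        assert set(kept_builtin["qseqid"]) == set(kept_blast["qseqid"])


class TestIngestTabular:
    GOOD = "q1\ts1\t97.5\t100\t2\t1\t1\t100\t5\t104\t1e-30\t200.1\n"

    def test_field_mapping(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.GOOD)
        hits = rm.ingest_tabular_hits(path)
        assert len(hits) == 1
        h = hits[0]
        assert (h.query_id, h.subject_id) == ("q1", "s1")
        assert h.percent_identity == 97.5
        assert h.alignment_length == 100
        assert h.evalue == 1e-30
        assert h.bitscore == 200.1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert rm.ingest_tabular_hits(path) == []

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(self.GOOD + "q2\ts2\tnot-enough-columns\n")
        with pytest.raises(ValueError, match="line 2"):
            rm.ingest_tabular_hits(path)

    def test_lenient_mode_skips_bad_rows(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(self.GOOD + "q2\ts2\tjunk\n")
        with pytest.warns(UserWarning, match="line 2"):
            hits = rm.ingest_tabular_hits(path, strict=False)
        assert len(hits) == 1

    def test_roundtrip_through_frame(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.GOOD)
        frame = hits_to_frame(rm.ingest_tabular_hits(path))
        assert list(frame.columns) == rm.screen.OUTFMT6_COLUMNS
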