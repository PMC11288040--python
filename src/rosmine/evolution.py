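"""Pairwise Ka/Ks estimation: protein-guided codon alignment + NG86.

The two coding sequences are translated, globally aligned at the protein
level (BLOSUM62, affine gaps), and the alignment is back-translated so gaps
fall on whole-codon boundaries.  Ka and Ks then follow Nei & Gojobori's
1986 counting method:

* per-codon synonymous site fractions are the fraction of the nine possible
  single-base changes that preserve the encoded amino acid (changes to stop
  codons count as nonsynonymous, so synonymous + nonsynonymous sites sum to
  exactly 3 per codon); site counts are averaged over the two sequences;
* observed differences between codons differing at >1 position are averaged
  with equal weight over all mutational pathways, excluding pathways that
  pass through a stop codon (all pathways are used if every one is blocked);
* proportions p = d/sites are distance-corrected with the Jukes-Cantor
  formula d = -(3/4) ln(1 - (4/3) p), undefined for p >= 3/4.

The Ka/Ks ratio is reported as NaN when Ks = 0 or either correction is
undefined; batch summaries exclude NaNs and report their count.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

_STOPS = set(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)
_BASES = "ACGT"


@dataclasses.dataclass
class CodonAlignmentPair:
    """A codon-aware pairwise alignment; gaps only in whole-codon units."""

    id_a: str
    id_b: str
    aligned_cds_a: str
    aligned_cds_b: str

    def __post_init__(self) -> None:
        if len(self.aligned_cds_a) != len(self.aligned_cds_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.aligned_cds_a) % 3 != 0:
            raise ValueError("aligned length must be divisible by 3")


@dataclasses.dataclass
class KaKsResult:
    id_a: str
    id_b: str
    ka: float
    ks: float
    ratio: float  # NaN when undefined
    s_sites: float
    n_sites: float
    sd: float
    nd: float


def _validate_cds(cds: str, name: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    cds = cds.upper().replace("U", "T")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for idx, codon in enumerate(codons):
        if codon in _STOPS and idx < len(codons) - 1:
            raise ValueError(f"{name}: internal stop codon {codon} at codon {idx + 1}")
        if codon not in _CODON_AA and codon not in _STOPS:
            raise ValueError(f"{name}: invalid codon {codon!r} at codon {idx + 1}")
    # a trailing stop is tolerated but dropped from analysis
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    return codons


def _translate(codons: Sequence[str]) -> str:
    return "".join(_CODON_AA[c] for c in codons)


def codon_align(
    cds_a: str,
    cds_b: str,
    *,
    id_a: str = "a",
    id_b: str = "b",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> CodonAlignmentPair:
    """Protein-guided codon alignment (global, BLOSUM62, affine gaps).

    Translations are aligned globally and the protein alignment is
    back-translated codon-wise, so every gap is a whole-codon gap and
    stripping gaps recovers the input CDS exactly.
    """
    codons_a = _validate_cds(cds_a, id_a)
    codons_b = _validate_cds(cds_b, id_b)
    prot_a, prot_b = _translate(codons_a), _translate(codons_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    it_a, it_b = iter(codons_a), iter(codons_b)
    out_a, out_b = [], []
    for ra, rb in zip(row_a, row_b):
        out_a.append(next(it_a) if ra != "-" else "---")
        out_b.append(next(it_b) if rb != "-" else "---")
    return CodonAlignmentPair(id_a, id_b, "".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of a sense codon (0..3).

    Each of the nine single-base changes contributes 1/3 of a site;
    changes producing stop codons count as nonsynonymous.
    """
    aa = _CODON_AA[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOPS and _CODON_AA[alt] == aa:
                syn += 1
    return syn / 3.0


_SYN_SITES = {codon: _syn_fraction(codon) for codon in _CODON_AA}


def _step_type(c1: str, c2: str) -> str:
    """Classify a single-base codon change as synonymous or nonsynonymous."""
    return "syn" if _CODON_AA[c1] == _CODON_AA[c2] else "nonsyn"


def _pairwise_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts for one codon pair."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    if len(diff_pos) == 1:
        return (1.0, 0.0) if _step_type(codon_a, codon_b) == "syn" else (0.0, 1.0)
    valid: list[tuple[int, int]] = []  # (syn, nonsyn) per pathway
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                through_stop = True
                # classify the step anyway for the all-blocked fallback
                nonsyn += 1
                cur = nxt
                continue
            if cur in _STOPS or _step_type(cur, nxt) == "nonsyn":
                nonsyn += 1
            else:
                syn += 1
            cur = nxt
        (blocked if through_stop else valid).append((syn, nonsyn))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(pair: CodonAlignmentPair) -> KaKsResult:
    """NG86 Ka/Ks over the gap-free codon columns of a codon alignment."""
    codons_a = [pair.aligned_cds_a[i:i + 3] for i in range(0, len(pair.aligned_cds_a), 3)]
    codons_b = [pair.aligned_cds_b[i:i + 3] for i in range(0, len(pair.aligned_cds_b), 3)]
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb:
            continue
        n_codons += 1
        s_a += _SYN_SITES[ca]
        s_b += _SYN_SITES[cb]
        d_syn, d_nonsyn = _pairwise_differences(ca, cb)
        sd += d_syn
        nd += d_nonsyn
    if n_codons == 0:
        raise ValueError("no gap-free codon columns to compare")
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = float("nan")
    else:
        ratio = ka / ks
    return KaKsResult(pair.id_a, pair.id_b, ka, ks, ratio, s_sites, n_sites, sd, nd)


def kaks_pair(cds_a: str, cds_b: str, *, id_a: str = "a", id_b: str = "b") -> KaKsResult:
    """Convenience: codon-align then NG86."""
    return ng86(codon_align(cds_a, cds_b, id_a=id_a, id_b=id_b))


# ---------------------------------------------------------------------------
# batch + summaries
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with midranks for ties; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def kaks_batch(
    pairs: Iterable[tuple[str, str, str, str]],
    *,
    lenient: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Ka/Ks for a batch of (id_a, id_b, cds_a, cds_b) pairs.

    Returns a per-pair table (columns id_a, id_b, ka, ks, ratio, s_sites,
    n_sites, sd, nd) and a summary dict with NaN-excluded means, the NaN
    count and Spearman correlations among ka, ks and ratio.  In lenient
    mode failing pairs are skipped with a logged message.
    """
    rows = []
    errors: list[str] = []
    for id_a, id_b, cds_a, cds_b in pairs:
        try:
            res = kaks_pair(cds_a, cds_b, id_a=id_a, id_b=id_b)
        except ValueError as exc:
            if not lenient:
                raise
            errors.append(f"{id_a}/{id_b}: {exc}")
            continue
        rows.append(dataclasses.asdict(res))
    if not rows:
        raise ValueError("no pair produced a Ka/Ks estimate")
    table = pd.DataFrame(rows, columns=[
        "id_a", "id_b", "ka", "ks", "ratio", "s_sites", "n_sites", "sd", "nd",
    ])
    valid_ratio = table["ratio"].dropna()
    summary = {
        "n_pairs": len(table),
        "n_failed": len(errors),
        "n_ratio_na": int(table["ratio"].isna().sum()),
        "mean_ka": float(table["ka"].mean()),
        "mean_ks": float(table["ks"].mean()),
        "mean_ratio": float(valid_ratio.mean()) if len(valid_ratio) else float("nan"),
        "errors": errors,
    }
    complete = table.dropna(subset=["ka", "ks", "ratio"])
    if len(complete) >= 3:
        summary["spearman_ka_ks"] = spearman(complete["ka"], complete["ks"])
        summary["spearman_ka_ratio"] = spearman(complete["ka"], complete["ratio"])
        summary["spearman_ks_ratio"] = spearman(complete["ks"], complete["ratio"])
    return table, summary
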