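"""Homolog recovery by local alignment with identity and E-value gates.

Optimal Smith-Waterman alignment with affine gaps (via Biopython's
PairwiseAligner) stands in for a SWIPE-style database search.  E-values
follow Karlin-Altschul statistics, E = K m n exp(-lambda * score), with
published per-matrix constants (no edge-effect correction at this
scale).  Hits pass when E <= evalue_max and identity >= min_identity,
where identity is the fraction of identical residue pairs over aligned
(non-gap) columns — the common "BLAST identity" convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .iocore import FormatError, Sequence

#: ungapped Karlin-Altschul parameters for common matrices
#: (matrix, gap_open, gap_extend) -> (lambda, K); gapped values for
#: BLOSUM62 11/1 are the BLAST defaults
KA_PARAMS = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM62", 0, 0): (0.3176, 0.134),
}


@dataclass
class SearchParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    evalue_max: float = 10.0
    min_identity: float = 0.40

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass
class HomologHit:
    query_id: str
    target_id: str
    raw_score: float
    bitscore: float
    evalue: float
    aligned_length: int
    identity: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int


def karlin_altschul_evalue(raw_score: float, m: int, n: int,
                           ka_lambda: float, ka_k: float) -> float:
    """E = K m n exp(-lambda score); monotone decreasing in score."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    if ka_lambda <= 0 or ka_k <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return ka_k * m * n * math.exp(-ka_lambda * raw_score)


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -float(params.gap_open)
    aligner.extend_gap_score = -float(params.gap_extend)
    return aligner


def local_align(query: Sequence, target: Sequence,
                params: Optional[SearchParams] = None,
                db_length: Optional[int] = None) -> HomologHit:
    """Optimal local alignment of two protein sequences.

    ``db_length`` (total database residues) enters the E-value; it
    defaults to the target length.
    """
    params = params or SearchParams()
    if not query.residues or not target.residues:
        raise FormatError("cannot align empty sequences")
    aligner = _aligner(params)
    score = float(aligner.score(query.residues, target.residues))
    n_total = db_length if db_length is not None else len(target.residues)
    if score <= 0:
        return HomologHit(query.id, target.id, 0.0, 0.0,
                          karlin_altschul_evalue(0.0, len(query.residues),
                                                 max(1, n_total),
                                                 params.ka_lambda,
                                                 params.ka_k),
                          0, 0.0, 0, 0, 0, 0)
    best = aligner.align(query.residues, target.residues)[0]
    qa, ta = best[0], best[1]
    ident = cols = 0
    for a, b in zip(qa, ta):
        if a == "-" or b == "-":
            continue
        cols += 1
        if a == b:
            ident += 1
    aligned_len = len(qa)
    qs, qe = best.aligned[0][0][0] + 1, best.aligned[0][-1][1]
    ts, te = best.aligned[1][0][0] + 1, best.aligned[1][-1][1]
    evalue = karlin_altschul_evalue(score, len(query.residues),
                                    max(1, n_total), params.ka_lambda,
                                    params.ka_k)
    bitscore = (params.ka_lambda * score - math.log(params.ka_k)) / math.log(2)
    return HomologHit(query.id, target.id, score, bitscore, evalue,
                      aligned_len, ident / cols if cols else 0.0,
                      qs, qe, ts, te)


def find_homologs(query: Sequence, database: Iterable[Sequence],
                  params: Optional[SearchParams] = None) -> list[HomologHit]:
    """All database hits passing the E-value and identity gates.

    Sorted by ascending E-value, then descending score, then target id.
    """
    params = params or SearchParams()
    database = list(database)
    if not database:
        raise FormatError("empty database")
    db_len = sum(len(s.residues) for s in database)
    hits = []
    for target in database:
        hit = local_align(query, target, params, db_length=db_len)
        if hit.evalue <= params.evalue_max and \
                hit.identity >= params.min_identity:
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.target_id))
    return hits
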