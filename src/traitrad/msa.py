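"""Alignment construction and the paper-style filtering tool-chain.

``progressive_align`` is a deterministic, alignment-free-guided
progressive aligner: a neighbor-joining guide tree on k-mer cosine
distances followed by profile-profile global alignment with affine
gaps (BLOSUM62 by default).  The remaining operations implement the
occupancy-trimming, poorly-aligned-row removal, codon back-threading,
completeness-window and clean-data filters used between tree
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio.Align import substitution_matrices

from .gencode import STOP_CODONS, translate_cds
from .iocore import (GAP, Alignment, CodonAlignment, FormatError, Sequence)
from .protmodel import DistanceMatrix
from .treeinfer import nj_tree

_NEG = -1e30


@dataclass
class TrimConfig:
    """Column-occupancy and row-coverage thresholds."""

    min_occupancy: float = 0.01
    min_seq_coverage: float = 0.5

    def __post_init__(self):
        for v in (self.min_occupancy, self.min_seq_coverage):
            if not 0 < v <= 1:
                raise ValueError("fractions must lie in (0, 1]")


@dataclass
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    kmer: int = 3


def _score_matrix(name: str) -> tuple[np.ndarray, str]:
    mat = substitution_matrices.load(name)
    letters = "".join(a for a in mat.alphabet if a.isalpha() and a != "X")
    # keep the 20 canonical residues in matrix order
    keep = [a for a in letters if a in "ACDEFGHIKLMNPQRSTVWY"]
    S = np.array([[mat[a, b] for b in keep] for a in keep], dtype=float)
    return S, "".join(keep)


def _profile(rows: list[str], alphabet: str) -> np.ndarray:
    """(L, n_letters) residue frequencies; gaps contribute zero mass."""
    idx = {a: i for i, a in enumerate(alphabet)}
    L = len(rows[0])
    F = np.zeros((L, len(alphabet)))
    for row in rows:
        for j, ch in enumerate(row):
            k = idx.get(ch)
            if k is not None:
                F[j, k] += 1.0
    return F / len(rows)


def _gotoh_global(S: np.ndarray, go: float, ge: float):
    """Global affine-gap DP over a precomputed column-score matrix.

    Returns the three DP matrices for traceback.  The horizontal gap
    state is filled row-wise in closed form (a running maximum), which
    is equivalent to the textbook recurrence for linear gap extension.
    """
    L1, L2 = S.shape
    M = np.full((L1 + 1, L2 + 1), _NEG)
    Ix = np.full((L1 + 1, L2 + 1), _NEG)
    Iy = np.full((L1 + 1, L2 + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, L2 + 1)
    Iy[0, 1:] = -go - (j - 1) * ge
    i = np.arange(1, L1 + 1)
    Ix[1:, 0] = -go - (i - 1) * ge
    for r in range(1, L1 + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], Ix[r - 1]), Iy[r - 1])
        M[r, 1:] = S[r - 1] + prev_best[:-1]
        Ix[r, 1:] = np.maximum(M[r - 1, 1:] - go, Ix[r - 1, 1:] - ge)
        # Iy[r, j] = max_{k<j} (max(M,Ix)[r, k] - go - (j-1-k) ge)
        base = np.maximum(M[r, :-1], Ix[r, :-1]) + np.arange(L2) * ge
        Iy[r, 1:] = np.maximum.accumulate(base) - go - (j - 1) * ge
    return M, Ix, Iy


def _traceback(M, Ix, Iy, go, ge):
    """Yield moves ('D','U','L') from the DP matrices, end to start."""
    L1 = M.shape[0] - 1
    L2 = M.shape[1] - 1
    i, j = L1, L2
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    moves = []
    while i > 0 or j > 0:
        if i == 0:
            moves.append("L")
            j -= 1
            continue
        if j == 0:
            moves.append("U")
            i -= 1
            continue
        if state == 0:
            moves.append("D")
            nxt = int(np.argmax([M[i - 1, j - 1], Ix[i - 1, j - 1],
                                 Iy[i - 1, j - 1]]))
            i, j, state = i - 1, j - 1, nxt
        elif state == 1:
            moves.append("U")
            state = 0 if M[i - 1, j] - go >= Ix[i - 1, j] - ge else 1
            i -= 1
        else:
            moves.append("L")
            state = 0 if max(M[i, j - 1], Ix[i, j - 1]) - go >= \
                Iy[i, j - 1] - ge else 2
            # disambiguate source of the closed-form maximum
            if state == 0 and Ix[i, j - 1] > M[i, j - 1]:
                state = 1
            j -= 1
    return moves[::-1]


def _merge(rows1: list[str], rows2: list[str],
           params: AlignParams, S: np.ndarray, alphabet: str) -> list[str]:
    F1 = _profile(rows1, alphabet)
    F2 = _profile(rows2, alphabet)
    col_scores = F1 @ S @ F2.T
    M, Ix, Iy = _gotoh_global(col_scores, params.gap_open, params.gap_extend)
    moves = _traceback(M, Ix, Iy, params.gap_open, params.gap_extend)
    out1 = [[] for _ in rows1]
    out2 = [[] for _ in rows2]
    i = j = 0
    for mv in moves:
        if mv == "D":
            for r, row in enumerate(rows1):
                out1[r].append(row[i])
            for r, row in enumerate(rows2):
                out2[r].append(row[j])
            i += 1
            j += 1
        elif mv == "U":
            for r, row in enumerate(rows1):
                out1[r].append(row[i])
            for r in range(len(rows2)):
                out2[r].append(GAP)
            i += 1
        else:
            for r in range(len(rows1)):
                out1[r].append(GAP)
            for r, row in enumerate(rows2):
                out2[r].append(row[j])
            j += 1
    return ["".join(r) for r in out1] + ["".join(r) for r in out2]


def _kmer_distance_matrix(seqs: list[Sequence], k: int) -> DistanceMatrix:
    vocab: dict[str, int] = {}
    vecs = []
    for s in seqs:
        counts: dict[int, float] = {}
        for i in range(max(0, len(s.residues) - k + 1)):
            mer = s.residues[i:i + k]
            idx = vocab.setdefault(mer, len(vocab))
            counts[idx] = counts.get(idx, 0.0) + 1.0
        vecs.append(counts)
    n = len(seqs)
    D = np.zeros((n, n))
    norms = [np.sqrt(sum(v * v for v in c.values())) or 1.0 for c in vecs]
    for i in range(n):
        for j in range(i + 1, n):
            dot = sum(v * vecs[j].get(kk, 0.0) for kk, v in vecs[i].items())
            cos = dot / (norms[i] * norms[j])
            D[i, j] = D[j, i] = max(0.0, 1.0 - cos)
    return DistanceMatrix([s.id for s in seqs], D)


def progressive_align(seqs: list[Sequence],
                      params: Optional[AlignParams] = None) -> Alignment:
    """Guide-tree progressive alignment of protein sequences.

    Deterministic for a fixed input order; every input residue appears
    exactly once, in order, in its row.
    """
    params = params or AlignParams()
    if not seqs:
        raise FormatError("no sequences to align")
    if len(seqs) == 1:
        return Alignment([seqs[0].id], [seqs[0].residues], kind="protein")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sequence ids")
    S, alphabet = _score_matrix(params.matrix)
    by_id = {s.id: s for s in seqs}

    if len(seqs) == 2:
        merged = _merge([seqs[0].residues], [seqs[1].residues],
                        params, S, alphabet)
        return Alignment(ids, merged, kind="protein")

    guide = nj_tree(_kmer_distance_matrix(seqs, params.kmer))
    groups: dict[int, list[str]] = {}
    orders: dict[int, list[str]] = {}
    for node in guide.postorder():
        if node.is_leaf:
            groups[id(node)] = [by_id[node.label].residues]
            orders[id(node)] = [node.label]
        else:
            kids = node.children
            rows = groups[id(kids[0])]
            order = orders[id(kids[0])]
            for c in kids[1:]:
                rows = _merge(rows, groups[id(c)], params, S, alphabet)
                order = order + orders[id(c)]
            groups[id(node)] = rows
            orders[id(node)] = order
    final_rows = groups[id(guide.root)]
    final_order = orders[id(guide.root)]
    # restore the input row order
    row_by_id = dict(zip(final_order, final_rows))
    return Alignment(ids, [row_by_id[i] for i in ids], kind="protein")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def trim_columns(aln: Alignment, min_occupancy: float,
                 removed: Optional[list] = None) -> Alignment:
    """Keep columns whose non-gap fraction is >= min_occupancy."""
    if aln.n_rows == 0 or aln.n_columns == 0:
        raise FormatError("empty alignment")
    keep, drop = [], []
    for c in range(1, aln.n_columns + 1):
        if aln.column_occupancy(c) >= min_occupancy:
            keep.append(c)
        else:
            drop.append(c)
    if not keep:
        raise FormatError(
            f"occupancy {min_occupancy} removed every column; "
            "lower the threshold")
    if removed is not None:
        removed.extend(drop)
    out = aln.subset_columns(keep)
    if isinstance(aln, CodonAlignment):
        return CodonAlignment(out.ids, out.rows)
    return out


def remove_poorly_aligned(aln: Alignment, min_seq_coverage: float = 0.5,
                          removed: Optional[list] = None) -> Alignment:
    """Drop rows with low residue coverage of the well-occupied core.

    The core is the set of columns with >= 50% occupancy; a row is kept
    iff its non-gap fraction over the core is >= ``min_seq_coverage``.
    """
    if aln.n_rows < 2:
        raise FormatError("need at least 2 rows")
    core = [c for c in range(1, aln.n_columns + 1)
            if aln.column_occupancy(c) >= 0.5]
    if not core:
        return aln
    keep_ids, drop_ids = [], []
    for sid, row in zip(aln.ids, aln.rows):
        cov = sum(row[c - 1] != GAP for c in core) / len(core)
        (keep_ids if cov >= min_seq_coverage else drop_ids).append(sid)
    if not keep_ids:
        raise FormatError("coverage filter removed every row")
    if removed is not None:
        removed.extend(drop_ids)
    return aln.subset_rows(keep_ids)


def backtranslate(aa_aln: Alignment, cds: Iterable[Sequence]) -> CodonAlignment:
    """Thread ungapped CDS through a protein alignment (gap -> ---)."""
    cds_by_id = {s.id: s for s in cds}
    rows = []
    for sid, row in zip(aa_aln.ids, aa_aln.rows):
        if sid not in cds_by_id:
            raise FormatError(f"no CDS for aligned row {sid!r}")
        seq = cds_by_id[sid].residues
        prot = row.replace(GAP, "")
        trans = translate_cds(seq)
        if trans != prot:
            pos = next((k + 1 for k, (a, b) in enumerate(zip(trans, prot))
                        if a != b), min(len(trans), len(prot)) + 1)
            raise FormatError(
                f"CDS of {sid!r} does not translate to its aligned row "
                f"(first mismatch at residue {pos})")
        out = []
        k = 0
        for ch in row:
            if ch == GAP:
                out.append("---")
            else:
                out.append(seq[3 * k: 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(list(aa_aln.ids), rows)


def window_complete_filter(aln: Alignment, first: int, last: int,
                           reference_id: str,
                           removed: Optional[list] = None) -> Alignment:
    """Keep rows with no gap across reference positions [first, last].

    Positions are 1-based in the ungapped reference row, mirroring
    "complete between codons i and j of the reference" filters.
    """
    from .diagnostics import map_alignment_to_reference
    colmap = map_alignment_to_reference(aln, reference_id)
    ref_len = len(colmap.position_to_column)
    if not 1 <= first <= last <= ref_len:
        raise FormatError(
            f"window {first}..{last} outside reference 1..{ref_len}")
    cols = [colmap.position_to_column[p] for p in range(first, last + 1)]
    keep_ids, drop_ids = [], []
    for sid, row in zip(aln.ids, aln.rows):
        ok = all(row[c - 1] != GAP for c in cols)
        (keep_ids if ok else drop_ids).append(sid)
    if removed is not None:
        removed.extend(drop_ids)
    if not keep_ids:
        raise FormatError("window filter removed every row")
    return aln.subset_rows(keep_ids)


def clean_codon_columns(caln: CodonAlignment,
                        removed: Optional[list] = None) -> CodonAlignment:
    """Drop every codon column containing a gap or ambiguous codon."""
    keep, drop = [], []
    for p in range(1, caln.n_codons + 1):
        col = caln.codon_column(p)
        if any(GAP in c or "N" in c for c in col):
            drop.append(p)
        else:
            keep.append(p)
    if not keep:
        raise FormatError("clean-data filter removed every codon column")
    if removed is not None:
        removed.extend(drop)
    return caln.subset_codons(keep)
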