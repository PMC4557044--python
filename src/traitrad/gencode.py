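"""Standard genetic code tables shared by the codon machinery.

The 61 sense codons of the universal code define the state space of the
codon substitution models; stop codons are excluded.  Tables are built
from Bio.Data.CodonTable at import time.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

STOP_CODONS: frozenset = frozenset(_STANDARD.stop_codons)

#: the 61 sense codons in lexicographic order (model state space)
SENSE_CODONS: tuple = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS)

CODON_INDEX: dict = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> one-letter amino acid
CODON_AA: dict = {c: _STANDARD.forward_table[c] for c in SENSE_CODONS}

N_SENSE = len(SENSE_CODONS)  # 61 for the standard code

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES) == (b in _PURINES) and a != b


def _pair_tables():
    """Precompute single-change pair structure over sense codons.

    Returns boolean matrices (61x61): single-nucleotide change,
    transition, nonsynonymous.
    """
    n = N_SENSE
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = is_transition(a, b)
            nonsyn[i, j] = CODON_AA[ci] != CODON_AA[cj]
    return single, transition, nonsyn


SINGLE_CHANGE, TRANSITION, NONSYNONYMOUS = _pair_tables()


def translate_cds(cds: str) -> str:
    """Translate an ungapped CDS; N-containing codons become X."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    out = []
    for k in range(0, len(cds), 3):
        codon = cds[k:k + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_AA[codon])
    return "".join(out)
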