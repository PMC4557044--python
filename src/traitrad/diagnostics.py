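"""Clade-diagnostic residues and genomic gene-cluster detection.

A diagnostic site is an alignment column where one clade is invariant
for a residue the other clade never shows.  Strict mode requires both
clades invariant; tolerant mode allows the contrast clade to be
"almost invariant" (majority residue frequency >= 1 - tau) as long as
the focal residue is absent from it.  Positions are reported both as
1-based alignment columns and in ungapped reference numbering.
Cluster detection measures the bp gap between nearest gene ends and
counts annotated loci strictly between the focal pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .iocore import GAP, Alignment, FormatError, GeneAnnotation


@dataclass
class ReferenceMap:
    """Bijection between alignment columns and reference positions."""

    reference_id: str
    column_to_position: dict       # 1-based column -> 1-based position
    position_to_column: dict       # inverse

    def position(self, column: int) -> Optional[int]:
        return self.column_to_position.get(column)

    def column(self, position: int) -> int:
        return self.position_to_column[position]


def map_alignment_to_reference(aln: Alignment,
                               reference_id: str) -> ReferenceMap:
    """Map non-gap reference columns to positions 1..L (gaps skipped)."""
    row = aln.row(reference_id)
    c2p, p2c = {}, {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            pos += 1
            c2p[col] = pos
            p2c[pos] = col
    return ReferenceMap(reference_id, c2p, p2c)


@dataclass
class DiagnosticSite:
    column: int                    # 1-based alignment column
    reference_position: Optional[int]
    cladeA_residue: str
    cladeB_profile: dict           # residue -> frequency in clade B
    strict: bool                   # True when clade B is invariant too

    @property
    def cladeB_majority(self) -> str:
        return max(self.cladeB_profile, key=self.cladeB_profile.get)


def diagnostic_sites(aln: Alignment, cladeA_rows: Iterable[str],
                     cladeB_rows: Iterable[str], reference_id: str,
                     mode: str = "strict", tau: float = 0.1,
                     max_gap_fraction: float = 0.5) -> list[DiagnosticSite]:
    """Columns invariant in clade A for a residue absent from clade B.

    Rows with a gap at a column are excluded from the invariance
    check, but a clade with more than ``max_gap_fraction`` gaps at a
    column makes that column ineligible.  ``mode`` is ``strict``
    (clade B invariant for a single different residue) or ``tolerant``
    (clade B majority residue frequency >= 1 - tau and the clade-A
    residue never present).
    """
    if mode not in ("strict", "tolerant"):
        raise ValueError(f"unknown mode {mode!r}")
    a_ids, b_ids = list(cladeA_rows), list(cladeB_rows)
    if set(a_ids) & set(b_ids):
        raise FormatError("clade partitions overlap")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise FormatError("each clade needs at least 2 rows")
    a_rows = [aln.row(i) for i in a_ids]
    b_rows = [aln.row(i) for i in b_ids]
    refmap = map_alignment_to_reference(aln, reference_id)
    out = []
    for col in range(1, aln.n_columns + 1):
        a_res = [r[col - 1] for r in a_rows if r[col - 1] != GAP]
        b_res = [r[col - 1] for r in b_rows if r[col - 1] != GAP]
        if len(a_res) < (1 - max_gap_fraction) * len(a_rows) or \
                len(b_res) < (1 - max_gap_fraction) * len(b_rows):
            continue
        if not a_res or len(set(a_res)) != 1:
            continue
        res_a = a_res[0]
        if res_a in b_res or not b_res:
            continue
        freq = {r: b_res.count(r) / len(b_res) for r in set(b_res)}
        strict = len(freq) == 1
        if mode == "strict" and not strict:
            continue
        if mode == "tolerant" and max(freq.values()) < 1 - tau:
            continue
        out.append(DiagnosticSite(
            column=col, reference_position=refmap.position(col),
            cladeA_residue=res_a, cladeB_profile=freq, strict=strict))
    return out


@dataclass
class ClusterReport:
    gene_a: str
    gene_b: str
    chromosome: Optional[str]
    distance: Optional[int]        # bp between nearest ends
    intervening_genes: Optional[int]
    within_threshold: bool
    linked: bool                   # False when on different chromosomes


def gene_clusters(annotations: Iterable[GeneAnnotation],
                  focal_ids: tuple, max_distance: int = 50000) -> ClusterReport:
    """Proximity report for a focal gene pair.

    Distance is ``max(0, later.start - earlier.end - 1)``; intervening
    genes lie strictly between the pair.  The report is symmetric in
    the pair order.
    """
    anns = list(annotations)
    by_id = {a.gene_id: a for a in anns}
    ga, gb = sorted(focal_ids)
    for g in (ga, gb):
        if g not in by_id:
            raise FormatError(f"focal gene {g!r} not annotated")
    a, b = by_id[ga], by_id[gb]
    if a.chromosome != b.chromosome:
        return ClusterReport(ga, gb, None, None, None,
                             within_threshold=False, linked=False)
    first, second = (a, b) if a.start <= b.start else (b, a)
    distance = max(0, second.start - first.end - 1)
    intervening = sum(
        1 for g in anns
        if g.chromosome == a.chromosome and g.gene_id not in (ga, gb)
        and g.start > first.end and g.end < second.start)
    return ClusterReport(ga, gb, a.chromosome, distance, intervening,
                         within_threshold=distance <= max_distance,
                         linked=True)
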