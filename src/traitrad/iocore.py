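"""Shared data model and file readers/writers.

Sequences (protein or CDS), alignments, codon alignments, trait tables,
gene annotations and the gene-tip -> species mapping rule.  FASTA I/O
goes through Bio.SeqIO; genomic coordinates are kept 1-based inclusive
exactly as GFF3 states them, and alignment columns are reported 1-based
everywhere.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
NUC_ALPHABET = set("ACGT") | {"N"}
GAP = "-"

TRAIT_STATES = ("anthocyanin", "betalain", "missing")


class FormatError(ValueError):
    """Raised for malformed input files or invalid sequence content."""


@dataclass
class Sequence:
    """An ungapped biological sequence.

    ``kind`` is ``"protein"`` or ``"cds"``; CDS residues must be a
    multiple of 3.  Ambiguity codes (X / N) are allowed and treated as
    missing data by the likelihood engines downstream.
    """

    id: str
    residues: str
    kind: str = "protein"

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if self.kind not in ("protein", "cds"):
            raise FormatError(f"unknown sequence kind {self.kind!r}")
        self.residues = self.residues.upper()
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else NUC_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise FormatError(
                f"illegal {self.kind} characters {sorted(bad)} in {self.id!r}")
        if self.kind == "cds" and len(self.residues) % 3 != 0:
            raise FormatError(
                f"CDS {self.id!r} length {len(self.residues)} not divisible by 3")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length gapped rows over one alphabet.

    ``kind`` is ``"protein"`` or ``"nucleotide"``; the gap character
    is ``-``.  Column indices in all public reports are 1-based.
    """

    ids: list[str]
    rows: list[str]
    kind: str = "protein"

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise FormatError(f"row {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """1-based column accessor."""
        if not 1 <= col <= self.n_columns:
            raise FormatError(f"column {col} out of range 1..{self.n_columns}")
        return "".join(r[col - 1] for r in self.rows)

    def column_occupancy(self, col: int) -> float:
        """Fraction of non-gap rows in a 1-based column."""
        chars = self.column(col)
        return sum(c != GAP for c in chars) / len(chars)

    def subset_columns(self, keep: Iterable[int]) -> "Alignment":
        """New alignment keeping the given 1-based columns, in order."""
        keep = list(keep)
        rows = ["".join(r[c - 1] for c in keep) for r in self.rows]
        return Alignment(list(self.ids), rows, kind=self.kind)

    def subset_rows(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = list(keep_ids)
        rows = [self.row(i) for i in keep]
        return Alignment(keep, rows, kind=self.kind)

    def to_sequences(self, kind: str = "protein") -> list[Sequence]:
        """Ungapped rows as Sequence objects."""
        return [Sequence(i, r.replace(GAP, ""), kind=kind)
                for i, r in zip(self.ids, self.rows)]


class CodonAlignment(Alignment):
    """Gapped CDS alignment whose column unit is the codon triplet.

    Every non-gap triplet must be a sense codon (or contain N,
    flagging missing data); gap triplets are exactly ``---``.
    """

    def __init__(self, ids: list[str], rows: list[str]):
        super().__init__(ids, rows, kind="nucleotide")
        if self.n_columns % 3 != 0:
            raise FormatError("codon alignment length not a multiple of 3")
        from .gencode import STOP_CODONS
        for sid, row in zip(self.ids, self.rows):
            for k in range(0, len(row), 3):
                codon = row[k:k + 3]
                if GAP in codon and codon != "---":
                    raise FormatError(
                        f"partial gap codon {codon!r} at codon "
                        f"{k // 3 + 1} in {sid!r}")
                if codon in STOP_CODONS:
                    raise FormatError(
                        f"internal stop codon {codon} at codon "
                        f"{k // 3 + 1} in {sid!r}")

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def codon(self, seq_id: str, pos: int) -> str:
        """1-based codon accessor."""
        row = self.row(seq_id)
        if not 1 <= pos <= self.n_codons:
            raise FormatError(f"codon {pos} out of range 1..{self.n_codons}")
        return row[(pos - 1) * 3: pos * 3]

    def codon_column(self, pos: int) -> list[str]:
        return [r[(pos - 1) * 3: pos * 3] for r in self.rows]

    def subset_codons(self, keep: Iterable[int]) -> "CodonAlignment":
        keep = list(keep)
        rows = ["".join(r[(p - 1) * 3: p * 3] for p in keep)
                for r in self.rows]
        return CodonAlignment(list(self.ids), rows)


@dataclass
class TraitTable:
    """OTU label -> pigment state (anthocyanin / betalain / missing)."""

    states: dict[str, str]

    def __post_init__(self):
        for otu, st in self.states.items():
            if st not in TRAIT_STATES:
                raise FormatError(
                    f"unknown trait state {st!r} for {otu!r}; "
                    f"allowed: {', '.join(TRAIT_STATES)}")

    def __getitem__(self, otu: str) -> str:
        return self.states[otu]

    def __contains__(self, otu: str) -> bool:
        return otu in self.states

    def species(self, state: Optional[str] = None) -> list[str]:
        if state is None:
            return list(self.states)
        return [o for o, s in self.states.items() if s == state]


@dataclass
class GeneAnnotation:
    """A gene feature with 1-based inclusive genomic coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1:
            raise FormatError(f"{self.gene_id}: start {self.start} < 1")
        if self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TipSpeciesMap:
    """Rule mapping gene-tree tip labels to species labels.

    The default convention is ``species@gene_id``: the species label is
    everything before the first delimiter occurrence.
    """

    delimiter: str = "@"

    def species_of(self, tip_label: str) -> str:
        sp = tip_label.split(self.delimiter, 1)[0]
        if not sp:
            raise FormatError(
                f"tip {tip_label!r} yields an empty species label")
        return sp

    def __call__(self, tip_label: str) -> str:
        return self.species_of(tip_label)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path, kind: str = "protein") -> list[Sequence]:
    """Read a FASTA file into Sequence objects, order preserved.

    The record id is the token before the first whitespace; duplicate
    ids are an error.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(Sequence(rec.id, str(rec.seq), kind=kind))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path, width: int = 80) -> None:
    seqs = list(seqs)
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate ids in FASTA output")
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment_fasta(path, kind: str = "protein") -> Alignment:
    """Read gapped FASTA as an Alignment (rows may contain '-')."""
    ids, rows = [], []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if kind == "codon":
        return CodonAlignment(ids, rows)
    return Alignment(ids, rows, kind=kind)


def write_alignment_fasta(aln: Alignment, path, width: int = 80) -> None:
    records = [SeqRecord(Seq(r), id=i, description="")
               for i, r in zip(aln.ids, aln.rows)]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3(path) -> list[GeneAnnotation]:
    """Read gene features from GFF3; other feature types are skipped."""
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            m = _GFF_ID_RE.search(attrs)
            gene_id = m.group(1) if m else f"{chrom}:{start}-{end}"
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id "
                                  f"{gene_id!r}")
            seen.add(gene_id)
            out.append(GeneAnnotation(gene_id, chrom, int(start), int(end),
                                      strand if strand in "+-" else "+"))
    return out


def write_gff3(annotations: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write("\t".join([
                a.chromosome, "traitrad", "gene", str(a.start), str(a.end),
                ".", a.strand, ".", f"ID={a.gene_id}"]) + "\n")


def read_trait_csv(path) -> TraitTable:
    """Read a two-column CSV (otu,state) into a TraitTable."""
    states: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                not {"otu", "state"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns otu,state")
        for row in reader:
            otu = row["otu"].strip()
            if otu in states:
                raise FormatError(f"{path}: duplicate OTU {otu!r}")
            states[otu] = row["state"].strip()
    return TraitTable(states)


def write_trait_csv(traits: TraitTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["otu", "state"])
        for otu, st in traits.states.items():
            writer.writerow([otu, st])
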