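"""Reading, writing and translating the standard formats the pipeline touches.

Everything downstream (intron scanning, likelihood, co-phylogeny tests) works on
the containers defined here: :class:`SequenceRecord`, :class:`MultipleAlignment`
and :class:`GeneticCode`.  Parsing of FASTA and NEXUS is delegated to Biopython;
Newick trees are handled in :mod:`cophylointron.phylo.tree` (dendropy-backed) and
re-exported here for convenience.

All user-facing coordinates are 1-based and inclusive, matching the field
convention of naming an intron by the reference CDS position immediately
preceding it ("inserted after position N").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN-?")

#: IUPAC nucleotide code -> set of compatible unambiguous bases.
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class SequenceRecord:
    """A single named sequence (DNA or protein)."""

    id: str
    seq: str
    alphabet: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} with empty sequence")
        self.seq = self.seq.upper()
        if self.alphabet == "dna":
            bad = set(self.seq) - IUPAC_DNA
            if bad:
                raise FormatError(
                    f"record {self.id!r}: non-IUPAC nucleotide codes {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "").replace("?", "")


@dataclass
class MultipleAlignment:
    """An aligned matrix of equal-length :class:`SequenceRecord` rows.

    Column indices are 1-based in every reported coordinate.
    """

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("empty alignment")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids in alignment: {dup}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, taxon: str) -> SequenceRecord:
        for r in self.records:
            if r.id == taxon:
                return r
        raise KeyError(taxon)

    def column(self, j: int) -> str:
        """Column ``j`` (1-based) as a string, one character per row."""
        return "".join(r.seq[j - 1] for r in self.records)

    def subset(self, taxa: Sequence[str]) -> "MultipleAlignment":
        by_id = {r.id: r for r in self.records}
        missing = [t for t in taxa if t not in by_id]
        if missing:
            raise KeyError(f"taxa absent from alignment: {missing}")
        return MultipleAlignment([by_id[t] for t in taxa])

    def concat(self, other: "MultipleAlignment") -> "MultipleAlignment":
        """Column-wise concatenation; rows matched by id (order from self)."""
        rows = []
        for r in self.records:
            rows.append(SequenceRecord(r.id, r.seq + other[r.id].seq, r.alphabet))
        return MultipleAlignment(rows)


@dataclass
class GeneticCode:
    """A 64-codon translation table, built from the NCBI tables in Biopython.

    Table 4 (the mold/protozoan/coelenterate mitochondrial code, used by
    demosponge mitochondria) maps TGA to tryptophan; table 1 (standard) maps it
    to stop.
    """

    table_id: int
    codon_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.codon_map:
            table = CodonTable.unambiguous_dna_by_id[self.table_id]
            self.codon_map = dict(table.forward_table)
            for stop in table.stop_codons:
                self.codon_map[stop] = "*"
        if len(self.codon_map) != 64:
            raise FormatError(f"genetic code table {self.table_id}: "
                              f"{len(self.codon_map)} codons mapped, expected 64")

    def __call__(self, codon: str) -> str:
        return self.codon_map.get(codon, "X")


TABLE_4 = GeneticCode(4)
TABLE_1 = GeneticCode(1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {r.id!r}")
        seen.add(r.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# NEXUS alignments
# ---------------------------------------------------------------------------

def read_nexus_alignment(path: str | Path, alphabet: str = "dna") -> MultipleAlignment:
    """Read a NEXUS DATA/CHARACTERS block (simple or interleaved).

    Dimensions declared in the file must match the parsed matrix.  TREES
    blocks, if present, are ignored with a logged warning.
    """
    path = Path(path)
    text = path.read_text()
    if "begin trees" in text.lower():
        logger.warning("%s: TREES block present and ignored", path)
    try:
        aln = AlignIO.read(str(path), "nexus")
    except Exception as exc:  # Bio.Nexus raises assorted exception types
        raise FormatError(f"{path}: cannot parse NEXUS alignment: {exc}") from exc
    records = [SequenceRecord(rec.id, str(rec.seq), alphabet) for rec in aln]
    out = MultipleAlignment(records)
    import re
    m = re.search(r"ntax\s*=\s*(\d+)", text, re.I)
    n = re.search(r"nchar\s*=\s*(\d+)", text, re.I)
    if m and int(m.group(1)) != out.n_taxa:
        raise FormatError(f"{path}: ntax={m.group(1)} but {out.n_taxa} rows parsed")
    if n and int(n.group(1)) != out.n_cols:
        raise FormatError(f"{path}: nchar={n.group(1)} but {out.n_cols} columns parsed")
    return out


def write_nexus_alignment(aln: MultipleAlignment, path: str | Path,
                          datatype: str = "dna") -> None:
    """Write a non-interleaved NEXUS DATA block (diff-stable output)."""
    pad = max(len(i) for i in aln.ids) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={aln.n_taxa} nchar={aln.n_cols};\n")
        fh.write(f"  format datatype={datatype} missing=? gap=-;\n  matrix\n")
        for r in aln.records:
            fh.write(f"    {r.id:<{pad}}{r.seq}\n")
        fh.write("  ;\nend;\n")


# ---------------------------------------------------------------------------
# Association tables (TSV)
# ---------------------------------------------------------------------------

def read_links_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read host<TAB>parasite link pairs, '#'-comments and blank lines skipped."""
    links: list[tuple[str, str]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{line_no}: expected 2 tab-separated fields")
        links.append((parts[0], parts[1]))
    if not links:
        raise FormatError(f"{path}: no links found")
    if len(set(links)) != len(links):
        raise FormatError(f"{path}: duplicate links")
    return links


def write_links_tsv(links: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#host\tparasite\n")
        for h, p in links:
            fh.write(f"{h}\t{p}\n")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str, code: GeneticCode = TABLE_4, frame: int = 0) -> str:
    """Translate a DNA string; stops rendered ``*``, partial tail codon dropped.

    ``frame`` is the 0-based offset into the sequence (0, 1 or 2).
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    bad = set(seq.upper()) - IUPAC_DNA
    if bad:
        raise FormatError(f"translate: non-nucleotide characters {sorted(bad)}")
    sub = seq.upper()[frame:]
    if len(sub) < 3:
        raise ValueError("fewer than one complete codon after frame offset")
    sub = sub[: len(sub) - len(sub) % 3]
    return "".join(code(sub[i:i + 3]) for i in range(0, len(sub), 3))
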