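"""Detection and characterisation of insertions in cox1 relative to a reference CDS.

A query cox1 sequence is globally aligned to an intronless reference CDS;
runs of gaps in the reference identify insertions (candidate group I
introns).  Insertions are named by the field's "position N" convention: N is
the last reference CDS nucleotide (1-based, counted from the A of the
reference start codon) preceding the inserted sequence.  When the insertion
boundary is ambiguous because the intron shares its flanking bases with the
exon, the placement is canonicalised to the leftmost equivalent position.

ORFs inside each insertion are scanned on both strands for the LAGLIDADG
homing-endonuclease motif, and internal TGA codons (tryptophan in the
mold/protozoan/coelenterate mitochondrial code, stop in the standard code)
are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align

from .formats_io import (AMBIGUITY, GeneticCode, MultipleAlignment,
                         SequenceRecord, TABLE_1, TABLE_4, reverse_complement,
                         translate)

LAGLIDADG = "LAGLIDADG"


# ---------------------------------------------------------------------------
# reference mapping
# ---------------------------------------------------------------------------

@dataclass
class ReferenceMap:
    """Pairing of query columns with reference CDS positions (both 1-based).

    ``pairs[k] = (query_pos, ref_pos)`` for every aligned, non-gap reference
    position; reference positions are strictly increasing.
    """

    pairs: list[tuple[int, int]]
    query_id: str
    reference_id: str
    identity: float  # % identity over aligned (both non-gap) positions

    def __post_init__(self) -> None:
        refs = [r for _, r in self.pairs]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("reference positions not strictly increasing")


def _global_aligner(match: float = 2.0, mismatch: float = -3.0,
                    gap_open: float = -8.0, gap_extend: float = -0.05,
                    free_end_gaps: bool = True) -> Align.PairwiseAligner:
    """Affine-gap global aligner tuned for exon/intron structure.

    Gap extension is nearly free so that a kilobase intron costs little more
    than one gap opening — otherwise insertions near a sequence end would be
    pushed into the (unpenalised) terminal overhang instead of being aligned
    as an internal reference-gap run.  End gaps are free by default because
    queries are typically partial CDSs.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if free_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def map_to_reference(query: SequenceRecord, reference: SequenceRecord,
                     min_identity: float = 40.0,
                     **aligner_scores) -> ReferenceMap:
    """Pairwise-align ``query`` to an intronless reference CDS.

    Returns the column map; raises if exon identity over aligned positions is
    below ``min_identity`` percent (reference unsuitable).
    """
    q = query.ungapped()
    r = reference.ungapped()
    aligner = _global_aligner(**aligner_scores)
    alignment = aligner.align(q, r)[0]
    pairs: list[tuple[int, int]] = []
    matches = aligned = 0
    q_blocks, r_blocks = alignment.aligned
    for (qs, qe), (rs, re_) in zip(q_blocks, r_blocks):
        for k in range(qe - qs):
            pairs.append((qs + k + 1, rs + k + 1))
            aligned += 1
            if q[qs + k] == r[rs + k]:
                matches += 1
    # exon identity denominator: aligned columns, short query-insertion runs,
    # and every internal reference-deletion run, all scored as mismatches.
    # Insertion-scale query runs (>= 30 bp: candidate introns) and terminal
    # overhangs (partial CDSs) are excluded, so a kilobase intron does not
    # depress identity — but a patchwork alignment of unrelated sequences,
    # which must skip large reference stretches between chance matches, does.
    denom = aligned
    for i in range(1, len(q_blocks)):
        dq = q_blocks[i][0] - q_blocks[i - 1][1]
        dr = r_blocks[i][0] - r_blocks[i - 1][1]
        if 0 < dq < 30:
            denom += dq
        denom += dr
    identity = 100.0 * matches / denom if denom else 0.0
    if identity < min_identity:
        raise ValueError(
            f"reference unsuitable: {identity:.1f}% identity between "
            f"{query.id!r} and {reference.id!r} over aligned exon")
    return ReferenceMap(pairs, query.id, reference.id, identity)


# ---------------------------------------------------------------------------
# insertion detection
# ---------------------------------------------------------------------------

@dataclass
class InsertionRecord:
    """One detected insertion: reference position immediately before it,
    length, and the inserted sequence itself."""

    query_id: str
    site: int      # 1-based reference CDS position preceding the insertion
    length: int
    seq: str
    orfs: list["OrfRecord"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length != len(self.seq) or self.length <= 0:
            raise ValueError("insertion length must equal len(seq) and be > 0")
        if self.site < 1:
            raise ValueError("insertion site must be >= 1")


def detect_insertions(refmap: ReferenceMap, query: SequenceRecord,
                      reference: SequenceRecord,
                      min_len: int = 30) -> list[InsertionRecord]:
    """Insertions (reference-gap runs >= ``min_len``) from a reference map.

    Placement is canonicalised leftmost: while the last inserted base equals
    the reference base at the insertion site, the insertion is shifted one
    position left.  Records are sorted by site.
    """
    q = query.ungapped()
    r = reference.ungapped()
    out: list[InsertionRecord] = []
    pairs = refmap.pairs
    for k in range(len(pairs) - 1):
        q0, r0 = pairs[k]
        q1, r1 = pairs[k + 1]
        if r1 == r0 + 1 and q1 > q0 + 1:
            ins = q[q0:q1 - 1]
            site = r0
            # canonicalise to the leftmost equivalent placement
            while site >= 1 and ins[-1] == r[site - 1]:
                ins = r[site - 1] + ins[:-1]
                site -= 1
            if site >= 1 and len(ins) >= min_len:
                out.append(InsertionRecord(query.id, site, len(ins), ins))
    out.sort(key=lambda rec: rec.site)
    return out


def scan_query(query: SequenceRecord, reference: SequenceRecord,
               code: GeneticCode = TABLE_4, min_len: int = 30,
               min_aa: int = 50) -> list[InsertionRecord]:
    """Map, detect and ORF-annotate in one call."""
    refmap = map_to_reference(query, reference)
    records = detect_insertions(refmap, query, reference, min_len=min_len)
    for rec in records:
        rec.orfs = find_orfs(rec.seq, code=code, min_aa=min_aa)
    return records


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------

@dataclass
class OrfRecord:
    """A start-to-stop ORF inside an intron, positions 1-based on the intron's
    forward strand."""

    start: int
    end: int
    strand: str          # '+' or '-'
    frame: int           # 0..2 on the scanned strand
    protein: str         # translation without the terminal stop
    has_laglidadg: bool
    internal_tga_count: int

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("ORF span not a multiple of 3")


def _motif_hit(protein: str, motif: str = LAGLIDADG, max_mismatch: int = 1) -> bool:
    m = len(motif)
    for i in range(len(protein) - m + 1):
        mism = sum(a != b for a, b in zip(protein[i:i + m], motif))
        if mism <= max_mismatch:
            return True
    return False


def find_orfs(intron: str, code: GeneticCode = TABLE_4,
              min_aa: int = 50) -> list[OrfRecord]:
    """All maximal start-to-stop ORFs of >= ``min_aa`` residues, both strands.

    Each ORF is translated under ``code`` (so TGA reads through as W under
    table 4), scanned for the LAGLIDADG motif allowing one mismatch, and its
    internal TGA codons — stops under the standard code — are counted.
    """
    intron = intron.upper()
    n = len(intron)
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        seq = intron if strand == "+" else reverse_complement(intron)
        for frame in range(3):
            codons = [seq[i:i + 3] for i in range(frame, n - 2, 3)]
            start_idx: Optional[int] = None
            for ci, codon in enumerate(codons):
                aa = code(codon)
                if start_idx is None:
                    if codon == "ATG":
                        start_idx = ci
                    continue
                if aa == "*":
                    length_aa = ci - start_idx
                    if length_aa >= min_aa:
                        out.append(_make_orf(seq, strand, frame, start_idx, ci,
                                             n, code))
                    start_idx = None
    out.sort(key=lambda o: (o.start, o.strand))
    return out


def _make_orf(seq: str, strand: str, frame: int, start_ci: int, stop_ci: int,
              n: int, code: GeneticCode) -> OrfRecord:
    s = frame + 3 * start_ci          # 0-based on scanned strand, incl. ATG
    e = frame + 3 * stop_ci + 3       # exclusive, incl. stop codon
    sub = seq[s:e]
    protein = translate(sub[:-3], code) if len(sub) > 3 else ""
    tga = sum(1 for i in range(0, len(sub) - 3, 3) if sub[i:i + 3] == "TGA")
    if strand == "+":
        start, end = s + 1, e
    else:
        start, end = n - e + 1, n - s
    return OrfRecord(start=start, end=end, strand=strand, frame=frame,
                     protein=protein, has_laglidadg=_motif_hit(protein),
                     internal_tga_count=tga)


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str, **aligner_scores) -> float:
    """Percent identity from a global alignment.

    Both-gap columns are excluded from the denominator; a gap against a base
    counts as a mismatch.  Identical sequences give exactly 100.0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 100.0
    aligner = _global_aligner(free_end_gaps=False, gap_extend=-1.0,
                              **aligner_scores)
    alignment = aligner.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    matches = total = 0
    for x, y in zip(sa, sb):
        if x == "-" and y == "-":
            continue
        total += 1
        if x == y:
            matches += 1
    return 100.0 * matches / total


# ---------------------------------------------------------------------------
# alignment column statistics
# ---------------------------------------------------------------------------

@dataclass
class ColumnStats:
    """Per-column classification counts for a nucleotide alignment."""

    n_cols: int
    n_constant: int
    n_variable: int
    n_informative: int
    n_with_missing: int


_UNAMBIG = set("ACGT")
_MISSING = set("-?N")


def column_stats(aln: MultipleAlignment) -> ColumnStats:
    """Constant / variable / parsimony-informative / missing-data counts.

    A column is classified on its unambiguous residues only: constant when at
    most one state occurs among them (columns that are all-missing count as
    constant), variable otherwise, parsimony-informative when at least two
    states each occur in at least two sequences.  ``n_with_missing`` counts
    columns containing '-', '?' or 'N'.
    """
    n_constant = n_variable = n_informative = n_missing = 0
    for j in range(1, aln.n_cols + 1):
        col = aln.column(j)
        if any(c in _MISSING for c in col):
            n_missing += 1
        residues = [c for c in col if c in _UNAMBIG]
        states = set(residues)
        if len(states) <= 1:
            n_constant += 1
            continue
        n_variable += 1
        counts = sorted((residues.count(s) for s in states), reverse=True)
        if len([c for c in counts if c >= 2]) >= 2:
            n_informative += 1
    return ColumnStats(aln.n_cols, n_constant, n_variable, n_informative,
                       n_missing)
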