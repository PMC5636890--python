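"""Identification and triage of candidate virophage / giant-virus genomes.

Uncultivated virophage genomes are recovered from assemblies by looking for
their hallmark gene — the major capsid protein (MCP) — among predicted
proteins, then classified by how complete the assembled contig is likely to
be.  A contig is considered a *complete* genome when its assembly shows one of
the two known virophage genome architectures: a circular (or circularly
permuted) molecule, detected as identical overlapping 5'/3' contig ends, or a
linear molecule flanked by terminal inverted repeats (TIRs) of at least
100 bp.  Linear contigs of at least 13 kb — the low end of known complete
virophage genome sizes — are treated as *near-complete*; everything shorter is
a partial genome.  Contigs assembled independently from the same population
(>99% nucleotide identity) are deduplicated, keeping the longest
representative.

All coordinates are 1-based inclusive, as in GFF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: Linear contigs at least this long count as near-complete genomes.
NEAR_COMPLETE_MIN_BP = 13_000

#: Default similarity thresholds for marker and affiliation searches.
DEFAULT_MIN_BITSCORE = 50.0
DEFAULT_MAX_EVALUE = 1e-3

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """A predicted protein-coding gene on a contig (1-based inclusive)."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    protein: str = ""
    wraps_origin: bool = False  # only legal on circular genomes

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or (self.end < self.start and not self.wraps_origin):
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for {self.gene_id}"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A contig (or multi-contig bin) with its genes and assembly topology."""

    id: str
    sequence: str
    topology: str = "linear"       # circular | tir | linear
    completeness: str = "partial"  # complete | near_complete | partial
    genes: list[GeneRecord] = field(default_factory=list)
    marker_class: str = "none"     # virophage_mcp | ncldv_mcp | none
    source: str = ""               # originating dataset (lake/layer)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Nucleotide sequence of a gene in coding orientation."""
        seg = self.sequence[gene.start - 1 : gene.end]
        return reverse_complement(seg) if gene.strand == "-" else seg


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column tabular (BLAST outfmt-6 dialect) comparison."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    query_coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.e_value < 0 or self.bit_score < 0:
            raise ValueError("e_value and bit_score must be non-negative")
        if not 0.0 <= self.query_coverage_fraction <= 1.0:
            raise ValueError("query_coverage_fraction must lie in [0, 1]")

    def passes(self, min_bitscore: float = DEFAULT_MIN_BITSCORE,
               max_evalue: float = DEFAULT_MAX_EVALUE) -> bool:
        return self.bit_score >= min_bitscore and self.e_value <= max_evalue


# ---------------------------------------------------------------------------
# Marker-based discovery
# ---------------------------------------------------------------------------

def detect_marker_contigs(
    genes: Sequence[GeneRecord],
    hits: Iterable[SimilarityHit],
    marker_reference_lengths: Mapping[str, int],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_marker_completeness: float = 0.8,
    marker_class: str = "virophage_mcp",
) -> dict[str, str]:
    """Flag genomes carrying a (near-)complete marker gene.

    A genome is flagged when at least one of its predicted proteins hits a
    marker reference with bit score >= ``min_bitscore``, E-value <=
    ``max_evalue``, and an aligned fraction of the reference marker length
    above ``min_marker_completeness`` (the ">80% of the MCP" rule).

    Parameters
    ----------
    genes
        Predicted genes; hits must reference their ``gene_id``s.
    hits
        Protein similarity hits of genes (queries) against marker references
        (subjects).
    marker_reference_lengths
        Length (aa) of each marker reference protein, keyed by subject id.

    Returns
    -------
    dict mapping flagged genome id -> marker_class.
    """
    gene_to_genome = {g.gene_id: g.genome_id for g in genes}
    flagged: dict[str, str] = {}
    for hit in hits:
        if hit.query_id not in gene_to_genome:
            raise KeyError(f"hit references unknown gene id {hit.query_id!r}")
        if hit.subject_id not in marker_reference_lengths:
            continue  # hit against a non-marker subject
        if not hit.passes(min_bitscore, max_evalue):
            continue
        ref_len = marker_reference_lengths[hit.subject_id]
        completeness = hit.alignment_length / ref_len
        if completeness >= min_marker_completeness:
            flagged[gene_to_genome[hit.query_id]] = marker_class
    return flagged


# ---------------------------------------------------------------------------
# Topology: circularity and terminal inverted repeats
# ---------------------------------------------------------------------------

def detect_circularity(sequence: str, min_overlap_bp: int = 20) -> tuple[bool, int]:
    """Detect a circular contig via identical overlapping 5' and 3' ends.

    Scans for the longest exact match between a prefix and a suffix of the
    contig (overlap capped at half the contig length so the two copies are
    disjoint).  Returns ``(is_circular, overlap_length)`` with overlap 0 when
    no qualifying overlap exists.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= 2 * min_overlap_bp:
        warnings.warn(
            f"sequence of {n} bp too short for circularity scan "
            f"(needs > {2 * min_overlap_bp} bp)", stacklevel=2)
        return False, 0
    for k in range(n // 2, min_overlap_bp - 1, -1):
        if seq[:k] == seq[n - k:]:
            return True, k
    return False, 0


def detect_tir(sequence: str, min_tir_bp: int = 100,
               topology: str = "linear") -> tuple[bool, int]:
    """Detect terminal inverted repeats on a linear contig.

    A TIR is a prefix whose reverse complement equals a suffix of the contig.
    The longest such match of at least ``min_tir_bp`` is reported.  Calling
    this on a circular contig is a precondition violation.
    """
    if topology == "circular":
        raise ValueError("TIR detection applies to linear contigs only")
    seq = sequence.upper()
    n = len(seq)
    best = 0
    for k in range(min(n // 2, n), 0, -1):
        if reverse_complement(seq[:k]) == seq[n - k:]:
            best = k
            break
    if best >= min_tir_bp:
        return True, best
    return False, best


def assign_topology(record: GenomeRecord, min_overlap_bp: int = 20,
                    min_tir_bp: int = 100) -> GenomeRecord:
    """Set ``record.topology`` from the sequence (circular > tir > linear)."""
    circ, _ = detect_circularity(record.sequence, min_overlap_bp)
    if circ:
        record.topology = "circular"
        return record
    tir, _ = detect_tir(record.sequence, min_tir_bp)
    record.topology = "tir" if tir else "linear"
    return record


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

def classify_completeness(topology: str, length_bp: int,
                          near_complete_min_bp: int = NEAR_COMPLETE_MIN_BP) -> str:
    """Completeness class from assembly topology and contig length.

    Circular contigs and linear contigs with TIRs are complete genomes;
    linear contigs of at least 13 kb are near-complete; the rest are partial.
    """
    if topology in ("circular", "tir"):
        return "complete"
    if topology == "linear":
        return "near_complete" if length_bp >= near_complete_min_bp else "partial"
    raise ValueError(f"unknown topology {topology!r}")


def classify_record(record: GenomeRecord, **kwargs) -> GenomeRecord:
    record.completeness = classify_completeness(record.topology,
                                                record.length_bp, **kwargs)
    return record


# ---------------------------------------------------------------------------
# Deduplication of near-identical contigs
# ---------------------------------------------------------------------------

def deduplicate_contigs(
    records: Sequence[GenomeRecord],
    identity_pairs: Iterable[tuple[str, str, float]],
    min_identity: float = 0.99,
) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Collapse contigs assembled independently from the same population.

    Pairs above ``min_identity`` nucleotide identity are linked; within each
    connected component the longest contig is retained (ties broken by
    lexicographically smallest id).  Returns the representative records plus a
    log of (dropped_id, kept_id, identity) decisions.
    """
    by_id = {r.id: r for r in records}
    parent = {r.id: r.id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    best_identity: dict[str, float] = {}
    for a, b, ident in identity_pairs:
        if a not in by_id or b not in by_id:
            raise KeyError(f"identity pair references unknown contig: {a}, {b}")
        if ident > min_identity:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
            for x in (a, b):
                best_identity[x] = max(best_identity.get(x, 0.0), ident)

    components: dict[str, list[str]] = {}
    for rid in by_id:
        components.setdefault(find(rid), []).append(rid)

    kept: list[GenomeRecord] = []
    log_rows = []
    for members in components.values():
        # keep the longest contig; ties broken by lexicographically smallest id
        rep = sorted(members, key=lambda i: (-by_id[i].length_bp, i))[0]
        kept.append(by_id[rep])
        for m in members:
            if m != rep:
                log_rows.append((m, rep, best_identity.get(m, float("nan"))))
    kept.sort(key=lambda r: r.id)
    log = pd.DataFrame(log_rows, columns=["dropped_id", "kept_id", "identity"])
    return kept, log


# ---------------------------------------------------------------------------
# Tabular / FASTA I/O
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def read_hits_tsv(path) -> list[SimilarityHit]:
    """Read similarity hits from 12-column tab-separated (outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        span = abs(row.qend - row.qstart) + 1
        hits.append(SimilarityHit(
            query_id=str(row.qseqid), subject_id=str(row.sseqid),
            percent_identity=float(row.pident),
            alignment_length=int(row.length),
            e_value=float(row.evalue), bit_score=float(row.bitscore),
            query_coverage_fraction=min(1.0, span / max(span, row.length)),
        ))
    return hits


def write_hits_tsv(hits: Sequence[SimilarityHit], path) -> None:
    rows = []
    for h in hits:
        rows.append([h.query_id, h.subject_id, h.percent_identity,
                     h.alignment_length, 0, 0, 1, h.alignment_length,
                     1, h.alignment_length, h.e_value, h.bit_score])
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False)


def read_genomes_fasta(path) -> list[GenomeRecord]:
    return [GenomeRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_genomes_fasta(records: Sequence[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i:i + 70] + "\n")


GENE_TSV_COLUMNS = ["genome_id", "gene_id", "start", "end", "strand"]


def read_genes_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    return [GeneRecord(gene_id=str(r.gene_id), genome_id=str(r.genome_id),
                       start=int(r.start), end=int(r.end), strand=str(r.strand))
            for r in df.itertuples(index=False)]


def write_genes_tsv(genes: Sequence[GeneRecord], path) -> None:
    pd.DataFrame(
        [(g.genome_id, g.gene_id, g.start, g.end, g.strand) for g in genes],
        columns=GENE_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_proteins_fasta(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.protein}\n")


def read_proteins_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
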