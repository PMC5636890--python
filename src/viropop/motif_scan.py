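"""Promoter-motif extraction and fuzzy scanning across viral contigs.

Virophages are thought to hijack the "late" transcription programme of their
giant-virus host, so a promoter motif discovered upstream of the host's genes
and found again upstream of (or anywhere on) the associated virophage contig
strengthens a co-occurrence-based host prediction.  This module extracts the
30-nt regions upstream of predicted CDS, scans IUPAC nucleotide motifs
(4-30 nt) across contigs on both strands allowing a configurable number of
mismatches (default 1), filters out motifs that are merely AT-rich, and
reports motifs shared between predicted virophage-host partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_discovery import GeneRecord, GenomeRecord, reverse_complement

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

MIN_MOTIF_LEN, MAX_MOTIF_LEN = 4, 30

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_iupac(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """An IUPAC nucleotide motif and the entity it was discovered in."""

    pattern: str
    source_entity: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not MIN_MOTIF_LEN <= len(pat) <= MAX_MOTIF_LEN:
            raise ValueError(
                f"motif length must be {MIN_MOTIF_LEN}-{MAX_MOTIF_LEN} nt")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in motif: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)

    @property
    def at_fraction(self) -> float:
        """Fraction of positions whose IUPAC code allows only A/T."""
        at = sum(1 for c in self.pattern if IUPAC[c] <= {"A", "T"})
        return at / len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    contig: str
    position: int        # 1-based start of the window on the forward strand
    strand: str          # '+' or '-'
    mismatches: int
    motif: str
    upstream_of_gene: str | None = None


def filter_at_rich(motifs: Iterable[Motif],
                   max_at_fraction: float = 0.85) -> list[Motif]:
    """Drop motifs that are only an AT-rich stretch (A+T fraction above cut)."""
    return [m for m in motifs if m.at_fraction <= max_at_fraction]


# ---------------------------------------------------------------------------
# Upstream region extraction
# ---------------------------------------------------------------------------

def extract_upstream(genes: Sequence[GeneRecord],
                     genomes: Sequence[GenomeRecord],
                     window: int = 30) -> pd.DataFrame:
    """The ``window`` nt immediately 5' of each CDS, in coding orientation.

    For '+'-strand genes this is positions [start-window, start-1]; for
    '-'-strand genes the reverse complement of [end+1, end+window].  On
    linear contigs the window is truncated at the contig edge (and flagged);
    on circular contigs it wraps around the origin.
    """
    by_id = {g.id: g for g in genomes}
    rows = []
    for gene in genes:
        genome = by_id[gene.genome_id]
        seq = genome.sequence.upper()
        L = len(seq)
        circular = genome.topology == "circular"
        if gene.strand == "+":
            lo, hi = gene.start - window, gene.start - 1  # 1-based inclusive
            if lo < 1 and not circular:
                lo, truncated = 1, True
            else:
                truncated = False
            if hi < 1:
                region = ""
            elif lo >= 1:
                region = seq[lo - 1: hi]
            else:  # circular wrap through the origin
                region = seq[lo - 1 + L:] + seq[:hi]
        else:
            lo, hi = gene.end + 1, gene.end + window
            if hi > L and not circular:
                hi, truncated = L, True
            else:
                truncated = False
            if lo > L and not circular:
                region = ""
            elif hi <= L:
                region = seq[lo - 1: hi]
            else:
                region = seq[lo - 1:] + seq[: hi - L]
            region = reverse_complement(region)
        rows.append((gene.gene_id, gene.genome_id, region, len(region),
                     truncated))
    return pd.DataFrame(rows, columns=["gene_id", "genome_id", "upstream",
                                       "length", "truncated"])


# ---------------------------------------------------------------------------
# Fuzzy IUPAC scanning
# ---------------------------------------------------------------------------

def _scan_one_strand(pattern: str, seq: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(0-based window start, mismatches) for windows within the budget."""
    sets = [IUPAC[c] for c in pattern]
    m, n = len(pattern), len(seq)
    hits = []
    for i in range(n - m + 1):
        mism = 0
        for j, allowed in enumerate(sets):
            if seq[i + j] not in allowed:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append((i, mism))
    return hits


def scan_motif(motif: Motif, sequences: Mapping[str, str],
               max_mismatch: int = 1, both_strands: bool = True
               ) -> list[MotifHit]:
    """Scan an IUPAC motif across sequences allowing mismatches.

    A window matches when the number of positions whose base is not in the
    motif's IUPAC set is at most ``max_mismatch`` (ambiguity codes give full
    match, never partial credit).  Reverse-strand hits are found by scanning
    the reverse-complemented pattern; their reported position is the window
    start on the forward strand.
    """
    hits: list[MotifHit] = []
    rc = reverse_complement_iupac(motif.pattern)
    for contig, seq in sequences.items():
        seq = seq.upper()
        for start, mism in _scan_one_strand(motif.pattern, seq, max_mismatch):
            hits.append(MotifHit(contig=contig, position=start + 1,
                                 strand="+", mismatches=mism,
                                 motif=motif.pattern))
        if both_strands:
            for start, mism in _scan_one_strand(rc, seq, max_mismatch):
                hits.append(MotifHit(contig=contig, position=start + 1,
                                     strand="-", mismatches=mism,
                                     motif=motif.pattern))
    return hits


# ---------------------------------------------------------------------------
# Shared-motif support for host predictions
# ---------------------------------------------------------------------------

def shared_motif_report(virophage_hits: Iterable[MotifHit],
                        ncldv_hits: Iterable[MotifHit],
                        predicted_pairs: Iterable[tuple[str, str]]
                        ) -> pd.DataFrame:
    """Motifs found on both sides of each predicted (virophage, host) pair.

    A motif supports a pair when it hits the host contig (where it was
    discovered or scanned) and also hits the associated virophage contig.
    Pairs without any shared motif appear with an empty motif list, leaving
    the prediction unchanged.
    """
    v_by_contig: dict[str, set[str]] = {}
    for h in virophage_hits:
        v_by_contig.setdefault(h.contig, set()).add(h.motif)
    n_by_contig: dict[str, set[str]] = {}
    for h in ncldv_hits:
        n_by_contig.setdefault(h.contig, set()).add(h.motif)
    rows = []
    for viro, host in predicted_pairs:
        shared = sorted(v_by_contig.get(viro, set())
                        & n_by_contig.get(host, set()))
        rows.append((viro, host, shared, len(shared) > 0))
    return pd.DataFrame(rows, columns=["virophage", "host", "shared_motifs",
                                       "supported"])


def hits_to_tsv(hits: Sequence[MotifHit], path) -> None:
    pd.DataFrame(
        [(h.contig, h.position, h.strand, h.mismatches, h.motif) for h in hits],
        columns=["contig", "pos", "strand", "mismatches", "motif"],
    ).to_csv(path, sep="\t", index=False)


def read_motifs_tsv(path) -> list[Motif]:
    df = pd.read_csv(path, sep="\t")
    return [Motif(pattern=str(r.pattern),
                  source_entity=str(getattr(r, "source_entity", "")))
            for r in df.itertuples(index=False)]
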