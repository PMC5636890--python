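"""Population genetics of sequence-discrete virophage populations.

Virophage populations in lake metagenomes behave as *sequence-discrete*
populations: reads recruited by a contig map overwhelmingly at >= 99%
nucleotide identity, with minimal coverage below the ~95% identity "species"
gap.  This module profiles per-contig read-identity histograms, calls SNPs
from pooled pileups (a non-reference allele needs >= 4 supporting reads),
classifies coding SNPs as synonymous or non-synonymous by codon translation,
and evaluates selective constraint per gene through pN/pS — observed
non-synonymous and synonymous polymorphism rates normalised by the
Nei-Gojobori expected site counts under neutral, equal-rate mutation.
pN/pS < 1 indicates purifying selection.

Pileups arrive as tidy tables with columns
``contig, sample, pos, ref, A, C, G, T`` (1-based positions); read identity
tables as ``read_id, contig_id, percent_identity, sample_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_discovery import GeneRecord, GenomeRecord, reverse_complement

NUCLEOTIDES = ("A", "C", "G", "T")

#: Minimum read support for a SNP allele.
MIN_SNP_SUPPORT = 4

PILEUP_COLUMNS = ["contig", "sample", "pos", "ref", "A", "C", "G", "T"]
IDENTITY_COLUMNS = ["read_id", "contig_id", "percent_identity", "sample_id"]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    """One-letter amino acid, with '*' for stop codons."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


# ---------------------------------------------------------------------------
# Read-identity recruitment profiles
# ---------------------------------------------------------------------------

def recruitment_profile(identity_table: pd.DataFrame, bin_width: float = 1.0
                        ) -> pd.DataFrame:
    """Per-contig read-identity histogram with discreteness summaries.

    Returns one row per contig with ``n_reads``, ``frac_ge_99`` (fraction of
    reads mapping at >= 99% identity), ``frac_lt_95`` and the normalised
    histogram over [0, 100] at ``bin_width``-percent bins (as a list).
    Contigs recruiting zero reads simply do not appear.
    """
    if identity_table.empty:
        raise ValueError("identity table is empty")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    rows = []
    for contig, grp in identity_table.groupby("contig_id"):
        ident = grp["percent_identity"].to_numpy(dtype=float)
        hist, _ = np.histogram(np.clip(ident, 0, 100 - 1e-9), bins=edges)
        hist = hist / len(ident)
        rows.append({
            "contig_id": contig,
            "n_reads": len(ident),
            "frac_ge_99": float(np.mean(ident >= 99.0)),
            "frac_lt_95": float(np.mean(ident < 95.0)),
            "histogram": hist,
        })
    return pd.DataFrame(rows).set_index("contig_id")


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def call_snps(pileups: pd.DataFrame, min_support: int = MIN_SNP_SUPPORT,
              contig_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Call SNPs from pileups pooled across all samples/time points.

    A site is a SNP when any non-reference allele is supported by at least
    ``min_support`` reads in the pooled counts; every qualifying alternate
    allele yields one row.  Fixed differences from the assembly consensus
    (zero reference reads) are included.  ``n_alleles_detected`` counts
    alleles with >= 1 pooled read at sites with total coverage >= 4.

    Returns a table with columns
    ``contig, position, ref, alt, support, total, n_alleles_detected``.
    """
    pooled = (pileups.groupby(["contig", "pos", "ref"], as_index=False)
              [list(NUCLEOTIDES)].sum())
    if contig_lengths is not None:
        bad = pooled[[p > contig_lengths[c] or p < 1
                      for c, p in zip(pooled["contig"], pooled["pos"])]]
        if len(bad):
            raise ValueError(
                f"pileup positions outside contig bounds:\n{bad.head()}")
    rows = []
    for row in pooled.itertuples(index=False):
        counts = {b: int(getattr(row, b)) for b in NUCLEOTIDES}
        total = sum(counts.values())
        n_alleles = sum(1 for c in counts.values() if c >= 1)
        for alt in NUCLEOTIDES:
            if alt == row.ref:
                continue
            if counts[alt] >= min_support:
                rows.append((row.contig, int(row.pos), row.ref, alt,
                             counts[alt], total, n_alleles))
    return pd.DataFrame(rows, columns=["contig", "position", "ref", "alt",
                                       "support", "total",
                                       "n_alleles_detected"])


# ---------------------------------------------------------------------------
# Synonymous / non-synonymous classification
# ---------------------------------------------------------------------------

def classify_snp(gene: GeneRecord, genome: GenomeRecord, position: int,
                 ref: str, alt: str) -> str:
    """Classify a substitution at a genomic position relative to one gene.

    The codon containing the site (in coding orientation; minus-strand genes
    are reverse-complemented) is mutated and translated; an unchanged amino
    acid is ``synonymous``, anything else — including stop gain/loss — is
    ``nonsynonymous``.  Positions outside the gene are ``intergenic``.
    """
    if not (gene.start <= position <= gene.end):
        return "intergenic"
    coding = genome.gene_sequence(gene).upper()
    if gene.strand == "+":
        offset = position - gene.start
        c_ref, c_alt = ref.upper(), alt.upper()
    else:
        offset = gene.end - position
        c_ref = reverse_complement(ref.upper())
        c_alt = reverse_complement(alt.upper())
    if coding[offset] != c_ref:
        warnings.warn(
            f"reference mismatch at {genome.id}:{position} in {gene.gene_id}: "
            f"gene has {coding[offset]}, pileup says {c_ref}", stacklevel=2)
    codon_idx = offset // 3
    codon_start = codon_idx * 3
    codon = coding[codon_start:codon_start + 3]
    if len(codon) < 3:
        return "intergenic"  # trailing partial codon: not classifiable
    mutated = codon[:offset - codon_start] + c_alt + codon[offset - codon_start + 1:]
    return ("synonymous" if _translate_codon(codon) == _translate_codon(mutated)
            else "nonsynonymous")


def annotate_snps(snps: pd.DataFrame, genomes: Sequence[GenomeRecord]
                  ) -> pd.DataFrame:
    """Attach gene context and syn/nonsyn labels to a SNP table.

    Each SNP is classified independently in every gene covering it; SNPs in
    more than one gene appear once per gene with ``overlapping=True``.
    Intergenic SNPs keep one row with ``effect='intergenic'``.
    """
    by_id = {g.id: g for g in genomes}
    rows = []
    for snp in snps.itertuples(index=False):
        genome = by_id[snp.contig]
        covering = [g for g in genome.genes
                    if g.start <= snp.position <= g.end]
        if not covering:
            rows.append({**snp._asdict(), "gene_id": None, "codon_index": None,
                         "effect": "intergenic", "overlapping": False})
            continue
        for g in covering:
            offset = (snp.position - g.start if g.strand == "+"
                      else g.end - snp.position)
            rows.append({**snp._asdict(), "gene_id": g.gene_id,
                         "codon_index": offset // 3,
                         "effect": classify_snp(g, genome, snp.position,
                                                snp.ref, snp.alt),
                         "overlapping": len(covering) > 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neutral site counting (Nei-Gojobori, equal rates)
# ---------------------------------------------------------------------------

def codon_site_counts(codon: str) -> tuple[float, float]:
    """(n_sites, s_sites) for one codon by enumerating its 9 point mutations.

    Each codon position contributes 1 site split between non-synonymous and
    synonymous in proportion to its 3 possible substitutions; totals over the
    codon sum to exactly 3.  Stop gains/losses count as non-synonymous;
    stop-to-stop changes as synonymous.
    """
    codon = codon.upper()
    aa = _translate_codon(codon)
    syn = 0
    for i in range(3):
        for b in NUCLEOTIDES:
            if b == codon[i]:
                continue
            mutated = codon[:i] + b + codon[i + 1:]
            if _translate_codon(mutated) == aa:
                syn += 1
    s = syn / 3.0
    return 3.0 - s, s


def neutral_site_counts(gene_nt: str) -> tuple[float, float]:
    """Expected non-synonymous and synonymous site counts for a gene.

    Nei-Gojobori counting with equal mutation rates over all substitutions.
    A trailing partial codon is truncated with a warning; internal stop
    codons are counted but flagged.
    """
    seq = gene_nt.upper()
    if len(seq) % 3:
        warnings.warn(f"gene length {len(seq)} not divisible by 3; trailing "
                      "partial codon truncated", stacklevel=2)
        seq = seq[: len(seq) - len(seq) % 3]
    n_sites = s_sites = 0.0
    n_codons = len(seq) // 3
    for k in range(n_codons):
        codon = seq[3 * k: 3 * k + 3]
        if _translate_codon(codon) == "*" and k < n_codons - 1:
            warnings.warn(f"internal stop codon at codon {k}", stacklevel=2)
        n, s = codon_site_counts(codon)
        n_sites += n
        s_sites += s
    return n_sites, s_sites


# ---------------------------------------------------------------------------
# pN/pS and summaries
# ---------------------------------------------------------------------------

@dataclass
class GeneSelectionStats:
    """Per-gene polymorphism summary with pN/pS when defined."""

    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    pn_ps: float | None
    undefined_reason: str | None = None
    snp_density_per_kb: float = 0.0


def pn_ps(n_obs: int, s_obs: int, n_sites: float, s_sites: float,
          min_syn: int = 1) -> tuple[float | None, str | None]:
    """pN/pS ratio, or (None, reason) when not defined.

    pN = n_obs / n_sites, pS = s_obs / s_sites.  The ratio is undefined —
    reported separately rather than coerced to 0 or infinity — when fewer
    than ``min_syn`` synonymous SNPs were observed, or when the gene has no
    synonymous sites at all.
    """
    if s_sites <= 0:
        return None, "no synonymous sites in gene"
    if s_obs < min_syn:
        return None, f"fewer than {min_syn} synonymous SNPs observed"
    if n_sites <= 0:
        return None, "no nonsynonymous sites in gene"
    return (n_obs / n_sites) / (s_obs / s_sites), None


def gene_selection_stats(genome: GenomeRecord, annotated_snps: pd.DataFrame,
                         min_syn: int = 1) -> list[GeneSelectionStats]:
    """pN/pS and SNP density for every gene of a genome (pooled samples)."""
    out = []
    snps = annotated_snps[annotated_snps["contig"] == genome.id]
    for gene in genome.genes:
        gsnps = snps[snps["gene_id"] == gene.gene_id]
        n_obs = int((gsnps["effect"] == "nonsynonymous").sum())
        s_obs = int((gsnps["effect"] == "synonymous").sum())
        n_sites, s_sites = neutral_site_counts(genome.gene_sequence(gene))
        ratio, reason = pn_ps(n_obs, s_obs, n_sites, s_sites, min_syn=min_syn)
        density = 1000.0 * len(gsnps) / gene.length_nt
        out.append(GeneSelectionStats(
            gene_id=gene.gene_id, n_obs=n_obs, s_obs=s_obs,
            n_sites=n_sites, s_sites=s_sites, pn_ps=ratio,
            undefined_reason=reason, snp_density_per_kb=density))
    return out


def snp_density(contig_length_bp: int, n_snps: int) -> float:
    """SNPs per kilobase of contig, counting each site once."""
    if contig_length_bp <= 0:
        raise ValueError("contig length must be positive")
    return 1000.0 * n_snps / contig_length_bp


def multiallele_fraction(snps: pd.DataFrame, pileups: pd.DataFrame,
                         min_cov: int = 4) -> float:
    """Fraction of SNP sites where multiple alleles are detectable.

    Among per-sample observations of SNP sites with coverage >= ``min_cov``,
    the fraction where at least two distinct alleles have >= 1 read.
    """
    if snps.empty:
        raise ValueError("SNP table is empty")
    sites = set(zip(snps["contig"], snps["position"]))
    n_obs = n_multi = 0
    for row in pileups.itertuples(index=False):
        if (row.contig, int(row.pos)) not in sites:
            continue
        counts = [int(getattr(row, b)) for b in NUCLEOTIDES]
        if sum(counts) >= min_cov:
            n_obs += 1
            if sum(1 for c in counts if c >= 1) >= 2:
                n_multi += 1
    return n_multi / n_obs if n_obs else float("nan")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_snps_tsv(snps: pd.DataFrame, path) -> None:
    """VCF-like tab-separated SNP table (CHROM POS REF ALT SUPPORT TOTAL ANN)."""
    df = snps.rename(columns={"contig": "CHROM", "position": "POS",
                              "ref": "REF", "alt": "ALT",
                              "support": "SUPPORT", "total": "TOTAL"})
    if "effect" in df.columns:
        df = df.rename(columns={"effect": "ANN"})
    df.to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pileups_tsv(pileups: pd.DataFrame, path) -> None:
    pileups.to_csv(path, sep="\t", index=False)


def read_identity_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_identity_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
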