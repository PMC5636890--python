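"""Synthetic lake-metagenome virophage data with planted ground truth.

Every downstream stage of the package is exercised on synthetic data that
emulates the statistical structure of virophage communities in long-term lake
time series, without any real sequencing data:

* **Genomes and gene content** — genomes are organised into candidate genera.
  All genomes carry a small set of core protein clusters (PCs; one genome is
  left missing one core PC, mirroring the empirical "detected in all but one
  genome" core definition), near-core PCs present with high probability,
  per-genus signature PCs (present in every member, absent elsewhere), and
  accessory PCs drawn from a large shared pool.  Proteins within a PC are
  point-mutated copies of a family ancestor, so all-vs-all similarity
  clustering can recover the families.  Default PC counts are calibrated so
  that within-genus gene sharing clears the hypergeometric significance score
  of 9 used by the genome network while cross-genus sharing never does.

* **Reads** — the aligner is out of scope, so the generator emits idealised
  alignment summaries directly: per-read identity tables drawn from a
  sequence-discrete mixture (a >= 99%-identity core class, a 95-99% cloud,
  and optional <90% cross-population reads) and per-position pileups with
  planted SNPs at binomial allele counts plus uniform sequencing errors.

* **Abundance time series** — each planted virophage-host pair shares a
  smooth latent log-scale signal, the virophage copy delayed by the pair's
  lag (0-3 samples); decoy entities get independent signals.  Seasonal
  non-detection periods are emulated by zeroing abundances when the latent
  signal is in its low quantile.  Environmental covariates (temperature,
  chlorophyll a, DOC) are emitted alongside.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.ndimage import gaussian_filter1d

from .dynamics import AbundanceSeries
from .genome_discovery import (GeneRecord, GenomeRecord, SimilarityHit,
                               reverse_complement)
from .population_genetics import NUCLEOTIDES, classify_snp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: amino acid -> codons, standard code, stops excluded
CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    CODONS_FOR_AA.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# Design and planted truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDesign:
    """Study-condition knobs for the synthetic community.

    Defaults emulate the empirical structure of the lake virophage data set:
    4 core PCs, near-core PCs at high presence probability, enough signature
    PCs per genus for within-genus sharing to be significant at network
    score >= 9, intra-population divergence <= 1% (reads >= 99% identity) and
    inter-population divergence >= 10%.
    """

    n_genera: int = 3
    genomes_per_genus: int = 4
    n_core_pcs: int = 4
    n_near_core_pcs: int = 4
    near_core_presence_prob: float = 0.9
    n_signature_pcs_per_genus: int = 10
    n_accessory_pcs: int = 150
    accessory_per_genome: int = 4
    genome_length_bp: tuple[int, int] = (14_000, 30_000)
    gene_length_codons: tuple[int, int] = (150, 300)
    intra_pop_divergence: float = 0.01
    inter_pop_divergence: float = 0.10
    protein_mut_rate: float = 0.02
    tir_length_bp: int = 120
    circular_overlap_bp: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_genera, self.genomes_per_genus, self.n_core_pcs,
                  self.n_near_core_pcs, self.n_signature_pcs_per_genus,
                  self.n_accessory_pcs)
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if not 0.68 < self.near_core_presence_prob <= 1.0:
            raise ValueError("near_core_presence_prob must lie in (0.68, 1]")
        for f in (self.intra_pop_divergence, self.inter_pop_divergence):
            if not 0.0 <= f <= 1.0:
                raise ValueError("divergence fractions must lie in [0, 1]")
        if self.intra_pop_divergence >= self.inter_pop_divergence:
            raise ValueError("intra-population divergence must be below "
                             "inter-population divergence")


@dataclass
class PlantedSNP:
    genome: str
    position: int      # 1-based genomic coordinate
    ref: str
    alt: str
    effect: str        # synonymous | nonsynonymous
    allele_freq: float
    gene_id: str


@dataclass
class HostPair:
    virophage: str
    host: str
    lag: int           # samples by which the virophage lags its host


@dataclass
class PlantedTruth:
    """Ground truth of the synthetic community, for recovery tests."""

    genus_of_genome: dict[str, str] = field(default_factory=dict)
    pc_class: dict[str, str] = field(default_factory=dict)
    pc_of_gene: dict[str, str] = field(default_factory=dict)
    ancestors: dict[str, str] = field(default_factory=dict)
    marker_pc: str | None = None
    planted_snps: list[PlantedSNP] = field(default_factory=list)
    host_pairs: list[HostPair] = field(default_factory=list)

    def signature_pcs(self, genus: str) -> set[str]:
        return {pc for pc, cls in self.pc_class.items()
                if cls == f"signature:{genus}"}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_snps"] = [PlantedSNP(**s) for s in d["planted_snps"]]
        d["host_pairs"] = [HostPair(**p) for p in d["host_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(CODONS_FOR_AA[aa][rng.integers(len(CODONS_FOR_AA[aa]))]
                   for aa in protein)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def generate_genomes(design: SyntheticDesign
                     ) -> tuple[list[GenomeRecord], PlantedTruth]:
    """Generate the synthetic virophage genomes and their planted truth.

    Guarantees: every genome of a genus carries all of that genus's
    signature PCs and no other genus's; all genomes carry every core PC
    except that exactly one genome (the first) is missing one core PC (the
    last); topology cycles circular / TIR / linear within each genus.  The
    first core PC acts as the planted MCP marker.
    """
    rng = np.random.default_rng(design.seed)
    genera = [f"genus_{g:02d}" for g in range(design.n_genera)]

    core = [f"PCcore_{i:02d}" for i in range(design.n_core_pcs)]
    near = [f"PCnear_{i:02d}" for i in range(design.n_near_core_pcs)]
    sig = {g: [f"PCsig_{g[-2:]}_{i:02d}"
               for i in range(design.n_signature_pcs_per_genus)]
           for g in genera}
    acc = [f"PCacc_{i:03d}" for i in range(design.n_accessory_pcs)]
    all_sig = [pc for g in genera for pc in sig[g]]
    if len(set(all_sig)) != len(all_sig):
        raise ValueError("signature PC ids collide across genera")

    lo, hi = design.gene_length_codons
    truth = PlantedTruth(marker_pc=core[0])
    for pc in core + near + acc + all_sig:
        truth.ancestors[pc] = _random_protein(rng, int(rng.integers(lo, hi + 1)))
    for pc in core:
        truth.pc_class[pc] = "core"
    for pc in near:
        truth.pc_class[pc] = "near_core"
    for pc in acc:
        truth.pc_class[pc] = "accessory"
    for g in genera:
        for pc in sig[g]:
            truth.pc_class[pc] = f"signature:{g}"

    n_genomes = design.n_genera * design.genomes_per_genus
    # near-core presence per genome, enforcing the planted prevalence band
    # (0.68, (n-1)/n) whenever the genome count makes it realisable
    near_presence: dict[str, np.ndarray] = {}
    min_ct = int(np.floor(0.68 * n_genomes)) + 1
    max_ct = n_genomes - 2
    for pc in near:
        present = rng.random(n_genomes) < design.near_core_presence_prob
        if min_ct <= max_ct and design.near_core_presence_prob < 1.0:
            for _ in range(200):
                if min_ct <= present.sum() <= max_ct:
                    break
                present = rng.random(n_genomes) < design.near_core_presence_prob
            else:
                present = np.zeros(n_genomes, bool)
                present[rng.permutation(n_genomes)[:min_ct]] = True
        near_presence[pc] = present

    topologies = ["circular", "tir", "linear"]
    genomes: list[GenomeRecord] = []
    k = 0
    for gi, genus in enumerate(genera):
        for m in range(design.genomes_per_genus):
            gid = f"virophage_{k:03d}"
            truth.genus_of_genome[gid] = genus
            pcs = list(core)
            if k == 0:  # exactly one genome missing one core PC
                pcs.remove(core[-1])
            pcs += [pc for pc in near if near_presence[pc][k]]
            pcs += sig[genus]
            pcs += list(rng.choice(acc, size=design.accessory_per_genome,
                                   replace=False))
            order = list(rng.permutation(len(pcs)))

            parts: list[str] = []
            cursor = 0
            topology = topologies[m % 3]
            if topology == "tir":
                tir = _random_dna(rng, design.tir_length_bp)
                parts.append(tir)
                cursor += len(tir)
            genes: list[GeneRecord] = []
            for idx in order:
                pc = pcs[idx]
                spacer = _random_dna(rng, int(rng.integers(30, 200)))
                parts.append(spacer)
                cursor += len(spacer)
                protein = _mutate_protein(rng, truth.ancestors[pc],
                                          design.protein_mut_rate)
                nt = _reverse_translate(rng, protein)
                strand = "+" if rng.random() < 0.5 else "-"
                seg = nt if strand == "+" else reverse_complement(nt)
                gene_id = f"{gid}_g{len(genes):03d}"
                genes.append(GeneRecord(gene_id=gene_id, genome_id=gid,
                                        start=cursor + 1,
                                        end=cursor + len(seg), strand=strand,
                                        protein=protein))
                truth.pc_of_gene[gene_id] = pc
                parts.append(seg)
                cursor += len(seg)
            parts.append(_random_dna(rng, int(rng.integers(100, 400))))
            seq = "".join(parts)
            if len(seq) < design.genome_length_bp[0]:
                seq += _random_dna(rng, design.genome_length_bp[0] - len(seq))
            if topology == "tir":
                seq += reverse_complement(seq[: design.tir_length_bp])
            elif topology == "circular":
                seq += seq[: design.circular_overlap_bp]
            completeness = "complete" if topology in ("circular", "tir") \
                else ("near_complete" if len(seq) >= 13_000 else "partial")
            genomes.append(GenomeRecord(
                id=gid, sequence=seq, topology=topology,
                completeness=completeness, genes=genes,
                marker_class=("virophage_mcp" if core[0] in pcs else "none"),
                source=f"lake_{gi % 2}"))
            k += 1
    return genomes, truth


def presence_from_truth(genomes: Sequence[GenomeRecord], truth: PlantedTruth
                        ) -> pd.DataFrame:
    """Genome x PC presence matrix straight from the planted gene->PC map."""
    pcs = sorted(truth.ancestors)
    mat = pd.DataFrame(False, index=[g.id for g in genomes], columns=pcs)
    for genome in genomes:
        for gene in genome.genes:
            mat.loc[genome.id, truth.pc_of_gene[gene.gene_id]] = True
    return mat


# ---------------------------------------------------------------------------
# All-vs-all protein similarity hits
# ---------------------------------------------------------------------------

def simulate_protein_hits(genomes: Sequence[GenomeRecord], truth: PlantedTruth,
                          seed: int = 0) -> list[SimilarityHit]:
    """Idealised all-vs-all protein hits: one hit per within-family pair.

    Every pair of genes belonging to the same planted PC yields a hit whose
    identity is the true pairwise protein identity and whose E-value is
    drawn log-uniformly in [1e-80, 1e-20]; no cross-family hits are emitted.
    """
    rng = np.random.default_rng(seed)
    by_pc: dict[str, list[GeneRecord]] = {}
    for genome in genomes:
        for gene in genome.genes:
            by_pc.setdefault(truth.pc_of_gene[gene.gene_id], []).append(gene)
    hits = []
    for pc in sorted(by_pc):
        members = by_pc[pc]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                matches = sum(x == y for x, y in zip(a.protein, b.protein))
                ident = 100.0 * matches / max(len(a.protein), len(b.protein))
                e = 10.0 ** (-rng.uniform(20, 80))
                hits.append(SimilarityHit(
                    query_id=a.gene_id, subject_id=b.gene_id,
                    percent_identity=ident,
                    alignment_length=min(len(a.protein), len(b.protein)),
                    e_value=e, bit_score=rng.uniform(100, 500)))
    return hits


def marker_reference_hits(genomes: Sequence[GenomeRecord], truth: PlantedTruth,
                          reference_id: str = "MCP_ref",
                          seed: int = 0
                          ) -> tuple[list[SimilarityHit], dict[str, int]]:
    """Hits of each genome's marker-PC gene against a reference MCP.

    Returns (hits, reference lengths) ready for ``detect_marker_contigs``.
    Only genomes that actually carry the marker PC produce a hit.
    """
    rng = np.random.default_rng(seed)
    ref_len = len(truth.ancestors[truth.marker_pc])
    hits = []
    for genome in genomes:
        for gene in genome.genes:
            if truth.pc_of_gene[gene.gene_id] == truth.marker_pc:
                hits.append(SimilarityHit(
                    query_id=gene.gene_id, subject_id=reference_id,
                    percent_identity=rng.uniform(90, 100),
                    alignment_length=ref_len,
                    e_value=10.0 ** (-rng.uniform(30, 80)),
                    bit_score=rng.uniform(100, 400)))
    return hits, {reference_id: ref_len}


# ---------------------------------------------------------------------------
# Planted SNPs and pileups
# ---------------------------------------------------------------------------

def plant_snps(genomes: Sequence[GenomeRecord], truth: PlantedTruth,
               snps_per_gene: int = 10, omega: float = 1.0,
               allele_freq_range: tuple[float, float] = (0.2, 0.8),
               genes_per_genome: int | None = None,
               seed: int = 0) -> PlantedTruth:
    """Plant SNPs in genes under an equal-rate mutation model.

    Candidate substitutions are proposed uniformly over gene positions and
    alternate bases; non-synonymous proposals are accepted with probability
    ``omega`` (1.0 = neutral), synonymous proposals always.  At most one SNP
    is planted per genomic site.  Allele frequencies are uniform in
    ``allele_freq_range``.  Appends to ``truth.planted_snps`` and returns
    the truth object.
    """
    rng = np.random.default_rng(seed)
    for genome in genomes:
        genes = genome.genes if genes_per_genome is None \
            else genome.genes[:genes_per_genome]
        used: set[int] = set()
        for gene in genes:
            planted = 0
            attempts = 0
            while planted < snps_per_gene and attempts < 200 * snps_per_gene:
                attempts += 1
                pos = int(rng.integers(gene.start, gene.end + 1))
                if pos in used:
                    continue
                ref = genome.sequence[pos - 1]
                alts = [b for b in NUCLEOTIDES if b != ref]
                alt = alts[rng.integers(3)]
                effect = classify_snp(gene, genome, pos, ref, alt)
                if effect == "nonsynonymous" and rng.random() >= omega:
                    continue
                if effect == "intergenic":
                    continue
                used.add(pos)
                truth.planted_snps.append(PlantedSNP(
                    genome=genome.id, position=pos, ref=ref, alt=alt,
                    effect=effect,
                    allele_freq=float(rng.uniform(*allele_freq_range)),
                    gene_id=gene.gene_id))
                planted += 1
    return truth


def simulate_pileups(genomes: Sequence[GenomeRecord], truth: PlantedTruth,
                     depth: float = 50.0, error_rate: float = 0.0,
                     n_samples: int = 1, seed: int = 0,
                     poisson_depth: bool = True) -> pd.DataFrame:
    """Per-position allele-count pileups with planted SNPs and errors.

    Coverage per position and sample is Poisson(``depth``) (or exactly
    ``depth`` when ``poisson_depth=False``); at planted SNP sites the
    alternate allele draws Binomial(coverage, allele_freq) reads.  Each read
    base is independently miscalled with probability ``error_rate`` to a
    uniformly random other base.  Returns a tidy table with columns
    ``contig, sample, pos, ref, A, C, G, T``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    snp_at = {(s.genome, s.position): s for s in truth.planted_snps}
    rows = []
    for genome in genomes:
        seq = genome.sequence.upper()
        for sample in range(n_samples):
            sample_id = f"s{sample:03d}"
            for pos in range(1, len(seq) + 1):
                ref = seq[pos - 1]
                if ref not in NUCLEOTIDES:
                    continue
                cov = (int(rng.poisson(depth)) if poisson_depth
                       else int(depth))
                counts = dict.fromkeys(NUCLEOTIDES, 0)
                snp = snp_at.get((genome.id, pos))
                if snp is not None:
                    n_alt = int(rng.binomial(cov, snp.allele_freq))
                    counts[snp.alt] += n_alt
                    counts[ref] += cov - n_alt
                else:
                    counts[ref] += cov
                if error_rate > 0:
                    for base in NUCLEOTIDES:
                        n = counts[base]
                        if n == 0:
                            continue
                        n_err = int(rng.binomial(n, error_rate))
                        counts[base] -= n_err
                        others = [b for b in NUCLEOTIDES if b != base]
                        for _ in range(n_err):
                            counts[others[rng.integers(3)]] += 1
                rows.append((genome.id, sample_id, pos, ref,
                             counts["A"], counts["C"], counts["G"],
                             counts["T"]))
    return pd.DataFrame(rows, columns=["contig", "sample", "pos", "ref",
                                       "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Read identities
# ---------------------------------------------------------------------------

def simulate_read_identities(genomes: Sequence[GenomeRecord],
                             truth: PlantedTruth, n_reads: int,
                             frac_core: float = 0.83,
                             frac_cloud: float = 0.17,
                             frac_cross: float = 0.0,
                             intra_pop_divergence: float = 0.01,
                             inter_pop_divergence: float = 0.10,
                             n_samples: int = 1,
                             seed: int = 0) -> pd.DataFrame:
    """Per-read identity table from a sequence-discrete population mixture.

    Mapped reads belong to a >= ``100*(1-intra_pop_divergence)``% identity
    core class, a 95-99% cloud, or (optionally) a cross-population class
    below ``100*(1-inter_pop_divergence)``%.  Default weights mirror the
    empirical 83% dominance of >= 99%-identity reads with minimal coverage
    below 95%.
    """
    weights = np.array([frac_core, frac_cloud, frac_cross], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    contigs = [g.id for g in genomes]
    rows = []
    core_floor = 100.0 * (1.0 - intra_pop_divergence)
    cross_ceil = 100.0 * (1.0 - inter_pop_divergence)
    for r in range(n_reads):
        contig = contigs[rng.integers(len(contigs))]
        cls = rng.choice(3, p=weights)
        if cls == 0:
            ident = rng.uniform(core_floor, 100.0)
        elif cls == 1:
            ident = rng.uniform(95.0, min(99.0, core_floor))
        else:
            ident = rng.uniform(75.0, cross_ceil)
        rows.append((f"read_{r:07d}", contig, float(ident),
                     f"s{rng.integers(n_samples):03d}"))
    return pd.DataFrame(rows, columns=["read_id", "contig_id",
                                       "percent_identity", "sample_id"])


# ---------------------------------------------------------------------------
# Abundance time series
# ---------------------------------------------------------------------------

def _smooth_signal(rng: np.random.Generator, length: int,
                   sigma: float = 1.0, scale: float = 1.5) -> np.ndarray:
    """Smoothed Gaussian latent with unit-lag autocorrelation ~ exp(-1/4).

    The correlation time (sigma=1 sample) is chosen so that independent
    decoy series at 45 samples keep |Pearson r| below 0.5 for ~95% of
    pairs, the regime the association stage assumes.
    """
    raw = rng.normal(size=length)
    s = gaussian_filter1d(raw, sigma=sigma, mode="wrap")
    sd = s.std()
    return scale * s / sd if sd > 0 else s


def simulate_abundance_series(truth: PlantedTruth, n_samples: int = 45,
                              noise_sd: float = 0.3, decoys: int = 20,
                              seed: int = 0, n_pairs: int = 5,
                              max_lag: int = 3,
                              off_fraction: float = 0.15
                              ) -> AbundanceSeries:
    """Abundance matrix with planted lagged virophage-host pairs and decoys.

    Each planted pair shares a smooth latent log-abundance signal; the
    virophage copy is delayed by the pair's lag (cycling 0..``max_lag``).
    Both partners are zeroed during the host's seasonal low period
    (``off_fraction`` lowest latent values), emulating non-detection.
    Decoys get independent signals and masks.  Fills ``truth.host_pairs``
    and returns an :class:`AbundanceSeries` carrying a breadth matrix,
    entity types and environmental covariates.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    viro_ids = (list(truth.genus_of_genome)[:n_pairs]
                if truth.genus_of_genome else
                [f"virophage_{i:03d}" for i in range(n_pairs)])
    while len(viro_ids) < n_pairs:
        viro_ids.append(f"virophage_{len(viro_ids):03d}")
    host_ids = [f"ncldv_{i:03d}" for i in range(n_pairs)]
    decoy_ids = [f"ncldv_decoy_{i:03d}" for i in range(decoys)]

    truth.host_pairs = []
    values = {}
    types = {}
    ext = n_samples + max_lag
    for i, (v, h) in enumerate(zip(viro_ids, host_ids)):
        lag = i % (max_lag + 1)
        latent = _smooth_signal(rng, ext)
        host_log = latent[max_lag:]
        viro_log = latent[max_lag - lag: ext - lag]
        h_mask = (host_log > np.quantile(host_log, off_fraction)
                  if off_fraction > 0 else np.ones(n_samples, bool))
        v_mask = (viro_log > np.quantile(viro_log, off_fraction)
                  if off_fraction > 0 else np.ones(n_samples, bool))
        values[h] = np.exp(host_log + rng.normal(0, noise_sd, n_samples)) * h_mask
        values[v] = np.exp(viro_log + rng.normal(0, noise_sd, n_samples)) * v_mask
        types[v], types[h] = "virophage", "ncldv"
        truth.host_pairs.append(HostPair(virophage=v, host=h, lag=lag))
    for d in decoy_ids:
        latent = _smooth_signal(rng, n_samples)
        mask = (latent > np.quantile(latent, off_fraction)
                if off_fraction > 0 else np.ones(n_samples, bool))
        values[d] = np.exp(latent + rng.normal(0, noise_sd, n_samples)) * mask
        types[d] = "ncldv"

    samples = [f"t{t:03d}" for t in range(n_samples)]
    df = pd.DataFrame(values).T
    df.columns = samples
    breadth = pd.DataFrame(
        np.where(df.to_numpy() > 0,
                 rng.uniform(0.8, 1.0, df.shape),
                 rng.uniform(0.0, 0.3, df.shape)),
        index=df.index, columns=samples)
    env = pd.DataFrame({
        "temperature": 10 + 8 * np.sin(2 * np.pi * np.arange(n_samples) / 12)
        + rng.normal(0, 1, n_samples),
        "chlorophyll_a": np.exp(_smooth_signal(rng, n_samples, scale=0.8)),
        "doc": 5 + _smooth_signal(rng, n_samples, scale=0.5),
    }, index=samples).T
    return AbundanceSeries(values=df, breadth=breadth, entity_types=types,
                           env=env)
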