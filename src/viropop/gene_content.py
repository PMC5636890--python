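"""Gene-content taxonomy of virophage genomes.

The taxonomy works purely from shared gene content, without alignment-based
phylogenetics.  Predicted proteins are grouped into protein clusters (PCs) by
Markov clustering (MCL) of the all-vs-all similarity graph, then PCs with
significant cross-similarity are gathered by a greedy, size-ordered merge.
For every pair of (complete or near-complete) genomes the number ``n`` of
shared PCs is scored against the hypergeometric expectation given the total
PC universe ``N`` and the two genomes' repertoire sizes ``a`` and ``b``:

    P(X >= n) = sum_{k=n}^{min(a,b)} C(a,k) C(N-a, b-k) / C(N, b)

and turned into a Bonferroni-style significance score
``-log10(P * n_comparisons)``.  Genomes linked at score >= 9 form a
gene-sharing network whose MCL clusters containing two or more genomes are
reported as *candidate genera*.  PCs are further classified by prevalence:
*core* (present in all genomes but at most one), *near-core* (present in
> 68% of genomes), and per-genus *signature* PCs (present in every member of
one genus and in no outside genome); everything else is accessory.

Gene-level taxonomic affiliation follows a strict priority: known reference
virophages first, then any other viral or cellular genome, then peer proteins
from other newly assembled virophages (never the gene's own genome or its
>99%-identical duplicates); genes with no significant hit anywhere are ORFans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_discovery import (DEFAULT_MAX_EVALUE, DEFAULT_MIN_BITSCORE,
                               SimilarityHit)

#: Edge weight cap for -log10(E) when E underflows to 0.
MAX_NEG_LOG10_EVALUE = 200.0

#: Default significance-score threshold for genome-network edges.
DEFAULT_MIN_NETWORK_SCORE = 9.0

#: Prevalence threshold (strict) for the near-core class.
NEAR_CORE_PREVALENCE = 0.68


# ---------------------------------------------------------------------------
# Markov clustering (shared by the genome network and the co-occurrence stage)
# ---------------------------------------------------------------------------

def mcl(adjacency, inflation: float = 2.0, expansion: int = 2,
        prune: float = 1e-6, max_iter: int = 200, tol: float = 1e-8,
        labels: Sequence | None = None) -> tuple[list[set], bool]:
    """Markov clustering of a weighted undirected graph.

    The adjacency matrix is scaled to unit maximum (making the result
    invariant under global weight scaling), given unit self-loops, and made
    column-stochastic.  Iterations alternate expansion (matrix power) and
    inflation (entrywise power followed by column renormalisation); entries
    below ``prune`` are dropped.  Convergence is declared when the largest
    entrywise change falls below ``tol``.

    Returns
    -------
    (clusters, converged)
        ``clusters`` is a list of node-label sets covering all nodes;
        ``converged`` is False when ``max_iter`` was exhausted.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if (A < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    n = A.shape[0]
    if labels is None:
        labels = list(range(n))
    if n == 0:
        return [], True
    A = A.copy()
    mx = A.max()
    if mx > 0:
        A /= mx
    np.fill_diagonal(A, 1.0)
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning "
                      "current clustering", stacklevel=2)

    # Attractors are rows with mass on their own diagonal; each attractor row
    # spans one cluster.  Overlapping attractor rows are merged.
    thresh = max(prune, tol)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attractors = [i for i in range(n) if M[i, i] > thresh]
    for i in attractors:
        members = np.nonzero(M[i] > thresh)[0]
        for j in members:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[ri] = rj
    clusters_map: dict[int, set] = {}
    assigned = set()
    for i in attractors:
        for j in np.nonzero(M[i] > thresh)[0]:
            clusters_map.setdefault(find(i), set()).add(labels[int(j)])
            assigned.add(int(j))
    clusters = [s for _, s in sorted(clusters_map.items())]
    for j in range(n):  # orphans (numerically dead columns) become singletons
        if j not in assigned:
            clusters.append({labels[j]})
    return clusters, converged


# ---------------------------------------------------------------------------
# Protein clusters
# ---------------------------------------------------------------------------

@dataclass
class PCCatalog:
    """Protein-cluster membership plus the genome x PC presence matrix."""

    pc_members: dict[str, set[str]]            # PC id -> gene ids
    gene_to_genome: dict[str, str]
    pc_class: dict[str, str] = field(default_factory=dict)

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean genomes x PCs presence/absence matrix."""
        genomes = sorted(set(self.gene_to_genome.values()))
        pcs = sorted(self.pc_members)
        mat = pd.DataFrame(False, index=genomes, columns=pcs)
        for pc, genes in self.pc_members.items():
            for g in genes:
                mat.loc[self.gene_to_genome[g], pc] = True
        return mat

    def pc_of_gene(self) -> dict[str, str]:
        return {g: pc for pc, genes in self.pc_members.items() for g in genes}


def cluster_proteins(hits: Iterable[SimilarityHit],
                     gene_to_genome: Mapping[str, str],
                     max_evalue: float = DEFAULT_MAX_EVALUE,
                     inflation: float = 2.0) -> PCCatalog:
    """Group proteins into protein clusters by MCL of the similarity graph.

    Edges connect proteins with E-value <= ``max_evalue``; the weight is
    ``-log10(E)`` capped at 200.  Proteins without any qualifying edge become
    singleton PCs.  PC ids are assigned by decreasing cluster size then by
    smallest member id, as ``PC_0001``...
    """
    genes = sorted(gene_to_genome)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    A = np.zeros((n, n))
    for h in hits:
        if h.query_id not in index or h.subject_id not in index:
            raise KeyError(f"hit references unknown protein: "
                           f"{h.query_id} vs {h.subject_id}")
        if h.e_value > max_evalue or h.query_id == h.subject_id:
            continue
        w = MAX_NEG_LOG10_EVALUE if h.e_value == 0 else min(
            MAX_NEG_LOG10_EVALUE, -math.log10(h.e_value))
        i, j = index[h.query_id], index[h.subject_id]
        A[i, j] = max(A[i, j], w)
        A[j, i] = max(A[j, i], w)
    clusters, _ = mcl(A, inflation=inflation, labels=genes)
    clusters.sort(key=lambda s: (-len(s), min(s)))
    members = {f"PC_{k + 1:04d}": set(c) for k, c in enumerate(clusters)}
    return PCCatalog(pc_members=members, gene_to_genome=dict(gene_to_genome))


def merge_pcs(catalog: PCCatalog,
              pc_similarity: Iterable[tuple[str, str, float]],
              max_evalue: float = DEFAULT_MAX_EVALUE) -> PCCatalog:
    """Greedy merge of PCs with significant profile-level similarity.

    PCs are visited by decreasing member count (ties by id).  Each PC not yet
    absorbed becomes a seed and absorbs every not-yet-assigned PC directly
    similar to it at E <= ``max_evalue``.  The merge is single-pass and
    non-transitive: an absorbed PC does not pull in its own neighbours.
    """
    sig: dict[str, set[str]] = {}
    for a, b, e in pc_similarity:
        if a not in catalog.pc_members or b not in catalog.pc_members:
            raise KeyError(f"PC similarity references unknown PC: {a}, {b}")
        if e <= max_evalue and a != b:
            sig.setdefault(a, set()).add(b)
            sig.setdefault(b, set()).add(a)

    order = sorted(catalog.pc_members,
                   key=lambda p: (-len(catalog.pc_members[p]), p))
    assigned: set[str] = set()
    merged: dict[str, set[str]] = {}
    for seed in order:
        if seed in assigned:
            continue
        assigned.add(seed)
        members = set(catalog.pc_members[seed])
        for other in sorted(sig.get(seed, ())):
            if other not in assigned:
                assigned.add(other)
                members |= catalog.pc_members[other]
        merged[seed] = members
    return PCCatalog(pc_members=merged,
                     gene_to_genome=dict(catalog.gene_to_genome),
                     pc_class=dict(catalog.pc_class))


# ---------------------------------------------------------------------------
# Hypergeometric gene-sharing significance
# ---------------------------------------------------------------------------

def hypergeom_tail(N: int, a: int, b: int, n: int) -> Fraction:
    """Exact upper-tail hypergeometric P(X >= n shared of N total PCs).

    ``a`` and ``b`` are the PC repertoire sizes of the two genomes.  Computed
    in exact rational arithmetic.
    """
    if not (0 <= a <= N and 0 <= b <= N):
        raise ValueError("repertoire sizes must lie within [0, N]")
    if n > min(a, b):
        raise ValueError("shared count exceeds smaller repertoire")
    if n < max(0, a + b - N):
        n = max(0, a + b - N)
    denom = math.comb(N, b)
    num = sum(math.comb(a, k) * math.comb(N - a, b - k)
              for k in range(n, min(a, b) + 1))
    return Fraction(num, denom)


def shared_pc_significance(presence: pd.DataFrame, genome_i: str,
                           genome_j: str,
                           n_comparisons: int) -> tuple[int, float, float]:
    """Shared-PC count, hypergeometric p, and significance score for a pair.

    The score is ``-log10(p * n_comparisons)``, clamped to 0 when the
    Bonferroni-adjusted probability reaches 1.
    """
    vi = presence.loc[genome_i].to_numpy(dtype=bool)
    vj = presence.loc[genome_j].to_numpy(dtype=bool)
    N = presence.shape[1]
    a, b, n = int(vi.sum()), int(vj.sum()), int((vi & vj).sum())
    p = hypergeom_tail(N, a, b, n)
    return n, float(p), significance_score(float(p), n_comparisons)


def significance_score(p: float, n_comparisons: int) -> float:
    adj = p * n_comparisons
    if adj >= 1.0:
        return 0.0
    if adj <= 0.0:
        return math.inf
    return -math.log10(adj)


# ---------------------------------------------------------------------------
# Genome network and candidate genera
# ---------------------------------------------------------------------------

@dataclass
class GenomeNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: genome_i, genome_j, n_shared, p, score
    clusters: dict[str, int]     # genome -> cluster id; singletons included
    candidate_genera: dict[int, set[str]]
    n_comparisons: int

    def to_edge_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def cluster_labels(self) -> pd.Series:
        return pd.Series(self.clusters)


def build_genome_network(
    presence: pd.DataFrame,
    min_score: float = DEFAULT_MIN_NETWORK_SCORE,
    genome_lengths: Mapping[str, int] | None = None,
    min_length_bp: int = 13_000,
    n_comparisons: int | None = None,
    inflation: float = 2.0,
    min_genus_size: int = 2,
) -> GenomeNetwork:
    """Build the gene-sharing genome network and call candidate genera.

    Only complete/near-complete genomes take part: when ``genome_lengths`` is
    given, genomes below ``min_length_bp`` are dropped first.  All remaining
    genome pairs are scored; edges with significance score >= ``min_score``
    (weighted by score) are clustered with MCL.  Clusters with at least
    ``min_genus_size`` genomes are reported as candidate genera.

    ``n_comparisons`` defaults to the number of genome pairs tested.
    """
    if presence.empty:
        raise ValueError("presence matrix must be nonempty")
    genomes = list(presence.index)
    if genome_lengths is not None:
        genomes = [g for g in genomes if genome_lengths[g] >= min_length_bp]
    sub = presence.loc[genomes]
    m = len(genomes)
    pairs = [(genomes[i], genomes[j]) for i in range(m) for j in range(i + 1, m)]
    if n_comparisons is None:
        n_comparisons = max(1, len(pairs))

    rows = []
    A = np.zeros((m, m))
    idx = {g: k for k, g in enumerate(genomes)}
    for gi, gj in pairs:
        n_shared, p, score = shared_pc_significance(sub, gi, gj, n_comparisons)
        if score >= min_score:
            rows.append((gi, gj, n_shared, p, score))
            w = min(score, 10 * MAX_NEG_LOG10_EVALUE)
            A[idx[gi], idx[gj]] = A[idx[gj], idx[gi]] = w
    edges = pd.DataFrame(rows, columns=["genome_i", "genome_j", "n_shared",
                                        "p", "score"])
    clusters, _ = mcl(A, inflation=inflation, labels=genomes)
    clusters.sort(key=lambda s: (-len(s), min(s)))
    assignment = {g: k for k, members in enumerate(clusters) for g in members}
    genera = {k: set(members) for k, members in enumerate(clusters)
              if len(members) >= min_genus_size}
    return GenomeNetwork(nodes=genomes, edges=edges, clusters=assignment,
                         candidate_genera=genera, n_comparisons=n_comparisons)


# ---------------------------------------------------------------------------
# PC prevalence classes and signature genes
# ---------------------------------------------------------------------------

def classify_pc_prevalence(presence: pd.DataFrame,
                           near_core_prevalence: float = NEAR_CORE_PREVALENCE
                           ) -> dict[str, str]:
    """Classify PCs as core / near_core / accessory by prevalence.

    Core: detected in all genomes but at most one (count >= n - 1).
    Near-core: prevalence strictly above ``near_core_prevalence`` but not
    core.  Everything else is accessory.
    """
    n = presence.shape[0]
    if n < 3:
        raise ValueError("prevalence classes need at least 3 genomes")
    out = {}
    counts = presence.sum(axis=0)
    for pc, c in counts.items():
        if c >= n - 1:
            out[pc] = "core"
        elif c / n > near_core_prevalence:
            out[pc] = "near_core"
        else:
            out[pc] = "accessory"
    return out


def find_signature_genes(presence: pd.DataFrame,
                         clusters: Mapping[int, Iterable[str]]
                         ) -> dict[int, set[str]]:
    """Signature PCs per genome cluster (candidate genus).

    A PC is a signature of cluster ``C`` iff it is present in 100% of C's
    members and absent from every genome outside C.  Singleton clusters are
    excluded from signature calling.
    """
    out: dict[int, set[str]] = {}
    for cid, members in clusters.items():
        members = set(members)
        if len(members) < 2:
            continue
        inside = presence.loc[sorted(members)]
        outside = presence.drop(index=sorted(members))
        mask = inside.all(axis=0) & ~outside.any(axis=0)
        out[cid] = set(presence.columns[mask])
    return out


# ---------------------------------------------------------------------------
# Gene and genome affiliation
# ---------------------------------------------------------------------------

def affiliate_genes(
    gene_ids: Sequence[str],
    reference_hits: Iterable[SimilarityHit],
    other_hits: Iterable[SimilarityHit],
    peer_hits: Iterable[SimilarityHit],
    gene_to_genome: Mapping[str, str],
    duplicate_groups: Mapping[str, set[str]] | None = None,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> dict[str, str]:
    """Affiliate each gene by strict tier priority.

    Tier 1 — significant hit to a reference virophage protein.
    Tier 2 — significant hit to any other viral or cellular genome.
    Tier 3 — significant hit to a peer protein from another newly assembled
    virophage, excluding the gene's own genome and genomes listed as its
    >99%-identical duplicates (``duplicate_groups``: genome -> excluded
    genomes).  No significant hit in any tier yields ``ORFan``.
    """
    def passing(hits):
        out: dict[str, list[SimilarityHit]] = {}
        for h in hits:
            if h.passes(min_bitscore, max_evalue):
                out.setdefault(h.query_id, []).append(h)
        return out

    t1, t2, t3 = passing(reference_hits), passing(other_hits), passing(peer_hits)
    duplicate_groups = duplicate_groups or {}
    labels = {}
    for g in gene_ids:
        if g in t1:
            labels[g] = "reference_virophage"
            continue
        if g in t2:
            labels[g] = "other_viral_or_cellular"
            continue
        own = gene_to_genome[g]
        excluded = {own} | set(duplicate_groups.get(own, ()))
        peers = [h for h in t3.get(g, ())
                 if gene_to_genome.get(h.subject_id, h.subject_id)
                 not in excluded]
        labels[g] = "novel_virophage_peer" if peers else "ORFan"
    return labels


def best_hit_affiliation(hits: Iterable[SimilarityHit],
                         min_bitscore: float = DEFAULT_MIN_BITSCORE,
                         max_evalue: float = DEFAULT_MAX_EVALUE,
                         subject_label: Mapping[str, str] | None = None
                         ) -> dict[str, str | None]:
    """Best-hit affiliation per query among hits passing the thresholds.

    Highest bit score wins; ties broken by lowest E-value, then by
    lexicographic subject id.  Queries with no passing hit map to None.
    ``subject_label`` optionally translates subject ids into taxon labels.
    """
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if not h.passes(min_bitscore, max_evalue):
            continue
        cur = best.get(h.query_id)
        key = (-h.bit_score, h.e_value, h.subject_id)
        if cur is None or key < (-cur.bit_score, cur.e_value, cur.subject_id):
            best[h.query_id] = h
    out: dict[str, str | None] = {}
    for q, h in best.items():
        label = h.subject_id
        if subject_label is not None:
            label = subject_label.get(h.subject_id, h.subject_id)
        out[q] = label
    return out


def genome_affiliation_by_vote(gene_labels: Mapping[str, str | None],
                               gene_to_genome: Mapping[str, str]
                               ) -> dict[str, str | None]:
    """Genome-level affiliation by strict-majority vote over its gene labels.

    Requires at least one vote; a tie for the top label yields None
    (unaffiliated).
    """
    votes: dict[str, dict[str, int]] = {}
    for gene, label in gene_labels.items():
        if label is None:
            continue
        genome = gene_to_genome[gene]
        votes.setdefault(genome, {}).setdefault(label, 0)
        votes[genome][label] += 1
    out: dict[str, str | None] = {}
    for genome, counts in votes.items():
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[genome] = None
        else:
            out[genome] = ranked[0][0]
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_presence_tsv(presence: pd.DataFrame, path) -> None:
    presence.astype(int).to_csv(path, sep="\t")


def read_presence_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)
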