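"""Protein clustering, hypergeometric gene sharing, genera, affiliations."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from viropop.gene_content import (PCCatalog, affiliate_genes,
                                  best_hit_affiliation, build_genome_network,
                                  classify_pc_prevalence, cluster_proteins,
                                  find_signature_genes,
                                  genome_affiliation_by_vote, hypergeom_tail,
                                  mcl, merge_pcs, shared_pc_significance)
from viropop.genome_discovery import SimilarityHit


def _hit(q, s, e=1e-30, bit=200.0):
    return SimilarityHit(query_id=q, subject_id=s, percent_identity=90.0,
                         alignment_length=100, e_value=e, bit_score=bit)


def enumerate_tail(N, a, b, n):
    """Oracle: exhaustive subset enumeration of P(|A ∩ B| >= n)."""
    A = set(range(a))
    hits = total = 0
    for B in itertools.combinations(range(N), b):
        total += 1
        if len(A & set(B)) >= n:
            hits += 1
    return Fraction(hits, total)


# ---------------------------------------------------------------------------
# Hypergeometric significance
# ---------------------------------------------------------------------------

def test_hypergeom_tail_known_value():
    # N=10, a=4, b=5, n=3: 66 of the 252 5-subsets share >= 3 of A's 4
    assert hypergeom_tail(10, 4, 5, 3) == Fraction(66, 252)


def test_hypergeom_full_tail_is_one():
    assert hypergeom_tail(12, 5, 6, 0) == 1


def test_hypergeom_identical_full_repertoires_closed_form():
    N = b = 9
    assert hypergeom_tail(N, N, b, b) == Fraction(1, math.comb(N, b))


def test_hypergeom_matches_enumeration_oracle(rng):
    """Exact rational agreement with subset enumeration, random instances."""
    for _ in range(60):
        N = int(rng.integers(2, 13))
        a = int(rng.integers(1, N + 1))
        b = int(rng.integers(1, N + 1))
        n = int(rng.integers(0, min(a, b) + 1))
        assert hypergeom_tail(N, a, b, n) == enumerate_tail(N, a, b, n)


def test_hypergeom_matches_scipy_sf():
    """Independent cross-check against scipy's hypergeometric tail."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        N = int(rng.integers(5, 200))
        a = int(rng.integers(1, N + 1))
        b = int(rng.integers(1, N + 1))
        n = int(rng.integers(max(0, a + b - N), min(a, b) + 1))
        ours = float(hypergeom_tail(N, a, b, n))
        scipys = float(hypergeom(N, a, b).sf(n - 1))
        assert ours == pytest.approx(scipys, rel=1e-9, abs=1e-300)


def test_hypergeom_tail_monotone_in_n():
    N, a, b = 12, 7, 9
    tails = [hypergeom_tail(N, a, b, n) for n in range(0, min(a, b) + 1)]
    assert all(x >= y for x, y in zip(tails, tails[1:]))


def test_shared_pc_significance_score_clamps_to_zero():
    presence = pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["x", "y"],
                            columns=["p1", "p2", "p3"]).astype(bool)
    n, p, score = shared_pc_significance(presence, "x", "y", 10)
    assert n == 0 and p == 1.0 and score == 0.0


def test_shared_pc_significance_rejects_impossible_n():
    with pytest.raises(ValueError):
        hypergeom_tail(10, 3, 3, 4)


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def _two_triangles():
    A = np.zeros((6, 6))
    for (i, j) in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[i, j] = A[j, i] = 1.0
    return A


def test_mcl_disconnected_triangles():
    clusters, converged = mcl(_two_triangles())
    assert converged
    assert sorted(map(sorted, clusters)) == [[0, 1, 2], [3, 4, 5]]


def test_mcl_single_node():
    clusters, _ = mcl(np.zeros((1, 1)), labels=["only"])
    assert clusters == [{"only"}]


def test_mcl_planted_two_block_graph(rng):
    """Weakly coupled blocks are recovered; oracle = connected components
    of the strong (within-block) edges."""
    n = 20
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < 10) == (j < 10)
            A[i, j] = A[j, i] = 1.0 if same else 0.01
    clusters, _ = mcl(A)
    assert sorted(map(sorted, clusters)) == [list(range(10)),
                                             list(range(10, 20))]


def test_mcl_invariant_under_relabeling_and_scaling(rng):
    A = _two_triangles() + rng.uniform(0, 0.05, (6, 6))
    A = np.triu(A, 1)
    A = A + A.T
    base, _ = mcl(A, labels=list("abcdef"))
    scaled, _ = mcl(37.5 * A, labels=list("abcdef"))
    assert sorted(map(sorted, base)) == sorted(map(sorted, scaled))
    perm = np.array([3, 1, 4, 0, 5, 2])
    relabeled, _ = mcl(A[np.ix_(perm, perm)],
                       labels=[list("abcdef")[i] for i in perm])
    assert sorted(map(sorted, base)) == sorted(map(sorted, relabeled))


# ---------------------------------------------------------------------------
# Protein clustering and greedy PC merging
# ---------------------------------------------------------------------------

def test_cluster_proteins_disconnected_families():
    g2g = {f"f1_{i}": "G1" for i in range(5)}
    g2g.update({f"f2_{i}": "G2" for i in range(5)})
    hits = [_hit(f"f1_{i}", f"f1_{j}") for i in range(5) for j in range(i)]
    hits += [_hit(f"f2_{i}", f"f2_{j}") for i in range(5) for j in range(i)]
    catalog = cluster_proteins(hits, g2g)
    sizes = sorted(len(m) for m in catalog.pc_members.values())
    assert sizes == [5, 5]


def test_cluster_proteins_ignores_above_threshold_edge():
    g2g = {f"f1_{i}": "G1" for i in range(3)}
    g2g.update({f"f2_{i}": "G2" for i in range(3)})
    hits = [_hit(f"f1_{i}", f"f1_{j}") for i in range(3) for j in range(i)]
    hits += [_hit(f"f2_{i}", f"f2_{j}") for i in range(3) for j in range(i)]
    hits.append(_hit("f1_0", "f2_0", e=0.01))  # above E threshold
    catalog = cluster_proteins(hits, g2g)
    assert sorted(len(m) for m in catalog.pc_members.values()) == [3, 3]


def test_cluster_proteins_recovers_planted_families(small_community):
    from viropop.synthetic_data import simulate_protein_hits

    genomes, truth = small_community
    hits = simulate_protein_hits(genomes, truth, seed=5)
    g2g = {g.gene_id: rec.id for rec in genomes for g in rec.genes}
    catalog = cluster_proteins(hits, g2g)
    planted = {}
    for gene, pc in truth.pc_of_gene.items():
        planted.setdefault(pc, set()).add(gene)
    assert (sorted(map(sorted, catalog.pc_members.values()))
            == sorted(map(sorted, planted.values())))


def _catalog(sizes):
    members = {f"pc{k}": {f"pc{k}_m{i}" for i in range(s)}
               for k, s in enumerate(sizes)}
    g2g = {m: "G" for ms in members.values() for m in ms}
    return PCCatalog(pc_members=members, gene_to_genome=g2g)


def test_merge_pcs_greedy_is_single_pass_non_transitive():
    # sizes (5,3,2); sim(5,3) and sim(3,2): the size-5 seed absorbs the 3,
    # but the absorbed 3 cannot pull in the 2, which seeds alone.
    cat = _catalog([5, 3, 2])
    merged = merge_pcs(cat, [("pc0", "pc1", 1e-10), ("pc1", "pc2", 1e-10)])
    sizes = sorted(len(m) for m in merged.pc_members.values())
    assert sizes == [2, 8]
    assert merged.pc_members["pc2"] == cat.pc_members["pc2"]


def test_merge_pcs_no_significant_similarity_is_identity():
    cat = _catalog([4, 3])
    merged = merge_pcs(cat, [("pc0", "pc1", 0.01)])  # above threshold
    assert merged.pc_members == cat.pc_members


def test_merge_pcs_deterministic_under_input_shuffling(rng):
    cat = _catalog([3, 3, 3])
    sims = [("pc0", "pc1", 1e-9), ("pc1", "pc2", 1e-9)]
    ref = merge_pcs(cat, sims).pc_members
    for _ in range(5):
        shuffled = [sims[i] for i in rng.permutation(len(sims))]
        assert merge_pcs(cat, shuffled).pc_members == ref


def test_merge_pcs_unknown_pc_raises():
    with pytest.raises(KeyError):
        merge_pcs(_catalog([2]), [("pc0", "ghost", 1e-9)])


# ---------------------------------------------------------------------------
# Genome network and candidate genera
# ---------------------------------------------------------------------------

def test_genome_network_recovers_planted_genera(small_community):
    from viropop.synthetic_data import presence_from_truth

    genomes, truth = small_community
    presence = presence_from_truth(genomes, truth)
    net = build_genome_network(
        presence, genome_lengths={g.id: g.length_bp for g in genomes})
    assert len(net.candidate_genera) == 2
    recovered = {frozenset(m) for m in net.candidate_genera.values()}
    planted = {}
    for genome, genus in truth.genus_of_genome.items():
        planted.setdefault(genus, set()).add(genome)
    assert recovered == {frozenset(m) for m in planted.values()}


def test_genome_network_infinite_threshold_leaves_all_unclassified():
    presence = pd.DataFrame(np.eye(4, dtype=bool),
                            index=list("wxyz"), columns=[f"p{i}" for i in range(4)])
    net = build_genome_network(presence, min_score=math.inf)
    assert net.edges.empty and net.candidate_genera == {}
    assert len(set(net.clusters.values())) == 4  # all singletons


def test_genome_network_weak_sharing_gives_no_edges():
    # 6 genomes sharing only 2 of 32 PCs pairwise: nothing clears score 9
    presence = pd.DataFrame(False, index=[f"g{i}" for i in range(6)],
                            columns=[f"p{i}" for i in range(32)])
    presence.iloc[:, :2] = True  # shared "core"
    for i in range(6):  # disjoint accessory blocks of 5
        presence.iloc[i, 2 + 5 * i: 7 + 5 * i] = True
    net = build_genome_network(presence)
    assert net.edges.empty and net.candidate_genera == {}


def test_genome_network_respects_length_filter(small_community):
    from viropop.synthetic_data import presence_from_truth

    genomes, truth = small_community
    presence = presence_from_truth(genomes, truth)
    lengths = {g.id: g.length_bp for g in genomes}
    lengths[genomes[0].id] = 10_000  # below the 13-kb inclusion rule
    net = build_genome_network(presence, genome_lengths=lengths)
    assert genomes[0].id not in net.nodes


# ---------------------------------------------------------------------------
# PC prevalence classes and signature genes
# ---------------------------------------------------------------------------

def _presence_with_prevalence(n_genomes, counts):
    presence = pd.DataFrame(False, index=[f"g{i}" for i in range(n_genomes)],
                            columns=list(counts))
    for pc, c in counts.items():
        presence.iloc[:c, presence.columns.get_loc(pc)] = True
    return presence


def test_pc_prevalence_classes():
    presence = _presence_with_prevalence(25, {
        "all": 25, "all_but_one": 24, "eighty_pct": 20,
        "exactly_68pct": 17, "rare": 5})
    classes = classify_pc_prevalence(presence)
    assert classes["all"] == "core"
    assert classes["all_but_one"] == "core"
    assert classes["eighty_pct"] == "near_core"       # 80% > 68%
    assert classes["exactly_68pct"] == "accessory"    # strict > 68%
    assert classes["rare"] == "accessory"


def test_pc_prevalence_requires_three_genomes():
    with pytest.raises(ValueError):
        classify_pc_prevalence(_presence_with_prevalence(2, {"p": 1}))


def test_signature_genes_recovered_and_core_excluded(small_community):
    from viropop.synthetic_data import presence_from_truth

    genomes, truth = small_community
    presence = presence_from_truth(genomes, truth)
    genera = {}
    for genome, genus in truth.genus_of_genome.items():
        genera.setdefault(genus, set()).add(genome)
    clusters = dict(enumerate(genera.values()))
    sigs = find_signature_genes(presence, clusters)
    for cid, members in clusters.items():
        genus = truth.genus_of_genome[next(iter(members))]
        assert sigs[cid] == truth.signature_pcs(genus)
        assert not any(truth.pc_class[pc] == "core" for pc in sigs[cid])


def test_signature_excludes_singleton_clusters():
    presence = pd.DataFrame([[1, 0], [0, 1], [0, 1]],
                            index=["a", "b", "c"],
                            columns=["p1", "p2"]).astype(bool)
    sigs = find_signature_genes(presence, {0: {"a"}, 1: {"b", "c"}})
    assert 0 not in sigs and sigs[1] == {"p2"}


# ---------------------------------------------------------------------------
# Affiliation
# ---------------------------------------------------------------------------

def test_affiliate_genes_tier_priority_and_orfans():
    g2g = {"gene1": "G1", "gene2": "G1", "gene3": "G1"}
    ref = [_hit("gene1", "sputnik_v20")]
    other = [_hit("gene1", "some_bacterium"), _hit("gene2", "algal_virus")]
    peers = [_hit("gene3", "gene_self")]
    labels = affiliate_genes(list(g2g), ref, other, peers, g2g | {"gene_self": "G1"})
    assert labels["gene1"] == "reference_virophage"   # tier 1 beats tier 2
    assert labels["gene2"] == "other_viral_or_cellular"
    assert labels["gene3"] == "ORFan"                 # only a self-genome peer


def test_affiliate_genes_excludes_duplicate_genomes():
    g2g = {"gene1": "G1", "peerA": "G2", "peerB": "G3"}
    peers = [_hit("gene1", "peerA"), _hit("gene1", "peerB")]
    labels = affiliate_genes(["gene1"], [], [], peers, g2g,
                             duplicate_groups={"G1": {"G2", "G3"}})
    assert labels["gene1"] == "ORFan"
    labels2 = affiliate_genes(["gene1"], [], [], peers, g2g,
                              duplicate_groups={"G1": {"G2"}})
    assert labels2["gene1"] == "novel_virophage_peer"


def test_best_hit_tie_breaking():
    hits = [_hit("q", "subjB", e=1e-10, bit=100),
            _hit("q", "subjA", e=1e-20, bit=100),
            _hit("q", "weak", e=1e-30, bit=90)]
    assert best_hit_affiliation(hits)["q"] == "subjA"  # same bit, lower E
    hits = [_hit("q", "zz", e=1e-20, bit=100), _hit("q", "aa", e=1e-20, bit=100)]
    assert best_hit_affiliation(hits)["q"] == "aa"     # full tie: lexicographic


def test_best_hit_no_passing_hit_is_unaffiliated():
    assert best_hit_affiliation([_hit("q", "s", bit=10.0)]) == {}


def test_genome_affiliation_majority_vote():
    g2g = {f"g{i}": "bin1" for i in range(4)}
    labels = {"g0": "Mimiviridae", "g1": "Mimiviridae", "g2": "Mimiviridae",
              "g3": "Phycodnaviridae"}
    assert genome_affiliation_by_vote(labels, g2g)["bin1"] == "Mimiviridae"
    tie = {"g0": "A", "g1": "A", "g2": "B", "g3": "B"}
    assert genome_affiliation_by_vote(tie, g2g)["bin1"] is None
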