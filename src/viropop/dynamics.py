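"""Abundance dynamics and multi-method virophage-host association.

Virophages depend on a co-infecting giant virus (NCLDV) for replication, so
their abundance trajectories across a time series should track those of their
host, possibly with a short lag.  This module normalises per-sample coverage
(per Gbp sequenced), flags detections (breadth > 75% of contig positions
covered), z-scores environmental covariates, and predicts virophage-host
pairs with three complementary methods:

1. a conservative Bray-Curtis similarity network thresholded by a
   row-permutation null and clustered with MCL;
2. module co-membership from a WGCNA-style global clustering, ingested as an
   external table (a desk-scale correlation-graph emulation is provided);
3. local similarity analysis (LSA): the best partial-sum alignment of the
   normal-score-transformed series over time offsets up to ±3 samples,
   with significance from seeded permutations and Benjamini-Hochberg
   q-values.

Predictions are combined by priority: detected by all three methods first,
then WGCNA ∧ LSA, then either alone; within a rank, delay-0 LSA pairs
outrank lagged ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from statsmodels.stats.multitest import multipletests

from .gene_content import mcl

#: LSA maximum |time offset| between the two series, in samples.
DEFAULT_MAX_DELAY = 3

#: Detection requires breadth strictly above this fraction.
DEFAULT_MIN_BREADTH = 0.75

#: Default number of LSA significance permutations.
DEFAULT_N_PERM_LSA = 2000


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceSeries:
    """Normalized coverage (entities x samples) with detection metadata."""

    values: pd.DataFrame                 # entities x samples, >= 0
    breadth: pd.DataFrame | None = None  # same shape, in [0, 1]
    entity_types: dict[str, str] = field(default_factory=dict)
    env: pd.DataFrame | None = None      # covariates x samples

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def of_type(self, entity_type: str) -> list[str]:
        return [e for e in self.entities
                if self.entity_types.get(e) == entity_type]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class AssociationResult:
    entity_a: str                       # virophage
    entity_b: str                       # candidate host (NCLDV / 18S entity)
    methods_detected: frozenset[str]    # subset of {bc_mcl, wgcna, lsa}
    priority_rank: int
    lsa_delay: int | None = None
    lsa_span: int | None = None
    bc_similarity: float | None = None
    ls_score: float | None = None
    p: float | None = None
    q: float | None = None


# ---------------------------------------------------------------------------
# Normalisation, detection, z-scores
# ---------------------------------------------------------------------------

def normalize_coverage(raw: pd.DataFrame,
                       sample_total_bp: Mapping[str, float] | pd.Series
                       ) -> pd.DataFrame:
    """Scale raw per-sample coverage to coverage per Gbp sequenced."""
    totals = pd.Series(sample_total_bp).reindex(raw.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive total bp sequenced")
    return raw.div(totals, axis=1) * 1e9


def detection_flags(breadth: pd.DataFrame,
                    min_breadth: float = DEFAULT_MIN_BREADTH) -> pd.DataFrame:
    """An entity is detected in a sample iff breadth is strictly > 75%."""
    return breadth > min_breadth


def zscore_series(values: Sequence[float] | pd.Series
                  ) -> tuple[np.ndarray, bool]:
    """Z-score a series (sample sd, ddof=1), propagating missing values.

    Returns ``(z, degenerate)``: a constant series yields all zeros with
    ``degenerate=True``.  NaNs are ignored when computing the moments and
    stay NaN in the output.
    """
    x = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(x)) < 2:
        raise ValueError("z-scoring needs at least 2 observed values")
    mean = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        out = np.where(np.isnan(x), np.nan, 0.0)
        return out, True
    return (x - mean) / sd, False


# ---------------------------------------------------------------------------
# Bray-Curtis network with permutation-null threshold
# ---------------------------------------------------------------------------

def bray_curtis_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """1 minus Bray-Curtis dissimilarity; NaN for two all-zero vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.sum() == 0 and y.sum() == 0:
        return float("nan")
    return 1.0 - float(braycurtis(x, y))


def _pairwise_bc(matrix: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Bray-Curtis similarities for matrix rows."""
    m = matrix.shape[0]
    sims = []
    for i in range(m):
        for j in range(i + 1, m):
            if matrix[i].sum() == 0 and matrix[j].sum() == 0:
                continue
            sims.append(1.0 - braycurtis(matrix[i], matrix[j]))
    return np.asarray(sims)


def permutation_threshold(series: pd.DataFrame, n_perm: int = 10,
                          quantile: float = 1.0,
                          seed: int | np.random.Generator = 0) -> float:
    """Empirical similarity threshold from row-permuted null matrices.

    Each of the ``n_perm`` null matrices shuffles every row (entity)
    independently across samples, destroying temporal coupling while keeping
    marginal abundance distributions.  The threshold is the requested upper
    ``quantile`` of all pairwise Bray-Curtis similarities pooled over the
    null matrices (default: their maximum, the most conservative choice).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if series.shape[0] < 2:
        raise ValueError("need at least 2 entities")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mat = series.to_numpy(dtype=float)
    null_sims = []
    for _ in range(n_perm):
        perm = np.vstack([rng.permutation(row) for row in mat])
        null_sims.append(_pairwise_bc(perm))
    pooled = np.concatenate(null_sims)
    return float(np.quantile(pooled, quantile))


def bc_mcl_network(series: AbundanceSeries, threshold: float,
                   inflation: float = 2.0,
                   virophage_type: str = "virophage",
                   host_types: tuple[str, ...] = ("ncldv", "18S"),
                   ) -> tuple[list[set[str]], set[tuple[str, str]]]:
    """Cluster the thresholded Bray-Curtis similarity network with MCL.

    Edges connect entities with similarity strictly above ``threshold``.
    Returns the MCL clusters and the set of co-clustered
    (virophage, candidate-host) pairs.
    """
    ents = series.entities
    mat = series.values.to_numpy(dtype=float)
    m = len(ents)
    A = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            s = bray_curtis_similarity(mat[i], mat[j])
            if not np.isnan(s) and s > threshold:
                A[i, j] = A[j, i] = s
    clusters, _ = mcl(A, inflation=inflation, labels=ents)
    pairs = set()
    for cluster in clusters:
        viro = [e for e in cluster
                if series.entity_types.get(e) == virophage_type]
        hosts = [e for e in cluster
                 if series.entity_types.get(e) in host_types]
        for v in viro:
            for h in hosts:
                pairs.add((v, h))
    return clusters, pairs


# ---------------------------------------------------------------------------
# Local similarity analysis
# ---------------------------------------------------------------------------

def normal_scores(x: Sequence[float]) -> np.ndarray:
    """Blom rank-based normal scores; ties get average ranks."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _ls_core(xs: np.ndarray, ys: np.ndarray, max_delay: int
             ) -> tuple[float, int, int, int]:
    """Best local alignment score of two transformed series.

    Returns (raw best partial sum, delay, span, sign).  Positive delay means
    the second series lags the first (x[i] aligned with y[i + d]).
    """
    n = len(xs)
    best = (0.0, 0, 0, 1)
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            prods = xs[: n - d] * ys[d:]
        else:
            prods = xs[-d:] * ys[: n + d]
        pos = neg = 0.0
        pos_start = neg_start = 0
        for i, z in enumerate(prods):
            pos = pos + z
            if pos <= 0:
                pos, pos_start = 0.0, i + 1
            elif pos > best[0]:
                best = (pos, d, i - pos_start + 1, 1)
            neg = neg - z
            if neg <= 0:
                neg, neg_start = 0.0, i + 1
            elif neg > best[0]:
                best = (neg, d, i - neg_start + 1, -1)
    return best


def _ls_best_batch(X: np.ndarray, y: np.ndarray, max_delay: int) -> np.ndarray:
    """Best |partial sum| per row of X against y (vectorised over rows)."""
    B, n = X.shape
    best = np.zeros(B)
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            P = X[:, : n - d] * y[d:]
        else:
            P = X[:, -d:] * y[: n + d]
        pos = np.zeros(B)
        neg = np.zeros(B)
        for i in range(P.shape[1]):
            pos = np.maximum(0.0, pos + P[:, i])
            neg = np.maximum(0.0, neg - P[:, i])
            np.maximum(best, pos, out=best)
            np.maximum(best, neg, out=best)
    return best


@dataclass
class LSResult:
    ls_score: float
    delay: int
    span: int
    sign: int
    p: float | None = None
    q: float | None = None


def local_similarity(x: Sequence[float], y: Sequence[float],
                     max_delay: int = DEFAULT_MAX_DELAY,
                     n_perm: int = 0,
                     seed: int | np.random.Generator = 0) -> LSResult:
    """Local similarity of two equal-length series with bounded time delay.

    Both series are rank-transformed to normal scores; a dynamic programme
    finds the maximal contiguous partial sum of aligned products over all
    offsets |d| <= ``max_delay``, for positive and negative association.
    The LS score is that maximum divided by the series length.  With
    ``n_perm`` > 0, a permutation p-value is computed by shuffling one series
    (p = (1 + #null >= observed) / (1 + n_perm)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    if n < max_delay + 2:
        raise ValueError("series too short for the requested max_delay")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant series: rank transform is degenerate")
    xs, ys = normal_scores(x), normal_scores(y)
    raw, delay, span, sign = _ls_core(xs, ys, max_delay)
    result = LSResult(ls_score=raw / n, delay=delay, span=span, sign=sign)
    if n_perm > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        perms = np.vstack([rng.permutation(xs) for _ in range(n_perm)])
        null = _ls_best_batch(perms, ys, max_delay)
        result.p = (1 + int(np.sum(null >= raw - 1e-12))) / (1 + n_perm)
    return result


def lsa_all_pairs(series: AbundanceSeries,
                  pairs: Iterable[tuple[str, str]],
                  max_delay: int = DEFAULT_MAX_DELAY,
                  n_perm: int = DEFAULT_N_PERM_LSA,
                  seed: int = 0) -> pd.DataFrame:
    """LSA over a set of entity pairs, with BH q-values across all pairs.

    Pairs whose series are constant (degenerate rank transform) are skipped.
    Missing values: each pair is evaluated on its samples observed in both
    series.
    """
    rng = np.random.default_rng(seed)
    rows = []
    vals = series.values
    for a, b in pairs:
        x = vals.loc[a].to_numpy(dtype=float)
        y = vals.loc[b].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < max_delay + 2 or np.all(x == x[0]) or np.all(y == y[0]):
            continue
        r = local_similarity(x, y, max_delay=max_delay, n_perm=n_perm,
                             seed=rng)
        rows.append((a, b, r.ls_score, r.delay, r.span, r.sign, r.p))
    df = pd.DataFrame(rows, columns=["entity_a", "entity_b", "ls_score",
                                     "delay", "span", "sign", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def filter_lsa_pairs(results: pd.DataFrame, min_span: int,
                     max_p: float = 1e-5, max_q: float = 1e-5
                     ) -> pd.DataFrame:
    """Keep pairs with span >= min_span and both p and q below thresholds."""
    keep = ((results["span"] >= min_span) & (results["p"] <= max_p)
            & (results["q"] <= max_q))
    return results[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Correlation screen and WGCNA-style module ingestion
# ---------------------------------------------------------------------------

def correlation_screen(series: AbundanceSeries,
                       entities: Sequence[str] | None = None,
                       min_r: float = 0.9) -> tuple[pd.DataFrame, int, int]:
    """Pearson correlations between entity pairs; return the strong ones.

    Correlations use samples where both series are observed; degenerate
    (constant) series are excluded.  Returns (strong_pairs, n_strong,
    n_total_pairs).
    """
    ents = list(entities) if entities is not None else series.entities
    vals = series.values
    rows = []
    n_total = 0
    for i in range(len(ents)):
        for j in range(i + 1, len(ents)):
            x = vals.loc[ents[i]].to_numpy(dtype=float)
            y = vals.loc[ents[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                continue
            n_total += 1
            r = float(np.corrcoef(x, y)[0, 1])
            if r > min_r:
                rows.append((ents[i], ents[j], r))
    strong = pd.DataFrame(rows, columns=["entity_a", "entity_b", "r"])
    return strong, len(strong), n_total


def emulate_wgcna_modules(series: AbundanceSeries, power: int = 12,
                          adjacency_cutoff: float = 0.25) -> pd.DataFrame:
    """Desk-scale stand-in for a WGCNA module table (synthetic runs only).

    Follows the shape of the WGCNA procedure applied to metagenome coverage
    matrices — Hellinger normalisation, log transform, soft-thresholded
    adjacency ``|r|^power`` — and reads modules off the connected components
    of the adjacency above ``adjacency_cutoff`` (power 12 with cutoff 0.25
    links only pairs with |r| of about 0.89 or more).  It reproduces WGCNA's
    same-module co-membership output format, not its dendrogram internals.
    """
    ents = series.entities
    mat = series.values.to_numpy(dtype=float)
    colsum = mat.sum(axis=0, keepdims=True)
    colsum[colsum == 0] = 1.0
    transformed = np.log1p(np.sqrt(mat / colsum))
    m = len(ents)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = transformed[i], transformed[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            adj = abs(np.corrcoef(xi, xj)[0, 1]) ** power
            if adj > adjacency_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots: dict[int, int] = {}
    rows = []
    for i, e in enumerate(ents):
        r = find(i)
        rows.append((e, roots.setdefault(r, len(roots))))
    return pd.DataFrame(rows, columns=["entity", "module"])


def module_pairs(module_table: pd.DataFrame, entity_types: Mapping[str, str],
                 virophage_type: str = "virophage",
                 host_types: tuple[str, ...] = ("ncldv", "18S"),
                 min_module_size: int = 2) -> set[tuple[str, str]]:
    """(virophage, host) pairs co-occurring in the same module."""
    pairs = set()
    for _, grp in module_table.groupby("module"):
        if len(grp) < min_module_size:
            continue
        members = list(grp["entity"])
        viro = [e for e in members if entity_types.get(e) == virophage_type]
        hosts = [e for e in members if entity_types.get(e) in host_types]
        for v in viro:
            for h in hosts:
                pairs.add((v, h))
    return pairs


# ---------------------------------------------------------------------------
# Combination priority rules
# ---------------------------------------------------------------------------

def combine_predictions(bc_pairs: set[tuple[str, str]],
                        wgcna_pairs: set[tuple[str, str]],
                        lsa_results: pd.DataFrame,
                        bc_similarities: Mapping[tuple[str, str], float]
                        | None = None) -> list[AssociationResult]:
    """Rank virophage-host predictions by method agreement.

    Rank 1: detected by all three methods.  Rank 2: WGCNA and LSA.  Rank 3:
    exactly one of WGCNA / LSA.  Pairs supported only by the Bray-Curtis
    network get rank 4.  Within a rank, pairs with LSA delay 0 come before
    lagged ones (|delay| ascending), mirroring the expectation of
    synchronised virus-host abundance peaks.
    """
    lsa_pairs = set(zip(lsa_results["entity_a"], lsa_results["entity_b"]))
    lsa_by_pair = {(r.entity_a, r.entity_b): r
                   for r in lsa_results.itertuples(index=False)}
    all_pairs = bc_pairs | wgcna_pairs | lsa_pairs
    out = []
    for pair in all_pairs:
        methods = set()
        if pair in bc_pairs:
            methods.add("bc_mcl")
        if pair in wgcna_pairs:
            methods.add("wgcna")
        if pair in lsa_pairs:
            methods.add("lsa")
        if {"bc_mcl", "wgcna", "lsa"} <= methods:
            rank = 1
        elif {"wgcna", "lsa"} <= methods:
            rank = 2
        elif "wgcna" in methods or "lsa" in methods:
            rank = 3
        else:
            rank = 4
        r = lsa_by_pair.get(pair)
        out.append(AssociationResult(
            entity_a=pair[0], entity_b=pair[1],
            methods_detected=frozenset(methods), priority_rank=rank,
            lsa_delay=int(r.delay) if r is not None else None,
            lsa_span=int(r.span) if r is not None else None,
            ls_score=float(r.ls_score) if r is not None else None,
            p=float(r.p) if r is not None else None,
            q=float(r.q) if r is not None else None,
            bc_similarity=(bc_similarities or {}).get(pair)))
    out.sort(key=lambda a: (a.priority_rank,
                            abs(a.lsa_delay) if a.lsa_delay is not None else
                            DEFAULT_MAX_DELAY + 1,
                            a.entity_a, a.entity_b))
    return out


def best_hosts_per_virophage(results: Sequence[AssociationResult]
                             ) -> dict[str, list[AssociationResult]]:
    """For each virophage, its predictions at the best (lowest) rank."""
    out: dict[str, list[AssociationResult]] = {}
    for r in results:
        cur = out.get(r.entity_a)
        if cur is None or r.priority_rank < cur[0].priority_rank:
            out[r.entity_a] = [r]
        elif r.priority_rank == cur[0].priority_rank:
            out[r.entity_a].append(r)
    return out


def associations_to_tsv(results: Sequence[AssociationResult], path) -> None:
    rows = [(r.entity_a, r.entity_b, "+".join(sorted(r.methods_detected)),
             r.priority_rank, r.bc_similarity, r.ls_score, r.lsa_delay,
             r.lsa_span, r.p, r.q) for r in results]
    pd.DataFrame(rows, columns=["a", "b", "methods", "rank", "bc", "ls",
                                "delay", "span", "p", "q"]).to_csv(
        path, sep="\t", index=False)
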