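"""Cross-dataset signature integration.

Three tools operating on signed gene sets and ranked fold-change vectors:

* signed-overlap enrichment between two signatures (concordant-up,
  concordant-down, discordant), reported as fold over the independence
  expectation with a hypergeometric tail probability;
* agglomerative clustering of per-gene fold-change profiles (Euclidean
  distance, average linkage by default, tree cut to k clusters);
* pre-ranked GSEA in the weighted Kolmogorov-Smirnov formulation with a
  gene-label permutation null, normalized enrichment scores and the
  standard positive/negative-null FDR, plus leading-edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

from .genesets import SignedGeneSets

# ---------------------------------------------------------------------------
# signed overlap enrichment
# ---------------------------------------------------------------------------


@dataclass
class OverlapEnrichment:
    category: str  # concordant-up | concordant-down | discordant
    observed: int
    expected: float
    fold: float
    p_value: float
    degenerate: bool = False


def hypergeom_overlap_p(universe: int, n_a: int, n_b: int, observed: int) -> float:
    """Two-tailed hypergeometric p for an overlap of two sets.

    Model: a fixed set of size n_a, a uniformly random set of size n_b, both
    within a universe of the given size; the overlap is Hypergeom(universe,
    n_a, n_b). Two-tailed = twice the smaller of P(X >= obs) and
    P(X <= obs), capped at 1.
    """
    if not (0 <= n_a <= universe and 0 <= n_b <= universe):
        raise ValueError("set sizes exceed the universe")
    rv = hypergeom(universe, n_a, n_b)
    upper = float(rv.sf(observed - 1))  # P(X >= observed)
    lower = float(rv.cdf(observed))  # P(X <= observed)
    return min(1.0, 2.0 * min(upper, lower))


def _discordant_p(universe: int, a_up: int, a_dn: int, b_up: int, b_dn: int, observed: int) -> float:
    """Two-tailed p for the pooled discordant count.

    The count is |A.up & B.down| + |A.down & B.up|. Its exact joint null is
    awkward (the two overlaps are dependent through the disjointness of the
    B sets); the distribution used here is the convolution of the two exact
    marginal hypergeometric PMFs, i.e. an independence approximation.
    """
    x = hypergeom(universe, a_up, b_dn).pmf(np.arange(min(a_up, b_dn) + 1))
    y = hypergeom(universe, a_dn, b_up).pmf(np.arange(min(a_dn, b_up) + 1))
    pmf = np.convolve(x, y)
    upper = float(pmf[observed:].sum())
    lower = float(pmf[: observed + 1].sum())
    return min(1.0, 2.0 * min(upper, lower))


def signed_overlap_enrichment(
    a: SignedGeneSets, b: SignedGeneSets
) -> dict[str, OverlapEnrichment]:
    """Concordant-up / concordant-down / discordant enrichment of two signatures.

    Both signatures are restricted to the shared universe first. Fold is
    observed / expected with expected = |A||B| / |universe|; empty sets on
    either side give fold 0 reported with p = 1 and a degenerate flag.
    """
    shared = a.universe & b.universe
    if not shared:
        raise ValueError("signatures share no universe genes")
    a = a.restricted_to(shared)
    b = b.restricted_to(shared)
    n = len(shared)

    def one(category: str, sa: frozenset, sb: frozenset) -> OverlapEnrichment:
        obs = len(sa & sb)
        exp = len(sa) * len(sb) / n
        if exp == 0:
            return OverlapEnrichment(category, obs, 0.0, 0.0, 1.0, degenerate=True)
        p = hypergeom_overlap_p(n, len(sa), len(sb), obs)
        return OverlapEnrichment(category, obs, exp, obs / exp, p)

    out = {
        "concordant-up": one("concordant-up", a.up, b.up),
        "concordant-down": one("concordant-down", a.down, b.down),
    }
    obs = len(a.up & b.down) + len(a.down & b.up)
    exp = (len(a.up) * len(b.down) + len(a.down) * len(b.up)) / n
    if exp == 0:
        out["discordant"] = OverlapEnrichment("discordant", obs, 0.0, 0.0, 1.0, degenerate=True)
    else:
        p = _discordant_p(n, len(a.up), len(a.down), len(b.up), len(b.down), obs)
        out["discordant"] = OverlapEnrichment("discordant", obs, exp, obs / exp, p)
    return out


# ---------------------------------------------------------------------------
# fold-change profile clustering
# ---------------------------------------------------------------------------


def cluster_profiles(
    profiles: pd.DataFrame, k: int = 10, method: str = "average"
) -> pd.Series:
    """Cut an agglomerative tree of fold-change profiles into k clusters.

    `profiles`: genes x contrasts DataFrame (no missing values). Distance is
    Euclidean; linkage defaults to average. Rows are sorted by gene id
    before linkage so output is independent of input order, and cluster
    labels are reassigned by decreasing cluster size (1 = largest; equal
    sizes break by the lexicographically smallest member).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    if profiles.index.duplicated().any():
        dups = profiles.index[profiles.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing coordinates")
    ordered = profiles.sort_index()
    Z = linkage(ordered.to_numpy(dtype=float), method=method, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=ordered.index, name="cluster")
    # relabel by decreasing size, ties by smallest member id
    order = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), sorted(map(str, kv[1]))[0]),
    )
    remap = {old: new for new, (old, _) in enumerate(order, start=1)}
    return labels.map(remap)


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    label: str
    es: float
    nes: float
    fdr: float
    p_value: float
    leading_edge_count: int
    set_size: int
    n_permutations: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.fdr < 0.01


def _rank_genes(ranked: pd.Series) -> pd.Series:
    """Sort descending by statistic, ties broken by gene id (stable)."""
    df = pd.DataFrame({"stat": ranked})
    df["gene"] = df.index.astype(str)
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
    return df["stat"]


def _es_from_positions(weights: np.ndarray, positions: np.ndarray, n: int):
    """Enrichment scores from sorted 0-based hit positions.

    `positions`: (n_runs, K) ascending per row; `weights`: abs-statistic^w
    per ranked position (length n). Returns (es, extremum_hit_index) where
    the extremum index is the hit ordinal (0-based) attaining the extremum.

    The running sum adds w_hit/W at hits and subtracts 1/(n-K) at misses;
    its extrema can only occur immediately after a hit (maxima) or
    immediately before one (minima), so only hit positions are evaluated.
    """
    n_runs, k = positions.shape
    if n == k:
        raise ValueError("gene set covers the whole ranking; ES undefined")
    w_hits = weights[positions]
    totals = w_hits.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all hit statistics zero; ES undefined")
    cum = np.cumsum(w_hits, axis=1) / totals
    miss_step = 1.0 / (n - k)
    misses_before = positions - np.arange(k)[None, :]
    after = cum - misses_before * miss_step
    before = after - w_hits / totals
    i_max = np.argmax(after, axis=1)
    i_min = np.argmin(before, axis=1)
    rows = np.arange(n_runs)
    pos_es = after[rows, i_max]
    neg_es = before[rows, i_min]
    take_pos = pos_es >= -neg_es
    es = np.where(take_pos, pos_es, neg_es)
    extremum = np.where(take_pos, i_max, i_min)
    return es, extremum


def _normalize(es: np.ndarray, null_es: np.ndarray) -> np.ndarray:
    """NES = ES / mean(|null ES| of the same sign)."""
    pos_mean = null_es[null_es > 0].mean() if (null_es > 0).any() else np.abs(null_es).mean()
    neg_mean = -null_es[null_es < 0].mean() if (null_es < 0).any() else np.abs(null_es).mean()
    out = np.where(es >= 0, es / pos_mean, es / neg_mean)
    return out


def preranked_gsea(
    ranked: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = None,
    label: str = "",
) -> GseaResult:
    """Weighted-KS pre-ranked GSEA of one gene set with a permutation null.

    Genes are sorted by statistic (descending, ties by id); the running sum
    gains |stat|^weight / sum_hits |stat|^weight at set members and loses
    1/(N - K) elsewhere; ES is the signed extremum. The null re-draws the K
    member positions uniformly (gene-label permutation), NES divides by the
    mean same-sign null |ES|, the p-value is the same-sign null tail, and
    with a single set the FDR equals the normalized same-sign tail fraction
    of the null NES distribution.
    """
    results = gsea_batch(
        ranked,
        {label or "set": gene_set},
        weight_exponent=weight_exponent,
        n_permutations=n_permutations,
        seed=seed,
    )
    return next(iter(results.values()))


def gsea_batch(
    ranked: pd.Series,
    gene_sets: dict,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict[str, GseaResult]:
    """Pre-ranked GSEA of several gene sets against one ranking.

    Null NES values are pooled across sets for the FDR, as in the standard
    multiple-set procedure.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    stats = _rank_genes(ranked)
    if (stats == 0).all():
        raise ValueError("all ranking statistics are zero; ES undefined")
    genes = np.asarray(stats.index.astype(str))
    n = len(genes)
    weights = np.abs(stats.to_numpy(dtype=float)) ** weight_exponent
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    observed: dict[str, tuple[float, int, int, np.ndarray]] = {}
    null_nes_pool: list[np.ndarray] = []
    nes_obs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for name, gs in gene_sets.items():
        members = sorted({str(g) for g in gs} & set(pos_of))
        if not members:
            raise ValueError(f"gene set {name!r} shares no genes with the ranking")
        positions = np.sort(np.array([pos_of[g] for g in members]))[None, :]
        es, extremum = _es_from_positions(weights, positions, n)
        es, ext = float(es[0]), int(extremum[0])
        k = len(members)
        lead = ext + 1 if es >= 0 else k - ext
        null_pos = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :k]
        null_pos.sort(axis=1)
        null_es, _ = _es_from_positions(weights, null_pos, n)
        same = null_es >= 0 if es >= 0 else null_es < 0
        p = (np.abs(null_es[same]) >= abs(es)).sum() / max(same.sum(), 1)
        null_nes = _normalize(null_es, null_es)
        nes = float(_normalize(np.array([es]), null_es)[0])
        observed[name] = (es, lead, k, null_es)
        nes_obs[name] = nes
        pvals[name] = float(p)
        null_nes_pool.append(null_nes)

    pool = np.concatenate(null_nes_pool)
    obs_vals = np.array(list(nes_obs.values()))
    results = {}
    for name, (es, lead, k, _) in observed.items():
        nes = nes_obs[name]
        if nes >= 0:
            null_frac = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
            obs_frac = (obs_vals >= nes).sum() / max((obs_vals >= 0).sum(), 1)
        else:
            null_frac = (pool <= nes).sum() / max((pool < 0).sum(), 1)
            obs_frac = (obs_vals <= nes).sum() / max((obs_vals < 0).sum(), 1)
        fdr = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        results[name] = GseaResult(
            label=name,
            es=es,
            nes=nes,
            fdr=float(fdr),
            p_value=pvals[name],
            leading_edge_count=lead,
            set_size=k,
            n_permutations=n_permutations,
            seed=seed,
        )
    return results


def reversal_screen(
    cluster_sets: dict[str, set],
    contrast_rank: pd.Series,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict[str, GseaResult]:
    """GSEA of each signature cluster against a contrast ranking.

    Typical use: rank genes by the drug-vs-control logFC and ask whether an
    aging-up cluster is negatively enriched (reversal) at FDR < 0.01.
    """
    return gsea_batch(
        contrast_rank,
        cluster_sets,
        weight_exponent=weight_exponent,
        n_permutations=n_permutations,
        seed=seed,
    )
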