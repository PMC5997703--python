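"""Population statistics on aligned mitochondrial haplotypes.

The differentiation statistic throughout is ΦST: the AMOVA estimator of
the among-population fraction of molecular variance, computed from the
matrix of pairwise nucleotide differences.  The pairwise-difference counts
enter the AMOVA sums of squared deviations directly (this is the
"pairwise difference" distance mode of standard AMOVA software for
sequence data; the counts are NOT squared again).  Slatkin's
linearization ΦST/(1−ΦST) grows linearly with divergence time under pure
drift, which makes it the natural scale for ordination and for the
drift-only continuity test.

Missing data (N or gap) is handled by complete deletion — every column
with a missing call in any sequence is removed before haplotypes are
compared — matching the convention of classical sequence-statistics
software; pairwise deletion is available for the distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .exceptions import (
    NoInformativeSitesError,
    PartitionError,
)
from .io_meta import HaplotypeAlignment

_MISSING = np.frombuffer(b"N-", dtype=np.uint8)

FST_CAP = 0.999999


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise nucleotide differences."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)


def _called_mask(matrix: np.ndarray) -> np.ndarray:
    return ~np.isin(matrix, _MISSING)


def complete_deletion(matrix: np.ndarray) -> np.ndarray:
    """Drop every column containing a missing call in any row."""
    keep = _called_mask(matrix).all(axis=0)
    return matrix[:, keep]


def pairwise_distances(
    aln: HaplotypeAlignment, missing_policy: str = "complete_deletion"
) -> DistanceMatrix:
    """Pairwise nucleotide differences between all haplotypes.

    ``complete_deletion`` removes every column with an N or gap anywhere
    before counting mismatches; ``pairwise_deletion`` counts mismatches
    over the columns called in both members of each pair.
    """
    if aln.n_samples < 2:
        raise PartitionError("need at least 2 sequences for distances")
    X = aln.matrix
    if missing_policy == "complete_deletion":
        X = complete_deletion(X)
        if X.shape[1] == 0:
            raise NoInformativeSitesError(
                "no comparable sites: every column carries missing data"
            )
        n = X.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            diff = (X[i] != X[i + 1 :]).sum(axis=1)
            d[i, i + 1 :] = diff
            d[i + 1 :, i] = diff
        return DistanceMatrix(list(aln.sample_ids), d)
    if missing_policy == "pairwise_deletion":
        called = _called_mask(aln.matrix)
        n = aln.n_samples
        d = np.zeros((n, n))
        for i in range(n):
            both = called[i] & called[i + 1 :]
            diff = ((aln.matrix[i] != aln.matrix[i + 1 :]) & both).sum(axis=1)
            d[i, i + 1 :] = diff
            d[i + 1 :, i] = diff
        if not called.any():
            raise NoInformativeSitesError("no comparable sites: all cells missing")
        return DistanceMatrix(list(aln.sample_ids), d)
    raise ValueError(f"unknown missing policy: {missing_policy!r}")


# ---------------------------------------------------------------------------
# AMOVA ΦST


def _amova_phi(d: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """ΦST from a pairwise-difference matrix and index groups.

    Standard two-level AMOVA: the pairwise differences are used as the
    squared deviations.  Returns 0 for degenerate (monomorphic) data; the
    estimator may be slightly negative for weakly structured data.
    """
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    G = len(groups)
    total = d.sum() / 2.0
    ssd_t = total / N
    ssd_w = 0.0
    for g in groups:
        sub = d[np.ix_(g, g)]
        ssd_w += sub.sum() / 2.0 / len(g)
    ssd_a = ssd_t - ssd_w
    df_a = G - 1
    df_w = N - G
    ms_a = ssd_a / df_a
    ms_w = ssd_w / df_w if df_w > 0 else 0.0
    n_prime = (N - (sizes**2).sum() / N) / df_a
    sigma_a = (ms_a - ms_w) / n_prime
    sigma_w = ms_w
    denom = sigma_a + sigma_w
    if denom <= 0:
        return 0.0
    return sigma_a / denom


def _resolve_partition(
    dist: DistanceMatrix, partition: Sequence[Sequence[str]]
) -> list[np.ndarray]:
    groups = [dist.index(g) for g in partition]
    flat = np.concatenate(groups)
    if len(np.unique(flat)) != len(flat):
        raise PartitionError("groups overlap")
    for g, ids in zip(groups, partition):
        if len(g) < 2:
            raise PartitionError(
                f"group of size {len(g)} (< 2) cannot enter the AMOVA"
            )
    return groups


def phi_st(dist: DistanceMatrix, partition: Sequence[Sequence[str]]) -> float:
    """AMOVA ΦST for a two-group partition given by sample-id lists."""
    if len(partition) != 2:
        raise PartitionError("phi_st expects exactly two groups")
    groups = _resolve_partition(dist, partition)
    return _amova_phi(dist.d, groups)


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearization FST/(1−FST).

    Negative estimates are clamped to 0 before the transform; values at or
    above 1 are capped just below 1 with a warning (the transform diverges).
    """
    f = max(0.0, float(fst))
    if f >= 1.0:
        warnings.warn(
            f"FST {fst} >= 1 capped at {FST_CAP} before linearization",
            RuntimeWarning,
            stacklevel=2,
        )
        f = FST_CAP
    return f / (1.0 - f)


@dataclass(frozen=True)
class FstResult:
    pop_a: str
    pop_b: str
    fst: float
    linearized: float
    p_value: float
    n_permutations: int


def fst_permutation_test(
    dist: DistanceMatrix,
    partition: Sequence[Sequence[str]],
    n_perm: int = 10_000,
    seed: int | Generator | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Permutation test of ΦST under random reassignment of individuals.

    Individuals are shuffled between the two populations, keeping group
    sizes; p = (1 + #{permuted ΦST >= observed}) / (n_perm + 1), which never
    returns an exact zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(partition) != 2:
        raise PartitionError("permutation test expects exactly two groups")
    groups = _resolve_partition(dist, partition)
    ga, gb = groups
    idx = np.concatenate([ga, gb])
    D = dist.d[np.ix_(idx, idx)]
    na, nb = len(ga), len(gb)
    n = na + nb
    obs = _amova_phi(D, [np.arange(na), np.arange(na, n)])
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        phi = _amova_phi(D, [perm[:na], perm[na:]])
        if phi >= obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return FstResult(
        pop_a=labels[0],
        pop_b=labels[1],
        fst=obs,
        linearized=slatkin_linearize(obs),
        p_value=p,
        n_permutations=n_perm,
    )


def fst_matrix(
    dist: DistanceMatrix,
    groups: Mapping[str, Sequence[str]],
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """All pairwise ΦST values between named groups.

    Returns (raw ΦST, Slatkin-linearized, permutation p-values or None).
    The linearized matrix is a valid dissimilarity input for NMDS.
    """
    names = list(groups)
    raw = pd.DataFrame(0.0, index=names, columns=names)
    lin = pd.DataFrame(0.0, index=names, columns=names)
    pvals = pd.DataFrame(np.nan, index=names, columns=names) if n_perm else None
    rng = default_rng(seed)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if n_perm:
                res = fst_permutation_test(
                    dist, [groups[a], groups[b]], n_perm, rng, labels=(a, b)
                )
                f, l, p = res.fst, res.linearized, res.p_value
                pvals.loc[a, b] = pvals.loc[b, a] = p
            else:
                f = phi_st(dist, [groups[a], groups[b]])
                l = slatkin_linearize(f)
            raw.loc[a, b] = raw.loc[b, a] = f
            lin.loc[a, b] = lin.loc[b, a] = l
    return raw, lin, pvals


# ---------------------------------------------------------------------------
# haplotype diversity & sharing


def haplotype_classes(aln: HaplotypeAlignment) -> np.ndarray:
    """Identical-sequence class index per sample, after complete deletion."""
    X = complete_deletion(aln.matrix)
    if X.shape[1] == 0 and aln.length > 0:
        raise NoInformativeSitesError(
            "no comparable sites after removing missing-data columns"
        )
    _, labels = np.unique(X, axis=0, return_inverse=True)
    return labels


def haplotype_diversity(aln: HaplotypeAlignment, return_se: bool = False):
    """Haplotype (gene) diversity Hd.

    The probability that two haplotypes drawn without replacement differ:
    Hd = n/(n−1) · (1 − Σ p_i²) over identical-sequence classes, computed
    after complete deletion of missing-data columns.  With
    ``return_se=True`` also returns the sampling standard error (Nei's
    variance formula).
    """
    n = aln.n_samples
    if n < 2:
        raise PartitionError("haplotype diversity needs at least 2 sequences")
    labels = haplotype_classes(aln)
    _, counts = np.unique(labels, return_counts=True)
    p = counts / n
    sum2 = float(np.sum(p**2))
    hd = n / (n - 1) * (1.0 - sum2)
    if not return_se:
        return hd
    sum3 = float(np.sum(p**3))
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return hd, float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class SharingResult:
    shared_pairs: int  # cross-group pairs of identical haplotypes
    distinct_shared: int  # distinct haplotypes present in both groups
    nmax: int  # Ntot(Ntot−1)/2
    normalized: float


def haplotype_sharing(
    aln: HaplotypeAlignment,
    group_a: Sequence[str],
    group_b: Sequence[str],
    mode: str = "pairs",
) -> SharingResult:
    """Haplotype sharing between two disjoint groups.

    The numerator counts cross-group pairs (i in A, j in B) with identical
    post-deletion sequences (``mode="pairs"``, default, keeping numerator
    and denominator commensurable) or distinct haplotypes observed in both
    groups (``mode="distinct"``); the denominator is the maximum number of
    pairwise comparisons Nmax = Ntot·(Ntot−1)/2 with Ntot = |A|+|B|.
    """
    if set(group_a) & set(group_b):
        raise PartitionError("sharing groups overlap")
    if not group_a or not group_b:
        raise PartitionError("sharing groups must be non-empty")
    sub = aln.subset(list(group_a) + list(group_b))
    labels = haplotype_classes(sub)
    la = labels[: len(group_a)]
    lb = labels[len(group_a) :]
    shared_pairs = int(sum((lb == x).sum() for x in la))
    distinct = len(set(la.tolist()) & set(lb.tolist()))
    ntot = len(group_a) + len(group_b)
    nmax = ntot * (ntot - 1) // 2
    numer = shared_pairs if mode == "pairs" else distinct
    return SharingResult(
        shared_pairs=shared_pairs,
        distinct_shared=distinct,
        nmax=nmax,
        normalized=numer / nmax,
    )


# ---------------------------------------------------------------------------
# haplogroup frequencies with Bayesian intervals


def beta_hpd(k: int, n: int, mass: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval of Beta(k+1, n−k+1).

    The posterior of a proportion under a uniform prior after observing k
    successes in n trials.  At k=0 / k=n the posterior is monotone and the
    HPD abuts the corresponding boundary.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    a, b = k + 1, n - k + 1
    post = stats.beta(a, b)
    if k == 0:
        return 0.0, float(post.ppf(mass))
    if k == n:
        return float(post.ppf(1.0 - mass)), 1.0

    def width(lo: float) -> float:
        return post.ppf(post.cdf(lo) + mass) - lo

    res = optimize.minimize_scalar(
        width, bounds=(0.0, float(post.ppf(1.0 - mass))), method="bounded",
        options={"xatol": 1e-10},
    )
    lo = float(res.x)
    return lo, float(post.ppf(post.cdf(lo) + mass))


def haplogroup_ci(
    counts: Mapping[str, int] | pd.Series, n: int | None = None, mass: float = 0.95
) -> pd.DataFrame:
    """Per-haplogroup frequency with Bayesian 95% HPD bounds for one population."""
    s = pd.Series(counts, dtype=float)
    total = int(n) if n is not None else int(s.sum())
    if total < 1:
        raise ValueError("population size must be >= 1")
    if (s > total).any():
        raise ValueError("a haplogroup count exceeds the population size")
    rows = []
    for hg, k in s.items():
        lo, hi = beta_hpd(int(k), total, mass)
        rows.append({"haplogroup": hg, "count": int(k), "freq": k / total,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).set_index("haplogroup")


@dataclass
class HaplogroupFreqTable:
    """Populations × haplogroups counts with frequencies and HPD bounds."""

    counts: pd.DataFrame  # populations × haplogroups, non-negative ints
    freqs: pd.DataFrame = field(init=False)
    ci_low: pd.DataFrame = field(init=False)
    ci_high: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("haplogroup counts must be non-negative")
        totals = c.sum(axis=1)
        if (totals < 1).any():
            raise ValueError("every population needs at least one sample")
        self.freqs = c.div(totals, axis=0)
        lo = pd.DataFrame(index=c.index, columns=c.columns, dtype=float)
        hi = pd.DataFrame(index=c.index, columns=c.columns, dtype=float)
        for pop in c.index:
            tab = haplogroup_ci(c.loc[pop], int(totals[pop]))
            lo.loc[pop] = tab["ci_low"]
            hi.loc[pop] = tab["ci_high"]
        self.ci_low = lo
        self.ci_high = hi

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplogroups(self) -> list[str]:
        return list(self.counts.columns)


def haplogroup_counts(meta: pd.DataFrame, groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Tabulate haplogroup counts (populations × haplogroups) from metadata."""
    by_id = meta.set_index("sample_id")["haplogroup"]
    table: dict[str, pd.Series] = {}
    for name, ids in groups.items():
        hgs = by_id.reindex(ids).dropna()
        table[name] = hgs.value_counts()
    df = pd.DataFrame(table).T.fillna(0).astype(int)
    return df.sort_index(axis=1)


# ---------------------------------------------------------------------------
# ordination


@dataclass(frozen=True)
class PCAResult:
    coordinates: pd.DataFrame  # populations × PCs
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    loadings: pd.DataFrame  # haplogroups × PCs


def pca_haplogroups(
    table: HaplogroupFreqTable | pd.DataFrame, scale_unit: bool = True
) -> PCAResult:
    """PCA of a population × haplogroup frequency matrix via SVD.

    Columns are centered and (by default) scaled to unit variance;
    constant columns are dropped with a warning when scaling.  Percent
    variance across all components sums to 100.
    """
    F = table.freqs if isinstance(table, HaplogroupFreqTable) else table
    F = F.astype(float)
    if F.shape[0] < 3 or F.shape[1] < 2:
        raise ValueError("PCA needs >= 3 populations and >= 2 haplogroups")
    X = F.values - F.values.mean(axis=0)
    cols = list(F.columns)
    if scale_unit:
        sd = X.std(axis=0, ddof=1)
        const = sd <= 1e-15
        if const.any():
            dropped = [c for c, f in zip(cols, const) if f]
            warnings.warn(
                f"dropping constant haplogroup columns under unit scaling: {dropped}",
                RuntimeWarning,
                stacklevel=2,
            )
            X = X[:, ~const]
            cols = [c for c, f in zip(cols, const) if not f]
            sd = sd[~const]
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    pct = 100.0 * s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    pcs = [f"PC{i+1}" for i in range(len(s))]
    coords = pd.DataFrame(U * s, index=F.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=cols, columns=pcs)
    return PCAResult(coords, eig, pct, loadings)


@dataclass(frozen=True)
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1 of the best restart
    stress_history: np.ndarray  # per-iteration stress-1 of the best restart
    n_iter: int


def nmds(
    dissimilarity: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 8,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> NMDSResult:
    """Non-metric MDS by SMACOF majorization with isotonic regression.

    Each iteration fits monotone disparities to the configuration
    distances in the rank order of the input dissimilarities (Kruskal's
    primary approach), rescales them, and applies the Guttman transform;
    Kruskal stress-1 = sqrt(Σ(d−d̂)²/Σd²) is non-increasing across
    iterations.  The best of ``n_restarts`` random starts is returned.
    Negative input entries (e.g. negative ΦST) are clamped to 0.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        index = list(dissimilarity.index)
        D = dissimilarity.values.astype(float)
    else:
        D = np.asarray(dissimilarity, dtype=float)
        index = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if k >= n:
        raise ValueError(f"embedding dimension k={k} must be < n populations={n}")
    delta = np.maximum(squareform(np.maximum(D, 0.0), checks=False), 0.0)
    m = len(delta)
    rng = default_rng(seed)
    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ in range(max(1, n_restarts)):
        X = rng.uniform(-1.0, 1.0, size=(n, k))
        history: list[float] = []
        prev_raw = None
        for _it in range(max_iter):
            dist = pdist(X)
            dist = np.maximum(dist, 1e-12)
            dhat = IsotonicRegression().fit_transform(delta, dist)
            dhat *= np.sqrt(m / np.maximum(np.sum(dhat**2), 1e-300))
            raw = float(np.sum((dist - dhat) ** 2))
            history.append(float(np.sqrt(raw / np.sum(dist**2))))
            if prev_raw is not None and prev_raw - raw < tol * m:
                break
            prev_raw = raw
            # Guttman transform (unit weights)
            ratio = squareform(dhat / dist, checks=False)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
            X -= X.mean(axis=0)
        stress1 = history[-1]
        if best is None or stress1 < best[0]:
            best = (stress1, X, history)
    stress1, X, history = best
    coords = pd.DataFrame(X, index=index, columns=[f"Dim{i+1}" for i in range(k)])
    return NMDSResult(coords, stress1, np.array(history), len(history))


# ---------------------------------------------------------------------------
# maternal kinship candidates


@dataclass(frozen=True)
class KinPair:
    sample_a: str
    sample_b: str
    site: str
    basis: str  # "haplotype" | "haplogroup"


def kin_candidates(
    aln: HaplotypeAlignment | None,
    meta: pd.DataFrame,
    same_site_only: bool = True,
) -> list[KinPair]:
    """Flag sample pairs compatible with maternal kinship.

    Pairs share an identical post-deletion mitochondrial haplotype (or,
    for samples absent from the alignment, an identical haplogroup
    label), restricted to pairs excavated at the same site by default —
    shared burial context plus an identical maternal lineage is the
    paper-trail archaeogeneticists use to nominate relatives.
    """
    sites = meta.set_index("sample_id")["site"]
    hg = meta.set_index("sample_id")["haplogroup"]
    in_aln = set(aln.sample_ids) if aln is not None else set()

    key: dict[str, tuple[str, object]] = {}
    if aln is not None and aln.n_samples >= 1:
        labels = (
            haplotype_classes(aln) if aln.n_samples > 1 else np.zeros(1, dtype=int)
        )
        for sid, lab in zip(aln.sample_ids, labels):
            key[sid] = ("haplotype", int(lab))
    for sid in meta["sample_id"]:
        if sid not in in_aln and pd.notna(hg.get(sid)):
            key[sid] = ("haplogroup", hg[sid])

    ids = [s for s in meta["sample_id"] if s in key]
    pairs: list[KinPair] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if key[a][0] != key[b][0] or key[a][1] != key[b][1]:
                continue
            site_a, site_b = sites.get(a), sites.get(b)
            if same_site_only and site_a != site_b:
                continue
            pairs.append(
                KinPair(a, b, site=str(site_a) if site_a == site_b else
                        f"{site_a}|{site_b}", basis=key[a][0])
            )
    return pairs
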