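"""Multilocus spatial genetic autocorrelation for codominant genotypes.

Pairwise squared genetic distances follow the codominant microsatellite
metric of the standard autocorrelation framework: per locus, the squared
distance is half the squared Euclidean distance between allele-count
vectors, giving 0 for identical genotypes, 1 for AA-AB, 2 for AB-CD, 3 for
AA-BC and 4 for AA-BB; loci are summed and, with missing data, rescaled to
the full locus count.

The squared-distance matrix is Gower-centred, c_ij = -1/2 (d2_ij - rowmean_i
- colmean_j + grandmean), and the autocorrelation coefficient for a set S of
pairs is the pair-symmetric ratio

    r(S) = sum_{(i,j) in S} c_ij / sum_{(i,j) in S} (c_ii + c_jj) / 2.

On top of this sit the distance-class correlogram, increasing ("multiple
distance class") analyses, bootstrap confidence intervals, permutation
envelopes, the dual significance rule (bootstrap CI excludes 0 AND r falls
outside the permutation envelope), t2/omega correlogram heterogeneity
tests, two-dimensional local autocorrelation lr over n nearest neighbours,
and Mantel matrix-correspondence tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneticDistanceMatrix",
    "DistanceClassResult",
    "HeterogeneityResult",
    "MantelResult",
    "genotype_matrix_from_tables",
    "squared_genetic_distance",
    "gower_center",
    "autocorr_r_by_class",
    "correlogram",
    "multi_dclass",
    "bootstrap_ci_r",
    "permutation_envelope_r",
    "heterogeneity_tests",
    "local_autocorr_2d",
    "mantel_test",
    "geographic_distances",
]


@dataclass
class GenotypeMatrix:
    """Individuals with coordinates and diploid multilocus genotypes.

    ``alleles`` has shape (n, n_loci, 2) with integer allele sizes; 0 marks
    a missing allele (a locus is treated as missing if either allele is 0).
    """

    ids: np.ndarray
    sex: np.ndarray
    coords: np.ndarray  # (n, 2) metres
    loci: list
    alleles: np.ndarray  # (n, L, 2) int

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.coords.shape != (n, 2) or not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite with shape (n, 2)")
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError("alleles must have shape (n, n_loci, 2)")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, mask) -> "GenotypeMatrix":
        idx = np.asarray(mask)
        return GenotypeMatrix(
            self.ids[idx], self.sex[idx], self.coords[idx],
            list(self.loci), self.alleles[idx],
        )

    @property
    def missing_rate(self) -> float:
        return float((self.alleles == 0).any(axis=2).mean())


@dataclass
class GeneticDistanceMatrix:
    values: np.ndarray  # (n, n) squared multilocus distances; nan = no shared loci
    loci_used: np.ndarray  # (n, n) count of loci scored in both individuals


@dataclass
class DistanceClassResult:
    label: str
    lower_m: float
    upper_m: float
    n_pairs: int
    r: float
    ci_lower: float
    ci_upper: float
    perm_lower: float
    perm_upper: float
    significant: bool
    flags: list = field(default_factory=list)


@dataclass
class HeterogeneityResult:
    classes: list  # labels
    t2: np.ndarray
    t2_p: np.ndarray
    omega: float
    omega_p: float
    n_perm: int
    skipped: list = field(default_factory=list)


@dataclass
class MantelResult:
    r_xy: float
    p_value: float
    n_perm: int


def genotype_matrix_from_tables(
    genotypes: pd.DataFrame, individuals: pd.DataFrame
) -> GenotypeMatrix:
    """Join a two-column-per-locus genotype table with coordinates/sex.

    ``individuals`` needs columns individual_id, sex, x_m, y_m; only
    individuals present in both tables are kept, in genotype-table order.
    """
    meta = individuals.set_index("individual_id")
    keep = genotypes["individual_id"].isin(meta.index)
    g = genotypes[keep]
    allele_cols = [c for c in g.columns if c != "individual_id"]
    if len(allele_cols) % 2:
        raise ValueError("odd number of allele columns")
    loci = [allele_cols[i][:-2] for i in range(0, len(allele_cols), 2)]
    arr = g[allele_cols].to_numpy(int).reshape(len(g), len(loci), 2)
    ids = g["individual_id"].to_numpy()
    return GenotypeMatrix(
        ids=ids,
        sex=meta.loc[ids, "sex"].to_numpy(),
        coords=meta.loc[ids, ["x_m", "y_m"]].to_numpy(float),
        loci=loci,
        alleles=arr,
    )


# --------------------------------------------------------------------------
# squared genetic distance
# --------------------------------------------------------------------------

def squared_genetic_distance(g: GenotypeMatrix) -> GeneticDistanceMatrix:
    """Pairwise squared multilocus genetic distances.

    Computed per locus as half the squared Euclidean distance between
    allele-count vectors, summed over loci scored in both individuals and
    rescaled to the full locus count.  Pairs with no shared scored locus get
    a missing (nan) entry with a warning.
    """
    n, L, _ = g.alleles.shape
    if n < 2:
        raise ValueError("need >= 2 individuals")
    if L < 1:
        raise ValueError("need >= 1 locus")
    D = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for li in range(L):
        a = g.alleles[:, li, :]
        scored = (a != 0).all(axis=1)
        sizes = np.unique(a[scored])
        if sizes.size == 0:
            continue
        counts = np.zeros((n, sizes.size))
        for k, s in enumerate(sizes):
            counts[:, k] = (a == s).sum(axis=1)
        sq = ((counts[:, None, :] - counts[None, :, :]) ** 2).sum(-1) / 2.0
        both = np.outer(scored, scored)
        D += np.where(both, sq, 0.0)
        shared += both.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(shared > 0, D * (L / np.maximum(shared, 1)), np.nan)
    np.fill_diagonal(out, 0.0)
    if np.isnan(out).any():
        warnings.warn(
            "some pairs share no scored locus; their distances are missing",
            stacklevel=2,
        )
    return GeneticDistanceMatrix(out, shared)


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centred covariance matrix of a squared-distance matrix."""
    d = np.asarray(D, dtype=float)
    rm = d.mean(axis=1, keepdims=True)
    cm = d.mean(axis=0, keepdims=True)
    return -0.5 * (d - rm - cm + d.mean())


def geographic_distances(coords: np.ndarray) -> np.ndarray:
    xy = np.asarray(coords, dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


# --------------------------------------------------------------------------
# autocorrelation r by distance class
# --------------------------------------------------------------------------

def _pair_indices(geo: np.ndarray, lower: float, upper: float,
                  include_lower: bool) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(geo.shape[0], k=1)
    d = geo[iu, ju]
    mask = (d >= lower if include_lower else d > lower) & (d <= upper)
    return iu[mask], ju[mask]


def _r_from_pairs(C: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    num = C[ii, jj].sum()
    diag = np.diag(C)
    den = 0.5 * (diag[ii] + diag[jj]).sum()
    if den == 0:
        return np.nan
    return float(num / den)


def autocorr_r_by_class(
    D: GeneticDistanceMatrix | np.ndarray,
    geo: np.ndarray,
    class_bounds,
) -> list[DistanceClassResult]:
    """Autocorrelation r per distance class (no resampling attached).

    ``class_bounds`` is an increasing sequence of upper bounds; class h
    covers (bounds[h-1], bounds[h]] with the first class closed at 0.
    Empty classes and degenerate (all-identical genotypes) classes yield
    nan r with a flag.
    """
    Dv = D.values if isinstance(D, GeneticDistanceMatrix) else np.asarray(D)
    C = gower_center(np.nan_to_num(Dv))
    bounds = list(class_bounds)
    if bounds != sorted(bounds):
        raise ValueError("class bounds must be increasing")
    out = []
    lower = 0.0
    for h, upper in enumerate(bounds):
        ii, jj = _pair_indices(geo, lower, upper, include_lower=(h == 0))
        r = _r_from_pairs(C, ii, jj) if ii.size else np.nan
        flags = []
        if ii.size == 0:
            flags.append("empty class")
        elif np.isnan(r):
            flags.append("degenerate: zero denominator")
        out.append(DistanceClassResult(
            f"{lower:g}-{upper:g}", lower, upper, int(ii.size), r,
            np.nan, np.nan, np.nan, np.nan, False, flags,
        ))
        lower = upper
    return out


def bootstrap_ci_r(
    C: np.ndarray, ii: np.ndarray, jj: np.ndarray,
    n_boot: int = 1000, seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI for r, resampling pairs within the class."""
    if ii.size < 1:
        raise ValueError("class has no pairs")
    rng = np.random.default_rng(seed)
    diag = np.diag(C)
    num = C[ii, jj]
    den = 0.5 * (diag[ii] + diag[jj])
    if ii.size == 1:
        r = float(num.sum() / den.sum())
        return (r, r)
    idx = rng.integers(0, ii.size, size=(n_boot, ii.size))
    rs = num[idx].sum(axis=1) / den[idx].sum(axis=1)
    return (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5)))


def permutation_envelope_r(
    C: np.ndarray, ii: np.ndarray, jj: np.ndarray,
    n_perm: int = 1000, seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """95% envelope of r under random permutation of genotypes over positions."""
    if ii.size < 1:
        raise ValueError("class has no pairs")
    rng = np.random.default_rng(seed)
    n = C.shape[0]
    diag = np.diag(C)
    rp = np.empty(n_perm)
    for s in range(n_perm):
        p = rng.permutation(n)
        num = C[p[ii], p[jj]].sum()
        den = 0.5 * (diag[p[ii]] + diag[p[jj]]).sum()
        rp[s] = num / den if den else np.nan
    # exact Monte Carlo envelope: order statistics at ranks floor/ceil of
    # q*(n+1), so that under exchangeability P(outside) <= 5%
    srt = np.sort(rp[np.isfinite(rp)])
    m = srt.size
    lo_k = max(int(np.floor(0.025 * (m + 1))) - 1, 0)
    hi_k = min(int(np.ceil(0.975 * (m + 1))) - 1, m - 1)
    return float(srt[lo_k]), float(srt[hi_k]), rp


def _attach_resampling(C, geo, results, n_boot, n_perm, seed, cumulative):
    rng = np.random.default_rng(seed)
    for res in results:
        if res.n_pairs == 0 or np.isnan(res.r):
            continue
        lower = 0.0 if cumulative else res.lower_m
        include0 = not cumulative and res.lower_m == 0.0
        ii, jj = _pair_indices(geo, lower, res.upper_m, include_lower=include0)
        b_seed = int(rng.integers(2 ** 31))
        p_seed = int(rng.integers(2 ** 31))
        res.ci_lower, res.ci_upper = bootstrap_ci_r(C, ii, jj, n_boot, b_seed)
        res.perm_lower, res.perm_upper, _ = permutation_envelope_r(
            C, ii, jj, n_perm, p_seed
        )
        ci_excludes0 = res.ci_lower > 0 or res.ci_upper < 0
        outside = res.r > res.perm_upper or res.r < res.perm_lower
        res.significant = bool(ci_excludes0 and outside)
        if res.n_pairs == 1:
            res.flags.append("single pair: degenerate CI")
    return results


def correlogram(
    D: GeneticDistanceMatrix | np.ndarray,
    geo: np.ndarray,
    class_bounds,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[DistanceClassResult]:
    """Traditional correlogram: disjoint distance classes with the dual rule.

    A class is significant when the bootstrap 95% CI of r excludes 0 AND r
    lies outside the 95% permutation envelope.
    """
    Dv = D.values if isinstance(D, GeneticDistanceMatrix) else np.asarray(D)
    C = gower_center(np.nan_to_num(Dv))
    results = autocorr_r_by_class(Dv, geo, class_bounds)
    return _attach_resampling(C, geo, results, n_boot, n_perm, seed,
                              cumulative=False)


def multi_dclass(
    D: GeneticDistanceMatrix | np.ndarray,
    geo: np.ndarray,
    upper_bounds,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[DistanceClassResult]:
    """Increasing distance classes: r over all pairs with 0 < d <= bound."""
    bounds = list(upper_bounds)
    if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
        raise ValueError("upper bounds must be strictly increasing")
    Dv = D.values if isinstance(D, GeneticDistanceMatrix) else np.asarray(D)
    C = gower_center(np.nan_to_num(Dv))
    results = []
    for u in bounds:
        ii, jj = _pair_indices(geo, 0.0, u, include_lower=False)
        r = _r_from_pairs(C, ii, jj) if ii.size else np.nan
        flags = [] if ii.size else ["empty class"]
        results.append(DistanceClassResult(
            f"0-{u:g}", 0.0, u, int(ii.size), r,
            np.nan, np.nan, np.nan, np.nan, False, flags,
        ))
    return _attach_resampling(C, geo, results, n_boot, n_perm, seed,
                              cumulative=True)


# --------------------------------------------------------------------------
# correlogram heterogeneity (t2 per class, omega overall)
# --------------------------------------------------------------------------

def _group_correlogram_r(D_pool, geo_pool, idx, class_bounds):
    """Per-class r of the subset ``idx`` of a pooled dataset."""
    sub = D_pool[np.ix_(idx, idx)]
    C = gower_center(np.nan_to_num(sub))
    g = geo_pool[np.ix_(idx, idx)]
    rs = []
    lower = 0.0
    for h, upper in enumerate(class_bounds):
        ii, jj = _pair_indices(g, lower, upper, include_lower=(h == 0))
        rs.append(_r_from_pairs(C, ii, jj) if ii.size else np.nan)
        lower = upper
    return np.array(rs)


def heterogeneity_tests(
    gA: GenotypeMatrix,
    gB: GenotypeMatrix,
    class_bounds,
    n_perm: int = 1000,
    seed: int = 0,
) -> HeterogeneityResult:
    """t2 per distance class and correlogram-wide omega between two groups.

    Individuals (genotype + location) are permuted between the groups; the
    per-class statistic is the squared difference of the two r values
    standardized by its permutation variance, omega is the sum over classes,
    and p-values come from the permutation distributions (+1 correction).
    Classes empty in either observed group are skipped.
    """
    if list(gA.loci) != list(gB.loci):
        raise ValueError("groups must share the same locus panel")
    nA, nB = len(gA), len(gB)
    pooled = GenotypeMatrix(
        np.concatenate([gA.ids, gB.ids]),
        np.concatenate([gA.sex, gB.sex]),
        np.vstack([gA.coords, gB.coords]),
        list(gA.loci),
        np.vstack([gA.alleles, gB.alleles]),
    )
    D = squared_genetic_distance(pooled).values
    geo = geographic_distances(pooled.coords)
    bounds = list(class_bounds)

    idxA = np.arange(nA)
    idxB = np.arange(nA, nA + nB)
    rA = _group_correlogram_r(D, geo, idxA, bounds)
    rB = _group_correlogram_r(D, geo, idxB, bounds)
    usable = np.isfinite(rA) & np.isfinite(rB)
    skipped = [f"{(0 if h == 0 else bounds[h-1]):g}-{bounds[h]:g}"
               for h in range(len(bounds)) if not usable[h]]
    obs_diff = rA - rB

    rng = np.random.default_rng(seed)
    diffs = np.full((n_perm, len(bounds)), np.nan)
    all_idx = np.arange(nA + nB)
    for s in range(n_perm):
        perm = rng.permutation(all_idx)
        pa, pb = perm[:nA], perm[nA:]
        diffs[s] = (_group_correlogram_r(D, geo, pa, bounds)
                    - _group_correlogram_r(D, geo, pb, bounds))

    finite = np.isfinite(diffs).sum(axis=0)
    var = np.full(len(bounds), np.nan)
    enough = finite >= 2
    if enough.any():
        var[enough] = np.nanvar(diffs[:, enough], axis=0)
    var = np.where(var > 0, var, np.nan)
    t2_obs = np.where(usable, obs_diff ** 2 / var, np.nan)
    t2_perm = diffs ** 2 / var

    t2_p = np.full(len(bounds), np.nan)
    for h in range(len(bounds)):
        if not np.isfinite(t2_obs[h]):
            continue
        ge = np.nansum(t2_perm[:, h] >= t2_obs[h] - 1e-12)
        t2_p[h] = (1 + ge) / (n_perm + 1)
    omega = float(np.nansum(np.where(usable, t2_obs, 0.0)))
    omega_perm = np.nansum(np.where(usable[None, :], t2_perm, 0.0), axis=1)
    omega_p = float((1 + (omega_perm >= omega - 1e-12).sum()) / (n_perm + 1))

    labels = [f"{(0 if h == 0 else bounds[h-1]):g}-{bounds[h]:g}"
              for h in range(len(bounds))]
    return HeterogeneityResult(labels, t2_obs, t2_p, omega, omega_p,
                               n_perm, skipped)


# --------------------------------------------------------------------------
# two-dimensional local autocorrelation (lr)
# --------------------------------------------------------------------------

def local_autocorr_2d(
    g: GenotypeMatrix,
    n_neighbors: int = 14,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Local autocorrelation lr of each individual with its nearest neighbours.

    lr is the class-r restricted to the pairs (i, each of i's ``n_neighbors``
    nearest neighbours); coordinate ties beyond the last rank are broken by
    individual id for determinism.  One-tailed p-values come from permuting
    whole genotypes across positions (+1 correction).
    """
    n = len(g)
    if n <= n_neighbors:
        raise ValueError("need more individuals than n_neighbors")
    D = squared_genetic_distance(g)
    C = gower_center(np.nan_to_num(D.values))
    geo = geographic_distances(g.coords)
    id_rank = np.argsort(np.argsort(g.ids, kind="stable"), kind="stable")

    nbrs = np.empty((n, n_neighbors), dtype=int)
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (geo[i, j], id_rank[j]),
        )
        nbrs[i] = order[:n_neighbors]

    diag = np.diag(C)

    def lr_all(perm: np.ndarray) -> np.ndarray:
        pi = perm[:, None]
        pj = perm[nbrs]
        num = C[np.broadcast_to(pi, pj.shape), pj].sum(axis=1)
        den = 0.5 * (diag[pi] + diag[pj]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den != 0, num / den, np.nan)

    identity = np.arange(n)
    lr_obs = lr_all(identity)
    rng = np.random.default_rng(seed)
    ge = np.zeros(n)
    for s in range(n_perm):
        lr_p = lr_all(rng.permutation(n))
        ge += lr_p >= lr_obs - 1e-12
    pvals = (1 + ge) / (n_perm + 1)
    return pd.DataFrame({
        "individual_id": g.ids,
        "lr": lr_obs,
        "p_value": pvals,
        "neighbors": [",".join(map(str, g.ids[nbrs[i]])) for i in range(n)],
    })


# --------------------------------------------------------------------------
# Mantel test
# --------------------------------------------------------------------------

def mantel_test(
    M1: np.ndarray, M2: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> MantelResult:
    """Mantel matrix correspondence with a one-tailed permutation p-value.

    r_xy is the Pearson correlation over the upper off-diagonal entries;
    rows and columns of the second matrix are permuted jointly and the
    p-value is the proportion of permutations with a statistic >= observed
    (+1 correction).
    """
    A = np.asarray(M1, dtype=float)
    B = np.asarray(M2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and conformable")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("matrices must be symmetric")
    if np.abs(np.diag(A)).max() > 1e-9 or np.abs(np.diag(B)).max() > 1e-9:
        raise ValueError("matrices must have zero diagonals")
    iu, ju = np.triu_indices(A.shape[0], k=1)
    a = A[iu, ju]
    if a.std() == 0 or B[iu, ju].std() == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")

    a = (a - a.mean()) / a.std()

    def corr(mat: np.ndarray) -> float:
        b = mat[iu, ju]
        return float((a * (b - b.mean())).mean() / b.std())

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    ge = 0
    for s in range(n_perm):
        p = rng.permutation(A.shape[0])
        ge += corr(B[np.ix_(p, p)]) >= r_obs - 1e-12
    return MantelResult(r_obs, (1 + ge) / (n_perm + 1), n_perm)
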