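"""Copy-state genotyping, mutation clustering and clone fractions.

The locus model
---------------
A biopsy with tumor purity rho contains cancer cells and diploid normal
cells.  A somatic mutation carried by a fraction ``f`` of the cancer cells
sits in one of four allele configurations in its carriers:

====== ================ =========================
state  mutant copies m  total copies n at locus
====== ================ =========================
AB     1                2   (heterozygous diploid)
B      1                1   (LOH: wild-type allele lost)
BB     2                2   (copy-neutral: wild-type lost, mutant gained)
ABB    2                3   (mutant gained, wild-type retained)
====== ================ =========================

Non-carrier cancer cells are assumed diploid at the locus (copy events ride
with the mutant lineage).  The expected B-allele frequency and the expected
depth log-ratio are then

    BAF(state, rho, f)  = rho*f*m / ( rho*(f*n + (1-f)*2) + 2*(1-rho) )
    LogR(state, rho, f) = log2( ( rho*(f*n + (1-f)*2) + 2*(1-rho) ) / 2 )

Each observed mutation is assigned the state (and candidate cancer-cell
fraction) whose expected (BAF, LogR) point is nearest, with per-axis
tolerances; the fraction f < 1 marks the event subclonal.

Clustering
----------
Mutations in the AB state carry the cleanest clone signal: their expected
BAF in biopsy b is rho_b * phi_kb / 2 for a clone with carrying fraction
phi_kb.  We fit a finite binomial mixture over biopsies — cluster k gives
alt_ib ~ Binomial(depth_ib, theta_kb) — by EM for K = 1..K_max, pick K by
BIC, and hard-assign each mutation to its maximum-responsibility cluster.
Initialization is deterministic (k-means on BAF vectors with a fixed seed).

Per-biopsy clone fractions come from the BAF ratio

    phi_kb = mean AB-BAF of cluster k in b / mean AB-BAF of the clonal
             cluster in b

clipped to [0, 1]; the clonal cluster is the one whose mean BAF is maximal
in every biopsy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CopyState",
    "STATES",
    "CloneCluster",
    "PurityEstimate",
    "ClusterFit",
    "expected_baf",
    "expected_logr",
    "estimate_purity",
    "assign_state",
    "cluster_mutations",
    "clone_fractions",
    "identify_clonal_cluster",
]


@dataclass(frozen=True)
class CopyState:
    label: str
    m: int  # mutant copies in carrier cells
    n: int  # total copies at the locus in carrier cells

    def __post_init__(self):
        if not 0 < self.m <= self.n:
            raise ValueError(f"need 0 < m <= n, got m={self.m}, n={self.n}")


STATES: dict[str, CopyState] = {
    "AB": CopyState("AB", 1, 2),
    "B": CopyState("B", 1, 1),
    "BB": CopyState("BB", 2, 2),
    "ABB": CopyState("ABB", 2, 3),
}

# number of copy-number changes away from the heterozygous diploid state;
# used to break distance ties toward the simpler explanation
_STATE_COMPLEXITY = {"AB": 0, "B": 1, "ABB": 1, "BB": 2}


def expected_baf(state: CopyState | str, rho: float, f: float) -> float:
    """Expected B-allele frequency of a mutation in ``state`` carried by a
    fraction ``f`` of cancer cells at purity ``rho``."""
    st = STATES[state] if isinstance(state, str) else state
    if not 0 < rho <= 1:
        raise ValueError(f"purity must be in (0, 1], got {rho}")
    if not 0 <= f <= 1:
        raise ValueError(f"cancer-cell fraction must be in [0, 1], got {f}")
    denom = rho * (f * st.n + (1 - f) * 2) + 2 * (1 - rho)
    return (rho * f * st.m) / denom


def expected_logr(state: CopyState | str, rho: float, f: float) -> float:
    """Expected depth log-ratio at the mutant locus for ``state``."""
    st = STATES[state] if isinstance(state, str) else state
    mean_cn = rho * (f * st.n + (1 - f) * 2) + 2 * (1 - rho)
    return math.log2(mean_cn / 2)


@dataclass
class PurityEstimate:
    sample_id: str
    rho: float
    source: str  # "max_clonal_baf" | "provided"

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValueError("purity must be in (0, 1]")


def estimate_purity(
    clonal_ab_bafs, sample_id: str = "", min_mutations: int = 5
) -> PurityEstimate:
    """Estimate purity as twice the mode of the clonal AB BAF distribution
    (an AB mutation in all cancer cells has BAF rho/2), capped at 1.

    The mode is located with a Gaussian KDE over [0, 0.5]; this is a
    pragmatic stand-in estimator and is labelled as such in its ``source``.
    """
    bafs = np.asarray(clonal_ab_bafs, dtype=float)
    bafs = bafs[np.isfinite(bafs)]
    if bafs.size < min_mutations:
        raise ValueError(
            f"need >= {min_mutations} clonal AB mutations to estimate purity "
            f"(got {bafs.size}); pass a provided purity instead"
        )
    if np.ptp(bafs) < 1e-9:
        mode = float(bafs[0])
    else:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(bafs)
        # grid extends past 0.5 so noise around a fully pure clonal peak
        # does not bias the mode at the boundary; the cap handles the rest
        grid = np.linspace(0.0, 0.75, 751)
        mode = float(grid[np.argmax(kde(grid))])
    rho = min(2.0 * mode, 1.0)
    if rho <= 0:
        raise ValueError("clonal BAF mode at 0; cannot estimate purity")
    return PurityEstimate(sample_id=sample_id, rho=rho, source="max_clonal_baf")


def assign_state(
    baf: float,
    logr: float,
    rho: float,
    candidate_fractions=(1.0,),
    tau_baf: float = 0.08,
    tau_logr: float = 0.4,
    clonal_margin: float = 0.05,
) -> tuple[str, float, bool]:
    """Assign the copy state whose expected (BAF, LogR) point is nearest.

    Candidates are the four states crossed with ``candidate_fractions``
    (typically the fitted cluster fractions plus 1.0).  Distance is squared
    error with each axis scaled by its tolerance; a candidate is admissible
    only when both |dBAF| <= tau_baf and |dLogR| <= tau_logr.  Ties go to
    the state with fewer copy-number changes from AB, then alphabetically,
    then to the larger fraction.  Returns ``(label, f, subclonal)`` with
    label ``"unassigned"`` (f=nan) when nothing is admissible; fractions
    within ``clonal_margin`` of 1 count as clonal (fitted clone fractions
    carry sampling noise).
    """
    fracs = sorted({float(f) for f in candidate_fractions if f > 0}, reverse=True)
    best = None
    for label, st in STATES.items():
        for f in fracs:
            eb = expected_baf(st, rho, f)
            el = expected_logr(st, rho, f)
            db, dl = abs(baf - eb), abs(logr - el)
            if db > tau_baf or dl > tau_logr:
                continue
            d2 = (db / tau_baf) ** 2 + (dl / tau_logr) ** 2
            key = (d2, _STATE_COMPLEXITY[label], label, -f)
            if best is None or key < best[0]:
                best = (key, label, f)
    if best is None:
        return ("unassigned", math.nan, False)
    _, label, f = best
    return (label, f, bool(f < 1.0 - clonal_margin))


# ---------------------------------------------------------------------------
# binomial mixture clustering
# ---------------------------------------------------------------------------

_THETA_FLOOR = 1e-6


@dataclass
class ClusterFit:
    """Result of the binomial-mixture fit at the BIC-selected K."""

    k: int
    labels: np.ndarray  # (n_mutations,) hard assignments 0..k-1
    theta: np.ndarray  # (k, n_biopsies) per-cluster success probabilities
    weights: np.ndarray  # (k,) mixing proportions
    loglik: float
    bic: float
    bic_by_k: dict[int, float]
    converged: bool
    mean_baf: np.ndarray = None  # (k, n_biopsies) pooled alt/depth per cluster


@dataclass
class CloneCluster:
    cluster_id: str
    members: list[int]  # mutation indices
    mean_baf: np.ndarray  # per-biopsy pooled AB BAF
    phi: np.ndarray | None = None  # per-biopsy clone fraction
    flags: set[str] = field(default_factory=set)


def _em_binomial(alt, depth, k, seed, max_iter=500, tol=1e-8):
    n, b = alt.shape
    rng = np.random.default_rng(seed)
    baf = np.divide(alt, depth, out=np.zeros_like(alt, dtype=float), where=depth > 0)
    if k == 1:
        theta = baf.mean(axis=0, keepdims=True)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=min(k, n), n_init=10, random_state=seed)
        lab = km.fit_predict(baf)
        theta = np.zeros((k, b))
        for j in range(k):
            mask = lab == (j % min(k, n))
            if mask.any():
                a, d = alt[mask].sum(axis=0), depth[mask].sum(axis=0)
                theta[j] = np.divide(a, d, out=np.full(b, 0.5), where=d > 0)
            else:
                theta[j] = rng.uniform(0.01, 0.5, size=b)
    theta = np.clip(theta, _THETA_FLOOR, 1 - _THETA_FLOOR)
    pi = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step: log p(mutation i | cluster j), binomial coefficient dropped
        logp = alt @ np.log(theta).T + (depth - alt) @ np.log1p(-theta).T
        logp = logp + np.log(pi)[None, :]
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        # M step
        rk = resp.sum(axis=0)
        pi = np.maximum(rk / n, 1e-12)
        pi = pi / pi.sum()
        num = resp.T @ alt
        den = resp.T @ depth
        theta = np.where(den > 0, num / np.maximum(den, 1e-12), theta)
        theta = np.clip(theta, _THETA_FLOOR, 1 - _THETA_FLOOR)
        if abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    logp = alt @ np.log(theta).T + (depth - alt) @ np.log1p(-theta).T + np.log(pi)[None, :]
    norm = logsumexp(logp, axis=1)
    ll = float(norm.sum())
    labels = np.argmax(logp, axis=1)
    return theta, pi, labels, ll, converged


def cluster_mutations(
    alt: np.ndarray,
    depth: np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    max_iter: int = 500,
) -> ClusterFit:
    """Cluster mutations by their per-biopsy read-count profiles with a
    finite binomial mixture, choosing K in 1..k_max by BIC.

    ``alt`` and ``depth`` are (n_mutations, n_biopsies) integer arrays of
    AB-state mutations.  Initialization is deterministic for a fixed seed;
    non-convergence at max_iter keeps the best iterate and warns.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 2:
        raise ValueError("alt and depth must be matching 2-D arrays")
    n, b = alt.shape
    if n == 0:
        raise ValueError("no mutations to cluster")
    if np.any(alt > depth):
        raise ValueError("alt reads exceed depth")
    best: ClusterFit | None = None
    bic_by_k: dict[int, float] = {}
    any_nonconv = False
    for k in range(1, min(k_max, n) + 1):
        theta, pi, labels, ll, converged = _em_binomial(alt, depth, k, seed, max_iter)
        any_nonconv |= not converged
        n_params = k * b + (k - 1)
        bic = -2.0 * ll + n_params * math.log(n)
        bic_by_k[k] = bic
        if best is None or bic < best.bic - 1e-9:
            best = ClusterFit(
                k=k, labels=labels, theta=theta, weights=pi, loglik=ll, bic=bic,
                bic_by_k={}, converged=converged,
            )
    assert best is not None
    if any_nonconv:
        warnings.warn("EM did not fully converge for at least one K; best iterate kept")
    best.bic_by_k = bic_by_k
    # pooled per-cluster mean BAF (depth-weighted; this is what fractions use)
    mean_baf = np.zeros((best.k, b))
    for j in range(best.k):
        mask = best.labels == j
        if mask.any():
            a, d = alt[mask].sum(axis=0), depth[mask].sum(axis=0)
            mean_baf[j] = np.divide(a, d, out=np.zeros(b), where=d > 0)
        else:
            mean_baf[j] = best.theta[j]
    best.mean_baf = mean_baf
    return best


def identify_clonal_cluster(
    mean_baf: np.ndarray, rtol: float = 0.02, atol: float = 0.02
) -> tuple[int, bool]:
    """Pick the clonal cluster: the one attaining the maximum mean BAF in
    every biopsy (within a tolerance absorbing binomial sampling noise on
    the per-cluster means).

    Returns (index, unambiguous).  When no single cluster dominates every
    biopsy, fall back to the cluster with the largest BAF sum and flag it.
    """
    mean_baf = np.asarray(mean_baf, dtype=float)
    col_max = mean_baf.max(axis=0)
    tol = np.maximum(col_max * rtol, atol)
    dominates = np.all(mean_baf >= col_max - tol, axis=1)
    idx = np.where(dominates)[0]
    if idx.size >= 1:
        # among dominating clusters prefer the largest overall signal
        j = int(idx[np.argmax(mean_baf[idx].sum(axis=1))])
        return j, idx.size == 1
    return int(np.argmax(mean_baf.sum(axis=1))), False


def clone_fractions(mean_baf: np.ndarray, clonal_index: int) -> np.ndarray:
    """Per-biopsy clone fractions as the ratio of each cluster's mean AB BAF
    to the clonal cluster's mean AB BAF, clipped to [0, 1].

    Biopsies where the clonal cluster has BAF 0 yield NaN (undefined) for
    every cluster; a cluster absent from a biopsy (BAF 0) gets fraction 0.
    """
    mean_baf = np.asarray(mean_baf, dtype=float)
    clonal = mean_baf[clonal_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(clonal > 0, mean_baf / clonal, np.nan)
    return np.clip(phi, 0.0, 1.0)
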