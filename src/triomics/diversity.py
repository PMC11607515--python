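"""Alpha diversity, Bray-Curtis distances, ordination and perMANOVA.

PCoA follows the classical Gower construction: double-center the matrix
of squared distances and eigendecompose.  Bray-Curtis is non-Euclidean,
so negative eigenvalues can appear; they are truncated (dropped from the
proportion-explained denominator and reported separately) rather than
Lingoes/Cailliez-corrected.

perMANOVA uses the pseudo-F of Anderson (among/within sums of squared
distances) with the "+1 in numerator and denominator" permutation
p-value convention, so p is never exactly zero.  dbRDA constrains the
non-negative PCoA axes on group indicator variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .stats import TestResult
from .tables import AbundanceTable, DegenerateSampleError


def shannon_index(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson_index(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2, in [0, 1)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero count vector")
    p = c / total
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Shannon and Simpson per sample."""
    rows = {
        s: (shannon_index(table.data[s]), simpson_index(table.data[s]))
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["shannon", "simpson"])


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample ids do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs."""
    x = table.values.T  # samples x features
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise DegenerateSampleError(
            f"Bray-Curtis undefined between all-zero samples: {bad}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    constrained: bool = False
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    constrained_proportion: float | None = None

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"Axis{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinates of a distance matrix (Gower centering)."""
    if dist.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    g = _gower_center(dist.values)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = eps * max(1.0, abs(evals[0]))
    pos = evals > tol
    neg = evals[evals < -tol]
    lam = evals[pos]
    scores = evecs[:, pos] * np.sqrt(lam)
    prop = lam / lam.sum() if lam.sum() > 0 else lam
    return OrdinationResult(
        dist.sample_ids, scores, lam, prop, negative_eigenvalues=neg
    )


def _ssw_batch(d2: np.ndarray, label_batch: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a batch of labelings.

    ``label_batch`` is (B, n); returns (B,).  Uses the identity
    SSW = sum_g z_g' D2 z_g / (2 n_g) with 0/1 indicators z_g.
    """
    ssw = np.zeros(label_batch.shape[0])
    for g in uniq:
        z = (label_batch == g).T.astype(float)  # n x B
        ng = z[:, 0].sum()
        ssw += (z * (d2 @ z)).sum(axis=0) / (2.0 * ng)
    return ssw


def permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances and group labels."""
    n = d2.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    sst = d2.sum() / (2.0 * n)
    ssw = _ssw_batch(d2, labels[None, :], uniq)[0]
    return float(((sst - ssw) / (k - 1)) / (ssw / (n - k)))


def permanova(
    dist: DistanceMatrix, groups, n_perm: int = 9999, seed: int = 0
) -> TestResult:
    """Permutational MANOVA on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm); the permutation stream
    is fully determined by ``seed``.
    """
    labels = np.asarray(list(groups))
    if len(labels) != dist.n:
        raise ValueError("labels must match distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("perMANOVA needs >= 2 groups with >= 2 samples each")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n, k = dist.n, len(uniq)
    d2 = dist.values**2
    sst = d2.sum() / (2.0 * n)
    f_obs = permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm_idx = np.argsort(rng.random((b, n)), axis=1)
        ssw = _ssw_batch(d2, labels[perm_idx], uniq)
        f_perm = ((sst - ssw) / (k - 1)) / (ssw / (n - k))
        hits += int((f_perm >= f_obs - 1e-12).sum())
        done += b
    p = (1 + hits) / (1 + n_perm)
    return TestResult(f_obs, p, 0, "permanova")


def dbrda(dist: DistanceMatrix, groups) -> OrdinationResult:
    """Distance-based redundancy analysis constrained on group labels.

    The positive-eigenvalue PCoA embedding is regressed on centered
    group indicator variables; constrained axes come from the
    eigendecomposition of the fitted values' covariance.
    """
    labels = np.asarray(list(groups))
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("dbRDA needs >= 2 groups to constrain on")
    emb = pcoa(dist)
    y = emb.scores  # n x a, columns centered by construction
    total_inertia = emb.eigenvalues.sum()
    # centered dummy design, full rank k-1
    x = np.stack([(labels == g).astype(float) for g in uniq[:-1]], axis=1)
    x = x - x.mean(axis=0)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    # eigen-decompose fitted cross-product: constrained axes
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    lam = s**2
    keep = lam > 1e-10 * max(1.0, lam.max(initial=0.0))
    lam = lam[keep]
    scores = (u[:, keep] * s[keep])
    constrained_inertia = lam.sum()
    prop = lam / total_inertia if total_inertia > 0 else lam
    return OrdinationResult(
        dist.sample_ids,
        scores,
        lam,
        prop,
        constrained=True,
        negative_eigenvalues=emb.negative_eigenvalues,
        constrained_proportion=float(constrained_inertia / total_inertia),
    )


def pca_log_relative(table: AbundanceTable, pseudocount: float | None = None) -> OrdinationResult:
    """PCA convention for compositional profiles: PCoA on Euclidean
    distances of log-transformed relative abundances."""
    rel = table.data.div(table.data.sum(axis=0), axis=1)
    vals = rel.to_numpy()
    if pseudocount is None:
        nz = vals[vals > 0]
        pseudocount = nz.min() / 2.0 if len(nz) else 1e-9
    logged = np.log(vals + pseudocount).T  # samples x features
    d = squareform(pdist(logged, metric="euclidean"))
    return pcoa(DistanceMatrix(table.sample_ids, d))
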