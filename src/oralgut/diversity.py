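"""Alpha diversity, zero-adjusted Bray-Curtis resemblance, ANOSIM, and ordination.

The beta-diversity chain mirrors the PRIMER workflow common in microbial
ecology: per-sample percentages, square-root transform, Bray-Curtis
*similarities* on a 0-100 scale with a constant dummy feature appended to
every sample (the "zero-adjusted" variant, which keeps pairs of near-empty
samples well-defined and mutually similar), ANOSIM with 4,999 label
permutations, and PCO/NMDS ordinations of the resemblance matrix.

ANOSIM and PCO are implemented here directly because the analysis contracts
pin down details (mid-ranked ties, the +1 permutation p-value convention,
exact enumeration for small designs, negative PCO eigenvalues reported rather
than corrected); independent implementations serve as cross-checks in the
test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, pearsonr

from .feature_table import FeatureTable, StateError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(sample_abundances: Sequence[float], base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive proportions.

    Natural log by default (matching index magnitudes of ~4.4-4.8 for
    communities of several hundred ASVs); pass ``base=2`` for bits.
    """
    x = np.asarray(sample_abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample has undefined Shannon diversity")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base)


def shannon_table(table: FeatureTable, base: float = math.e) -> pd.Series:
    """Per-sample Shannon diversity for every non-empty sample column."""
    out = {}
    for j, sid in enumerate(table.sample_ids):
        col = table.values[:, j]
        if col.sum() > 0:
            out[sid] = shannon(col, base=base)
        else:
            logger.warning("sample %s is all-zero; Shannon undefined, omitted", sid)
    return pd.Series(out, name="shannon")


def diversity_correlation(paired_h: Sequence[tuple[float, float]]) -> float:
    """Squared Pearson correlation of paired per-individual (gut H, oral H) values."""
    arr = np.asarray(paired_h, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >=3 (gut, oral) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in one habitat; correlation undefined")
    r = pearsonr(arr[:, 0], arr[:, 1]).statistic
    return float(r * r)


# ---------------------------------------------------------------------------
# Resemblance
# ---------------------------------------------------------------------------

@dataclass
class ResemblanceMatrix:
    """Symmetric matrix of Bray-Curtis similarities on a 0-100 scale."""

    sample_ids: list[str]
    values: np.ndarray
    transform_chain: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("resemblance matrix shape does not match sample_ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("resemblance matrix must be symmetric")
        if np.any((v < -1e-9) | (v > 100 + 1e-9)):
            raise ValueError("similarities must lie in [0, 100]")
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dissimilarity(self) -> np.ndarray:
        """Dissimilarity on [0, 1]: d = (100 - s) / 100, zero diagonal."""
        d = (100.0 - self.values) / 100.0
        np.fill_diagonal(d, 0.0)
        return d

    def select(self, sample_ids: Sequence[str]) -> "ResemblanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ResemblanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)],
                                 dict(self.transform_chain))

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.index.name = "sample-id"
        df.to_csv(path, sep="\t")


def read_resemblance(path: str | Path) -> ResemblanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ResemblanceMatrix(list(df.columns), df.to_numpy())


def bray_curtis(table: FeatureTable, dummy_value: float = 1.0) -> ResemblanceMatrix:
    """Zero-adjusted Bray-Curtis similarity matrix (0-100).

    A constant pseudo-feature of abundance ``dummy_value`` is appended to every
    sample before computing 100 * (1 - sum|x-y| / sum(x+y)).  With the default
    dummy of 1 (on the sqrt-percent scale) two all-zero samples are 100%
    similar instead of undefined.
    """
    if table.state not in ("sqrt_percent", "percent"):
        raise StateError(
            f"bray_curtis expects a percent or sqrt_percent table, got {table.state!r}"
        )
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    if dummy_value < 0:
        raise ValueError("dummy_value must be >= 0")
    X = table.values.T  # samples x features
    if dummy_value > 0:
        X = np.hstack([X, np.full((X.shape[0], 1), float(dummy_value))])
    elif np.any(X.sum(axis=1) == 0):
        sid = table.sample_ids[int(np.argwhere(X.sum(axis=1) == 0)[0, 0])]
        raise ValueError(
            f"sample {sid!r} is all-zero; Bray-Curtis undefined with dummy_value=0"
        )
    sim = 100.0 * (1.0 - squareform(pdist(X, metric="braycurtis")))
    np.fill_diagonal(sim, 100.0)
    return ResemblanceMatrix(
        list(table.sample_ids), sim,
        transform_chain={"state": table.state, "dummy_value": float(dummy_value)},
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False

    def to_json(self, path: str | Path) -> None:
        import json
        Path(path).write_text(json.dumps({
            "R": self.R, "p_value": self.p_value,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "exact": self.exact,
        }, indent=2) + "\n")


def _anosim_r(ranks: np.ndarray, iu: tuple[np.ndarray, np.ndarray],
              labels: np.ndarray) -> float:
    """ANOSIM R from precomputed condensed dissimilarity ranks."""
    within = labels[iu[0]] == labels[iu[1]]
    m = ranks.size
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (m / 2.0))


def _n_distinct_label_permutations(labels: np.ndarray) -> int:
    n = len(labels)
    total = math.factorial(n)
    for _, cnt in zip(*np.unique(labels, return_counts=True)):
        total //= math.factorial(int(cnt))
    return total


def anosim(resemblance: ResemblanceMatrix, group_labels: Sequence[str],
           n_permutations: int = 4999, seed: int | None = None) -> AnosimResult:
    """Analysis of similarities: rank-based test of group separation.

    R = (mean between-group rank - mean within-group rank) / (M/2) where ranks
    are taken over the M = n(n-1)/2 pairwise dissimilarities, ties mid-ranked.
    Significance by permuting labels; p uses the +1 convention
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations), so p >= 1/(n_perm+1).
    When the number of distinct label rearrangements is <= ``n_permutations``
    the full enumeration is used instead of sampling (then p is the exact
    fraction of rearrangements, including the observed one, with R >= R_obs).
    """
    labels = np.asarray(group_labels)
    if len(labels) != resemblance.n_samples:
        raise ValueError("group_labels length does not match the resemblance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = uniq[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    d = resemblance.to_dissimilarity()
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # mid-ranks on dissimilarity
    r_obs = _anosim_r(ranks, iu, labels)

    n_total = _n_distinct_label_permutations(labels)
    if n_total <= n_permutations:
        count_ge = 0
        for perm in _multiset_permutations(labels):
            if _anosim_r(ranks, iu, np.asarray(perm)) >= r_obs - 1e-12:
                count_ge += 1
        p = count_ge / n_total
        return AnosimResult(R=r_obs, p_value=p, n_permutations=n_total,
                            seed=seed, exact=True)

    rng = np.random.default_rng(seed)
    count_ge = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _anosim_r(ranks, iu, perm) >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_permutations,
                        seed=seed, exact=False)


def _multiset_permutations(labels: np.ndarray):
    """All distinct orderings of a label multiset (lexicographic successor walk)."""
    a = sorted(labels.tolist())
    n = len(a)
    while True:
        yield tuple(a)
        i = n - 2
        while i >= 0 and a[i] >= a[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while a[j] <= a[i]:
            j -= 1
        a[i], a[j] = a[j], a[i]
        a[i + 1:] = reversed(a[i + 1:])


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    method: str  # "PCO" or "NMDS"
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray | None = None  # PCO
    stress: float | None = None  # NMDS
    n_negative_eigenvalues: int = 0
    converged: bool = True

    def write_tsv(self, path: str | Path) -> None:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)
        df.index.name = "sample-id"
        df.to_csv(path, sep="\t")


def pco(resemblance: ResemblanceMatrix, eig_tol: float = 1e-9,
        correction: str | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS) of a resemblance.

    Similarities are converted to dissimilarities d = (100 - s)/100, Gower
    double-centered (-d^2/2), and eigendecomposed.  Coordinates are the
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues, ordered
    by descending eigenvalue.  Negative eigenvalues (non-Euclidean input) are
    counted and reported; ``correction="lingoes"`` adds the constant that
    makes all eigenvalues non-negative instead.
    """
    d = resemblance.to_dissimilarity()
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    if correction == "lingoes":
        a = -0.5 * d ** 2
        b = _gower_center(a)
        lam = np.linalg.eigvalsh(b)
        c = max(0.0, -lam.min())
        if c > 0:
            d2 = d ** 2 + 2 * c
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(d2)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    b = _gower_center(-0.5 * d ** 2)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int(np.sum(eigvals < -eig_tol))
    pos = eigvals > eig_tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    return OrdinationResult(
        method="PCO", sample_ids=list(resemblance.sample_ids),
        coordinates=coords, eigenvalues=eigvals, n_negative_eigenvalues=n_neg,
    )


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def nmds(resemblance: ResemblanceMatrix, n_axes: int = 2, n_restarts: int = 20,
         seed: int | None = None, max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 (SMACOF with monotone regression).

    Restart 0 is initialized from the PCO configuration; the remaining
    restarts are random.  The lowest-stress solution is returned.
    """
    from sklearn.manifold import MDS

    n = resemblance.n_samples
    if n < n_axes + 1:
        raise ValueError(f"need at least {n_axes + 1} samples for {n_axes} axes")
    d = resemblance.to_dissimilarity()
    rng = np.random.default_rng(seed)

    pco_coords = pco(resemblance).coordinates
    if pco_coords.shape[1] < n_axes:  # degenerate input, pad with zeros
        pad = np.zeros((n, n_axes - pco_coords.shape[1]))
        pco_coords = np.hstack([pco_coords, pad])
    inits: list[np.ndarray] = [pco_coords[:, :n_axes]]
    inits += [rng.normal(size=(n, n_axes)) for _ in range(max(0, n_restarts - 1))]

    best_coords, best_stress = None, np.inf
    converged = True
    for init in inits:
        mds = MDS(n_components=n_axes, metric_mds=False, metric="precomputed",
                  n_init=1, init="random", max_iter=max_iter, normalized_stress=True,
                  random_state=int(rng.integers(2 ** 31)), eps=1e-9)
        coords = mds.fit(d, init=init).embedding_
        if mds.stress_ < best_stress:
            best_stress, best_coords = float(mds.stress_), coords
            converged = mds.n_iter_ < max_iter
    if not converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    return OrdinationResult(
        method="NMDS", sample_ids=list(resemblance.sample_ids),
        coordinates=best_coords, stress=best_stress, converged=converged,
    )
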