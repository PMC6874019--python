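"""Population-level summaries: PAV spectra, cohort clustering, and the
transformed-Watterson pan-genome size model.

The size model treats the amount of individual-specific sequence like
segregating sites under Watterson's estimator: if two individuals differ by
thetaL base pairs of private sequence, the expected total discovered across
an (effective) population of n genomes is

    K = thetaL * a,   a = 1 + 1/2 + ... + 1/n,

so the discovery curve after n genomes is thetaL * H_n and each added genome
contributes thetaL / n new sequence. The formula is implemented with the
harmonic sum taken to n itself; classic Watterson theory sums to n - 1 over
sampled chromosomes, and the convention is switchable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

DEFAULT_BINS = (0.0, 0.01, 0.1, 0.5, 0.9, 1.0)


def harmonic_a(n: int, convention: str = "n") -> float:
    """Partial harmonic sum 1 + 1/2 + ... + 1/m by direct summation.

    ``convention="n"`` sums to m = n (the printed form of the size formula);
    ``"n-1"`` sums to m = n - 1 (classic Watterson).
    """
    if int(n) != n or n < 1:
        raise ValueError("n must be an integer >= 1")
    m = int(n) if convention == "n" else int(n) - 1
    if convention not in ("n", "n-1"):
        raise ValueError(f"unknown harmonic convention: {convention!r}")
    if m < 1:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, m + 1)))


@dataclasses.dataclass
class SizeModel:
    """(thetaL, n, a, K) of the transformed Watterson size estimator."""

    thetaL: float  # pairwise individual-specific sequence amount, bp
    n: int  # effective population size
    a: float
    K: float  # estimated total pan-sequence size, bp
    convention: str = "n"


def pansize_K(thetaL: float, n: int, convention: str = "n") -> SizeModel:
    """Total pan-sequence size K = thetaL * a(n)."""
    if thetaL <= 0:
        raise ValueError("thetaL must be positive")
    a = harmonic_a(n, convention)
    return SizeModel(thetaL=thetaL, n=int(n), a=a, K=thetaL * a, convention=convention)


def discovery_curve(thetaL: float, n_max: int, convention: str = "n") -> pd.DataFrame:
    """Expected cumulative novel sequence after each added genome.

    Columns: n, increment (= thetaL / n), cumulative (= thetaL * H_n).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n = np.arange(1, n_max + 1)
    inc = thetaL / n if convention == "n" else np.concatenate(
        ([0.0], thetaL / n[:-1]))
    cum = np.cumsum(inc)
    return pd.DataFrame({"n": n, "increment": inc, "cumulative": cum})


def observed_discovery_curve(build_log: list[dict]) -> pd.DataFrame:
    """Cumulative recovered pan-sequence bases after each donor added."""
    return pd.DataFrame({
        "donor": [row["donor"] for row in build_log],
        "new_bases": [row["new_bases"] for row in build_log],
        "cumulative_bases": [row["cumulative_bases"] for row in build_log],
    })


def frequency_spectrum(pav: pd.DataFrame, bins=DEFAULT_BINS) -> pd.DataFrame:
    """Histogram of pan-sequence presence frequencies.

    Bins are left-open/right-closed, matching frequency-class reporting like
    (0.01, 0.1]; frequency-zero sequences land in the first bin.
    """
    if pav.empty:
        raise ValueError("empty PAV matrix")
    freqs = pav.mean(axis=0, skipna=True)
    edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(np.clip(freqs, edges[0] + 1e-12, None), bins=edges)
    labels = [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
    return pd.DataFrame({"bin": labels, "count": counts})


def _weighted_jaccard_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise 1 - sum(min)/sum(max); equals Jaccard on binaries."""
    n = matrix.shape[0]
    out = []
    for i in range(n):
        a = matrix[i]
        mn = np.minimum(a, matrix[i + 1:]).sum(axis=1)
        mx = np.maximum(a, matrix[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(mx > 0, 1.0 - mn / np.maximum(mx, 1e-300), 0.0)
        out.append(d)
    return np.concatenate(out) if out else np.empty(0)


def _matching_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise mean absolute difference (simple matching on
    binaries); presence and absence count symmetrically."""
    n = matrix.shape[0]
    out = []
    for i in range(n):
        out.append(np.abs(matrix[i] - matrix[i + 1:]).mean(axis=1))
    return np.concatenate(out) if out else np.empty(0)


def cluster_individuals(pav: pd.DataFrame, n_groups: int = 2,
                        method: str = "average",
                        metric: str = "matching") -> pd.Series:
    """Hierarchical clustering of individuals on their presence profiles,
    cut to ``n_groups``.

    The default distance is simple matching (mean absolute disagreement),
    which treats shared absence as informative — under Jaccard, individuals
    from a low-frequency population are mutually farther apart than they are
    from a high-frequency cluster (sparse random presence sets barely
    intersect), and average linkage then fails to separate the populations.
    ``metric="jaccard"`` restores the asymmetric behaviour for cohorts where
    absence carries no signal.

    NA (ambiguous) entries are imputed to the column presence frequency so
    they cannot drive distances. All-identical profiles collapse to a single
    group regardless of ``n_groups``.
    """
    if len(pav) < 2:
        raise ValueError("need at least two individuals to cluster")
    mat = pav.to_numpy(dtype=float)
    col_freq = np.nanmean(mat, axis=0)
    nan_r, nan_c = np.where(np.isnan(mat))
    mat[nan_r, nan_c] = col_freq[nan_c]
    mat = np.nan_to_num(mat)
    if metric == "matching":
        dist = _matching_distance(mat)
    elif metric == "jaccard":
        dist = _weighted_jaccard_distance(mat)
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    if np.allclose(dist, 0.0):
        return pd.Series(1, index=pav.index, name="group")
    Z = linkage(dist, method=method)
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=pav.index, name="group")
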