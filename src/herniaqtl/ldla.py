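"""Haplotype-cluster linkage-disequilibrium-and-linkage (LDLA) scan.

Phased chromosomes are clustered within marker windows by exact allele-string
identity, with rare clusters merged into their Hamming-nearest neighbour —
a deterministic, desk-scale stand-in for DAG-based localized haplotype
clustering, whose granularity knobs (window size, minimum cluster frequency)
play the role of that model's scale/shift parameters. Ancestrally shared
haplotypes carry both linkage and linkage-disequilibrium information, so
cluster membership is converted into diallelic pseudomarkers (0/1/2 dosages
that sum to 2 per individual per window) and tested window-by-window as fixed
effects in the mixed model

    Y = X b + Z u + e,  u ~ N(0, sigma_u^2 G),  e ~ N(0, sigma_e^2 I)

against the no-pseudomarker null. Variance components are estimated once on
the null and held fixed across windows, keeping likelihood-ratio statistics
comparable; LOD = LR / (2 ln 10). The QTL support interval is taken by the
LOD-drop rule (default drop of 2) extended contiguously from the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genio import PhasedGenotypes
from .lmm import KinshipMatrix, _design_matrix, build_grm, fit_null


@dataclass
class HaploWindow:
    """Cluster assignment of every chromosome in one marker window."""

    chrom: str
    start_idx: int
    end_idx: int  # inclusive
    start_bp: int
    end_bp: int
    labels: np.ndarray  # (n_samples, 2) cluster label per chromosome
    n_clusters: int
    cluster_strings: list  # representative allele string per label

    @property
    def mid_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


def cluster_haplotypes(
    genotypes: PhasedGenotypes,
    window_size_variants: int = 10,
    min_cluster_freq: float = 0.0,
) -> list:
    """Windowed exact-match clustering of phased chromosomes.

    Within each non-overlapping window, chromosomes with identical allele
    strings form a cluster. Clusters rarer than ``min_cluster_freq`` (as a
    fraction of chromosomes) are merged into the nearest retained cluster by
    Hamming distance on representative strings (ties -> lowest label).
    Labels are deterministic: descending frequency, ties broken
    lexicographically by allele string, and are invariant to individual order.
    """
    if not genotypes.phased:
        raise ValueError("haplotype clustering requires phased input")
    if window_size_variants < 2:
        raise ValueError("window_size_variants must be >= 2")
    windows = []
    h = genotypes.haplotypes
    n = genotypes.n_samples
    for chrom, sub in genotypes.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for lo in range(0, len(idx), window_size_variants):
            cols = idx[lo : lo + window_size_variants]
            strings = h[:, :, cols].reshape(2 * n, len(cols))
            keys = [tuple(row) for row in strings]
            counts: dict = {}
            for k in keys:
                counts[k] = counts.get(k, 0) + 1
            ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            label_of = {k: i for i, (k, _) in enumerate(ordered)}
            labels = np.array([label_of[k] for k in keys])

            min_count = min_cluster_freq * 2 * n
            keep = [i for i, (_, c) in enumerate(ordered) if c >= min_count]
            if keep and len(keep) < len(ordered):
                reps = np.array([ordered[i][0] for i in range(len(ordered))])
                for i, (_, c) in enumerate(ordered):
                    if c >= min_count:
                        continue
                    dists = np.array(
                        [(reps[i] != reps[j]).sum() for j in keep], dtype=float
                    )
                    target = keep[int(np.argmin(dists))]  # ties -> lowest label
                    labels[labels == i] = target
            elif not keep:
                # everything rare: a single merged cluster
                labels[:] = 0

            # canonical relabel by final descending frequency, string tiebreak
            uniq, cnt = np.unique(labels, return_counts=True)
            rep_str = {u: ordered[u][0] for u in uniq}
            order = sorted(uniq, key=lambda u: (-cnt[list(uniq).index(u)], rep_str[u]))
            remap = {u: i for i, u in enumerate(order)}
            labels = np.array([remap[u] for u in labels]).reshape(n, 2)
            windows.append(
                HaploWindow(
                    chrom=str(chrom),
                    start_idx=int(cols[0]),
                    end_idx=int(cols[-1]),
                    start_bp=int(genotypes.variants["pos"].iloc[cols[0]]),
                    end_bp=int(genotypes.variants["pos"].iloc[cols[-1]]),
                    labels=labels,
                    n_clusters=len(order),
                    cluster_strings=[rep_str[u] for u in order],
                )
            )
    return windows


def to_pseudomarkers(window: HaploWindow) -> np.ndarray:
    """Diallelic pseudomarker dosages (n_samples, n_clusters); each row sums
    to 2 — the two chromosomes partition over clusters."""
    n = window.labels.shape[0]
    dose = np.zeros((n, window.n_clusters), dtype=float)
    for c in range(2):
        np.add.at(dose, (np.arange(n), window.labels[:, c]), 1.0)
    return dose


@dataclass
class LodInterval:
    """LOD-drop support interval.

    ``start_bp``/``end_bp`` are the outer edges of the boundary windows (so
    the interval always covers the peak window in full); ``peak_mid_bp`` is
    the peak window's midpoint.
    """

    chrom: str
    peak_mid_bp: float
    peak_lod: float
    drop: float
    start_bp: float
    end_bp: float
    left_censored: bool
    right_censored: bool

    def contains(self, bp: float) -> bool:
        return self.start_bp <= bp <= self.end_bp


def two_lod_interval(lod_profile: pd.DataFrame, drop: float = 2.0) -> LodInterval:
    """Support interval by the LOD-drop rule.

    From the peak window, extend left and right through contiguous windows
    with LOD >= peak - drop; the first crossing below the threshold closes
    the interval (not a global threshold scan). Profiles rising into an edge
    are flagged censored on that side. Interval bounds are the outer edges of
    the boundary windows.
    """
    prof = lod_profile.dropna(subset=["lod"]).reset_index(drop=True)
    if len(prof) == 0:
        raise ValueError("empty LOD profile")
    peak = int(prof["lod"].idxmax())
    thr = prof["lod"].iloc[peak] - drop
    left = peak
    while left > 0 and prof["lod"].iloc[left - 1] >= thr:
        left -= 1
    right = peak
    while right < len(prof) - 1 and prof["lod"].iloc[right + 1] >= thr:
        right += 1
    return LodInterval(
        chrom=str(prof["chrom"].iloc[peak]),
        peak_mid_bp=float(prof["mid_bp"].iloc[peak]),
        peak_lod=float(prof["lod"].iloc[peak]),
        drop=drop,
        start_bp=float(prof["start_bp"].iloc[left]),
        end_bp=float(prof["end_bp"].iloc[right]),
        left_censored=left == 0 and prof["lod"].iloc[0] >= thr,
        right_censored=right == len(prof) - 1 and prof["lod"].iloc[-1] >= thr,
    )


def intersect_intervals(a, b):
    """Closed-interval intersection of two (start, end) pairs on the same
    chromosome; returns ``(start, end)`` or None when disjoint."""
    start = max(a[0], b[0])
    end = min(a[1], b[1])
    if start > end:
        return None
    return (start, end)


def ldla_scan(
    genotypes: PhasedGenotypes,
    y,
    covariates=None,
    G: KinshipMatrix = None,
    window_size_variants: int = 10,
    min_cluster_freq: float = 0.02,
) -> pd.DataFrame:
    """Window-by-window mixed-model LOD profile over haplotype clusters.

    The window's pseudomarkers (all but the most frequent, reference cluster)
    enter as fixed effects beside the covariates; the likelihood ratio against
    the no-pseudomarker null uses the null's variance components. Windows with
    a single cluster have LOD 0 by definition.
    """
    y = np.asarray(y, dtype=float).ravel()
    if genotypes.n_samples != len(y):
        raise ValueError("Y does not match the individuals in the panel")
    if G is None:
        G = build_grm(genotypes)
    W = _design_matrix(len(y), covariates)
    null = fit_null(y, W, G)
    d = null.lmbda * null.eigvals + 1.0
    sd = np.sqrt(d)
    U = null.eigvecs
    ys = (U.T @ y) / sd
    Ws = (U.T @ W) / sd[:, None]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        r = ys - X @ beta
        return float(r @ r)

    rss0 = rss(Ws)
    windows = cluster_haplotypes(genotypes, window_size_variants, min_cluster_freq)
    rows = []
    for w in windows:
        if w.n_clusters <= 1:
            lod = 0.0
        else:
            P = to_pseudomarkers(w)[:, 1:]  # drop reference cluster (label 0)
            Ps = (U.T @ P) / sd[:, None]
            lr = (rss0 - rss(np.column_stack([Ws, Ps]))) / null.tau_inv
            lod = max(lr, 0.0) / (2.0 * np.log(10.0))
        rows.append(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "mid_bp": w.mid_bp,
                "n_clusters": w.n_clusters,
                "lod": lod,
            }
        )
    return pd.DataFrame(rows)


class LDLAScan(BaseEstimator):
    """Haplotype-cluster LDLA scan with a LOD-drop support interval.

    Parameters
    ----------
    window_size_variants : int, default 10
    min_cluster_freq : float, default 0.02
        Clusters rarer than this fraction of chromosomes are merged.
    drop : float, default 2.0
        LOD drop defining the support interval.

    Attributes
    ----------
    lod_profile_ : DataFrame (chrom, start_bp, end_bp, mid_bp, n_clusters, lod)
    interval_ : LodInterval
    """

    def __init__(self, window_size_variants=10, min_cluster_freq=0.02, drop=2.0):
        self.window_size_variants = window_size_variants
        self.min_cluster_freq = min_cluster_freq
        self.drop = drop

    def fit(self, genotypes: PhasedGenotypes, y, covariates=None, G: KinshipMatrix = None):
        self.lod_profile_ = ldla_scan(
            genotypes,
            y,
            covariates=covariates,
            G=G,
            window_size_variants=self.window_size_variants,
            min_cluster_freq=self.min_cluster_freq,
        )
        self.interval_ = two_lod_interval(self.lod_profile_, self.drop)
        return self
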