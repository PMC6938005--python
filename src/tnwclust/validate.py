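"""Hierarchical clustering of distance matrices and bootstrap validation.

Two questions are answered here by resampling patients with replacement:

* *How many clusters does the data support?*  For each bootstrap
  replicate, the resampled sub-matrix of D is re-clustered and, for every
  candidate cut ``q`` in ``[k_min, k_max]``, the replicate's partition is
  compared with the original partition restricted to the drawn multiset
  using five partition-comparison indices (Rand, adjusted Rand,
  Fowlkes-Mallows, Jaccard, adjusted Wallace).  A ``q`` whose indices stay
  high across replicates is well supported.

* *How stable is each individual cluster?*  Given a final partition
  {A_1..A_k}, each bootstrap replicate is re-clustered and cut at k; each
  original cluster is matched to its maximum-overlap bootstrap cluster
  and three set-similarity measures are recorded: the Jaccard index
  (tau*), the recovery rate (gamma*, the fraction of the cluster found in
  its best match) and the Dice coefficient (eta*).

Clustering itself is agglomerative with Lance-Williams updates on the
precomputed distance matrix (scipy's linkage), with single, complete,
average, centroid and Ward linkages.  Replicate ``r`` draws from a
generator that depends only on ``(seed..., r)``, so runs are reproducible
and individual replicates can be re-derived in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .align import DistanceMatrix

LINKAGES = ("single", "complete", "average", "centroid", "ward")
INDEX_NAMES = ("Rand", "AR", "FM", "Jaccard", "AW")


@dataclass(frozen=True)
class Dendrogram:
    """Merge history of N leaves: scipy linkage matrix plus linkage name."""

    merges: np.ndarray  # (N-1, 4) scipy linkage matrix
    linkage: str
    n_leaves: int

    def cut(self, q: int) -> np.ndarray:
        """Partition into exactly q groups by undoing the last q-1 merges."""
        if not 1 <= q <= self.n_leaves:
            raise ValueError(f"q={q} out of range [1, {self.n_leaves}]")
        return sch.cut_tree(self.merges, n_clusters=q).ravel()

    def cut_range(self, qs: Sequence[int]) -> np.ndarray:
        """Column-stacked cuts, one column per q in ``qs``."""
        for q in qs:
            if not 1 <= q <= self.n_leaves:
                raise ValueError(f"q={q} out of range [1, {self.n_leaves}]")
        return sch.cut_tree(self.merges, n_clusters=list(qs))


def agglomerate(D: DistanceMatrix | np.ndarray, linkage: str = "ward") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    The Lance-Williams update of the chosen linkage is applied directly to
    the given dissimilarities (for Ward and centroid this is a deliberate
    extension beyond their Euclidean derivation; see the methods note).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if isinstance(D, DistanceMatrix):
        condensed = D.condensed()
        n = D.n
    else:
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        condensed = D[np.triu_indices(n, k=1)]
    Z = sch.linkage(condensed, method=linkage)
    return Dendrogram(Z, linkage, n)


# ---------------------------------------------------------------------------
# partition comparison


def _pair_counts(p: np.ndarray, q: np.ndarray) -> tuple[float, float, float, float]:
    """Pair agreement counts (a, b, c, d) from a contingency table.

    a: together in both; b: together in p only; c: together in q only;
    d: apart in both.
    """
    n = p.size
    _, pi = np.unique(p, return_inverse=True)
    _, qi = np.unique(q, return_inverse=True)
    kp, kq = pi.max() + 1, qi.max() + 1
    cont = np.bincount(pi * kq + qi, minlength=kp * kq).reshape(kp, kq)
    sum_sq = float((cont.astype(float) ** 2).sum())
    a = (sum_sq - n) / 2.0
    rows = cont.sum(axis=1).astype(float)
    cols = cont.sum(axis=0).astype(float)
    P = float((rows * (rows - 1)).sum()) / 2.0  # together in p
    Q = float((cols * (cols - 1)).sum()) / 2.0  # together in q
    total = n * (n - 1) / 2.0
    b = P - a
    c = Q - a
    d = total - a - b - c
    return a, b, c, d


def compare_partitions(p, q) -> dict[str, float]:
    """Five partition-comparison indices between two labelings.

    Both arguments are label vectors over the same elements (labels are
    arbitrary hashables; only the induced partitions matter).  Returns
    ``{"Rand", "AR", "FM", "Jaccard", "AW"}``.

    From the pair counts a, b, c, d: Rand = (a+d)/(a+b+c+d);
    Jaccard = a/(a+b+c); FM = a/sqrt((a+b)(a+c)); AR is the
    Hubert-Arabie chance-corrected Rand; AW is the chance-corrected
    Wallace coefficient W = a/(a+b), directional from the first labeling
    to the second, with expected value Q/total under independence.
    Degenerate denominators: Jaccard and FM are 0 when their denominator
    vanishes; AR (and AW) with a zero denominator are 1 when the
    partitions are identical and 0 otherwise.
    """
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("label vectors must be 1-D and equally long")
    n = p.size
    a, b, c, d = _pair_counts(p, q)
    total = a + b + c + d
    identical = b == 0 and c == 0

    rand = (a + d) / total if total > 0 else 1.0
    jaccard = a / (a + b + c) if (a + b + c) > 0 else 0.0
    fm_den = (a + b) * (a + c)
    fm = a / np.sqrt(fm_den) if fm_den > 0 else 0.0

    P, Q = a + b, a + c
    expected = P * Q / total if total > 0 else 0.0
    ar_den = 0.5 * (P + Q) - expected
    if ar_den != 0:
        ar = (a - expected) / ar_den
    else:
        ar = 1.0 if identical else 0.0

    wi = Q / total if total > 0 else 0.0  # expected Wallace under independence
    if P > 0 and 1.0 - wi != 0:
        aw = (a / P - wi) / (1.0 - wi)
    else:
        aw = 1.0 if identical else 0.0

    return {"Rand": float(rand), "AR": float(ar), "FM": float(fm),
            "Jaccard": float(jaccard), "AW": float(aw)}


# ---------------------------------------------------------------------------
# bootstrap machinery


def _replicate_rng(entropy: Sequence[int], r: int) -> np.random.Generator:
    """Generator for replicate r, a pure function of (entropy..., r)."""
    return np.random.default_rng(np.random.SeedSequence([*entropy, r]))


def _resample(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, n, size=n)


@dataclass(frozen=True)
class IndexStats:
    """Bootstrap distributions of the five indices per candidate cut q.

    ``values[qi, ii, r]`` is index ``INDEX_NAMES[ii]`` at cut ``qs[qi]``
    for replicate r.
    """

    qs: tuple[int, ...]
    values: np.ndarray  # (n_q, 5, M)
    linkage: str
    metadata: dict

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def summary(self) -> pd.DataFrame:
        """Tidy table: one row per (q, index) with median/mean/var/std."""
        rows = []
        for qi, q in enumerate(self.qs):
            for ii, name in enumerate(INDEX_NAMES):
                v = self.values[qi, ii]
                rows.append(
                    {"q": q, "index": name, "median": float(np.median(v)),
                     "mean": float(v.mean()), "var": float(v.var(ddof=0)),
                     "std": float(v.std(ddof=0))}
                )
        return pd.DataFrame(rows)

    def mean_table(self) -> pd.DataFrame:
        """Wide table of means: rows q, columns the five indices."""
        return pd.DataFrame(
            self.values.mean(axis=2), index=pd.Index(self.qs, name="q"),
            columns=list(INDEX_NAMES),
        )

    def std_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.std(axis=2, ddof=0), index=pd.Index(self.qs, name="q"),
            columns=list(INDEX_NAMES),
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"metadata": self.metadata,
                       "stats": self.summary().to_dict(orient="records")}, fh, indent=2)


def bootstrap_index_stats(
    D: DistanceMatrix | np.ndarray,
    M: int = 1000,
    linkage: str = "ward",
    k_min: int = 2,
    k_max: int | None = None,
    seed: int | Sequence[int] = 42,
) -> IndexStats:
    """Bootstrap support for each candidate number of clusters.

    For each of M replicates, N patient indices are drawn with
    replacement; the induced sub-matrix of D is re-clustered (alignment
    scores are pairwise and fixed, so no re-alignment is needed) and for
    every q in ``[k_min, k_max]`` the five indices are computed between
    the original dendrogram's cut restricted to the drawn multiset and
    the replicate dendrogram's cut.  Each drawn copy counts as an
    element, so both partitions cover the same multiset.
    """
    Dm = D.distances if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = Dm.shape[0]
    if k_max is None:
        k_max = min(30, n)
    if not (2 <= k_min <= k_max <= n):
        raise ValueError(f"need 2 <= k_min <= k_max <= N, got [{k_min}, {k_max}], N={n}")
    if M < 1:
        raise ValueError("M must be >= 1")
    entropy = [seed] if isinstance(seed, (int, np.integer)) else list(seed)

    qs = list(range(k_min, k_max + 1))
    Z = agglomerate(D if isinstance(D, DistanceMatrix) else Dm, linkage)
    orig_cuts = Z.cut_range(qs)  # (N, n_q)

    values = np.empty((len(qs), len(INDEX_NAMES), M))
    iu = np.triu_indices(n, k=1)
    for r in range(M):
        rng = _replicate_rng(entropy, r)
        idx = _resample(rng, n)
        sub = Dm[np.ix_(idx, idx)]
        Zb = Dendrogram(sch.linkage(sub[iu], method=linkage), linkage, n)
        boot_cuts = Zb.cut_range(qs)
        for qi in range(len(qs)):
            res = compare_partitions(orig_cuts[idx, qi], boot_cuts[:, qi])
            for ii, name in enumerate(INDEX_NAMES):
                values[qi, ii, r] = res[name]
    meta = {"M": M, "linkage": linkage, "k_min": k_min, "k_max": k_max,
            "seed_entropy": entropy, "n": n,
            "aw_direction": "original->bootstrap"}
    return IndexStats(tuple(qs), values, linkage, meta)


@dataclass(frozen=True)
class StabilityReport:
    """Bootstrap stability of each cluster of a fixed partition.

    ``tau``, ``gamma`` and ``eta`` have shape (k, M): per original
    cluster, the Jaccard index, recovery rate and Dice coefficient
    against its maximum-overlap bootstrap cluster in each replicate.
    """

    cluster_ids: tuple[int, ...]
    sizes: tuple[int, ...]
    tau: np.ndarray
    gamma: np.ndarray
    eta: np.ndarray
    metadata: dict

    def summary(self) -> pd.DataFrame:
        """One row per cluster: size plus median/average/std of each measure."""
        rows = []
        for j, (cid, size) in enumerate(zip(self.cluster_ids, self.sizes)):
            row = {"cluster": cid, "size": size}
            for name, arr in (("tau", self.tau), ("eta", self.eta), ("gamma", self.gamma)):
                v = arr[j]
                row[f"{name}_median"] = float(np.median(v))
                row[f"{name}_average"] = float(v.mean())
                row[f"{name}_std"] = float(v.std(ddof=0))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"metadata": self.metadata,
                       "stats": self.summary().to_dict(orient="records")}, fh, indent=2)


def cluster_stability(
    D: DistanceMatrix | np.ndarray,
    labels,
    linkage: str = "ward",
    M: int = 1000,
    seed: int | Sequence[int] = 42,
) -> StabilityReport:
    """Per-cluster stability of a partition under bootstrap resampling.

    For each replicate, the resample is re-clustered and cut at the
    partition's k; each original cluster A_j (restricted to the drawn
    multiset, multiplicities counted) is matched to the bootstrap cluster
    with maximal overlap (ties: larger Jaccard, then lower cluster index)
    and tau* (Jaccard), gamma* (|A ∩ B|/|A|) and eta* (Dice) are
    recorded.  A cluster absent from a resample scores 0 on all three.
    """
    Dm = D.distances if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = Dm.shape[0]
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("labels must be one per element of D")
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("partition must have at least 2 clusters")
    entropy = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    lab_idx = np.searchsorted(uniq, labels)

    tau = np.zeros((k, M))
    gamma = np.zeros((k, M))
    eta = np.zeros((k, M))
    iu = np.triu_indices(n, k=1)
    for r in range(M):
        rng = _replicate_rng(entropy, r)
        idx = _resample(rng, n)
        sub = Dm[np.ix_(idx, idx)]
        Zb = Dendrogram(sch.linkage(sub[iu], method=linkage), linkage, n)
        B = Zb.cut(k)
        nb = np.bincount(B, minlength=k).astype(float)
        orig = lab_idx[idx]
        for j in range(k):
            mask = orig == j
            na = float(mask.sum())
            if na == 0:
                continue  # cluster absent from the resample: stays 0
            inter = np.bincount(B[mask], minlength=k).astype(float)
            tau_all = inter / (na + nb - inter)
            best_inter = inter.max()
            cand = np.flatnonzero(inter == best_inter)
            m = cand[np.argmax(tau_all[cand])]  # argmax returns first tie
            tau[j, r] = tau_all[m]
            gamma[j, r] = inter[m] / na
            eta[j, r] = 2.0 * inter[m] / (na + nb[m])
    sizes = np.bincount(lab_idx, minlength=k)
    meta = {"M": M, "linkage": linkage, "k": k, "seed_entropy": entropy, "n": n}
    return StabilityReport(tuple(int(u) for u in uniq), tuple(int(s) for s in sizes),
                           tau, gamma, eta, meta)
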