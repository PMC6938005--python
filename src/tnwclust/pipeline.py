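"""End-to-end orchestration: gap sweep, selection of (k, g), stability.

The full procedure is: build PE sequences; for each gap penalty g on a
grid, align all pairs (TNW), convert the similarity matrix to distances,
cluster, and bootstrap the partition-comparison indices for every
candidate number of clusters q; then select the number of clusters k and
the gap penalty g — automatically, or semi-automatically by handing the
tables and dendrograms to the user — and assess the stability of each
cluster of the final partition by a second bootstrap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .align import (DistanceMatrix, ScoringScheme, SimilarityMatrix,
                    similarity_matrix, to_distance)
from .pe import PESequence
from .validate import (INDEX_NAMES, Dendrogram, IndexStats, StabilityReport,
                       agglomerate, bootstrap_index_stats, cluster_stability)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of a full run.

    The gap grid is ``g_min, g_min + g_step, ...`` up to ``g_max``
    (inclusive, within floating-point tolerance).  ``mode`` is
    ``"automatic"`` (the pipeline selects k and g) or
    ``"semi-automatic"`` (tables are produced; the caller supplies the
    choice via ``run_sweep(..., chosen=(k, g))`` or
    ``SweepResult.finalize``).
    """

    g_min: float = 0.0
    g_max: float = 1.0
    g_step: float = 0.1
    match_score: float = 1.0
    mismatch_score: float = -1.1
    temporal_penalty: float = 0.25
    M: int = 1000
    linkage: str = "ward"
    k_min: int = 2
    k_max: int = 30
    mode: str = "automatic"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.g_min > self.g_max:
            raise ValueError("g_min must be <= g_max")
        if self.g_step <= 0:
            raise ValueError("g_step must be > 0")
        if self.mode not in ("automatic", "semi-automatic"):
            raise ValueError("mode must be 'automatic' or 'semi-automatic'")

    def gap_grid(self) -> np.ndarray:
        count = int(np.floor((self.g_max - self.g_min) / self.g_step + 1e-9)) + 1
        return self.g_min + self.g_step * np.arange(count)

    def scoring(self, g: float) -> ScoringScheme:
        return ScoringScheme(self.match_score, self.mismatch_score, g,
                             self.temporal_penalty)


@dataclass(frozen=True)
class GapResult:
    """Per-gap-value intermediate products."""

    g: float
    similarity: SimilarityMatrix
    distance: DistanceMatrix
    dendrogram: Dendrogram
    index_stats: IndexStats


@dataclass(frozen=True)
class SweepResult:
    """Everything a run produces; selection fields are None until chosen."""

    config: SweepConfig
    gap_results: tuple[GapResult, ...]
    selected_k: int | None = None
    selected_g: float | None = None
    partition: np.ndarray | None = None
    stability: StabilityReport | None = None
    selection_detail: dict | None = None

    @property
    def gap_values(self) -> tuple[float, ...]:
        return tuple(gr.g for gr in self.gap_results)

    def gap_result(self, g: float) -> GapResult:
        for gr in self.gap_results:
            if np.isclose(gr.g, g):
                return gr
        raise KeyError(f"gap value {g} not on the grid")

    def finalize(self, k: int, g: float) -> "SweepResult":
        """Fix (k, g) — the semi-automatic user choice — and run stability."""
        gr = self.gap_result(g)
        labels = gr.dendrogram.cut(k)
        stab = cluster_stability(
            gr.distance, labels, self.config.linkage, self.config.M,
            seed=[self.config.seed, len(self.gap_results)],
        )
        return replace(self, selected_k=k, selected_g=gr.g, partition=labels,
                       stability=stab)


def select_k(stats_by_g: dict[float, IndexStats]) -> tuple[int, float, dict]:
    """Automatic choice of the number of clusters and the gap penalty.

    For every gap value and every index, the candidate cut q with the
    highest bootstrap mean casts one vote; k is the modal vote.  Ties
    between modal candidates are broken by the smaller bootstrap standard
    deviation of the adjusted Rand (minimum over the grid), then by the
    smaller q.  The gap penalty is then the grid value whose five index
    means at k are highest on average.

    Returns (k, g, detail) where detail records the votes and tie-breaks.
    """
    if not stats_by_g:
        raise ValueError("no index statistics supplied")
    votes: list[int] = []
    for g, stats in stats_by_g.items():
        means = stats.mean_table()
        for name in INDEX_NAMES:
            votes.append(int(means[name].idxmax()))
    counts = pd.Series(votes).value_counts()
    top = counts[counts == counts.max()].index.to_numpy()
    if top.size == 1:
        k = int(top[0])
        tie_break = None
    else:
        ar_std = {
            int(q): min(float(stats.std_table().loc[q, "AR"])
                        for stats in stats_by_g.values())
            for q in top
        }
        best = min(ar_std.values())
        tied = sorted(q for q, s in ar_std.items() if s == best)
        k = tied[0]
        tie_break = {"candidates": sorted(int(q) for q in top), "ar_std": ar_std}
    mean_at_k = {g: float(stats.mean_table().loc[k].mean())
                 for g, stats in stats_by_g.items()}
    g_sel = max(mean_at_k, key=lambda g: (mean_at_k[g], -g))
    detail = {"votes": votes, "vote_counts": {int(q): int(c) for q, c in counts.items()},
              "tie_break": tie_break, "mean_at_k": mean_at_k}
    return k, float(g_sel), detail


def run_sweep(
    seqs: Sequence[PESequence],
    config: SweepConfig,
    chosen: tuple[int, float] | None = None,
) -> SweepResult:
    """Run the whole pipeline on ready-made PE sequences.

    Bootstrap replicate r of gap-grid position j draws from a generator
    seeded by ``(config.seed, j, r)``, so enlarging the grid never
    perturbs existing replicates, and two runs with the same config are
    bit-identical.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    grid = config.gap_grid()
    if grid.size == 0:
        raise ValueError("empty gap grid")
    k_max = min(config.k_max, len(seqs))
    gap_results = []
    for j, g in enumerate(grid):
        t0 = time.perf_counter()
        S = similarity_matrix(list(seqs), config.scoring(g))
        D = to_distance(S)
        Z = agglomerate(D, config.linkage)
        stats = bootstrap_index_stats(
            D, config.M, config.linkage, config.k_min, k_max,
            seed=[config.seed, j],
        )
        logger.info("gap %.3g done in %.2fs", g, time.perf_counter() - t0)
        gap_results.append(GapResult(float(g), S, D, Z, stats))

    result = SweepResult(config, tuple(gap_results))
    if chosen is not None:
        return result.finalize(*chosen)
    if config.mode == "automatic":
        k, g_sel, detail = select_k({gr.g: gr.index_stats for gr in gap_results})
        result = result.finalize(k, g_sel)
        result = replace(result, selection_detail=detail)
    return result
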