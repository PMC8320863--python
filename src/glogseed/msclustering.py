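"""Flat-kernel mean-shift clustering of seed candidates with a vote table.

Each cluster generation starts from an unvisited candidate, places a circular
kernel of radius r there, and repeatedly recenters the kernel at the mean of
the candidates strictly inside it until the membership set stops changing.
A per-candidate vote table tracks, per round, how many iterations each
candidate spent inside the kernel (current-round votes V_C), the best such
count over all rounds (maximum votes V_M) and the cluster that achieved it
(cluster number L).  Converged kernel centers closer than a merge threshold
to an existing nucleus are merged (midpoint rule) and their members' votes
are folded together.  The final reported coordinate of each nucleus is the
mean of the candidates assigned to its cluster.

Defaults: kernel radius r = 8 px, merge threshold 16 px, deterministic
row-major pick order (an optional seeded random order mimics arbitrary
hardware arbitration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = ["MSConfig", "ClusterTable", "iterate_kernel", "merge_or_add", "mean_shift_cluster"]


@dataclass(frozen=True)
class MSConfig:
    """Mean-shift parameters: kernel radius, merge threshold, candidate pick order."""

    radius: float = 8.0
    merge_threshold: float = 16.0
    pick_order: str = "scan"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("radius must be positive")
        if self.merge_threshold <= 0:
            raise ParameterError("merge_threshold must be positive")
        if self.pick_order not in ("scan", "random"):
            raise ParameterError(f"pick_order must be 'scan' or 'random', got {self.pick_order!r}")


@dataclass
class ClusterTable:
    """Per-candidate vote bookkeeping plus the identified-nuclei list.

    ``candidates`` is the (n, 2) integer coordinate array S; ``visited``,
    ``current_votes`` (V_C), ``max_votes`` (V_M) and ``cluster`` (L, -1 when
    unset) are parallel arrays.  ``nuclei`` holds one running center per
    cluster id, updated in place on merges; ``kernel_centers`` keeps each
    round's raw converged kernel center for inspection.
    """

    candidates: np.ndarray
    visited: np.ndarray = field(init=False)
    current_votes: np.ndarray = field(init=False)
    max_votes: np.ndarray = field(init=False)
    cluster: np.ndarray = field(init=False)
    nuclei: list[np.ndarray] = field(default_factory=list)
    kernel_centers: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=np.int64).reshape(-1, 2)
        n = len(self.candidates)
        self.visited = np.zeros(n, dtype=bool)
        self.current_votes = np.zeros(n, dtype=np.int64)
        self.max_votes = np.zeros(n, dtype=np.int64)
        self.cluster = np.full(n, -1, dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        """Table-1-style dump: one row per candidate plus the nuclei columns."""
        n = len(self.candidates)
        df = pd.DataFrame(
            {
                "seed_row": self.candidates[:, 0],
                "seed_col": self.candidates[:, 1],
                "visit_flag": self.visited.astype(int),
                "current_votes": self.current_votes,
                "max_votes": self.max_votes,
                "cluster": self.cluster,
            }
        )
        nuc_row = np.full(n, np.nan)
        nuc_col = np.full(n, np.nan)
        for i, c in enumerate(self.nuclei[:n]):
            nuc_row[i], nuc_col[i] = c
        df["nucleus_row"] = nuc_row
        df["nucleus_col"] = nuc_col
        return df


def iterate_kernel(
    start: int, table: ClusterTable, cfg: MSConfig = MSConfig()
) -> tuple[np.ndarray, frozenset[int]]:
    """Run one mean-shift ascent from candidate index ``start``.

    Each iteration finds the candidates strictly within radius r of the
    current center, marks them visited, increments their current-round votes,
    and recenters at their coordinate mean; iteration stops when the
    membership set repeats.  Returns (converged center, member index set).
    """
    S = table.candidates.astype(np.float64)
    center = S[start].copy()
    r2 = cfg.radius * cfg.radius
    prev: frozenset[int] | None = None
    seen: set[frozenset[int]] = set()
    while True:
        d2 = ((S - center) ** 2).sum(axis=1)
        members = frozenset(np.flatnonzero(d2 < r2).tolist())
        idx = sorted(members)
        table.visited[idx] = True
        table.current_votes[idx] += 1
        center = S[idx].mean(axis=0)
        if members == prev or members in seen:
            return center, members
        seen.add(members)
        prev = members


def merge_or_add(
    center: np.ndarray, table: ClusterTable, cfg: MSConfig = MSConfig()
) -> int:
    """Merge a converged center into the nuclei list, then settle the votes.

    If an existing nucleus lies strictly within the merge threshold of the
    center, that nucleus (the lowest-id match) is moved to the midpoint and
    the votes of its previously assigned candidates are folded in
    (V_M += V_C); otherwise the center is appended as a new nucleus.  Every
    participant of the round (current votes > 0) whose current votes beat its
    maximum votes is reassigned: V_M <- V_C, L <- the (merged or new) cluster
    id.  Applying the comparison to all round participants — not only the
    final kernel members — guarantees that a candidate swept through by the
    kernel but dropped before convergence still belongs to the round where it
    collected the most votes.  Returns the cluster id.
    """
    center = np.asarray(center, dtype=np.float64)
    cid = -1
    for l, nucleus in enumerate(table.nuclei):
        if float(np.hypot(*(nucleus - center))) < cfg.merge_threshold:
            table.nuclei[l] = (nucleus + center) / 2.0
            owned = table.cluster == l
            table.max_votes[owned] += table.current_votes[owned]
            cid = l
            break
    if cid < 0:
        table.nuclei.append(center.copy())
        cid = len(table.nuclei) - 1
    for i in np.flatnonzero(table.current_votes > 0):
        if table.max_votes[i] < table.current_votes[i]:
            table.max_votes[i] = table.current_votes[i]
            table.cluster[i] = cid
    return cid


def mean_shift_cluster(
    S: np.ndarray, cfg: MSConfig = MSConfig()
) -> tuple[np.ndarray, ClusterTable]:
    """Cluster the candidate set S into nuclei centers.

    Rounds repeat until every candidate is visited: pick the next unvisited
    candidate (row-major scan order, or a seeded random order), zero all
    current-round votes, run :func:`iterate_kernel`, then
    :func:`merge_or_add`.  The reported center of each cluster is the mean
    coordinate of the candidates finally assigned to it; the raw converged
    kernel centers remain available in the table.

    Returns (``(k, 2)`` float array of nuclei centers ordered by cluster id,
    ClusterTable).
    """
    S = np.asarray(S, dtype=np.int64).reshape(-1, 2)
    table = ClusterTable(S)
    n = len(S)
    if cfg.pick_order == "random":
        order = np.random.default_rng(cfg.rng_seed).permutation(n)
    else:
        order = np.arange(n)
    for i in order:
        if table.visited[i]:
            continue
        table.current_votes[:] = 0
        center, _members = iterate_kernel(int(i), table, cfg)
        table.kernel_centers.append(center)
        merge_or_add(center, table, cfg)
    centers = []
    for cid in sorted(set(table.cluster.tolist()) - {-1}):
        centers.append(S[table.cluster == cid].mean(axis=0))
    if not centers:
        return np.empty((0, 2), dtype=np.float64), table
    return np.asarray(centers, dtype=np.float64), table
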