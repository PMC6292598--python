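"""Standard stepped-wedge design layout and time bookkeeping.

A standard stepped-wedge cluster randomised trial (SWCRT) with K clusters
runs over n = K + 1 calendar time steps. Every cluster starts under the
control condition at step 1; at each subsequent step exactly one cluster
crosses over to the intervention and never reverts, so at the final step
all clusters are treated. Two clocks matter for each cluster k at calendar
step t:

* the treatment indicator ``x_tk`` — 1 once the cluster has crossed over;
* the exposure time ``d_tk`` — number of steps the intervention has been in
  place (0 under control, 1 at the first treated step, at most n − 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StepWedgeDesign", "standard_design"]


@dataclass(frozen=True)
class StepWedgeDesign:
    """Closed-cohort stepped-wedge layout.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    n_steps : int
        Number of calendar time steps n (t = 1..n).
    subjects_per_cluster : int
        Cohort size m per cluster; every participant is observed at all
        n steps (closed cohort), so N = K * m.
    crossover_step : tuple of int
        s_k for each cluster (1-based cluster order): the first calendar
        step at which cluster k is under the intervention. Each s_k lies
        in {2, ..., n}; for the standard design the multiset {s_k} is a
        permutation of {2, ..., n} and n = K + 1.
    """

    n_clusters: int
    n_steps: int
    subjects_per_cluster: int
    crossover_step: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_clusters < 1 or self.subjects_per_cluster < 1 or self.n_steps < 2:
            raise ValueError("counts must be positive (and n_steps >= 2)")
        if len(self.crossover_step) != self.n_clusters:
            raise ValueError(
                f"need one crossover step per cluster: got "
                f"{len(self.crossover_step)} for {self.n_clusters} clusters"
            )
        for s in self.crossover_step:
            if not (2 <= s <= self.n_steps):
                raise ValueError(f"crossover step {s} outside [2, {self.n_steps}]")

    # -- basic sizes ------------------------------------------------------
    @property
    def total_participants(self) -> int:
        """N = K * m."""
        return self.n_clusters * self.subjects_per_cluster

    # -- indicators -------------------------------------------------------
    def _check_tk(self, t: int, k: int) -> None:
        if not (1 <= t <= self.n_steps):
            raise ValueError(f"time step t={t} outside [1, {self.n_steps}]")
        if not (1 <= k <= self.n_clusters):
            raise ValueError(f"cluster k={k} outside [1, {self.n_clusters}]")

    def treatment_indicator(self, t: int, k: int) -> int:
        """x_tk: 1 iff cluster k is under the intervention at step t."""
        self._check_tk(t, k)
        return int(t >= self.crossover_step[k - 1])

    def exposure_time(self, t: int, k: int) -> int:
        """d_tk: steps of intervention exposure for cluster k at step t.

        Zero while under control; the first treated step counts as d = 1,
        so the maximum attainable exposure is n − 1.
        """
        self._check_tk(t, k)
        s = self.crossover_step[k - 1]
        return t - s + 1 if t >= s else 0

    def treatment_matrix(self) -> np.ndarray:
        """(n_steps, n_clusters) array of x_tk."""
        t = np.arange(1, self.n_steps + 1)[:, None]
        s = np.asarray(self.crossover_step)[None, :]
        return (t >= s).astype(int)

    def exposure_matrix(self) -> np.ndarray:
        """(n_steps, n_clusters) array of d_tk."""
        t = np.arange(1, self.n_steps + 1)[:, None]
        s = np.asarray(self.crossover_step)[None, :]
        return np.maximum(t - s + 1, 0)

    # -- serialization ----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the rollout schedule as (cluster_id, crossover_step) CSV."""
        pd.DataFrame(
            {
                "cluster_id": np.arange(1, self.n_clusters + 1),
                "crossover_step": list(self.crossover_step),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subjects_per_cluster: int) -> "StepWedgeDesign":
        """Rebuild a design from a (cluster_id, crossover_step) CSV."""
        df = pd.read_csv(path)
        required = {"cluster_id", "crossover_step"}
        if not required.issubset(df.columns):
            raise ValueError(f"schedule CSV must have columns {sorted(required)}")
        df = df.sort_values("cluster_id")
        steps = tuple(int(s) for s in df["crossover_step"])
        return cls(
            n_clusters=len(steps),
            n_steps=max(steps),
            subjects_per_cluster=subjects_per_cluster,
            crossover_step=steps,
        )


def standard_design(
    n_clusters: int, subjects_per_cluster: int, seed: int | None = None
) -> StepWedgeDesign:
    """Build the standard one-cluster-per-step rollout.

    n_steps = n_clusters + 1; the crossover schedule {s_k} is a permutation
    of {2, ..., n}. By default cluster order equals rollout order
    (s_k = k + 1); passing ``seed`` randomises which cluster takes which
    crossover step, which leaves every design-level summary unchanged.
    """
    if n_clusters < 2:
        raise ValueError("standard design needs at least 2 clusters")
    if subjects_per_cluster < 1:
        raise ValueError("subjects_per_cluster must be >= 1")
    n_steps = n_clusters + 1
    steps = np.arange(2, n_steps + 1)
    if seed is not None:
        steps = np.random.default_rng(seed).permutation(steps)
    return StepWedgeDesign(
        n_clusters=n_clusters,
        n_steps=n_steps,
        subjects_per_cluster=subjects_per_cluster,
        crossover_step=tuple(int(s) for s in steps),
    )
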