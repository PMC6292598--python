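"""Generating scenarios and the closed-cohort trial simulator.

The simulation study covers 36 scenarios (D1..D36) for a 12-cluster,
13-step standard stepped wedge with 20 participants per cluster. Each
scenario pairs a fixed-effect mean model — combinations of an intercept, a
step intervention effect, linear calendar/exposure slopes, and sinusoidal
calendar/exposure profiles — with a common random structure: a cluster
random intercept, a participant random intercept, and a stationary AR(1)
within-participant error built by a rescaled-innovation recursion

    eps_i1 ~ N(0, sigma^2),   eps_it = rho * eps_i,t-1 + s_it,
    s_it ~ N(0, (1 - rho^2) * sigma^2),

so that Var(eps_it) = sigma^2 at every step and corr(eps_it, eps_i,t+r)
= rho^r. Odd-numbered scenarios use rho = -0.5, even-numbered +0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import StepWedgeDesign

__all__ = [
    "VarianceComponents",
    "ScenarioSpec",
    "TrialDataset",
    "calendar_profile",
    "exposure_profile",
    "scenario_table",
    "get_scenario",
    "true_mean",
    "simulate_trial",
]

# Variance components estimated from the motivating trial's HoNOS data
# (cluster SD, participant SD, residual SD, in HoNOS units).
DEFAULT_SIGMA_GAMMA = 0.96
DEFAULT_SIGMA_H = 4.42
DEFAULT_SIGMA = 5.44

TRIAL_SCHEMA = ["cluster_id", "subject_id", "time", "treated", "exposure", "y"]


@dataclass(frozen=True)
class VarianceComponents:
    """Random-structure parameters of the generating/fitted model.

    sigma_gamma : cluster-intercept SD (HoNOS units)
    sigma_h     : participant-intercept SD
    sigma       : residual SD
    rho         : within-participant lag-1 correlation, |rho| < 1
    """

    sigma_gamma: float = DEFAULT_SIGMA_GAMMA
    sigma_h: float = DEFAULT_SIGMA_H
    sigma: float = DEFAULT_SIGMA
    rho: float = 0.0

    def __post_init__(self):
        if min(self.sigma_gamma, self.sigma_h, self.sigma) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")

    @property
    def composite_intercept_var(self) -> float:
        """sigma_nu^2 = sigma_gamma^2 + sigma_h^2."""
        return self.sigma_gamma**2 + self.sigma_h**2


# ---------------------------------------------------------------------------
# sinusoidal trend profiles
# ---------------------------------------------------------------------------

def calendar_profile(profile: str, t: int | np.ndarray) -> float | np.ndarray:
    """Non-linear calendar-time trend at step t (HoNOS units).

    K1(t) = 2 sin((t-1) pi / 12): half a sine cycle over 13 steps, peaking
    at t = 7. K2(t) = 2 sin((t-1) pi / 6): a full cycle with a peak at t = 4
    and a trough at t = 10.
    """
    t = np.asarray(t)
    if profile == "K1":
        out = 2.0 * np.sin((t - 1) * math.pi / 12)
    elif profile == "K2":
        out = 2.0 * np.sin((t - 1) * math.pi / 6)
    else:
        raise ValueError(f"unknown calendar profile {profile!r} (use 'K1' or 'K2')")
    return float(out) if out.ndim == 0 else out


def exposure_profile(profile: str, d: int | np.ndarray) -> float | np.ndarray:
    """Non-linear exposure-time trend after d steps of exposure.

    Zero under control (d = 0) and at the first treated step (d = 1):
    X1(d) = sin((d-1) pi / 12), X2(d) = sin((d-1) pi / 6) for d >= 1.
    """
    d = np.asarray(d)
    if profile == "X1":
        out = np.where(d == 0, 0.0, np.sin((d - 1) * math.pi / 12))
    elif profile == "X2":
        out = np.where(d == 0, 0.0, np.sin((d - 1) * math.pi / 6))
    else:
        raise ValueError(f"unknown exposure profile {profile!r} (use 'X1' or 'X2')")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One generating mean model plus variance components.

    The mean outcome at calendar step t, exposure d, treatment x is

        beta0 + delta*x + tau*t + psi*d + K(t) + X(d)

    where K/X are the optional sinusoidal profiles. A scenario uses either
    the linear terms (tau, psi) or the profiles (kappa_profile, xi_profile),
    never both kinds of calendar trend.
    """

    id: str
    intercept: float = 14.0
    delta: float = 0.0
    tau: float = 0.0
    psi: float = 0.0
    kappa_profile: str | None = None
    xi_profile: str | None = None
    variance: VarianceComponents = VarianceComponents()

    def __post_init__(self):
        if (self.tau or self.psi) and (self.kappa_profile or self.xi_profile):
            raise ValueError(f"{self.id}: linear terms and profiles are exclusive")


def _scenario_pairs():
    # (first odd id, delta, tau, psi, kappa, xi) for each of the 18 pairs
    return [
        (1, 0.0, 0.0, 0.0, None, None),        # y = 14
        (3, 0.0, 0.25, 0.0, None, None),       # + 0.25 t
        (5, 0.0, 0.0, 0.0, "K1", None),        # + kappa1
        (7, 0.0, 0.0, 0.0, "K2", None),        # + kappa2
        (9, 2.0, 0.0, 0.0, None, None),        # + 2 x
        (11, 2.0, 0.25, 0.0, None, None),
        (13, 2.0, 0.25, 0.15, None, None),
        (15, 0.0, 0.25, 0.15, None, None),
        (17, 2.0, 0.25, 0.25, None, None),
        (19, 0.0, 0.25, 0.25, None, None),
        (21, -2.0, 0.25, -0.50, None, None),
        (23, 0.0, 0.25, -0.50, None, None),
        (25, 2.0, 0.0, 0.0, "K1", None),
        (27, 2.0, 0.0, 0.0, "K1", "X1"),
        (29, 0.0, 0.0, 0.0, "K1", "X1"),
        (31, 2.0, 0.0, 0.0, "K2", None),
        (33, 2.0, 0.0, 0.0, "K2", "X2"),
        (35, 0.0, 0.0, 0.0, "K2", "X2"),
    ]


def scenario_table() -> list[ScenarioSpec]:
    """All 36 generating scenarios D1..D36.

    Odd ids carry within-participant correlation rho = -0.5, even ids +0.5;
    the mean models come in consecutive odd/even pairs sharing fixed effects.
    """
    specs = []
    for first, delta, tau, psi, kappa, xi in _scenario_pairs():
        for offset, rho in ((0, -0.5), (1, 0.5)):
            specs.append(
                ScenarioSpec(
                    id=f"D{first + offset}",
                    delta=delta,
                    tau=tau,
                    psi=psi,
                    kappa_profile=kappa,
                    xi_profile=xi,
                    variance=VarianceComponents(rho=rho),
                )
            )
    return specs


_REGISTRY = {s.id: s for s in scenario_table()}


def get_scenario(scenario_id: str, variance: VarianceComponents | None = None) -> ScenarioSpec:
    """Look up D1..D36, optionally overriding the variance components."""
    try:
        spec = _REGISTRY[scenario_id]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; expected D1..D36"
        ) from None
    if variance is not None:
        spec = replace(spec, variance=variance)
    return spec


def true_mean(scenario: ScenarioSpec, t, d, x) -> float | np.ndarray:
    """Generating mean outcome at (t, d, x) under a scenario.

    (t, d, x) must be design-consistent: d > 0 requires x = 1 and d = 0
    requires x = 0.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any((d > 0) != (x == 1)):
        raise ValueError("inconsistent (d, x): exposure d > 0 iff treated x = 1")
    mu = scenario.intercept + scenario.delta * x + scenario.tau * t + scenario.psi * d
    if scenario.kappa_profile:
        mu = mu + calendar_profile(scenario.kappa_profile, t.astype(int))
    if scenario.xi_profile:
        mu = mu + exposure_profile(scenario.xi_profile, d.astype(int))
    return float(mu) if mu.ndim == 0 else mu


# ---------------------------------------------------------------------------
# trial data container
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """Long-format closed-cohort trial data.

    ``df`` has one row per (participant, time step) with columns
    cluster_id, subject_id, time, treated, exposure, y — plus the latent
    columns mu, gamma, h, eps when a simulation retains them.
    """

    df: pd.DataFrame
    design: StepWedgeDesign | None = None
    scenario_id: str | None = None
    seed: int | None = None

    def __post_init__(self):
        missing = [c for c in TRIAL_SCHEMA if c not in self.df.columns]
        if missing:
            raise ValueError(f"trial data missing columns {missing}")
        self.validate()

    @property
    def has_latents(self) -> bool:
        return "eps" in self.df.columns

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ValueError("trial dataset is empty")
        dup = df.duplicated(["subject_id", "time"])
        if dup.any():
            row = df.index[dup][0]
            raise ValueError(f"duplicate (subject_id, time) pair at row {row}")
        bad = (df["exposure"] > 0) != (df["treated"] == 1)
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"row {row}: exposure must be 0 under control and positive "
                "exactly when treated"
            )
        # a subject may not belong to two clusters
        if (df.groupby("subject_id")["cluster_id"].nunique() > 1).any():
            raise ValueError("a subject_id appears in more than one cluster")
        if self.has_latents:
            resid = df["y"] - (df["mu"] + df["gamma"] + df["h"] + df["eps"])
            if not np.allclose(resid, 0.0, atol=1e-10):
                raise ValueError("latents do not reconstruct y")

    def sorted(self) -> "TrialDataset":
        """Rows ordered cluster-by-cluster, subject-by-subject, by time."""
        out = self.df.sort_values(["cluster_id", "subject_id", "time"], kind="stable")
        return TrialDataset(
            out.reset_index(drop=True), self.design, self.scenario_id, self.seed
        )

    def to_csv(self, path) -> None:
        self.df[TRIAL_SCHEMA].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

def replicate_seed_sequence(master_seed: int, scenario_id: str, replicate: int = 0):
    """Independent, reproducible substream for (scenario, replicate).

    Spawned from the master seed with a key derived from the scenario id and
    replicate index, so any single replicate can be regenerated in isolation
    and grid runs are resumable without changing results.
    """
    scen_key = int(scenario_id.lstrip("D")) if scenario_id.startswith("D") else 0
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(scen_key, int(replicate))
    )


def simulate_trial(
    design: StepWedgeDesign,
    scenario: ScenarioSpec,
    seed,
    keep_latents: bool = False,
    replicate: int = 0,
) -> TrialDataset:
    """Simulate one closed-cohort stepped-wedge dataset.

    Per cluster draws gamma_k ~ N(0, sigma_gamma^2); per participant
    h_i ~ N(0, sigma_h^2); per participant an AR(1) error path with
    stationary marginal variance sigma^2 (rescaled innovations). The
    outcome is y = mu(t, d, x) + gamma_k + h_i + eps_it. ``seed`` may be an
    integer master seed (combined with ``replicate`` and the scenario id
    into an independent substream) or a ready ``np.random.SeedSequence``.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
        seed_label = None
    else:
        ss = replicate_seed_sequence(int(seed), scenario.id, replicate)
        seed_label = int(seed)
    rng = np.random.default_rng(ss)

    vc = scenario.variance
    K, n, m = design.n_clusters, design.n_steps, design.subjects_per_cluster
    N = design.total_participants

    gamma = rng.normal(0.0, vc.sigma_gamma, size=K)
    h = rng.normal(0.0, vc.sigma_h, size=N)

    # AR(1) errors, participants stacked as rows: eps[:, 0] ~ N(0, sigma^2),
    # innovations have variance (1 - rho^2) sigma^2 so Var(eps_t) = sigma^2
    # at every t.
    eps = np.empty((N, n))
    eps[:, 0] = rng.normal(0.0, vc.sigma, size=N)
    innov_sd = vc.sigma * math.sqrt(1.0 - vc.rho**2)
    for t in range(1, n):
        eps[:, t] = vc.rho * eps[:, t - 1] + rng.normal(0.0, innov_sd, size=N)

    cluster_of = np.repeat(np.arange(1, K + 1), m)  # subject-major
    subj = np.arange(1, N + 1)

    x_mat = design.treatment_matrix()  # (n, K)
    d_mat = design.exposure_matrix()

    rows = {c: [] for c in TRIAL_SCHEMA + ["mu", "gamma", "h", "eps"]}
    t_vals = np.arange(1, n + 1)
    for i in range(N):
        k = cluster_of[i]
        x = x_mat[:, k - 1]
        d = d_mat[:, k - 1]
        mu = true_mean(scenario, t_vals, d, x)
        rows["cluster_id"].append(np.full(n, k))
        rows["subject_id"].append(np.full(n, subj[i]))
        rows["time"].append(t_vals)
        rows["treated"].append(x)
        rows["exposure"].append(d)
        rows["mu"].append(mu)
        rows["gamma"].append(np.full(n, gamma[k - 1]))
        rows["h"].append(np.full(n, h[i]))
        rows["eps"].append(eps[i])
        rows["y"].append(mu + gamma[k - 1] + h[i] + eps[i])

    cols = TRIAL_SCHEMA + (["mu", "gamma", "h", "eps"] if keep_latents else [])
    df = pd.DataFrame({c: np.concatenate(rows[c]) for c in cols})
    for c in ("cluster_id", "subject_id", "time", "treated", "exposure"):
        df[c] = df[c].astype(int)
    return TrialDataset(df, design=design, scenario_id=scenario.id, seed=seed_label)
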