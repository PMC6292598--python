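"""Configuration, dataset readers/writers, and the trial re-analysis mode.

Trial data travel as long-format CSV with header
``cluster_id,subject_id,time,treated,exposure,y`` — the same schema the
simulator writes. The re-analysis mode additionally ingests a deposited
trial workbook (XLSX) whose column names are discovered at read time, and
refits all nine formulations to produce a per-model report of both
intervention-effect estimands, their standard errors and p-values, and
BIC.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StepWedgeDesign, standard_design
from .models import ESTIMANDS, FORMULATIONS, contrast, estimate_effect, fit_formulation
from .scenarios import (
    TRIAL_SCHEMA,
    TrialDataset,
    VarianceComponents,
    _REGISTRY,
)

__all__ = [
    "RunConfig",
    "read_config",
    "read_trial_csv",
    "read_oxtext_xlsx",
    "reanalyze",
]

log = logging.getLogger("stepwedge")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat configuration of a simulation-grid run."""

    n_clusters: int = 12
    subjects_per_cluster: int = 20
    scenarios: tuple = tuple(f"D{i}" for i in range(1, 37))
    formulations: tuple = tuple(FORMULATIONS)
    structures: tuple = ("CS", "AR1")
    n_reps: int = 1000
    master_seed: int = 20181206
    sigma_gamma: float | None = None
    sigma_h: float | None = None
    sigma: float | None = None
    out_dir: str = "results"
    ci_reference: str = "normal"  # normal | t
    mse_mode: str = "conditional"  # conditional | marginal

    def validate(self) -> None:
        unknown = [s for s in self.scenarios if s not in _REGISTRY]
        if unknown:
            raise ValueError(f"unknown scenario ids in config: {unknown}")
        unknown = [m for m in self.formulations if m not in FORMULATIONS]
        if unknown:
            raise ValueError(f"unknown formulation ids in config: {unknown}")
        unknown = [s for s in self.structures if s.upper().replace("(1)", "1") not in ("CS", "AR1")]
        if unknown:
            raise ValueError(f"unknown covariance structures in config: {unknown}")
        if self.ci_reference not in ("normal", "t"):
            raise ValueError(f"ci_reference must be 'normal' or 't', got {self.ci_reference!r}")
        if self.mse_mode not in ("conditional", "marginal"):
            raise ValueError(f"mse_mode must be 'conditional' or 'marginal', got {self.mse_mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def make_design(self) -> StepWedgeDesign:
        return standard_design(self.n_clusters, self.subjects_per_cluster)

    def variance_for(self, scenario_id: str) -> VarianceComponents | None:
        """Variance-component override (None keeps the scenario default)."""
        if self.sigma_gamma is None and self.sigma_h is None and self.sigma is None:
            return None
        base = _REGISTRY[scenario_id].variance
        return VarianceComponents(
            sigma_gamma=self.sigma_gamma if self.sigma_gamma is not None else base.sigma_gamma,
            sigma_h=self.sigma_h if self.sigma_h is not None else base.sigma_h,
            sigma=self.sigma if self.sigma is not None else base.sigma,
            rho=base.rho,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_LIST_KEYS = {"scenarios", "formulations", "structures"}
_INT_KEYS = {"n_clusters", "subjects_per_cluster", "n_reps", "master_seed"}
_FLOAT_KEYS = {"sigma_gamma", "sigma_h", "sigma"}


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file (lists comma-separated).

    ``scenarios`` and ``formulations`` accept ranges like ``D1-D8`` and
    ``all``.
    """
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in _LIST_KEYS:
            items = []
            for tok in value.replace(",", " ").split():
                if tok == "all":
                    items.extend(
                        _REGISTRY if key == "scenarios"
                        else FORMULATIONS if key == "formulations"
                        else ("CS", "AR1")
                    )
                elif "-" in tok and key == "scenarios":
                    a, b = tok.split("-")
                    items.extend(f"D{i}" for i in range(int(a.lstrip("D")), int(b.lstrip("D")) + 1))
                else:
                    items.append(tok)
            kwargs[key] = tuple(items)
        elif key in _INT_KEYS:
            kwargs[key] = int(value)
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(value)
        elif key in ("out_dir", "ci_reference", "mse_mode"):
            kwargs[key] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    config = RunConfig(**kwargs)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# trial-data CSV
# ---------------------------------------------------------------------------

def read_trial_csv(path) -> TrialDataset:
    """Read a long-format trial CSV with the canonical six-column schema."""
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_SCHEMA:
        raise ValueError(
            f"trial CSV must have header {TRIAL_SCHEMA}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for c in ("cluster_id", "subject_id", "time", "treated", "exposure"):
        df[c] = df[c].astype(int)
    df["y"] = df["y"].astype(float)
    return TrialDataset(df)  # constructor validates consistency


# ---------------------------------------------------------------------------
# deposited-workbook ingest
# ---------------------------------------------------------------------------

# candidate substrings for mapping a deposited workbook's columns, lowercased
_XLSX_CANDIDATES = {
    "cluster_id": ("cmht", "cluster", "team", "centre", "center", "site"),
    "subject_id": ("participant", "subject", "patient", "id"),
    "time": ("month", "time", "step", "occasion"),
    "y": ("honos", "total", "score", "outcome", "y"),
    "treated": ("treat", "interv", "arm", "condition", "fwtc"),
}


def read_oxtext_xlsx(path, sheet=0) -> TrialDataset:
    """Map a deposited trial workbook onto the long-format trial schema.

    The exact column names of the deposited file are not fixed, so each
    schema field is matched against the observed header by substring
    (cluster <- CMHT/team/centre, outcome <- HoNOS total, and so on).
    Exposure time is derived from each cluster's first treated month. A
    field that cannot be mapped raises an error reporting the observed
    header.
    """
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    observed = list(df.columns)
    lowered = {str(c).strip().lower(): c for c in observed}
    mapping = {}
    used = set()
    for target, candidates in _XLSX_CANDIDATES.items():
        hit = None
        for cand in candidates:
            for low, orig in lowered.items():
                if cand in low and orig not in used:
                    hit = orig
                    break
            if hit is not None:
                break
        if hit is None:
            raise ValueError(
                f"cannot map required field {target!r} onto workbook columns "
                f"{observed}"
            )
        mapping[target] = hit
        used.add(hit)

    out = pd.DataFrame({t: df[c] for t, c in mapping.items()})
    out = out.dropna(subset=["y"])
    codes_c = pd.factorize(out["cluster_id"])[0] + 1
    codes_s = pd.factorize(out["subject_id"])[0] + 1
    time_map = {v: i + 1 for i, v in enumerate(np.sort(out["time"].unique()))}
    out["cluster_id"] = codes_c
    out["subject_id"] = codes_s
    out["time"] = out["time"].map(time_map).astype(int)
    out["treated"] = (
        pd.to_numeric(out["treated"], errors="coerce").fillna(0).astype(float) > 0
    ).astype(int)
    out["y"] = out["y"].astype(float)

    # exposure = months since the cluster's first treated month (first = 1)
    first_treated = (
        out[out["treated"] == 1].groupby("cluster_id")["time"].min().to_dict()
    )
    start = out["cluster_id"].map(first_treated)
    out["exposure"] = np.where(
        out["treated"] == 1, out["time"] - start + 1, 0
    ).astype(int)
    out = out[TRIAL_SCHEMA].sort_values(["cluster_id", "subject_id", "time"])
    return TrialDataset(out.reset_index(drop=True))


# ---------------------------------------------------------------------------
# nine-model re-analysis report
# ---------------------------------------------------------------------------

def reanalyze(
    dataset: TrialDataset,
    ci_reference: str = "normal",
    structure: str = "CS",
) -> pd.DataFrame:
    """Fit all nine formulations to one dataset and tabulate the estimands.

    One row per formulation: the six-month and time-averaged intervention
    effects with standard errors and two-sided p-values, plus BIC and the
    convergence flag. A formulation that fails to converge is reported
    in-row and the run continues.
    """
    n_steps = int(dataset.df["time"].max())
    rows = []
    for form_id in FORMULATIONS:
        row = {"formulation": form_id, "structure": structure}
        try:
            fit = fit_formulation(dataset, form_id, structure=structure)
            row["converged"] = fit.converged
            row["bic"] = fit.bic
            row["loglik"] = fit.loglik
            for e in ESTIMANDS:
                eff = estimate_effect(
                    fit, contrast(form_id, e, n_steps=n_steps),
                    estimand=e, reference=ci_reference,
                )
                row[f"{e}_estimate"] = eff.estimate
                row[f"{e}_se"] = eff.se
                row[f"{e}_p"] = eff.p
        except Exception as exc:  # pragma: no cover - defensive per-row guard
            log.warning("formulation %s failed: %s", form_id, exc)
            row["converged"] = False
            row["error"] = str(exc)
        rows.append(row)
        log.info("reanalyze: %s done", form_id)
    return pd.DataFrame(rows)
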