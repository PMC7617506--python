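"""File formats: trial CSVs, truth JSON, cohort CSVs, run configuration.

Everything is long/tidy CSV with explicit unit columns, JSON for
manifests and summaries; no binary formats.  Schemas are versioned via
the ``schema`` key in the truth/manifest files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import SubjectDesign
from .trial import TrialDataset

__all__ = [
    "write_trial",
    "read_observations",
    "designs_from_frame",
    "designs_to_frame",
    "read_cohorts",
    "RunConfig",
    "write_manifest",
]

SCHEMA_VERSION = 1

_OBS_COLUMNS = ["subject", "matrix", "analyte", "time_h", "t_start_h",
                "t_end_h", "volume_ml", "value", "unit", "censored", "lod"]
_VALID_UNITS = {"blood": "ng/mL", "urine": "ng"}


def designs_to_frame(designs) -> pd.DataFrame:
    """Serialize subject designs to a tidy frame (one row per event)."""
    rows = []
    for d in designs:
        for t in d.blood_times_h:
            rows.append({"subject": d.subject, "bw_kg": d.bw_kg,
                         "dose_ng_per_kg": d.dose_ng_per_kg,
                         "event": "blood", "time_h": t,
                         "t_start_h": np.nan, "t_end_h": np.nan,
                         "volume_ml": np.nan})
        for (a, b), v in zip(d.urine_intervals_h, d.urine_volumes_ml):
            rows.append({"subject": d.subject, "bw_kg": d.bw_kg,
                         "dose_ng_per_kg": d.dose_ng_per_kg,
                         "event": "urine_void", "time_h": np.nan,
                         "t_start_h": a, "t_end_h": b, "volume_ml": v})
    return pd.DataFrame(rows)


def designs_from_frame(frame: pd.DataFrame) -> list[SubjectDesign]:
    designs = []
    for subject, grp in frame.groupby("subject", sort=False):
        blood = grp[grp["event"] == "blood"].sort_values("time_h")
        urine = grp[grp["event"] == "urine_void"].sort_values("t_start_h")
        designs.append(SubjectDesign(
            subject=str(subject),
            bw_kg=float(grp["bw_kg"].iloc[0]),
            dose_ng_per_kg=float(grp["dose_ng_per_kg"].iloc[0]),
            blood_times_h=blood["time_h"].to_numpy(),
            urine_intervals_h=urine[["t_start_h", "t_end_h"]].to_numpy(),
            urine_volumes_ml=urine["volume_ml"].to_numpy(),
        ))
    return designs


def write_trial(dataset: TrialDataset, directory) -> dict:
    """Write a trial as observations.csv + designs.csv (+ truth.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": directory / "observations.csv",
        "designs": directory / "designs.csv",
    }
    dataset.observations.to_csv(paths["observations"], index=False)
    designs_to_frame(dataset.designs).to_csv(paths["designs"], index=False)
    if dataset.truth is not None:
        paths["truth"] = directory / "truth.json"
        payload = {"schema": SCHEMA_VERSION, "seed": dataset.seed,
                   **dataset.truth}
        paths["truth"].write_text(json.dumps(payload, indent=1, default=float))
    return {k: str(v) for k, v in paths.items()}


def _schema_error(row_no: int, message: str) -> ValueError:
    return ValueError(f"observations row {row_no}: {message}")


def read_observations(obs_path, designs_path) -> TrialDataset:
    """Load and validate a trial dataset from its two CSV files.

    Raises a schema error with the offending row number on unit
    mismatches, negative values or malformed intervals; overlapping
    urine intervals are rejected by the design layer.
    """
    obs = pd.read_csv(obs_path)
    missing = set(_OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"observations file missing columns: {sorted(missing)}")
    for i, row in obs.iterrows():
        expected = _VALID_UNITS.get(row["matrix"])
        if expected is None:
            raise _schema_error(i, f"unknown matrix {row['matrix']!r}")
        if row["unit"] != expected:
            raise _schema_error(
                i, f"unit {row['unit']!r} invalid for {row['matrix']}"
                   f" (expected {expected!r})")
        if row["analyte"] not in ("free", "total"):
            raise _schema_error(i, f"unknown analyte {row['analyte']!r}")
        if not row["value"] > 0:
            raise _schema_error(i, "value must be positive")
        if row["matrix"] == "urine" and not \
                row["t_end_h"] > row["t_start_h"]:
            raise _schema_error(i, "urine interval end must exceed start")
    designs = designs_from_frame(pd.read_csv(designs_path))
    truth = None
    truth_path = Path(obs_path).parent / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return TrialDataset(designs=designs, observations=obs, truth=truth)


def read_cohorts(path) -> list:
    """Read biomonitoring cohorts from a tidy CSV.

    Columns: cohort, matrix, unit, value, and optional bw_kg /
    urine_24h_ml (constant within a cohort).
    """
    from .screening import CohortData

    df = pd.read_csv(path)
    required = {"cohort", "matrix", "unit", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    cohorts = []
    for name, grp in df.groupby("cohort", sort=False):
        kwargs = {}
        if "bw_kg" in grp and grp["bw_kg"].notna().any():
            kwargs["bw_kg"] = float(grp["bw_kg"].iloc[0])
        if "urine_24h_ml" in grp and grp["urine_24h_ml"].notna().any():
            kwargs["urine_24h_ml"] = float(grp["urine_24h_ml"].iloc[0])
        cohorts.append(CohortData(
            name=str(name), matrix=str(grp["matrix"].iloc[0]),
            values=grp["value"].to_numpy(dtype=float),
            unit=str(grp["unit"].iloc[0]), **kwargs))
    return cohorts


class RunConfig:
    """Validated run configuration loaded from a YAML file.

    Known sections: ``seed`` (int, required for stochastic stages),
    ``trial`` (generator overrides), ``mcmc`` (chains, iterations,
    burn_frac, thin), ``ittc`` (ITTCConfig overrides), ``screening``
    (ScreeningConstants overrides), ``monte_carlo`` (n_outer,
    n_inner).  Unknown keys are rejected.
    """

    _SECTIONS = {"seed", "trial", "mcmc", "ittc", "screening",
                 "monte_carlo"}

    def __init__(self, data: dict | None = None):
        data = data or {}
        unknown = set(data) - self._SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = data.get("seed", 0)
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        self.trial = dict(data.get("trial", {}))
        self.mcmc = {"n_chains": 4, "n_iter": 20_000, "burn_frac": 0.5,
                     "thin": 1, **data.get("mcmc", {})}
        self.ittc = dict(data.get("ittc", {}))
        self.screening = dict(data.get("screening", {}))
        self.monte_carlo = {"n_outer": 2000, "n_inner": 5000,
                            **data.get("monte_carlo", {})}
        self._raw = data

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self._raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_manifest(path, stage: str, seed, config: RunConfig | None = None,
                   outputs: dict | None = None) -> None:
    """Machine-readable record of one pipeline stage run."""
    import teatk

    payload = {
        "schema": SCHEMA_VERSION,
        "stage": stage,
        "seed": seed,
        "config_digest": config.digest() if config else None,
        "versions": {
            "teatk": teatk.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
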