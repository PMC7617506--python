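"""Synthetic single-bolus intervention trial generator.

Emulates a 10-subject trial in which each volunteer ingests an oral
bolus of TeA at 1500 ng/kg body weight and is then sampled for 48 h:
~13 capillary-blood samples (dense over the first 13 h, where free TeA
is detectable, then sparse to 48 h) and ~11 urine voids per subject,
each measured both unhydrolyzed ("free") and after enzymatic hydrolysis
("total" = free + glucuronides).  Individual kinetic parameters are
drawn lognormally around population geometric means, measurement error
is multiplicative lognormal, and values below the limit of detection
are left-censored (recorded at the LOD).  There is no fecal route.

The generator records the generating truth (individual parameters,
population GM/GSD vectors, error GSDs, seed) so that fits can be judged
by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    FRACTION_PARAMS,
    PARAM_NAMES,
    SubjectDesign,
    TKParams,
    observe,
    simulate_analytic,
)

__all__ = [
    "TrialDataset",
    "gen_population",
    "gen_trial",
    "default_truth_gm",
    "default_truth_gsd",
    "DEFAULT_BLOOD_TIMES",
    "DEFAULT_VOID_EDGES",
    "DEFAULT_ERROR_GSD",
    "DEFAULT_LOD",
]

#: default blood sampling schedule (h): dense over the detectability
#: window (~13 h for free TeA at the trial dose), sparse to 48 h
DEFAULT_BLOOD_TIMES = np.array(
    [0.083, 0.25, 0.75, 1.5, 2.5, 4.0, 6.0, 8.0, 10.0, 13.0, 18.0, 24.0, 48.0]
)

#: default urine void boundaries (h) -> 11 voids over 48 h
DEFAULT_VOID_EDGES = np.array(
    [0.0, 1.5, 3.0, 5.0, 7.0, 9.0, 12.0, 15.0, 20.0, 26.0, 36.0, 48.0]
)

#: multiplicative measurement-error GSD per observation class
DEFAULT_ERROR_GSD = {
    "blood_free": 1.25,
    "blood_total": 1.25,
    "urine_free": 1.20,
    "urine_total": 1.20,
}

#: limits of detection, as concentrations (ng/mL).  Urine LODs are
#: converted per void to a mass LOD via the void volume.
DEFAULT_LOD = {
    "blood_free": 0.02,
    "blood_total": 0.02,
    "urine_free": 1.0,
    "urine_total": 1.0,
}

OBS_CLASSES = ("blood_free", "blood_total", "urine_free", "urine_total")


def default_truth_gm() -> TKParams:
    """Default generating population geometric means.

    These are the study-like population values for TeA (clearances in
    L/(h·kg), volumes in L/kg, rates in 1/h); ``f_gluc`` is back-derived
    from the conjugate recovery fraction 0.077 = (1 - k_ufrac) * f_gluc.
    """
    return TKParams(
        cl_tot=1.58, vd=4.35, vd_met=7.36, cl_met=33.7,
        k_gutabs=23.9, k_ufrac=0.212, f_gluc=0.077 / (1 - 0.212),
    )


def default_truth_gsd() -> dict[str, float]:
    """Default inter-individual variability (population GSD) per parameter."""
    return {
        "cl_tot": 1.60, "vd": 1.67, "vd_met": 1.29, "k_umet": 1.16,
        "k_gutabs": 1.14, "k_ufrac": 1.49, "f_gluc": 1.95,
    }


@dataclass
class TrialDataset:
    """A simulated (or loaded) intervention-trial dataset.

    ``observations`` is a tidy frame with one row per measurement:
    columns ``subject, matrix, analyte, time_h, t_start_h, t_end_h,
    volume_ml, value, unit, censored, lod``.  Blood rows carry
    ``time_h`` and concentrations in ng/mL; urine rows carry the void
    interval and absolute masses in ng.  Censored rows carry
    ``value == lod``.  ``truth`` is None for real data.
    """

    designs: list[SubjectDesign]
    observations: pd.DataFrame
    truth: dict | None = None
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.designs)

    def subject_ids(self) -> list[str]:
        return [d.subject for d in self.designs]

    def counts(self) -> pd.DataFrame:
        """Observation counts per subject and class (for logs/manifests)."""
        df = self.observations
        key = df["matrix"] + "_" + df["analyte"]
        return df.assign(obs_class=key).pivot_table(
            index="subject", columns="obs_class", values="value",
            aggfunc="count", fill_value=0)


def _gsd_vector(pop_gsd) -> np.ndarray:
    if isinstance(pop_gsd, dict):
        missing = set(PARAM_NAMES) - set(pop_gsd)
        if missing:
            raise ValueError(f"pop_gsd missing parameters: {sorted(missing)}")
        vec = np.array([pop_gsd[n] for n in PARAM_NAMES], dtype=float)
    else:
        vec = np.asarray(pop_gsd, dtype=float)
    if vec.shape != (7,):
        raise ValueError("pop_gsd must supply one GSD per parameter")
    if (vec <= 0).any():
        raise ValueError("population GSDs must be positive")
    return vec


def gen_population(
    n_subjects: int,
    pop_gm: TKParams,
    pop_gsd,
    seed=None,
    rng: np.random.Generator | None = None,
) -> list[TKParams]:
    """Draw individual parameter vectors from the population model.

    Each parameter is lognormal around its population GM with the given
    GSD; fraction parameters (``k_ufrac``, ``f_gluc``) are resampled
    until they fall in (0, 1] (truncated lognormal).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gm = pop_gm.to_array()
    if (gm <= 0).any():
        raise ValueError("population GMs must be positive")
    sig = np.log(_gsd_vector(pop_gsd))
    frac_idx = [PARAM_NAMES.index(p) for p in FRACTION_PARAMS]
    out = []
    for _ in range(n_subjects):
        vec = gm * np.exp(sig * rng.standard_normal(7))
        for j in frac_idx:
            # truncation to (0, 1]: lognormals are positive, so only the
            # upper bound needs rejection sampling
            while vec[j] > 1.0:
                vec[j] = gm[j] * np.exp(sig[j] * rng.standard_normal())
        out.append(TKParams.from_array(vec))
    return out


def gen_trial(
    pop_gm: TKParams | None = None,
    pop_gsd=None,
    n_subjects: int = 10,
    dose_ng_per_kg: float = 1500.0,
    error_gsd: dict[str, float] | None = None,
    lod: dict[str, float] | None = None,
    blood_times=None,
    void_edges=None,
    seed: int | None = None,
) -> TrialDataset:
    """Generate a complete synthetic trial dataset.

    Body weights are drawn uniform on 55–95 kg and void volumes
    lognormal around 150 mL (GSD 1.3); the sampling schedule defaults to
    :data:`DEFAULT_BLOOD_TIMES` / :data:`DEFAULT_VOID_EDGES`.
    Observations get multiplicative lognormal noise with the per-class
    error GSD and are left-censored at the LOD.  ``error_gsd == 1``
    everywhere with ``lod == 0`` reproduces the noise-free predictions
    exactly.
    """
    if pop_gm is None:
        pop_gm = default_truth_gm()
    if pop_gsd is None:
        pop_gsd = default_truth_gsd()
    error_gsd = dict(DEFAULT_ERROR_GSD, **(error_gsd or {}))
    lod = dict(DEFAULT_LOD, **(lod or {}))
    for k, g in error_gsd.items():
        if g < 1:
            raise ValueError(f"error GSD for {k} must be >= 1, got {g}")
    if blood_times is None:
        blood_times = DEFAULT_BLOOD_TIMES
    if void_edges is None:
        void_edges = DEFAULT_VOID_EDGES
    blood_times = np.asarray(blood_times, dtype=float)
    void_edges = np.asarray(void_edges, dtype=float)
    intervals = np.column_stack([void_edges[:-1], void_edges[1:]])

    rng = np.random.default_rng(seed)
    individuals = gen_population(n_subjects, pop_gm, pop_gsd, rng=rng)
    gsd_vec = _gsd_vector(pop_gsd)

    designs, rows = [], []
    for i, params in enumerate(individuals):
        bw = rng.uniform(55.0, 95.0)
        volumes = 150.0 * np.exp(np.log(1.3) * rng.standard_normal(len(intervals)))
        design = SubjectDesign(
            subject=f"S{i + 1:02d}", bw_kg=bw, dose_ng_per_kg=dose_ng_per_kg,
            blood_times_h=blood_times, urine_intervals_h=intervals,
            urine_volumes_ml=volumes,
        )
        designs.append(design)
        traj = simulate_analytic(params, dose_ng_per_kg, blood_times)
        pred = observe(traj, design)
        for cls, values in [
            ("blood_free", pred.blood_free), ("blood_total", pred.blood_total),
            ("urine_free", pred.urine_free), ("urine_total", pred.urine_total),
        ]:
            matrix, analyte = cls.split("_")
            sig = np.log(error_gsd[cls])
            noisy = values * np.exp(sig * rng.standard_normal(values.size)) \
                if sig > 0 else values.copy()
            if matrix == "blood":
                lods = np.full(values.size, lod[cls])
            else:
                lods = lod[cls] * volumes  # conc LOD (ng/mL) -> mass (ng)
            censored = noisy < lods
            noisy = np.where(censored, lods, noisy)
            for j in range(values.size):
                row = {
                    "subject": design.subject, "matrix": matrix,
                    "analyte": analyte, "value": noisy[j],
                    "censored": bool(censored[j]), "lod": lods[j],
                }
                if matrix == "blood":
                    row.update(time_h=blood_times[j], t_start_h=np.nan,
                               t_end_h=np.nan, volume_ml=np.nan,
                               unit="ng/mL")
                else:
                    row.update(time_h=np.nan, t_start_h=intervals[j, 0],
                               t_end_h=intervals[j, 1],
                               volume_ml=volumes[j], unit="ng")
                rows.append(row)

    obs = pd.DataFrame(rows)
    truth = {
        "pop_gm": {n: v for n, v in zip(PARAM_NAMES, pop_gm.to_array())},
        "pop_gsd": {n: g for n, g in zip(PARAM_NAMES, gsd_vec)},
        "individuals": [
            {n: v for n, v in zip(PARAM_NAMES, p.to_array())}
            for p in individuals
        ],
        "error_gsd": dict(error_gsd),
        "lod": dict(lod),
        "dose_ng_per_kg": dose_ng_per_kg,
    }
    return TrialDataset(designs=designs, observations=obs, truth=truth,
                        seed=seed)
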