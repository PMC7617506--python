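"""Hierarchical Bayesian population TK model for TeA.

The model layers inter-individual variability over the deterministic
cascade in :mod:`teatk.kinetics`: each subject's log parameter vector is
normal around a population mean (so parameters are lognormal with a
population geometric mean GM and geometric standard deviation GSD), and
each observation — blood concentration or per-void urinary mass, free or
hydrolyzed-total — carries multiplicative lognormal measurement error
with a per-class error GSD.  Observations below the limit of detection
contribute the lognormal CDF at the LOD (left-censoring).

Posterior sampling uses adaptive Metropolis-within-Gibbs (the contract
is the posterior, not the algorithm): individual log parameters are
updated coordinate-wise against the subject likelihoods, population
means and log-scale SDs against the hierarchical density (with explicit
truncated-normal normalization for the fraction parameters), and the
four error GSDs against the pooled residuals.  Step sizes adapt only
during burn-in.

Usage follows the statsmodels convention::

    model = PopTKModel(dataset)            # or .from_dataframe(...)
    res = model.fit(n_chains=4, n_iter=20_000, seed=1)
    res.rhat()
    res.summary()
    res.posterior_predict(dataset.designs[0])
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .kinetics import (
    FRACTION_PARAMS,
    PARAM_NAMES,
    SubjectDesign,
    TKParams,
    observe,
    simulate_analytic,
    urine_interval_amounts,
)
from .sampling import StepAdapter, mh_accept
from .trial import OBS_CLASSES, TrialDataset

__all__ = [
    "PopulationPrior",
    "PopTKModel",
    "PopTKResults",
    "log_likelihood",
    "split_rhat",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_FRAC_IDX = tuple(PARAM_NAMES.index(p) for p in FRACTION_PARAMS)


def _safe_ratio(new: float, old: float) -> float:
    """Log posterior ratio robust to -inf states."""
    if np.isneginf(new):
        return -np.inf
    if np.isneginf(old):
        return np.inf
    return new - old


_I_CL = PARAM_NAMES.index("cl_tot")
_I_VD = PARAM_NAMES.index("vd")
_I_KA = PARAM_NAMES.index("k_gutabs")
#: parameters entering the absorption-dominance support constraint
_FLIP_IDX = (_I_CL, _I_VD, _I_KA)


def _support_ok(theta: np.ndarray) -> np.ndarray:
    """Absorption-dominance indicator k_gutabs > k_el on log parameters.

    The cascade likelihood is exactly invariant under exchanging the
    absorption and elimination rates with a compensating volume of
    distribution (the classic flip-flop ambiguity), so the model
    restricts individual parameters to the absorption-dominant branch
    — consistent with the early observed blood peak.
    """
    theta = np.atleast_2d(theta)
    return theta[:, _I_KA] > theta[:, _I_CL] - theta[:, _I_VD]


@dataclass(frozen=True)
class PopulationPrior:
    """Priors of the hierarchical population model.

    ``gm0``/``gsd0`` parameterize a lognormal prior on each population
    geometric mean (very diffuse by default, GSD 9.97); fraction
    parameters are truncated to (0.01, 1].  Population variability gets
    a half-normal prior on the log-scale SD (scale ``ln 2.5``), and the
    per-class error GSDs a log-uniform prior on
    ``error_gsd_bounds``.  All overridable.
    """

    gm0: dict = field(default_factory=lambda: {
        "cl_tot": 0.37, "vd": 0.30, "vd_met": 0.30, "k_umet": 0.5,
        "k_gutabs": 4.9, "k_ufrac": 0.5, "f_gluc": 0.5,
    })
    gsd0: dict = field(default_factory=lambda: {n: 9.97 for n in PARAM_NAMES})
    frac_bounds: tuple = (0.01, 1.0)
    pop_sd_scale: float = math.log(2.5)
    error_gsd_bounds: tuple = (1.01, 3.0)

    def __post_init__(self):
        missing = set(PARAM_NAMES) - set(self.gm0)
        if missing:
            raise ValueError(f"prior gm0 missing parameters: {missing}")
        for n in PARAM_NAMES:
            if not self.gm0[n] > 0:
                raise ValueError(f"prior GM for {n} must be positive")
            if not self.gsd0[n] > 1:
                raise ValueError(f"prior GSD for {n} must exceed 1")
        lo, hi = self.frac_bounds
        if not (0 < lo < hi <= 1):
            raise ValueError("fraction truncation bounds must satisfy 0<lo<hi<=1")
        lo, hi = self.error_gsd_bounds
        if not (1 < lo < hi):
            raise ValueError("error GSD bounds must be ordered and exceed 1")

    @classmethod
    def default(cls) -> "PopulationPrior":
        return cls()

    def mu0(self) -> np.ndarray:
        return np.log([self.gm0[n] for n in PARAM_NAMES])

    def tau0(self) -> np.ndarray:
        return np.log([self.gsd0[n] for n in PARAM_NAMES])


# ---------------------------------------------------------------------------
# data preparation


class _SubjectData:
    """Per-subject observation arrays laid out for fast likelihood evals."""

    def __init__(self, design: SubjectDesign, obs: pd.DataFrame):
        self.design = design
        self.bw = design.bw_kg
        self.dose = design.dose_ng_per_kg
        blood = obs[obs["matrix"] == "blood"]
        urine = obs[obs["matrix"] == "urine"]
        t_blood = np.unique(blood["time_h"].to_numpy(dtype=float)) \
            if len(blood) else np.empty(0)
        edges = np.unique(urine[["t_start_h", "t_end_h"]].to_numpy(dtype=float)) \
            if len(urine) else np.empty(0)
        self.t_all = np.unique(np.concatenate([t_blood, edges]))
        pos = {t: i for i, t in enumerate(self.t_all)}

        self.blood_idx = {}
        self.urine_idx = {}
        self.logv = {}
        self.cens = {}
        self.loglod = {}
        for cls in OBS_CLASSES:
            matrix, analyte = cls.split("_")
            sub = obs[(obs["matrix"] == matrix) & (obs["analyte"] == analyte)]
            vals = sub["value"].to_numpy(dtype=float)
            if (vals <= 0).any():
                raise ValueError("observed values must be positive")
            self.logv[cls] = np.log(vals)
            self.cens[cls] = sub["censored"].to_numpy(dtype=bool)
            with np.errstate(divide="ignore"):
                self.loglod[cls] = np.log(sub["lod"].to_numpy(dtype=float))
            if matrix == "blood":
                self.blood_idx[cls] = np.array(
                    [pos[t] for t in sub["time_h"]], dtype=int)
            else:
                self.urine_idx[cls] = (
                    np.array([pos[a] for a in sub["t_start_h"]], dtype=int),
                    np.array([pos[b] for b in sub["t_end_h"]], dtype=int),
                )

    def predict_log(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        """Log predictions per observation class for a natural-scale
        parameter vector in :data:`PARAM_NAMES` order.

        Reference (per-subject) path: routed through the kinetics
        module so it agrees with :func:`teatk.kinetics.observe` exactly.
        """
        params = TKParams.from_array(vec)
        out = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.blood_idx:
                times = self.t_all
                traj = simulate_analytic(params, self.dose, times)
                series = {"blood_free": traj.c_free,
                          "blood_total": traj.c_total}
                for cls, idx in self.blood_idx.items():
                    out[cls] = np.log(series[cls][idx])
            for cls, (ia, ib) in self.urine_idx.items():
                intervals = np.column_stack([self.t_all[ia], self.t_all[ib]])
                free, total = urine_interval_amounts(params, self.dose,
                                                     intervals)
                amounts = free if cls == "urine_free" else total
                out[cls] = np.log(amounts * self.bw)
        return out

    def loglik(self, logpred: dict[str, np.ndarray], esd: np.ndarray) -> float:
        """Censored lognormal log likelihood given cached log predictions.

        ``esd[c]`` is the log-scale error SD (= ln error GSD) of class
        ``c``.  The density is that of the log residual, i.e. the
        constant data Jacobian of the lognormal is dropped; it does not
        involve any sampled parameter.
        """
        total = 0.0
        for ci, cls in enumerate(OBS_CLASSES):
            if cls not in logpred:
                continue
            lp = logpred[cls]
            sig = esd[ci]
            cens = self.cens[cls]
            if (~np.isfinite(lp) & ~cens).any():
                return -np.inf
            r = self.logv[cls][~cens] - lp[~cens]
            total += -r.size * (math.log(sig) + _LOG_SQRT_2PI) \
                - 0.5 * float(r @ r) / sig**2
            if cens.any():
                margin = self.loglod[cls][cens] - lp[cens]
                # a prediction that has decayed to zero is certainly
                # below the LOD: log CDF -> 0
                finite = np.isfinite(margin)
                total += float(log_ndtr(margin[finite] / sig).sum())
        return total


def _dataset_subjects(dataset: TrialDataset) -> list[_SubjectData]:
    out = []
    obs = dataset.observations
    for design in dataset.designs:
        out.append(_SubjectData(design, obs[obs["subject"] == design.subject]))
    return out


class _StackedData:
    """All subjects stacked into (n_subjects, n_obs) arrays.

    Possible when every subject shares the same sampling schedule (the
    default synthetic design); enables one vectorized likelihood
    evaluation across subjects per proposal coordinate.  Falls back to
    the per-subject path otherwise.  Observations are laid out in a
    fixed column order (class blocks); censored and uncensored entries
    are pre-indexed flat so the likelihood is two gather–scatter passes.
    """

    def __init__(self, subjects: list[_SubjectData]):
        ref = subjects[0]
        self.t = ref.t_all[None, :]                      # (1, m)
        self.n = len(subjects)
        self.dose = np.array([s.dose for s in subjects])[:, None]
        self.bw = np.array([s.bw for s in subjects])[:, None]
        self.blood_idx = ref.blood_idx
        self.urine_idx = ref.urine_idx

        # fixed column layout: concatenated class blocks
        self.classes = [c for c in OBS_CLASSES if c in ref.logv]
        self.col_slice = {}
        start = 0
        for c in self.classes:
            width = ref.logv[c].size
            self.col_slice[c] = slice(start, start + width)
            start += width
        self.m_cols = start
        logv = np.full((self.n, start), np.nan)
        loglod = np.full((self.n, start), np.nan)
        cens = np.zeros((self.n, start), dtype=bool)
        col_class = np.empty(start, dtype=int)
        for c in self.classes:
            sl = self.col_slice[c]
            col_class[sl] = OBS_CLASSES.index(c)
            for i, s in enumerate(subjects):
                logv[i, sl] = s.logv[c]
                loglod[i, sl] = s.loglod[c]
                cens[i, sl] = s.cens[c]
        unc = ~cens
        self.unc_rows, self.unc_cols = np.nonzero(unc)
        self.cen_rows, self.cen_cols = np.nonzero(cens)
        self.unc_class = col_class[self.unc_cols]
        self.cen_class = col_class[self.cen_cols]
        self.unc_logv = logv[unc]
        self.cen_loglod = loglod[cens]

    @staticmethod
    def compatible(subjects: list[_SubjectData]) -> bool:
        ref = subjects[0]
        for s in subjects[1:]:
            if s.t_all.shape != ref.t_all.shape or \
                    not np.array_equal(s.t_all, ref.t_all):
                return False
            for c in OBS_CLASSES:
                if (c in ref.logv) != (c in s.logv):
                    return False
                if c in ref.logv and s.logv[c].shape != ref.logv[c].shape:
                    return False
            for c in ref.blood_idx:
                if not np.array_equal(s.blood_idx[c], ref.blood_idx[c]):
                    return False
            for c in ref.urine_idx:
                if not (np.array_equal(s.urine_idx[c][0], ref.urine_idx[c][0])
                        and np.array_equal(s.urine_idx[c][1],
                                           ref.urine_idx[c][1])):
                    return False
        return True

    def _sep(self, a, b):
        # vectorized epsilon-separation of near-coincident rates
        coincident = np.abs(a - b) <= _RATE_SEP_V * np.maximum(a, b)
        return np.where(coincident, b * (1.0 + _RATE_NUDGE_V), b)

    def predict_log(self, vecs: np.ndarray) -> dict[str, np.ndarray]:
        """Log predictions per class for natural-scale params (n, 7)."""
        cl_tot = vecs[:, 0:1]
        vd = vecs[:, 1:2]
        vd_met = vecs[:, 2:3]
        kum = vecs[:, 3:4]
        ka = vecs[:, 4:5]
        k_ufrac = vecs[:, 5:6]
        f_gluc = vecs[:, 6:7]
        kel = cl_tot / vd
        kel = self._sep(ka, kel)
        kum = self._sep(ka, self._sep(kel, kum))
        k_u = k_ufrac * kel
        k_met = (1.0 - k_ufrac) * kel
        t = self.t
        e_ka = np.exp(-ka * t)
        e_kel = np.exp(-kel * t)
        e_kum = np.exp(-kum * t)
        c_ka = self.dose * ka / (kel - ka)
        a_central = c_ka * (e_ka - e_kel)
        d_ka = k_met * c_ka / (kum - ka)
        d_kel = -k_met * c_ka / (kum - kel)
        d_kum = -(d_ka + d_kel)
        a_met = d_ka * e_ka + d_kel * e_kel + d_kum * e_kum
        c_free = a_central / vd / 1000.0
        c_total = c_free + f_gluc * a_met / vd_met / 1000.0
        out = np.empty((vecs.shape[0], self.m_cols))
        with np.errstate(divide="ignore", invalid="ignore"):
            for cls, series in (("blood_free", c_free), ("blood_total", c_total)):
                if cls in self.blood_idx:
                    out[:, self.col_slice[cls]] = \
                        np.log(series[:, self.blood_idx[cls]])
            # urinary voids: difference the exponential terms directly
            # (stable for late voids at the cumulative asymptote)
            for cls in self.urine_idx:
                ia, ib = self.urine_idx[cls]
                f_ka = e_ka[:, ia] - e_ka[:, ib]
                f_kel = e_kel[:, ia] - e_kel[:, ib]
                dq_u = k_u * (c_ka * f_ka / ka - c_ka * f_kel / kel)
                if cls == "urine_free":
                    amounts = dq_u
                else:
                    f_kum = e_kum[:, ia] - e_kum[:, ib]
                    dq_umet = kum * (d_ka * f_ka / ka + d_kel * f_kel / kel
                                     + d_kum * f_kum / kum)
                    amounts = dq_u + f_gluc * dq_umet
                out[:, self.col_slice[cls]] = np.log(amounts * self.bw)
        return out

    def loglik(self, logpred: np.ndarray, esd: np.ndarray) -> np.ndarray:
        """Per-subject censored lognormal log likelihood, shape (n,)."""
        logsig = np.log(esd)
        lp_u = logpred[self.unc_rows, self.unc_cols]
        sig_u = esd[self.unc_class]
        with np.errstate(invalid="ignore"):
            r = (self.unc_logv - lp_u) / sig_u
            dens = -logsig[self.unc_class] - _LOG_SQRT_2PI - 0.5 * r * r
        dens = np.where(np.isfinite(lp_u), dens, -np.inf)
        total = np.bincount(self.unc_rows, weights=dens, minlength=self.n)
        if self.cen_rows.size:
            lp_c = logpred[self.cen_rows, self.cen_cols]
            with np.errstate(invalid="ignore"):
                margin = (self.cen_loglod - lp_c) / esd[self.cen_class]
            # prediction decayed to zero => certainly below LOD
            terms = np.where(np.isfinite(lp_c), log_ndtr(margin), 0.0)
            total += np.bincount(self.cen_rows, weights=terms,
                                 minlength=self.n)
        return total


_RATE_SEP_V = 1e-9
_RATE_NUDGE_V = 1e-7


def log_likelihood(dataset: TrialDataset, individual_params, error_gsds) -> float:
    """Data log likelihood for given individual parameters and error GSDs.

    Reference implementation routed through :func:`teatk.kinetics.observe`
    (the sampler uses an equivalent cached fast path).  ``error_gsds``
    maps observation class (e.g. ``"blood_free"``) to its multiplicative
    error GSD; censored observations contribute the lognormal log-CDF at
    the LOD, and a non-positive prediction for an uncensored observation
    yields ``-inf`` rather than an exception.
    """
    if len(individual_params) != dataset.n_subjects:
        raise ValueError("need one parameter vector per subject")
    esd = np.array([math.log(error_gsds[c]) for c in OBS_CLASSES])
    if (esd <= 0).any():
        raise ValueError("error GSDs must exceed 1")
    total = 0.0
    obs = dataset.observations
    for design, params in zip(dataset.designs, individual_params):
        sub = obs[obs["subject"] == design.subject]
        traj = simulate_analytic(params, design.dose_ng_per_kg,
                                 design.blood_times_h)
        pred = observe(traj, design)
        pred_map = {
            "blood_free": dict(zip(design.blood_times_h, pred.blood_free)),
            "blood_total": dict(zip(design.blood_times_h, pred.blood_total)),
            "urine_free": {tuple(iv): v for iv, v in
                           zip(design.urine_intervals_h, pred.urine_free)},
            "urine_total": {tuple(iv): v for iv, v in
                            zip(design.urine_intervals_h, pred.urine_total)},
        }
        for _, row in sub.iterrows():
            cls = f"{row['matrix']}_{row['analyte']}"
            ci = OBS_CLASSES.index(cls)
            if row["matrix"] == "blood":
                p = pred_map[cls][row["time_h"]]
            else:
                p = pred_map[cls][(row["t_start_h"], row["t_end_h"])]
            sig = esd[ci]
            if row["censored"]:
                if p <= 0:
                    continue  # certainly below LOD
                total += float(log_ndtr(
                    (math.log(row["lod"]) - math.log(p)) / sig))
            else:
                if p <= 0:
                    return -np.inf
                r = math.log(row["value"]) - math.log(p)
                total += -math.log(sig) - _LOG_SQRT_2PI - 0.5 * r * r / sig**2
    return total


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Classic split-chain Gelman–Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); each chain is split in
    half, so diagnosing within-chain nonstationarity as well.  Constant
    identical chains give 1.0; constant but different chains give inf.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    m, n = x.shape
    if m < 2:
        raise ValueError("at least two chains are required for R-hat")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    w = splits.var(axis=1, ddof=1).mean()
    b = splits.mean(axis=1).var(ddof=1)  # = B/n in Gelman-Rubin notation
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (half - 1) / half * w + b
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# model


class PopTKModel:
    """Hierarchical Bayesian population TK model (statsmodels-style).

    Parameters
    ----------
    dataset : TrialDataset
        Observations plus per-subject designs (synthetic via
        :func:`teatk.trial.gen_trial` or loaded via
        :func:`teatk.io.read_observations`).
    prior : PopulationPrior, optional
    """

    def __init__(self, dataset: TrialDataset,
                 prior: PopulationPrior | None = None):
        if dataset.n_subjects < 2:
            raise ValueError("population fitting requires at least 2 subjects")
        if bool(dataset.observations["censored"].all()):
            raise ValueError("no informative observations: all data censored")
        self.dataset = dataset
        self.prior = prior or PopulationPrior.default()
        self.subjects = _dataset_subjects(dataset)
        self.n_subjects = len(self.subjects)
        self.stacked = _StackedData(self.subjects) \
            if _StackedData.compatible(self.subjects) else None

    @classmethod
    def from_dataframe(cls, observations: pd.DataFrame, designs,
                       prior: PopulationPrior | None = None) -> "PopTKModel":
        """Build from a tidy observation frame and a design list/frame."""
        from .io import designs_from_frame
        if isinstance(designs, pd.DataFrame):
            designs = designs_from_frame(designs)
        return cls(TrialDataset(designs=list(designs),
                                observations=observations), prior=prior)

    # -- hierarchical log densities -------------------------------------

    def _hier_logpdf(self, theta_p: np.ndarray, mu: float, sig: float,
                     truncated: bool) -> np.ndarray:
        """Per-subject log density of log individual params given (mu, sig)."""
        z = (theta_p - mu) / sig
        lp = -np.log(sig) - _LOG_SQRT_2PI - 0.5 * z * z
        if truncated:
            lp = lp - log_ndtr(-mu / sig)  # normalization of theta <= 0
        return lp

    def _mu_prior(self, p: int, mu: float) -> float:
        m0, t0 = self._mu0[p], self._tau0[p]
        if p in _FRAC_IDX:
            lo, hi = self.prior.frac_bounds
            if not (math.log(lo) < mu <= math.log(hi)):
                return -np.inf
        z = (mu - m0) / t0
        return -0.5 * z * z

    def _sigma_prior(self, sig: float) -> float:
        # half-normal on the log-scale SD
        return -0.5 * (sig / self.prior.pop_sd_scale) ** 2

    def _log_p_support(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        """Log probability that a new individual is absorption-dominant.

        Normalization of the truncated hierarchical density induced by
        the k_gutabs > k_el support restriction (see
        :func:`_support_ok`); under independent log-scale normals the
        constraint is a linear combination, hence a probit.
        """
        z = (mu[_I_KA] - mu[_I_CL] + mu[_I_VD]) / math.sqrt(
            sigma[_I_KA] ** 2 + sigma[_I_CL] ** 2 + sigma[_I_VD] ** 2)
        return float(log_ndtr(z))

    # -- fitting ----------------------------------------------------------

    def fit(self, n_chains: int = 4, n_iter: int = 20_000,
            burn_frac: float = 0.5, seed: int | None = None,
            thin: int = 1, progress: bool = False) -> "PopTKResults":
        """Run MCMC and return a :class:`PopTKResults`.

        ``n_iter`` counts total iterations per chain; the first
        ``burn_frac`` fraction is discarded and adaptation of proposal
        steps happens only there.
        """
        if n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if n_iter < 1000:
            raise ValueError("n_iter must be at least 1000")
        self._mu0 = self.prior.mu0()
        self._tau0 = self.prior.tau0()
        seeds = np.random.SeedSequence(seed).spawn(n_chains)
        chains = [self._run_chain(np.random.default_rng(s), n_iter,
                                  burn_frac, thin, progress)
                  for s in seeds]
        stacked = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
        return PopTKResults(
            model=self, draws=stacked, n_chains=n_chains, n_iter=n_iter,
            burn_frac=burn_frac, seed=seed, thin=thin,
        )

    def _nca_init(self) -> np.ndarray:
        """Crude noncompartmental starting values per subject (log scale).

        Initialization only — a correct chain forgets its start; this
        merely shortens burn-in.  Per subject: clearance from the
        trapezoid AUC of uncensored free blood samples (+ terminal-slope
        tail), elimination rate from the terminal log-linear slope,
        urinary fraction from cumulative free urine recovery, and the
        conjugate recovery for ``f_gluc``.  Failures fall back to the
        prior medians.
        """
        inits = np.empty((self.n_subjects, 7))
        for i, s in enumerate(self.subjects):
            vec = np.exp(self._mu0.copy())
            dose, bw = s.dose, s.bw
            try:
                cls = "blood_free"
                keep = ~s.cens[cls]
                t = s.t_all[s.blood_idx[cls]][keep]
                c = np.exp(s.logv[cls][keep])
                kel = 0.4
                if keep.sum() >= 4:
                    tail = slice(-min(4, keep.sum() - 1), None)
                    slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
                    if slope < -1e-3:
                        kel = -slope
                if keep.sum() >= 3:
                    auc = np.trapezoid(c, t) * 1000.0 + c[-1] * 1000.0 / kel
                    vec[_I_CL] = np.clip(dose / auc, 1e-3, 1e3)
                vec[_I_VD] = np.clip(vec[_I_CL] / kel, 1e-3, 1e3)
                vec[_I_KA] = max(3.0 * kel, 5.0)
                if "urine_free" in s.urine_idx:
                    rec = np.exp(s.logv["urine_free"]).sum() / (dose * bw)
                    vec[PARAM_NAMES.index("k_ufrac")] = np.clip(rec, 0.02, 0.95)
                    if "urine_total" in s.urine_idx:
                        conj = (np.exp(s.logv["urine_total"]).sum()
                                - np.exp(s.logv["urine_free"]).sum()) / (dose * bw)
                        f_gluc = conj / max(1.0 - rec, 0.05)
                        vec[PARAM_NAMES.index("f_gluc")] = np.clip(
                            f_gluc, 0.02, 0.95)
            except (ValueError, KeyError):
                pass
            inits[i] = np.log(vec)
        return inits

    def _init_state(self, rng):
        n = self.n_subjects
        base = self._nca_init()
        theta = base + 0.3 * rng.standard_normal((n, 7))
        mu = theta.mean(axis=0) + 0.3 * rng.standard_normal(7)
        for p in _FRAC_IDX:
            lo, hi = self.prior.frac_bounds
            mu[p] = np.clip(mu[p], math.log(lo) + 1e-6, math.log(hi) - 1e-9)
            theta[:, p] = np.minimum(theta[:, p], -1e-6)
        sigma = np.maximum(theta.std(axis=0), 0.15) \
            * np.exp(0.3 * rng.standard_normal(7))
        # place initial states on the absorption-dominant branch
        kel0 = theta[:, _I_CL] - theta[:, _I_VD]
        bad = ~_support_ok(theta)
        theta[bad, _I_KA] = kel0[bad] + 0.5 + np.abs(rng.standard_normal(bad.sum()))
        lo, hi = np.log(np.log(self.prior.error_gsd_bounds[0])), \
            np.log(np.log(self.prior.error_gsd_bounds[1]))
        esd = np.exp(rng.uniform(lo, hi, 4))
        return mu, sigma, theta, esd

    def _subject_predict(self, theta_nat: np.ndarray) -> dict:
        """Log predictions for all subjects; theta_nat is (n, 7) natural."""
        if self.stacked is not None:
            return self.stacked.predict_log(theta_nat)
        per = [s.predict_log(theta_nat[i])
               for i, s in enumerate(self.subjects)]
        return {"_per_subject": per}

    def _subject_loglik(self, logpred, esd) -> np.ndarray:
        if self.stacked is not None:
            return self.stacked.loglik(logpred, esd)
        return np.array([s.loglik(lp, esd) for s, lp in
                         zip(self.subjects, logpred["_per_subject"])])

    @staticmethod
    def _merge_logpred(cache, new, accepted_rows):
        if isinstance(cache, dict):
            for i in np.nonzero(accepted_rows)[0]:
                cache["_per_subject"][i] = new["_per_subject"][i]
        else:
            cache[accepted_rows] = new[accepted_rows]

    def _run_chain(self, rng, n_iter, burn_frac, thin, progress):
        n = self.n_subjects
        mu, sigma, theta, esd = self._init_state(rng)
        logpred = self._subject_predict(np.exp(theta))
        sub_ll = self._subject_loglik(logpred, esd)

        ad_theta = StepAdapter((n, 7), step0=0.3)
        ad_mu = StepAdapter(7, step0=0.3)
        ad_lsig = StepAdapter(7, step0=0.3)
        ad_esd = StepAdapter(4, step0=0.2)
        ad_tr = StepAdapter(7, step0=0.2)
        ad_pair = StepAdapter(n, step0=0.2)
        ad_pair_pop = StepAdapter(1, step0=0.2)

        n_burn = int(n_iter * burn_frac)
        keep = (n_iter - n_burn) // thin
        out = {
            "mu": np.empty((keep, 7)), "sigma": np.empty((keep, 7)),
            "theta": np.empty((keep, n, 7)), "esd": np.empty((keep, 4)),
        }
        esd_lo = math.log(self.prior.error_gsd_bounds[0])
        esd_hi = math.log(self.prior.error_gsd_bounds[1])
        stored = 0
        accept_log = {"theta": 0.0, "n_theta": 0}

        for it in range(n_iter):
            if it == n_burn:
                for ad in (ad_theta, ad_mu, ad_lsig, ad_esd):
                    ad.freeze()

            # individual parameters, coordinate-wise across subjects
            acc_theta = np.zeros((n, 7))
            for p in range(7):
                prop = theta[:, p] + ad_theta.step[:, p] * rng.standard_normal(n)
                valid = np.ones(n, dtype=bool)
                if p in _FRAC_IDX:
                    valid = prop <= 0.0
                theta_new = theta.copy()
                theta_new[valid, p] = prop[valid]
                if p in _FLIP_IDX:
                    valid &= _support_ok(theta_new)
                    theta_new[~valid, p] = theta[~valid, p]
                lp_new = self._subject_predict(np.exp(theta_new))
                ll_new = self._subject_loglik(lp_new, esd)
                z_old = (theta[:, p] - mu[p]) / sigma[p]
                z_new = (theta_new[:, p] - mu[p]) / sigma[p]
                with np.errstate(invalid="ignore"):
                    dlog = ll_new - sub_ll - 0.5 * (z_new**2 - z_old**2)
                # a chain stuck at -inf accepts any finite proposal
                dlog = np.where(np.isneginf(ll_new), -np.inf,
                                np.where(np.isneginf(sub_ll), np.inf, dlog))
                acc = valid & mh_accept(rng, dlog)
                if acc.any():
                    theta[acc, p] = prop[acc]
                    self._merge_logpred(logpred, lp_new, acc)
                    sub_ll[acc] = ll_new[acc]
                    acc_theta[acc, p] = 1.0
            ad_theta.record(acc_theta)
            if it >= n_burn:
                accept_log["theta"] += acc_theta.mean()
                accept_log["n_theta"] += 1

            # population means
            acc_mu = np.zeros(7)
            for p in range(7):
                trunc = p in _FRAC_IDX
                prop = mu[p] + ad_mu.step[p] * rng.standard_normal()
                pr_new = self._mu_prior(p, prop)
                if np.isfinite(pr_new):
                    cur = self._hier_logpdf(theta[:, p], mu[p], sigma[p],
                                            trunc).sum() + self._mu_prior(p, mu[p])
                    new = self._hier_logpdf(theta[:, p], prop, sigma[p],
                                            trunc).sum() + pr_new
                    if p in _FLIP_IDX:
                        mu_new = mu.copy()
                        mu_new[p] = prop
                        cur -= n * self._log_p_support(mu, sigma)
                        new -= n * self._log_p_support(mu_new, sigma)
                    if mh_accept(rng, new - cur):
                        mu[p] = prop
                        acc_mu[p] = 1.0
            ad_mu.record(acc_mu)

            # population log-scale SDs (random walk on ln sigma)
            acc_s = np.zeros(7)
            for p in range(7):
                trunc = p in _FRAC_IDX
                lsig_new = math.log(sigma[p]) + ad_lsig.step[p] * rng.standard_normal()
                sig_new = math.exp(lsig_new)
                cur = self._hier_logpdf(theta[:, p], mu[p], sigma[p], trunc).sum() \
                    + self._sigma_prior(sigma[p]) + math.log(sigma[p])
                new = self._hier_logpdf(theta[:, p], mu[p], sig_new, trunc).sum() \
                    + self._sigma_prior(sig_new) + lsig_new
                if p in _FLIP_IDX:
                    sig_vec_new = sigma.copy()
                    sig_vec_new[p] = sig_new
                    cur -= n * self._log_p_support(mu, sigma)
                    new -= n * self._log_p_support(mu, sig_vec_new)
                if mh_accept(rng, new - cur):
                    sigma[p] = sig_new
                    acc_s[p] = 1.0
            ad_lsig.record(acc_s)

            # error GSDs (flat prior on ln gsd within bounds)
            acc_e = np.zeros(4)
            for c in range(4):
                prop = esd[c] + ad_esd.step[c] * rng.standard_normal()
                if esd_lo <= prop <= esd_hi:
                    esd_new = esd.copy()
                    esd_new[c] = prop
                    ll_new = self._subject_loglik(logpred, esd_new)
                    new_tot, old_tot = ll_new.sum(), sub_ll.sum()
                    ratio = -np.inf if np.isneginf(new_tot) else (
                        np.inf if np.isneginf(old_tot) else new_tot - old_tot)
                    if mh_accept(rng, ratio):
                        esd = esd_new
                        sub_ll = ll_new
                        acc_e[c] = 1.0
            ad_esd.record(acc_e)

            # joint translation of one population mean together with all
            # individual values (ridge move: the mean conditional is
            # tight around the individual average, so moving them
            # together mixes along the hierarchy)
            p = it % 7
            delta = ad_tr.step[p] * rng.standard_normal()
            mu_t = mu[p] + delta
            th_t = theta[:, p] + delta
            ok = True
            if p in _FRAC_IDX:
                ok = (th_t <= 0.0).all()
            if p in _FLIP_IDX:
                theta_try = theta.copy()
                theta_try[:, p] = th_t
                ok = ok and bool(_support_ok(theta_try).all())
            pr_new = self._mu_prior(p, mu_t)
            if ok and np.isfinite(pr_new):
                theta_new = theta.copy()
                theta_new[:, p] = th_t
                lp_new = self._subject_predict(np.exp(theta_new))
                ll_new = self._subject_loglik(lp_new, esd)
                mu_new = mu.copy()
                mu_new[p] = mu_t
                dlog = _safe_ratio(ll_new.sum(), sub_ll.sum()) \
                    + pr_new - self._mu_prior(p, mu[p])
                if p in _FRAC_IDX:
                    dlog += n * (log_ndtr(-mu[p] / sigma[p])
                                 - log_ndtr(-mu_t / sigma[p]))
                if p in _FLIP_IDX:
                    dlog += n * (self._log_p_support(mu, sigma)
                                 - self._log_p_support(mu_new, sigma))
                accepted = bool(mh_accept(rng, dlog))
                if accepted:
                    mu[p] = mu_t
                    theta[:, p] = th_t
                    self._merge_logpred(logpred, lp_new,
                                        np.ones(n, dtype=bool))
                    sub_ll = ll_new
                ad_tr.record(float(accepted), active=np.arange(7) == p)

            # (cl_tot, vd) pair moves along the fixed-k_el ridge: either
            # coordinate alone changes the elimination rate and is vetoed
            # by well-fit urinary data, so the pair must move together.
            delta = ad_pair.step * rng.standard_normal(n)
            theta_new = theta.copy()
            theta_new[:, _I_CL] += delta
            theta_new[:, _I_VD] += delta
            lp_new = self._subject_predict(np.exp(theta_new))
            ll_new = self._subject_loglik(lp_new, esd)
            dprior = np.zeros(n)
            for q in (_I_CL, _I_VD):
                z_new = (theta_new[:, q] - mu[q]) / sigma[q]
                z_old = (theta[:, q] - mu[q]) / sigma[q]
                dprior += -0.5 * (z_new**2 - z_old**2)
            with np.errstate(invalid="ignore"):
                dlog = ll_new - sub_ll + dprior
            dlog = np.where(np.isneginf(ll_new), -np.inf,
                            np.where(np.isneginf(sub_ll), np.inf, dlog))
            acc = mh_accept(rng, dlog)
            if acc.any():
                theta[acc] = theta_new[acc]
                self._merge_logpred(logpred, lp_new, acc)
                sub_ll[acc] = ll_new[acc]
            ad_pair.record(acc.astype(float))

            # population-level pair translation (mu and all theta move
            # together; hierarchy and support terms cancel)
            delta = float(ad_pair_pop.step[0] * rng.standard_normal())
            theta_new = theta.copy()
            theta_new[:, _I_CL] += delta
            theta_new[:, _I_VD] += delta
            mu_new = mu.copy()
            mu_new[_I_CL] += delta
            mu_new[_I_VD] += delta
            lp_new = self._subject_predict(np.exp(theta_new))
            ll_new = self._subject_loglik(lp_new, esd)
            dlog = _safe_ratio(ll_new.sum(), sub_ll.sum()) \
                + self._mu_prior(_I_CL, mu_new[_I_CL]) \
                - self._mu_prior(_I_CL, mu[_I_CL]) \
                + self._mu_prior(_I_VD, mu_new[_I_VD]) \
                - self._mu_prior(_I_VD, mu[_I_VD])
            accepted = bool(mh_accept(rng, dlog))
            if accepted:
                theta = theta_new
                mu = mu_new
                self._merge_logpred(logpred, lp_new, np.ones(n, dtype=bool))
                sub_ll = ll_new
            ad_pair_pop.record(np.array([float(accepted)]))

            if it >= n_burn and (it - n_burn) % thin == 0 and stored < keep:
                out["mu"][stored] = mu
                out["sigma"][stored] = sigma
                out["theta"][stored] = theta
                out["esd"][stored] = esd
                stored += 1
            if progress and (it + 1) % max(n_iter // 10, 1) == 0:
                print(f"  iter {it + 1}/{n_iter}")

        if accept_log["n_theta"]:
            out["accept_theta"] = np.array(
                [accept_log["theta"] / accept_log["n_theta"]])
        return out


# ---------------------------------------------------------------------------
# results


@dataclass
class PopTKResults:
    """Posterior draws of the population TK fit plus diagnostics.

    ``draws`` maps ``mu``/``sigma`` (log-scale population mean / SD,
    shape (chains, kept, 7)), ``theta`` (individual log parameters,
    (chains, kept, n_subjects, 7)) and ``esd`` (log-scale error SDs,
    (chains, kept, 4)).
    """

    model: PopTKModel
    draws: dict
    n_chains: int
    n_iter: int
    burn_frac: float
    seed: int | None
    thin: int

    # -- accessors --------------------------------------------------------

    @property
    def n_kept(self) -> int:
        return self.draws["mu"].shape[1]

    def population_gm(self) -> np.ndarray:
        """Population geometric means, shape (chains, kept, 7)."""
        return np.exp(self.draws["mu"])

    def population_gsd(self) -> np.ndarray:
        """Population geometric SDs, shape (chains, kept, 7)."""
        return np.exp(self.draws["sigma"])

    def error_gsd(self) -> np.ndarray:
        return np.exp(self.draws["esd"])

    def individual_params(self, i: int) -> np.ndarray:
        """Natural-scale parameter draws for subject i, (chains, kept, 7)."""
        return np.exp(self.draws["theta"][:, :, i, :])

    # -- diagnostics ------------------------------------------------------

    def rhat(self) -> pd.Series:
        """Split-chain Gelman–Rubin statistic per population parameter."""
        vals = {}
        for p, name in enumerate(PARAM_NAMES):
            vals[f"gm_{name}"] = split_rhat(self.draws["mu"][:, :, p])
            vals[f"gsd_{name}"] = split_rhat(self.draws["sigma"][:, :, p])
        for c, cls in enumerate(OBS_CLASSES):
            vals[f"err_{cls}"] = split_rhat(self.draws["esd"][:, :, c])
        return pd.Series(vals, name="rhat")

    @property
    def converged(self) -> bool:
        """True when all population-level R-hat values are <= 1.2."""
        return bool((self.rhat() <= 1.2).all())

    # -- summaries --------------------------------------------------------

    def _derived_gm_draws(self) -> dict[str, np.ndarray]:
        gm = self.population_gm().reshape(-1, 7)
        cols = {n: gm[:, i] for i, n in enumerate(PARAM_NAMES)}
        d = {
            "cl_met": cols["k_umet"] * cols["vd_met"],
            "k_el": cols["cl_tot"] / cols["vd"],
            "t_half": np.log(2.0) * cols["vd"] / cols["cl_tot"],
            "auc_1500": 1500.0 / cols["cl_tot"],
            "mat": 1.0 / cols["k_gutabs"],
            "f_met": (1.0 - cols["k_ufrac"]) * cols["f_gluc"],
        }
        return {**cols, **d}

    def _derived_gsd_draws(self) -> dict[str, np.ndarray]:
        gsd = self.population_gsd().reshape(-1, 7)
        s = {n: np.log(gsd[:, i]) for i, n in enumerate(PARAM_NAMES)}
        comb = lambda *ls: np.exp(np.sqrt(sum(x**2 for x in ls)))
        d = {n: np.exp(s[n]) for n in PARAM_NAMES}
        # ratio/product parameters combine log-variances (independence)
        d["cl_met"] = comb(s["k_umet"], s["vd_met"])
        d["k_el"] = comb(s["cl_tot"], s["vd"])
        d["t_half"] = d["k_el"]
        d["auc_1500"] = d["cl_tot"]
        d["mat"] = d["k_gutabs"]
        d["f_met"] = comb(s["k_ufrac"], s["f_gluc"])
        return d

    def summary(self, ci: float = 0.90) -> pd.DataFrame:
        """Posterior table: GM and GSD median with equal-tailed CI.

        Includes the fitted parameters plus derived rows (``cl_met``,
        ``k_el``, ``t_half``, ``auc_1500`` for a 1500 ng/kg bolus,
        ``mat``, ``f_met``), all computed per draw.
        """
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        gm_draws = self._derived_gm_draws()
        gsd_draws = self._derived_gsd_draws()
        units = {
            "cl_tot": "L/(h·kg)", "vd": "L/kg", "vd_met": "L/kg",
            "k_umet": "1/h", "k_gutabs": "1/h", "k_ufrac": "-",
            "f_gluc": "-", "cl_met": "L/(h·kg)", "k_el": "1/h",
            "t_half": "h", "auc_1500": "ng·h/L", "mat": "h", "f_met": "-",
        }
        rows = []
        for name, draws in gm_draws.items():
            q = np.percentile(draws, [lo, 50, hi])
            g = np.percentile(gsd_draws[name], [lo, 50, hi])
            rows.append({
                "parameter": name, "unit": units[name],
                "gm_median": q[1], "gm_lo": q[0], "gm_hi": q[2],
                "gsd_median": g[1], "gsd_lo": g[0], "gsd_hi": g[2],
            })
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (chain, draw, parameter, value)."""
        recs = []
        for p, name in enumerate(PARAM_NAMES):
            gm = self.population_gm()[:, :, p]
            gsd = self.population_gsd()[:, :, p]
            for c in range(self.n_chains):
                recs.append(pd.DataFrame({
                    "chain": c, "draw": np.arange(self.n_kept),
                    "parameter": f"gm_{name}", "value": gm[c]}))
                recs.append(pd.DataFrame({
                    "chain": c, "draw": np.arange(self.n_kept),
                    "parameter": f"gsd_{name}", "value": gsd[c]}))
        for ci_, cls in enumerate(OBS_CLASSES):
            eg = self.error_gsd()[:, :, ci_]
            for c in range(self.n_chains):
                recs.append(pd.DataFrame({
                    "chain": c, "draw": np.arange(self.n_kept),
                    "parameter": f"err_{cls}", "value": eg[c]}))
        return pd.concat(recs, ignore_index=True)

    # -- prediction -------------------------------------------------------

    def _draw_indices(self, n_draws: int, rng) -> tuple[np.ndarray, np.ndarray]:
        total = self.n_chains * self.n_kept
        flat = rng.choice(total, size=min(n_draws, total), replace=False) \
            if n_draws < total else np.arange(total)
        return flat // self.n_kept, flat % self.n_kept

    def posterior_predict(self, design: SubjectDesign, times=None,
                          n_draws: int = 500, seed: int | None = None,
                          subject: int | None = None, ci: float = 0.90):
        """Median and CI bands for the observable profiles of a design.

        With ``subject=None`` a new individual is drawn from the
        population distribution for every posterior draw (population
        predictive, reflecting uncertainty and inter-individual
        variability); with a subject index the subject's own parameter
        draws are used.  Returns a :class:`PosteriorPrediction`.
        """
        rng = np.random.default_rng(seed)
        if times is None:
            times = np.linspace(0.0, 48.0, 97)
        times = np.asarray(times, dtype=float)
        ch, it = self._draw_indices(n_draws, rng)
        curves = {k: [] for k in ("c_free", "c_total", "q_u_mass", "q_utot_mass")}
        for c, i in zip(ch, it):
            if subject is None:
                mu = self.draws["mu"][c, i]
                sig = self.draws["sigma"][c, i]
                while True:
                    logvec = mu + sig * rng.standard_normal(7)
                    if _support_ok(logvec).all() and \
                            (logvec[list(_FRAC_IDX)] <= 0.0).all():
                        break
                vec = np.exp(logvec)
            else:
                vec = np.exp(self.draws["theta"][c, i, subject])
            params = TKParams.from_array(vec)
            traj = simulate_analytic(params, design.dose_ng_per_kg, times)
            curves["c_free"].append(traj.c_free)
            curves["c_total"].append(traj.c_total)
            curves["q_u_mass"].append(traj.q_u * design.bw_kg)
            curves["q_utot_mass"].append(
                (traj.q_u + params.f_gluc * traj.q_umet) * design.bw_kg)
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        bands = {}
        for k, stack in curves.items():
            arr = np.stack(stack)
            bands[k] = np.percentile(arr, [lo, 50, hi], axis=0)
        return PosteriorPrediction(times=times, bands=bands, ci=ci,
                                   design=design)

    def predicted_vs_observed(self, n_draws: int = 200,
                              seed: int | None = None) -> pd.DataFrame:
        """Posterior-median predictions paired with every observation."""
        rng = np.random.default_rng(seed)
        ch, it = self._draw_indices(n_draws, rng)
        recs = []
        for si, sub in enumerate(self.model.subjects):
            preds = {cls: [] for cls in OBS_CLASSES if cls in sub.logv}
            for c, i in zip(ch, it):
                lp = sub.predict_log(np.exp(self.draws["theta"][c, i, si]))
                for cls in preds:
                    preds[cls].append(np.exp(lp[cls]))
            for cls, stack in preds.items():
                med = np.median(np.stack(stack), axis=0)
                for obs_v, pred_v, cens in zip(
                        np.exp(sub.logv[cls]), med, sub.cens[cls]):
                    recs.append({
                        "subject": sub.design.subject, "obs_class": cls,
                        "observed": obs_v, "predicted": pred_v,
                        "censored": cens})
        return pd.DataFrame(recs)


@dataclass
class PosteriorPrediction:
    """Prediction bands on a time grid.

    ``bands[key]`` has rows (lower, median, upper) for key in
    ``c_free``/``c_total`` (ng/mL) and cumulative urinary masses
    ``q_u_mass``/``q_utot_mass`` (ng).
    """

    times: np.ndarray
    bands: dict
    ci: float
    design: SubjectDesign

    def band(self, key: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo, med, hi = self.bands[key]
        return lo, med, hi

    def plot(self, key: str = "c_free", ax=None, observations=None):
        """Band plot in the style of posterior-prediction figures."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, med, hi = self.bands[key]
        ax.fill_between(self.times, lo, hi, alpha=0.3, color="goldenrod",
                        label=f"{int(self.ci * 100)}% CI")
        ax.plot(self.times, med, color="black", label="median")
        if observations is not None:
            ax.plot(observations[0], observations[1], "ko", mfc="none",
                    label="observed")
        ax.set_xlabel("time (h)")
        ax.set_ylabel(key)
        ax.legend()
        return ax
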