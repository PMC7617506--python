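"""Probabilistic internal Threshold of Toxicological Concern (iTTC).

An iTTC is an internal-dose analogue of the external TTC: a blood
concentration (nmol/L) or 24-h urinary excretion (nmol/kg-d) below
which appreciable risk is not expected for a substance lacking
chemical-specific toxicity data.  The derivation divides an internal
no-observed-effect level (NOEL, here the steady-state blood
concentrations from three in-silico TK models of the Munro NOEL
dataset) by three probabilistic assessment factors::

    iTTC = NOEL / (AF_pod * AF_inter_td * GSD_intra_td ** z)

* ``AF_pod`` — imprecision of a NOEL as an estimate of a benchmark
  dose (WHO/IPCS chronic continuous-endpoint distribution).
* ``AF_inter_td`` — interspecies toxicodynamic differences (the
  kinetic half of the classical interspecies factor is unnecessary on
  an internal-dose basis).
* ``GSD_intra_td ** z`` — human variability at a target incidence
  (z is the standard-normal quantile of 1 - I; a random individual
  instead draws z ~ N(0, 1)).

Every component is a lognormal uncertainty distribution parameterized
by its median (P50) and the ratio P95/P50; the quantities are combined
by Monte Carlo.  The reported point value ("probabilistic iTTC") is
the lower one-tailed 95% confidence bound, i.e. the 5th percentile of
the resulting uncertainty distribution.

For urine, the NOEL is converted from a steady-state blood
concentration to a 24-h urinary excretion with the population
geometric means of total clearance and urinary fraction, and the
intraspecies GSD additionally mixes the population variability of
those two kinetic parameters (independent TK x TD combination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtri

__all__ = [
    "UncertainFactor",
    "ITTCConfig",
    "ITTCResult",
    "noel_uncertainty",
    "interTD_gsd",
    "combine_intra_gsd",
    "af_from_gsd",
    "derive_ittc_blood",
    "derive_ittc_urine",
    "noel_blood_to_urine",
    "Z_95",
]

#: standard-normal 95th percentile used in P50/P95 parameterizations
Z_95 = float(ndtri(0.95))


@dataclass(frozen=True)
class UncertainFactor:
    """A lognormal uncertainty distribution for an assessment factor.

    Parameterized by the median ``p50`` and the ratio ``p95_over_p50``
    (>= 1); ``p95_over_p50 == 1`` collapses the factor to the fixed
    value ``p50``.
    """

    p50: float
    p95_over_p50: float = 1.0

    def __post_init__(self) -> None:
        if not self.p50 > 0:
            raise ValueError("p50 must be positive")
        if not self.p95_over_p50 >= 1:
            raise ValueError("p95_over_p50 must be >= 1")

    @property
    def sigma_ln(self) -> float:
        """SD of the natural-log of the factor."""
        return math.log(self.p95_over_p50) / Z_95

    @property
    def gsd(self) -> float:
        """Geometric standard deviation (= exp(sigma_ln))."""
        return math.exp(self.sigma_ln)

    @classmethod
    def from_gsd(cls, p50: float, gsd: float) -> "UncertainFactor":
        if gsd < 1:
            raise ValueError("GSD must be >= 1")
        return cls(p50, gsd ** Z_95)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.p95_over_p50 == 1.0:
            return np.full(n, self.p50)
        return self.p50 * np.exp(self.sigma_ln * rng.standard_normal(n))

    def quantile(self, q) -> np.ndarray:
        return self.p50 * np.exp(self.sigma_ln * ndtri(np.asarray(q)))


def noel_uncertainty(values) -> UncertainFactor:
    """Lognormal NOEL uncertainty from a handful of model estimates.

    GM is the geometric mean; the GSD uses the n-denominator
    (population) standard deviation of the log values, which is what
    reproduces the quoted 90% interval for the three steady-state
    estimates.  A single value yields GSD 1 (no spread).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("at least one NOEL value is required")
    if (values <= 0).any():
        raise ValueError("NOEL values must be positive")
    logs = np.log(values)
    gm = math.exp(logs.mean())
    gsd = math.exp(logs.std(ddof=0))  # population SD
    return UncertainFactor.from_gsd(gm, gsd)


def interTD_gsd(gsd_combined: float) -> float:
    """Toxicodynamic half of a combined interspecies TK+TD GSD.

    Assuming equal and independent TK and TD contributions,
    ``GSD_td = GSD_combined ** (1/sqrt(2))``.
    """
    if gsd_combined < 1:
        raise ValueError("GSD must be >= 1")
    return gsd_combined ** (1.0 / math.sqrt(2.0))


def combine_intra_gsd(gsd_list) -> float | np.ndarray:
    """Combine independent variability GSDs: exp(sqrt(sum(ln g)^2)).

    Accepts scalars or arrays (broadcast elementwise); inverse of the
    equal-split used by :func:`interTD_gsd` when given two equal GSDs.
    """
    total = 0.0
    for g in gsd_list:
        total = total + np.log(g) ** 2
    return np.exp(np.sqrt(total))


def af_from_gsd(gsd, incidence: float = 0.01):
    """Assessment factor for human variability at a target incidence.

    ``AF = GSD ** z`` with z the standard-normal quantile of
    ``1 - incidence`` (for a random individual draw z ~ N(0,1)
    instead).
    """
    if not 0 < incidence < 1:
        raise ValueError("incidence must be in (0, 1)")
    z = float(ndtri(1.0 - incidence))
    return np.asarray(gsd, dtype=float) ** z if np.ndim(gsd) else float(gsd) ** z


@dataclass(frozen=True)
class ITTCConfig:
    """Configuration of the probabilistic iTTC derivation.

    Defaults follow the WHO/IPCS parameterizations: ``af_pod`` has
    P50 = 0.333 and P95 = 1.567; ``af_inter_td`` is the TD half of the
    combined interspecies GSD 1.95; ``gsd_intra_td`` is lognormal with
    median 10^0.221 and P95/P50 = 2.85 (the spread ratio applied on
    the log10 scale, which reproduces the quoted quantiles of both the
    GSD and the derived factor).  ``z`` defaults to 2.326, the
    1%-incidence z-score.  The urinary conversion uses population
    geometric means (and, for variability, GSDs) of total clearance
    and the urinary fraction.
    """

    noel_css: tuple = (22.0, 8.5, 8.3)            # nmol/L
    incidence: float = 0.01
    z: float = 2.326
    n_draws: int = 100_000
    af_pod: UncertainFactor = field(
        default_factory=lambda: UncertainFactor(0.333, 1.567 / 0.333))
    af_inter_td: UncertainFactor = field(
        default_factory=lambda: UncertainFactor.from_gsd(
            1.0, 1.95 ** (1.0 / math.sqrt(2.0))))
    gsd_intra_td: UncertainFactor = field(
        default_factory=lambda: UncertainFactor(10.0 ** 0.221, 2.85))
    cl_tot_gm: float = 1.58       # L/(h·kg)
    k_ufrac_gm: float = 0.212
    cl_tot_gsd: float = 1.60
    k_ufrac_gsd: float = 1.49

    def __post_init__(self) -> None:
        if len(self.noel_css) < 1 or any(v <= 0 for v in self.noel_css):
            raise ValueError("noel_css must be positive values")
        if not 0 < self.incidence < 1:
            raise ValueError("incidence must be in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")
        for name in ("cl_tot_gm", "k_ufrac_gm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cl_tot_gsd", "k_ufrac_gsd"):
            if not getattr(self, name) >= 1:
                raise ValueError(f"{name} must be >= 1")

    def collapsed(self) -> "ITTCConfig":
        """Copy with every uncertainty spread set to 1 (degenerate)."""
        noel = noel_uncertainty(self.noel_css)
        return replace(
            self,
            noel_css=(noel.p50,),
            af_pod=UncertainFactor(self.af_pod.p50),
            af_inter_td=UncertainFactor(self.af_inter_td.p50),
            gsd_intra_td=UncertainFactor(self.gsd_intra_td.p50),
            cl_tot_gsd=1.0, k_ufrac_gsd=1.0,
        )


@dataclass(frozen=True)
class ITTCResult:
    """Monte Carlo iTTC uncertainty distribution and its summaries.

    ``prob_ittc`` is the lower one-tailed 95% confidence bound (5th
    percentile), the point value used for screening.
    """

    draws: np.ndarray
    median: float
    ci90: tuple
    prob_ittc: float
    units: str
    matrix: str

    @classmethod
    def from_draws(cls, draws, units, matrix) -> "ITTCResult":
        q5, q50, q95 = np.percentile(draws, [5.0, 50.0, 95.0])
        return cls(draws=draws, median=float(q50), ci90=(float(q5), float(q95)),
                   prob_ittc=float(q5), units=units, matrix=matrix)

    def summary(self) -> dict:
        return {
            "matrix": self.matrix, "units": self.units,
            "median": self.median, "ci90": list(self.ci90),
            "prob_ittc": self.prob_ittc, "n_draws": int(self.draws.size),
        }


def _sample_components(config: ITTCConfig, n: int, rng):
    noel = noel_uncertainty(config.noel_css).sample(rng, n)
    af_pod = config.af_pod.sample(rng, n)
    af_inter = config.af_inter_td.sample(rng, n)
    gsd_td = config.gsd_intra_td.sample(rng, n)
    return noel, af_pod, af_inter, gsd_td


def derive_ittc_blood(config: ITTCConfig | None = None,
                      n_draws: int | None = None,
                      seed: int | None = None) -> ITTCResult:
    """Monte Carlo derivation of the blood iTTC (nmol/L)."""
    config = config or ITTCConfig()
    n = n_draws or config.n_draws
    rng = np.random.default_rng(seed)
    noel, af_pod, af_inter, gsd_td = _sample_components(config, n, rng)
    draws = noel / (af_pod * af_inter * gsd_td ** config.z)
    return ITTCResult.from_draws(draws, "nmol/L", "blood")


def noel_blood_to_urine(noel_draws, cl_tot_gm: float,
                        k_ufrac_gm: float) -> np.ndarray:
    """Convert steady-state blood NOEL draws to 24-h urinary excretion.

    At steady state, urinary excretion rate = C_ss * Cl_tot * k_ufrac;
    over 24 h this gives nmol/kg-d from nmol/L with clearance in
    L/(h·kg).
    """
    if cl_tot_gm <= 0 or k_ufrac_gm <= 0:
        raise ValueError("conversion parameters must be positive")
    return np.asarray(noel_draws) * cl_tot_gm * k_ufrac_gm * 24.0


def derive_ittc_urine(config: ITTCConfig | None = None,
                      n_draws: int | None = None,
                      seed: int | None = None,
                      tk_gsd_samples: dict | None = None) -> ITTCResult:
    """Monte Carlo derivation of the urinary-excretion iTTC (nmol/kg-d).

    The NOEL is converted to a 24-h excretion and the intraspecies GSD
    combines the toxicodynamic distribution with the population
    variability GSDs of Cl_tot and k_ufrac (fixed at their posterior
    medians by default; pass ``tk_gsd_samples`` with arrays under
    ``"cl_tot"``/``"k_ufrac"`` to propagate their posterior
    uncertainty instead).
    """
    config = config or ITTCConfig()
    n = n_draws or config.n_draws
    rng = np.random.default_rng(seed)
    noel, af_pod, af_inter, gsd_td = _sample_components(config, n, rng)
    noel_u = noel_blood_to_urine(noel, config.cl_tot_gm, config.k_ufrac_gm)
    if tk_gsd_samples is not None:
        g_cl = rng.choice(np.asarray(tk_gsd_samples["cl_tot"]), size=n)
        g_ku = rng.choice(np.asarray(tk_gsd_samples["k_ufrac"]), size=n)
    else:
        g_cl, g_ku = config.cl_tot_gsd, config.k_ufrac_gsd
    gsd_intra = combine_intra_gsd([g_cl, g_ku, gsd_td])
    draws = noel_u / (af_pod * af_inter * gsd_intra ** config.z)
    return ITTCResult.from_draws(draws, "nmol/kg-d", "urine")
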