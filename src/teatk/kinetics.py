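"""Deterministic multi-compartment kinetics of tenuazonic acid (TeA).

The model is a linear cascade: an oral bolus enters the gastrointestinal
tract and is absorbed completely (first-order rate ``k_gutabs``) into a
central compartment of free TeA.  From there the toxin is either excreted
unchanged in urine (rate ``k_u``) or conjugated to phase-II metabolites
(rate ``k_met``), which occupy their own distribution volume and are in
turn excreted in urine (rate ``k_umet``).  There is no fecal route and no
enterohepatic recirculation.  Amounts are tracked in ng per kg body
weight, times in hours, and volumes of distribution in L/kg, so blood
concentrations come out in ng/L (converted to ng/mL at the observation
layer only).

Because the cascade is linear with distinct rate constants, the state is
a superposition of exponentials (Bateman-type solution); an independent
stiff ODE integration of the same system is provided as a numerical
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "TKParams",
    "DerivedTK",
    "Trajectory",
    "SubjectDesign",
    "PredictedObservations",
    "derive",
    "simulate_analytic",
    "simulate_ode",
    "auc_inf",
    "observe",
    "urine_interval_amounts",
    "PARAM_NAMES",
]

#: canonical ordering of the seven kinetic parameters (fitting order);
#: the fourth slot is the metabolite urinary rate k_umet = cl_met/vd_met.
PARAM_NAMES = ("cl_tot", "vd", "vd_met", "k_umet", "k_gutabs", "k_ufrac", "f_gluc")

#: parameters constrained to the unit interval (fractions)
FRACTION_PARAMS = ("k_ufrac", "f_gluc")

# relative separation below which two rate constants are treated as
# coincident and nudged apart (documented epsilon-separation fallback)
_RATE_SEP = 1e-9
_RATE_NUDGE = 1e-7


@dataclass(frozen=True)
class TKParams:
    """One individual's TeA kinetic parameter vector.

    Parameters
    ----------
    cl_tot : float
        Total clearance of free TeA, L/(h·kg bw).
    vd : float
        Volume of distribution of free TeA, L/kg bw.
    vd_met : float
        Volume of distribution of the phase-II metabolites, L/kg bw.
    cl_met : float
        Metabolite clearance, L/(h·kg bw); the urinary elimination rate
        of the metabolites is ``k_umet = cl_met / vd_met``.
    k_gutabs : float
        First-order gut absorption rate, 1/h.
    k_ufrac : float
        Fraction of free-TeA elimination that is urinary, in (0, 1].
    f_gluc : float
        Fraction of urinary TeA metabolites that is glucuronidated
        (i.e. released by enzymatic hydrolysis before quantification),
        in (0, 1].
    """

    cl_tot: float
    vd: float
    vd_met: float
    cl_met: float
    k_gutabs: float
    k_ufrac: float
    f_gluc: float

    def __post_init__(self) -> None:
        for name in ("cl_tot", "vd", "vd_met", "cl_met", "k_gutabs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in FRACTION_PARAMS:
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    @property
    def k_umet(self) -> float:
        """Metabolite urinary elimination rate cl_met/vd_met, 1/h."""
        return self.cl_met / self.vd_met

    @classmethod
    def from_kumet(cls, cl_tot, vd, vd_met, k_umet, k_gutabs, k_ufrac, f_gluc):
        """Construct from the rate parameterization (k_umet instead of cl_met)."""
        return cls(cl_tot, vd, vd_met, k_umet * vd_met, k_gutabs, k_ufrac, f_gluc)

    def to_array(self) -> np.ndarray:
        """Vector in :data:`PARAM_NAMES` order (k_umet slot)."""
        return np.array(
            [self.cl_tot, self.vd, self.vd_met, self.k_umet,
             self.k_gutabs, self.k_ufrac, self.f_gluc]
        )

    @classmethod
    def from_array(cls, arr) -> "TKParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError("expected a length-7 parameter vector")
        return cls.from_kumet(*arr)


@dataclass(frozen=True)
class DerivedTK:
    """Quantities derived from a :class:`TKParams` vector."""

    k_el: float      # elimination rate of free TeA = cl_tot/vd, 1/h
    k_u: float       # urinary elimination rate = k_ufrac * k_el, 1/h
    k_met: float     # metabolic rate = (1 - k_ufrac) * k_el, 1/h
    k_umet: float    # metabolite urinary rate = cl_met/vd_met, 1/h
    t_half: float    # ln 2 / k_el, h
    mat: float       # mean absorption time = 1/k_gutabs, h
    auc: float       # dose-normalised AUC = 1/cl_tot, (ng·h/L)/(ng/kg)
    t_max: float     # time of peak free blood concentration, h
    c_max: float     # peak free blood concentration per unit dose, see derive()
    f_met: float     # (1 - k_ufrac) * f_gluc, fraction of dose recovered
                     # in urine as measurable (glucuronide) conjugates


def derive(params: TKParams) -> DerivedTK:
    """Compute the derived kinetic quantities for one parameter vector.

    ``t_max`` uses the two-exponential peak formula
    ``ln(k_gutabs/k_el) / (k_gutabs - k_el)``; at the removable
    singularity ``k_gutabs == k_el`` the limit ``1/k_el`` is used.
    ``c_max`` is the free blood concentration (ng/mL) at ``t_max`` for a
    unit dose of 1 ng/kg bw; scale by the dose for absolute peaks.
    """
    k_el = params.cl_tot / params.vd
    ka = params.k_gutabs
    if math.isclose(ka, k_el, rel_tol=1e-12):
        t_max = 1.0 / k_el
    else:
        t_max = math.log(ka / k_el) / (ka - k_el)
    c_max = _free_conc_unit_dose(params, t_max)
    return DerivedTK(
        k_el=k_el,
        k_u=params.k_ufrac * k_el,
        k_met=(1.0 - params.k_ufrac) * k_el,
        k_umet=params.k_umet,
        t_half=math.log(2.0) / k_el,
        mat=1.0 / ka,
        auc=1.0 / params.cl_tot,
        t_max=t_max,
        c_max=c_max,
        f_met=(1.0 - params.k_ufrac) * params.f_gluc,
    )


def _free_conc_unit_dose(params: TKParams, t: float) -> float:
    """Free blood concentration in ng/mL at time t for dose 1 ng/kg."""
    kel = params.cl_tot / params.vd
    ka, kel = _separate_rates([params.k_gutabs, kel])
    a_central = ka / (kel - ka) * (math.exp(-ka * t) - math.exp(-kel * t))
    return a_central / params.vd / 1000.0


@dataclass(frozen=True)
class Trajectory:
    """Compartment amounts and blood concentrations over time.

    Amounts (``a_*``, ``q_*``) are ng per kg body weight; concentrations
    are ng/mL with ``c_free = a_central/vd`` and
    ``c_total = c_free + f_gluc * a_met/vd_met`` (both divided by 1000 to
    convert ng/L to ng/mL).  ``q_u``/``q_umet`` are cumulative urinary
    amounts of free TeA and of its metabolites.
    """

    times: np.ndarray
    a_gut: np.ndarray
    a_central: np.ndarray
    a_met: np.ndarray
    q_u: np.ndarray
    q_umet: np.ndarray
    c_free: np.ndarray
    c_total: np.ndarray
    params: TKParams = field(repr=False)
    dose: float = field(repr=False, default=0.0)

    def mass_balance_error(self) -> np.ndarray:
        """Absolute deviation of the compartment sum from the dose."""
        total = self.a_gut + self.a_central + self.a_met + self.q_u + self.q_umet
        return np.abs(total - self.dose)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export (time_h, compartment, value, unit)."""
        parts = []
        for name, values, unit in [
            ("a_gut", self.a_gut, "ng/kg"),
            ("a_central", self.a_central, "ng/kg"),
            ("a_met", self.a_met, "ng/kg"),
            ("q_u", self.q_u, "ng/kg"),
            ("q_umet", self.q_umet, "ng/kg"),
            ("c_free", self.c_free, "ng/mL"),
            ("c_total", self.c_total, "ng/mL"),
        ]:
            parts.append(
                pd.DataFrame(
                    {"time_h": self.times, "compartment": name,
                     "value": values, "unit": unit}
                )
            )
        return pd.concat(parts, ignore_index=True)


def _separate_rates(rates: list[float]) -> list[float]:
    """Nudge near-coincident rate constants apart.

    The closed-form solution has removable singularities where two rate
    constants coincide.  Rather than switch to polynomial-in-t limiting
    forms, rates closer than ``_RATE_SEP`` (relative) are separated by a
    multiplicative ``_RATE_NUDGE``; the perturbation is far below the
    1e-6 agreement tolerance against the ODE oracle.
    """
    out = list(rates)
    changed = True
    while changed:
        changed = False
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                if abs(out[i] - out[j]) <= _RATE_SEP * max(out[i], out[j]):
                    out[j] = out[j] * (1.0 + _RATE_NUDGE) + _RATE_NUDGE * 1e-12
                    changed = True
    return out


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be a 1-D array")
    if times.size and (times < 0).any():
        raise ValueError("times must be nonnegative")
    if times.size > 1 and (np.diff(times) < 0).any():
        raise ValueError("times must be sorted ascending")
    return times


def _cascade_coeffs(params: TKParams, dose: float):
    """Rates and exponential-superposition coefficients of the cascade.

    Returns ``(ka, kel, kum, k_u, k_met, c_ka, c_kel, d_ka, d_kel,
    d_kum)`` such that ``a_central = c_ka e^{-ka t} + c_kel e^{-kel t}``
    and ``a_met = d_ka e^{-ka t} + d_kel e^{-kel t} + d_kum e^{-kum t}``.
    """
    ka, kel, kum = _separate_rates(
        [params.k_gutabs, params.cl_tot / params.vd, params.k_umet])
    k_u = params.k_ufrac * kel
    k_met = (1.0 - params.k_ufrac) * kel
    c_ka = dose * ka / (kel - ka)
    c_kel = -c_ka
    d_ka = k_met * c_ka / (kum - ka)
    d_kel = k_met * c_kel / (kum - kel)
    d_kum = -(d_ka + d_kel)
    return ka, kel, kum, k_u, k_met, c_ka, c_kel, d_ka, d_kel, d_kum


def urine_interval_amounts(params: TKParams, dose: float, intervals):
    """Urinary amounts per void interval, ng per kg body weight.

    Returns ``(free, total)`` where total includes the glucuronide
    conjugates released by hydrolysis (``q_u + f_gluc q_umet``).
    Computed by differencing the exponential terms directly, which
    stays accurate for late voids where the cumulative amounts have
    numerically reached their asymptote.
    """
    intervals = np.asarray(intervals, dtype=float).reshape(-1, 2)
    a, b = intervals[:, 0], intervals[:, 1]
    ka, kel, kum, k_u, _, c_ka, c_kel, d_ka, d_kel, d_kum = \
        _cascade_coeffs(params, dose)

    def ediff(lam):
        return np.exp(-lam * a) - np.exp(-lam * b)

    dq_u = k_u * (c_ka * ediff(ka) / ka + c_kel * ediff(kel) / kel)
    dq_umet = kum * (d_ka * ediff(ka) / ka + d_kel * ediff(kel) / kel
                     + d_kum * ediff(kum) / kum)
    return dq_u, dq_u + params.f_gluc * dq_umet


def simulate_analytic(params: TKParams, dose: float, times) -> Trajectory:
    """Closed-form solution of the linear TeA cascade for an oral bolus.

    ``a_gut`` decays as ``dose * exp(-k_gutabs t)``; ``a_central`` and
    ``a_met`` are Bateman-type superpositions of exponentials with rates
    ``{k_gutabs, k_el, k_umet}``; the cumulative urinary amounts are the
    time integrals ``q_u = k_u ∫ a_central`` and
    ``q_umet = k_umet ∫ a_met``.  Mass balance
    ``a_gut + a_central + a_met + q_u + q_umet = dose`` holds to
    numerical precision at every time.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    times = _check_times(times)
    ka, kel, kum, k_u, k_met, c_ka, c_kel, d_ka, d_kel, d_kum = \
        _cascade_coeffs(params, dose)

    e_ka = np.exp(-ka * times)
    e_kel = np.exp(-kel * times)
    e_kum = np.exp(-kum * times)

    a_gut = dose * e_ka
    a_central = c_ka * e_ka + c_kel * e_kel
    a_met = d_ka * e_ka + d_kel * e_kel + d_kum * e_kum

    # cumulative urine: termwise integral of c exp(-lam t) is c(1-e)/lam
    q_u = k_u * (c_ka * (1 - e_ka) / ka + c_kel * (1 - e_kel) / kel)
    q_umet = kum * (
        d_ka * (1 - e_ka) / ka
        + d_kel * (1 - e_kel) / kel
        + d_kum * (1 - e_kum) / kum
    )

    c_free = a_central / params.vd / 1000.0
    c_total = c_free + params.f_gluc * a_met / params.vd_met / 1000.0
    return Trajectory(times, a_gut, a_central, a_met, q_u, q_umet,
                      c_free, c_total, params, dose)


def _rhs(t, y, ka, kel, ku, kmet, kum):
    a_gut, a_c, a_m, q_u, q_m = y
    return [
        -ka * a_gut,
        ka * a_gut - kel * a_c,
        kmet * a_c - kum * a_m,
        ku * a_c,
        kum * a_m,
    ]


def simulate_ode(params: TKParams, dose: float, times) -> Trajectory:
    """Numeric (stiff-safe) integration of the same cascade.

    Serves as the independent oracle for :func:`simulate_analytic`; it
    shares nothing with the closed form beyond the ODE right-hand side.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    times = _check_times(times)
    d = derive(params)
    if times.size == 0 or times[-1] == 0.0:
        zeros = np.zeros_like(times)
        gut = np.full_like(times, dose)
        c_free = zeros / params.vd
        return Trajectory(times, gut, zeros, zeros.copy(), zeros.copy(),
                          zeros.copy(), c_free, c_free.copy(), params, dose)
    sol = solve_ivp(
        _rhs,
        (0.0, float(times[-1])),
        [dose, 0.0, 0.0, 0.0, 0.0],
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=max(dose, 1.0) * 1e-13,
        args=(params.k_gutabs, d.k_el, d.k_u, d.k_met, params.k_umet),
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed ({sol.message}) for params={params!r}, dose={dose}"
        )
    a_gut, a_c, a_m, q_u, q_m = sol.y
    c_free = a_c / params.vd / 1000.0
    c_total = c_free + params.f_gluc * a_m / params.vd_met / 1000.0
    return Trajectory(times, a_gut, a_c, a_m, q_u, q_m,
                      c_free, c_total, params, dose)


def auc_inf(params: TKParams, dose: float) -> float:
    """Area under the free blood concentration curve to infinity, ng·h/L.

    For a fully absorbed oral bolus this is exactly ``dose / cl_tot``.
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    return dose / params.cl_tot


@dataclass(frozen=True)
class SubjectDesign:
    """Sampling design for one trial subject.

    ``urine_intervals`` are ``(start_h, end_h)`` void intervals, ordered
    and non-overlapping; ``urine_volumes_ml`` are the corresponding void
    volumes.
    """

    subject: str
    bw_kg: float
    dose_ng_per_kg: float
    blood_times_h: np.ndarray
    urine_intervals_h: np.ndarray      # shape (n_voids, 2)
    urine_volumes_ml: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "blood_times_h",
                           np.asarray(self.blood_times_h, dtype=float))
        iv = np.asarray(self.urine_intervals_h, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "urine_intervals_h", iv)
        object.__setattr__(self, "urine_volumes_ml",
                           np.asarray(self.urine_volumes_ml, dtype=float))
        if not self.bw_kg > 0:
            raise ValueError("body weight must be positive")
        if self.dose_ng_per_kg < 0:
            raise ValueError("dose must be nonnegative")
        if (np.diff(self.blood_times_h) < 0).any():
            raise ValueError("blood sample times must be sorted")
        if iv.size:
            if (iv[:, 1] <= iv[:, 0]).any():
                raise ValueError("urine interval end must be after start")
            if (iv[1:, 0] < iv[:-1, 1] - 1e-12).any():
                raise ValueError("urine intervals overlap")
        if self.urine_volumes_ml.shape[0] != iv.shape[0]:
            raise ValueError("one volume per urine interval required")

    @property
    def n_blood(self) -> int:
        return int(self.blood_times_h.size)

    @property
    def n_voids(self) -> int:
        return int(self.urine_intervals_h.shape[0])


@dataclass(frozen=True)
class PredictedObservations:
    """Noise-free observables implied by a parameter set and a design.

    Blood predictions are concentrations (ng/mL) at the sample times;
    urine predictions are absolute masses (ng) per void interval, i.e.
    interval differences of the cumulative urinary amounts scaled by
    body weight.  The hydrolyzed "total" urine analyte is
    ``q_u + f_gluc * q_umet`` (free TeA plus its glucuronides).
    """

    blood_free: np.ndarray    # ng/mL
    blood_total: np.ndarray   # ng/mL
    urine_free: np.ndarray    # ng per void
    urine_total: np.ndarray   # ng per void


def observe(traj: Trajectory, design: SubjectDesign) -> PredictedObservations:
    """Map a trajectory onto the observables of a sampling design.

    The trajectory carries its generating parameters, which are used to
    re-evaluate the closed form exactly at the design's sample times and
    void boundaries (the trajectory grid need not contain them).
    """
    params, dose = traj.params, traj.dose
    blood = simulate_analytic(params, dose, design.blood_times_h)
    free, total = urine_interval_amounts(params, dose,
                                         design.urine_intervals_h)
    return PredictedObservations(
        blood_free=blood.c_free,
        blood_total=blood.c_total,
        urine_free=free * design.bw_kg,
        urine_total=total * design.bw_kg,
    )


def replace_params(params: TKParams, **kwargs) -> TKParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **kwargs)
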