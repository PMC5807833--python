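"""Core kinetic model of the methionine metabolism cycle (MMC).

The model is a seven-compartment linear system describing plasma and tissue
handling of methionine and homocysteine after an intravenous methionine dose:

    A1  methionine, peripheral
    A2  methionine, central (plasma; doses enter here, elimination K_EL leaves here)
    A3  S-adenosylmethionine (SAM)
    A4  S-adenosyl-L-homocysteine (SAH)
    A5  homocysteine, central (plasma)
    A6  cysteine/cystathionine sink (transsulfuration product, absorbing)
    A7  homocysteine, peripheral

All transfers are first order, so dA/dt = M A for a constant coefficient
matrix M built from ten rate constants (h^-1).  Plasma concentrations of both
analytes are the central amounts divided by the single apparent volume Vc
(L/kg); amounts are carried in mmol per kg body weight, so concentrations are
mmol/L.

Diabetic (ZDF) status enters as a dichotomous covariate: five rate constants
(K_SH, K_HM, K_HC, K_HP, K_PH) carry a multiplicative group factor, and two of
them (K_HM, K_HP) additionally carry log-normal inter-individual random
effects:

    K_HM,i = theta_KHM * f_KHM^ZDF * exp(eta1),   eta1 ~ N(0, omega_KHM^2)
    K_HP,i = theta_KHP * f_KHP^ZDF * exp(eta2),   eta2 ~ N(0, omega_KHP^2)

Residual variability on observed concentrations is a combined
additive + proportional error model (see :mod:`metcycle.simulate`).

A note on the transsulfuration sink: the A6 balance uses K_HC * A5, matching
the K_HC outflow term in the A5 equation, so that with K_EL = 0 total mass is
conserved.  (Some published statements of this system print the A6 source as
K_HC * A4; because A6 is a pure sink, the choice does not alter the plasma
methionine or homocysteine kinetics, but only K_HC * A5 conserves mass.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "N_COMPARTMENTS",
    "COMPARTMENT_NAMES",
    "IDX_MET_PERIPH",
    "IDX_MET_CENTRAL",
    "IDX_SAM",
    "IDX_SAH",
    "IDX_HCY_CENTRAL",
    "IDX_SINK",
    "IDX_HCY_PERIPH",
    "RATE_NAMES",
    "ZDF_AFFECTED",
    "RatePars",
    "PopulationModel",
    "IndividualEffects",
    "InvalidParameterError",
    "cv_to_omega",
    "build_rate_matrix",
    "solve_exact",
    "solve_numeric",
    "solve_multidose",
    "individual_pars",
    "concentrations",
    "control_rates",
    "zdf_rates",
    "default_population",
    "load_preset",
    "read_config",
    "write_config",
    "population_from_config",
    "population_to_config",
]

N_COMPARTMENTS = 7
COMPARTMENT_NAMES = ("met_periph", "met_central", "sam", "sah",
                     "hcy_central", "cys_sink", "hcy_periph")
IDX_MET_PERIPH, IDX_MET_CENTRAL, IDX_SAM, IDX_SAH = 0, 1, 2, 3
IDX_HCY_CENTRAL, IDX_SINK, IDX_HCY_PERIPH = 4, 5, 6

RATE_NAMES = ("K_CM", "K_MC", "K_MS", "K_SS", "K_EL",
              "K_SH", "K_HM", "K_HC", "K_HP", "K_PH")
#: rate constants whose typical value differs between ZDF and control rats
ZDF_AFFECTED = ("K_SH", "K_HM", "K_HC", "K_HP", "K_PH")


class InvalidParameterError(ValueError):
    """A rate constant or variance component violates its domain."""


def cv_to_omega(cv_percent: float) -> float:
    """Convert a log-normal coefficient of variation (percent) to the SD of
    the underlying normal random effect: omega = sqrt(ln(1 + (CV/100)^2))."""
    if cv_percent < 0:
        raise InvalidParameterError("CV must be non-negative")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


@dataclass(frozen=True)
class RatePars:
    """First-order rate constants (h^-1) and central volume (L/kg) for one
    individual."""

    K_CM: float   # methionine peripheral -> central
    K_MC: float   # methionine central -> peripheral
    K_MS: float   # methionine -> SAM (MAT)
    K_SS: float   # SAM -> SAH
    K_EL: float   # methionine elimination from central
    K_SH: float   # SAH -> homocysteine (SAHH)
    K_HM: float   # homocysteine -> methionine (BHMT remethylation)
    K_HC: float   # homocysteine -> cysteine (CbetaS, transsulfuration)
    K_HP: float   # homocysteine central -> peripheral
    K_PH: float   # homocysteine peripheral -> central
    Vc: float     # apparent central volume, L/kg

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"{f.name} must be strictly positive and finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class IndividualEffects:
    """Subject-level random effects (log scale) and group membership."""

    eta1: float = 0.0  # on K_HM
    eta2: float = 0.0  # on K_HP
    zdf: int = 0       # 0 = control, 1 = diabetic

    def __post_init__(self) -> None:
        if self.zdf not in (0, 1):
            raise InvalidParameterError(f"zdf must be 0 or 1, got {self.zdf!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, diabetic covariate effects, inter-individual
    variability and residual error magnitudes.

    ``theta`` holds the control-group typical parameters; ``zdf_effects`` maps
    each group-affected rate constant to the multiplicative factor applied
    when ZDF = 1 (factor = ZDF typical value / control typical value).
    """

    theta: RatePars
    zdf_effects: Mapping[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in ZDF_AFFECTED})
    omega_khm: float = 0.0   # SD of eta1
    omega_khp: float = 0.0   # SD of eta2
    sigma_add: float = 0.0   # additive residual SD, mmol/L
    sigma_prop: float = 0.0  # proportional residual SD, fraction

    def __post_init__(self) -> None:
        for name in ("omega_khm", "omega_khp", "sigma_add", "sigma_prop"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")
        for k, v in self.zdf_effects.items():
            if k not in ZDF_AFFECTED:
                raise InvalidParameterError(f"unknown ZDF effect target {k!r}")
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"ZDF factor for {k} must be > 0")

    def group_rates(self, zdf: int) -> RatePars:
        """Typical-individual rates for a group (eta = 0)."""
        return individual_pars(self, IndividualEffects(0.0, 0.0, zdf))


# ---------------------------------------------------------------------------
# Table of published typical values (h^-1 except Vc in L/kg)

_CONTROL = dict(K_CM=0.13, K_MC=0.0629, K_MS=0.605, K_SS=3220.0, K_EL=0.245,
                K_SH=11.6, K_HM=30.7, K_HC=11.1, K_HP=142.0, K_PH=5.13,
                Vc=0.15)
_ZDF = dict(_CONTROL, K_SH=13.5, K_HM=2.54, K_HC=0.526, K_HP=20.4, K_PH=0.032)

#: default residual error magnitudes (not published for this model)
DEFAULT_SIGMA_ADD = 0.01   # mmol/L
DEFAULT_SIGMA_PROP = 0.15  # fraction
#: published IIV as %CV on K_HM and K_HP
DEFAULT_IIV_CV_KHM = 70.1
DEFAULT_IIV_CV_KHP = 45.4


def control_rates() -> RatePars:
    """Typical rate constants of the control (non-diabetic) group."""
    return RatePars(**_CONTROL)


def zdf_rates() -> RatePars:
    """Typical rate constants of the ZDF (diabetic) group."""
    return RatePars(**_ZDF)


def default_population() -> PopulationModel:
    """The packaged final population model (both groups, IIV, residual error)."""
    effects = {k: _ZDF[k] / _CONTROL[k] for k in ZDF_AFFECTED}
    return PopulationModel(
        theta=control_rates(),
        zdf_effects=effects,
        omega_khm=cv_to_omega(DEFAULT_IIV_CV_KHM),
        omega_khp=cv_to_omega(DEFAULT_IIV_CV_KHP),
        sigma_add=DEFAULT_SIGMA_ADD,
        sigma_prop=DEFAULT_SIGMA_PROP,
    )


# ---------------------------------------------------------------------------
# Covariate / random-effect model


def individual_pars(pop: PopulationModel, fx: IndividualEffects) -> RatePars:
    """Apply the covariate and random-effect model to the typical values.

    K_HM and K_HP carry both the ZDF factor and their log-normal random
    effect; K_SH, K_HC and K_PH carry the ZDF factor only; the remaining
    rates and Vc are shared between groups.
    """
    z = fx.zdf
    eff = dict(pop.zdf_effects)
    for k in ZDF_AFFECTED:
        eff.setdefault(k, 1.0)
    th = pop.theta
    return replace(
        th,
        K_SH=th.K_SH * (eff["K_SH"] if z else 1.0),
        K_HM=th.K_HM * (eff["K_HM"] if z else 1.0) * math.exp(fx.eta1),
        K_HC=th.K_HC * (eff["K_HC"] if z else 1.0),
        K_HP=th.K_HP * (eff["K_HP"] if z else 1.0) * math.exp(fx.eta2),
        K_PH=th.K_PH * (eff["K_PH"] if z else 1.0),
    )


# ---------------------------------------------------------------------------
# Rate matrix and solvers


def build_rate_matrix(p: RatePars) -> np.ndarray:
    """Coefficient matrix M of the linear system dA/dt = M A.

    Every column sums to zero except the methionine-central column, which
    sums to -K_EL (the only true elimination); off-diagonals are
    non-negative, so the system is a compartmental (Metzler) matrix.
    """
    M = np.zeros((7, 7))
    M[0, 0] = -p.K_CM
    M[0, 1] = p.K_MC
    M[1, 0] = p.K_CM
    M[1, 1] = -(p.K_MS + p.K_EL + p.K_MC)
    M[1, 4] = p.K_HM
    M[2, 1] = p.K_MS
    M[2, 2] = -p.K_SS
    M[3, 2] = p.K_SS
    M[3, 3] = -p.K_SH
    M[4, 3] = p.K_SH
    M[4, 4] = -(p.K_HM + p.K_HC + p.K_HP)
    M[4, 6] = p.K_PH
    M[5, 4] = p.K_HC
    M[6, 4] = p.K_HP
    M[6, 6] = -p.K_PH
    return M


class _Propagator:
    """Evaluate exp(M t) v cheaply for many t via eigendecomposition.

    Falls back to scipy's expm when M is close to defective (repeated
    eigenvalues with an ill-conditioned eigenvector basis), which does not
    occur for the published parameter sets but can for adversarial inputs.
    """

    def __init__(self, M: np.ndarray):
        self.M = np.asarray(M, dtype=float)
        w, V = np.linalg.eig(self.M)
        ok = np.isfinite(w).all()
        if ok:
            try:
                Vi = np.linalg.inv(V)
                ok = np.linalg.cond(V) < 1e10
            except np.linalg.LinAlgError:
                ok = False
        if ok:
            self.w, self.V, self.Vi = w, V, Vi
        else:
            self.w = None

    def apply(self, times: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Return exp(M t) v for each t in ``times`` (shape (nt, 7)).

        Negative times yield zeros (causality: nothing before an impulse).
        """
        times = np.asarray(times, dtype=float)
        out = np.zeros((times.size, 7))
        mask = times >= 0
        if not mask.any():
            return out
        t = times[mask]
        if self.w is not None:
            c = self.Vi @ v
            # (nt, 7) spectral mixture; result real for real M, v
            out[mask] = np.real(np.exp(np.outer(t, self.w)) * c @ self.V.T)
        else:
            order = np.argsort(t)
            ts = t[order]
            vals = np.empty((ts.size, 7))
            prev_t, state = 0.0, v.astype(float)
            for i, ti in enumerate(ts):
                if ti > prev_t:
                    state = expm(self.M * (ti - prev_t)) @ state
                    prev_t = ti
                vals[i] = state
            inv = np.empty_like(order)
            inv[order] = np.arange(order.size)
            out[mask] = vals[inv]
        return out


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    if (np.diff(times) < 0).any():
        raise ValueError("times must be ascending")
    return times


def solve_exact(M: np.ndarray, A0: Sequence[float], times: Sequence[float]) -> np.ndarray:
    """Closed-form trajectory A(t) = exp(M t) A0 on an ascending time grid.

    Returns an array of shape (len(times), 7).
    """
    times = _check_times(times)
    A0 = np.asarray(A0, dtype=float)
    if A0.shape != (7,):
        raise ValueError("A0 must have shape (7,)")
    return _Propagator(np.asarray(M, dtype=float)).apply(times, A0)


def solve_multidose(M: np.ndarray,
                    events: Iterable[tuple[float, float]],
                    times: Sequence[float],
                    *,
                    dose_compartment: int = IDX_MET_CENTRAL,
                    post_dose: bool = True) -> np.ndarray:
    """Trajectory under a train of instantaneous boluses (superposition).

    ``events`` is an iterable of (time h, amount) pairs, ascending in time;
    each amount is added to ``dose_compartment``.  With ``post_dose=True`` an
    output time equal to a dose time reports the state just after that dose
    (the 0+ convention); with ``post_dose=False`` it reports the state just
    before (the pre-dose/trough convention used for observation records).
    """
    times = _check_times(times)
    events = sorted((float(t), float(a)) for t, a in events)
    if any(a <= 0 for _, a in events):
        raise ValueError("dose amounts must be positive")
    prop = _Propagator(np.asarray(M, dtype=float))
    out = np.zeros((times.size, 7))
    # Segment the grid between consecutive dose times and propagate the
    # running state: cost is O(n_times + n_events), not their product.
    # An output time equal to a dose time joins the post-dose segment under
    # the 0+ convention, the pre-dose segment otherwise.
    boundary = "left" if post_dose else "right"
    state = np.zeros(7)
    prev, pos = 0.0, 0
    for td, amt in events:
        hi = int(np.searchsorted(times, td, side=boundary))
        if hi > pos:
            if state.any():
                out[pos:hi] = prop.apply(times[pos:hi] - prev, state)
            pos = hi
        if td > prev and state.any():
            state = prop.apply(np.array([td - prev]), state)[0]
        state[dose_compartment] += amt
        prev = td
    if times.size > pos:
        out[pos:] = prop.apply(times[pos:] - prev, state)
    return out


def solve_numeric(p: RatePars, A0: Sequence[float], times: Sequence[float],
                  rtol: float = 1e-9, atol: float = 1e-12) -> np.ndarray:
    """Adaptive-step stiff integration of dA/dt = M A (independent check of
    :func:`solve_exact`; the SAM turnover K_SS ~ 3e3 h^-1 makes the system
    stiff)."""
    from scipy.integrate import solve_ivp

    times = _check_times(times)
    A0 = np.asarray(A0, dtype=float)
    M = build_rate_matrix(p)
    t_end = float(times[-1]) if times[-1] > 0 else 1e-12
    sol = solve_ivp(lambda t, y: M @ y, (0.0, t_end), A0, method="BDF",
                    jac=lambda t, y: M, t_eval=np.asarray(times, dtype=float),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"stiff integrator failed: {sol.message}")
    return sol.y.T


def concentrations(traj: np.ndarray, p: RatePars) -> tuple[np.ndarray, np.ndarray]:
    """Plasma methionine and homocysteine concentrations (mmol/L) from a
    trajectory of compartment amounts: C = A_central / Vc."""
    traj = np.asarray(traj, dtype=float)
    return traj[..., IDX_MET_CENTRAL] / p.Vc, traj[..., IDX_HCY_CENTRAL] / p.Vc


# ---------------------------------------------------------------------------
# Flat key/value parameter files and shipped presets

_CONFIG_DOC = """\
# Methionine-cycle population model, flat key = value format.
# Rates in 1/h, Vc in L/kg, sigmas in mmol/L (additive) / fraction (proportional).
# ZDF_* keys are the diabetic-group typical values; IIV_CV_* are %CV of the
# log-normal inter-individual random effects. GROUP selects the default
# simulation group for this preset (0 control, 1 ZDF).
"""


def write_config(path: str | Path, values: Mapping[str, float]) -> None:
    """Write a flat ``KEY = value`` parameter file."""
    lines = [_CONFIG_DOC]
    for k, v in values.items():
        lines.append(f"{k} = {v!r}" if isinstance(v, float) else f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_config(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected 'KEY = value', got {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        out[k] = float(v)
    return out


def read_config(path: str | Path) -> dict[str, float]:
    """Read a flat ``KEY = value`` parameter file ('#' starts a comment)."""
    return _parse_config(Path(path).read_text())


def population_to_config(pop: PopulationModel, group: int = 0) -> dict[str, float]:
    """Flatten a PopulationModel to the config key set."""
    d: dict[str, float] = {}
    for k in ("K_CM", "K_MC", "K_MS", "K_SS", "K_EL"):
        d[k] = getattr(pop.theta, k)
    d["VC"] = pop.theta.Vc
    for k in ZDF_AFFECTED:
        d[k] = getattr(pop.theta, k)
    for k in ZDF_AFFECTED:
        d[f"ZDF_{k}"] = getattr(pop.theta, k) * pop.zdf_effects.get(k, 1.0)
    d["IIV_CV_K_HM"] = 100.0 * math.sqrt(math.expm1(pop.omega_khm ** 2))
    d["IIV_CV_K_HP"] = 100.0 * math.sqrt(math.expm1(pop.omega_khp ** 2))
    d["SIGMA_ADD"] = pop.sigma_add
    d["SIGMA_PROP"] = pop.sigma_prop
    d["GROUP"] = group
    return d


def population_from_config(values: Mapping[str, float]) -> tuple[PopulationModel, int]:
    """Build a PopulationModel from config keys; returns (model, group)."""
    v = dict(values)
    theta = RatePars(K_CM=v["K_CM"], K_MC=v["K_MC"], K_MS=v["K_MS"],
                     K_SS=v["K_SS"], K_EL=v["K_EL"], Vc=v["VC"],
                     K_SH=v["K_SH"], K_HM=v["K_HM"], K_HC=v["K_HC"],
                     K_HP=v["K_HP"], K_PH=v["K_PH"])
    effects = {k: v[f"ZDF_{k}"] / v[k] for k in ZDF_AFFECTED if f"ZDF_{k}" in v}
    pop = PopulationModel(
        theta=theta,
        zdf_effects=effects or {k: 1.0 for k in ZDF_AFFECTED},
        omega_khm=cv_to_omega(v.get("IIV_CV_K_HM", 0.0)),
        omega_khp=cv_to_omega(v.get("IIV_CV_K_HP", 0.0)),
        sigma_add=v.get("SIGMA_ADD", 0.0),
        sigma_prop=v.get("SIGMA_PROP", 0.0),
    )
    return pop, int(v.get("GROUP", 0))


def load_preset(name: str) -> tuple[PopulationModel, int]:
    """Load a shipped preset ('control' or 'zdf'); returns (model, group)."""
    ref = resources.files("metcycle").joinpath(f"presets/{name}.cfg")
    if not ref.is_file():
        raise FileNotFoundError(f"no preset named {name!r}")
    return population_from_config(_parse_config(ref.read_text()))
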