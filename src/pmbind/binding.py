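"""In-vitro membrane-binding analytics.

Covers the three tabular assays used to characterise a peripheral
membrane-binding domain:

* **Vesicle co-sedimentation** — protein incubated with multilamellar
  vesicles is spun down; supernatant (unbound) and pellet (vesicle-bound)
  band densities give a percent binding, optionally corrected against a
  zwitterionic control vesicle lane.
* **Charge-matched vesicle design** — mol% of a phosphoinositide (PIP)
  chosen so that vesicles carry the same total PIP headgroup charge as a
  reference composition (e.g. 5 mol% of a bisphosphate PIP is matched by
  3.3 mol% of the trisphosphate PIP3).
* **Surface plasmon resonance (SPR)** — sensorgrams are control-subtracted,
  saturation responses ``R_eq`` extracted and fitted to the 1:1 Langmuir
  isotherm ``R_eq = R_max / (1 + K_d/[P])``; kinetics are fitted separately,
  with ``k_d`` from single-exponential dissociation decays and ``k_a`` from
  the linear dependence ``k_obs = k_a·[P] + k_d`` of the observed
  association rate on analyte concentration.

Concentrations are molar throughout; responses are in response units (RU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import FitError

# nominal headgroup-charge proxy per PIP class: the number of phosphomonoesters
# on the inositol ring.  This is the table consistent with the printed
# 5 mol% bis <-> 3.3 mol% tris charge-matched design.
PIP_CLASS_CHARGE: Dict[str, float] = {"mono": 1.0, "bis": 2.0, "tris": 3.0}

# an alternative physiological per-headgroup net-charge table (pH ~7)
PHYSIOLOGICAL_CHARGE: Dict[str, float] = {"mono": 3.0, "bis": 4.0, "tris": 6.0}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidComposition:
    """A vesicle lipid composition as a species → mol% map.

    Mol percentages must be nonnegative and sum to 100 ± 0.1.
    """

    species: Dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.species.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("mol% values must be nonnegative")
        total = vals.sum()
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"mol% must sum to 100 +/- 0.1, got {total:g}")

    def molpct(self, name: str) -> float:
        return self.species[name]


def make_pip_composition(
    pip_species: Optional[str] = None,
    pip_molpct: float = 0.0,
    ps_molpct: float = 0.0,
    pe_molpct: float = 20.0,
) -> LipidComposition:
    """Convenience constructor for POPC/POPE(/POPS)(/PIP) vesicle mixes.

    POPC fills to 100 mol%.  ``make_pip_composition()`` is the 80:20
    POPC:POPE control; ``make_pip_composition("PI(4,5)P2", 5)`` is the
    75:20:5 active mix; adding ``ps_molpct=20`` gives the PS-containing
    variants.
    """
    species: Dict[str, float] = {}
    filler = 100.0 - pe_molpct - ps_molpct - pip_molpct
    if filler < 0:
        raise ValueError("mol% components exceed 100")
    species["POPC"] = filler
    species["POPE"] = pe_molpct
    if ps_molpct:
        species["POPS"] = ps_molpct
    if pip_species is not None and pip_molpct:
        species[pip_species] = pip_molpct
    return LipidComposition(species)


@dataclass(frozen=True)
class GelLane:
    """Densitometry of one co-sedimentation lane pair.

    ``supernatant`` and ``pellet`` are band densities in arbitrary
    densitometric units; at least one must be positive.
    """

    lane_id: str
    supernatant: float
    pellet: float
    composition: Optional[LipidComposition] = None

    def __post_init__(self) -> None:
        if self.supernatant < 0 or self.pellet < 0:
            raise ValueError("band densities must be nonnegative")


@dataclass
class Sensorgram:
    """An SPR binding curve: response vs time with phase labels.

    ``phase`` holds ``"association"`` or ``"dissociation"`` per sample; the
    phases must be contiguous and time strictly increasing.
    ``analyte_conc`` is the injected protein concentration [P] in molar.
    """

    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray
    analyte_conc: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time) == len(self.response) == len(self.phase)):
            raise ValueError("time, response and phase must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        labels = [k for k, _ in _contiguous_runs(self.phase)]
        if len(labels) != len(set(labels)):
            raise ValueError("phases must be contiguous")

    def select(self, phase: str) -> "Sensorgram":
        m = self.phase == phase
        if not m.any():
            raise ValueError(f"sensorgram has no {phase!r} phase")
        return Sensorgram(self.time[m], self.response[m], self.phase[m],
                          self.analyte_conc)


def _contiguous_runs(labels: np.ndarray):
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], (start, i)))
            start = i
    return runs


@dataclass(frozen=True)
class IsothermData:
    """Equilibrium (saturation) responses at a series of concentrations."""

    conc: np.ndarray  # [P], molar
    Req: np.ndarray   # RU

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        Req = np.asarray(self.Req, dtype=float)
        if conc.size == 0 or (conc <= 0).any():
            raise ValueError("concentrations must be nonempty and positive")
        if conc.shape != Req.shape:
            raise ValueError("conc and Req must have matching shapes")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "Req", Req)


@dataclass(frozen=True)
class IsothermFit:
    """Langmuir-isotherm fit result."""

    Kd: float          # molar
    Rmax: float        # RU
    Kd_se: float
    Rmax_se: float
    rss: float
    converged: bool

    def predict(self, conc) -> np.ndarray:
        return langmuir_isotherm(np.asarray(conc, dtype=float), self.Kd, self.Rmax)


@dataclass(frozen=True)
class KineticFit:
    """Separate association/dissociation kinetic analysis result."""

    k_a: float                 # 1/(M s)
    k_d: float                 # 1/s
    k_obs: Dict[float, float]  # [P] -> observed association rate, 1/s
    k_obs_intercept: float     # intercept of the k_obs vs [P] regression
    k_d_per_curve: Dict[float, float]

    @property
    def Kd_kinetic(self) -> float:
        """Equilibrium constant implied by the kinetics, k_d / k_a (molar)."""
        return self.k_d / self.k_a


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def langmuir_isotherm(conc, Kd: float, Rmax: float):
    """``R_eq = R_max / (1 + K_d/[P])`` — the 1:1 Langmuir binding isotherm."""
    conc = np.asarray(conc, dtype=float)
    return Rmax / (1.0 + Kd / conc)


def association_response(t, Req: float, k_obs: float):
    """1:1 Langmuir association transient ``R(t) = R_eq (1 - e^{-k_obs t})``."""
    return Req * (1.0 - np.exp(-k_obs * np.asarray(t, dtype=float)))


def dissociation_response(t, R0: float, k_d: float):
    """Single-exponential dissociation decay ``R(t) = R0 e^{-k_d t}``."""
    return R0 * np.exp(-k_d * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# co-sedimentation
# ---------------------------------------------------------------------------

def percent_binding(lane: GelLane, control: Optional[GelLane] = None) -> float:
    """Percent of protein in the pellet (vesicle-bound) fraction.

    ``100 * pellet / (pellet + supernatant)``.  If a control lane
    (zwitterionic vesicles) is given, its raw percent is subtracted and the
    result floored at zero, expressing binding relative to the control
    surface.
    """
    total = lane.pellet + lane.supernatant
    if total <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: zero total band density")
    raw = 100.0 * lane.pellet / total
    if control is None:
        return raw
    return max(raw - percent_binding(control), 0.0)


# ---------------------------------------------------------------------------
# charge-matched composition design
# ---------------------------------------------------------------------------

def charge_matched_molpercent(
    ref_class: str,
    ref_molpct: float,
    target_class: str,
    charge_table: Optional[Dict[str, float]] = None,
) -> float:
    """Mol% of ``target_class`` PIP carrying the same headgroup charge.

    With the default phosphate-count table (mono 1, bis 2, tris 3), 5 mol%
    of a bisphosphate PIP maps to 3.3 mol% PIP3.  The result is reported to
    one decimal, matching how compositions are specified on the bench.
    """
    table = PIP_CLASS_CHARGE if charge_table is None else charge_table
    for cls in (ref_class, target_class):
        if cls not in table:
            raise KeyError(f"unknown PIP class {cls!r}; known: {sorted(table)}")
    if not (ref_molpct > 0):
        raise ValueError("ref_molpct must be positive")
    return round(ref_molpct * table[ref_class] / table[target_class], 1)


# ---------------------------------------------------------------------------
# SPR processing
# ---------------------------------------------------------------------------

def subtract_control(active: Sensorgram, control: Sensorgram,
                     extrapolation_tol: float = 1e-6) -> Sensorgram:
    """Reference-subtract a sensorgram.

    The control (e.g. POPC:POPE 80:20 surface) response is interpolated onto
    the active channel's time grid and subtracted pointwise; phase labels of
    the active channel are preserved.  Raises ``ValueError`` when the control
    does not cover the active time range (beyond ``extrapolation_tol`` s).
    """
    t = active.time
    if (t.min() < control.time.min() - extrapolation_tol
            or t.max() > control.time.max() + extrapolation_tol):
        raise ValueError("control sensorgram does not cover the active time range")
    ctrl = np.interp(t, control.time, control.response)
    return Sensorgram(t, active.response - ctrl, active.phase.copy(),
                      active.analyte_conc)


def extract_Req(sensorgram: Sensorgram, window: Optional[float] = None) -> float:
    """Saturation response: mean over the tail of the association phase.

    ``window`` is in seconds; by default the final 10% of the association
    phase is averaged (at least 5 samples).  Note the estimate is biased low
    on curves that have not reached plateau.
    """
    assoc = sensorgram.select("association")
    t = assoc.time
    duration = t[-1] - t[0]
    if window is None:
        window = max(0.1 * duration, 0.0)
    if window > duration:
        raise ValueError(
            f"window {window:g}s exceeds association phase ({duration:g}s)")
    m = t >= t[-1] - window
    if m.sum() < 5:
        m = np.zeros_like(m)
        m[-min(5, len(t)):] = True
    return float(assoc.response[m].mean())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_isotherm(
    data: IsothermData,
    init: Optional[tuple] = None,
    fix_Rmax: Optional[float] = None,
) -> IsothermFit:
    """Nonlinear least-squares fit of the Langmuir isotherm.

    Initialisation is data-driven unless ``init=(Kd0, Rmax0)`` is given:
    ``Rmax0 = 1.1 * max(Req)`` and ``Kd0`` is the concentration whose
    response is nearest half of that.  Both parameters are constrained
    positive.  ``fix_Rmax`` fits only ``K_d`` with ``R_max`` held.

    Warns when the sampled concentrations do not span the fitted ``K_d``
    (the estimate is then ill-conditioned and its standard error wide).
    """
    conc, Req = data.conc, data.Req
    if np.unique(conc).size < 3:
        raise FitError("need >= 3 distinct concentrations to fit the isotherm")

    if init is not None:
        Kd0, Rmax0 = init
    else:
        Rmax0 = 1.1 * float(Req.max())
        Kd0 = float(conc[np.argmin(np.abs(Req - Rmax0 / 2.0))])
        Kd0 = max(Kd0, np.finfo(float).tiny)

    try:
        if fix_Rmax is not None:
            popt, pcov = optimize.curve_fit(
                lambda c, Kd: langmuir_isotherm(c, Kd, fix_Rmax),
                conc, Req, p0=[Kd0], bounds=(0, np.inf), maxfev=10000)
            Kd, Rmax = float(popt[0]), float(fix_Rmax)
            Kd_se = float(np.sqrt(pcov[0, 0]))
            Rmax_se = 0.0
        else:
            popt, pcov = optimize.curve_fit(
                langmuir_isotherm, conc, Req, p0=[Kd0, Rmax0],
                bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
            Kd, Rmax = map(float, popt)
            Kd_se, Rmax_se = map(float, np.sqrt(np.diag(pcov)))
    except RuntimeError as e:  # pragma: no cover - scipy non-convergence
        raise FitError(f"isotherm fit did not converge: {e}") from e

    if not (conc.min() <= Kd <= conc.max()):
        warnings.warn(
            "fitted K_d lies outside the sampled concentration range; "
            "the estimate is ill-conditioned and its standard error wide",
            stacklevel=2)

    resid = Req - langmuir_isotherm(conc, Kd, Rmax)
    return IsothermFit(Kd=Kd, Rmax=Rmax, Kd_se=Kd_se, Rmax_se=Rmax_se,
                       rss=float(resid @ resid), converged=True)


def _fit_dissociation(sg: Sensorgram) -> float:
    """k_d from a single-exponential fit of one dissociation phase."""
    dis = sg.select("dissociation")
    if len(dis.time) < 10:
        raise FitError(
            f"dissociation phase has {len(dis.time)} samples; need >= 10")
    t = dis.time - dis.time[0]
    R = dis.response
    R0_0 = max(float(R[0]), np.finfo(float).tiny)
    # log-linear slope as a robust rate initialiser
    pos = R > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(R[pos]), 1)[0]
        kd0 = max(-slope, 1e-6)
    else:
        kd0 = 1e-3
    try:
        popt, _ = optimize.curve_fit(dissociation_response, t, R,
                                     p0=[R0_0, kd0], maxfev=10000)
    except RuntimeError as e:  # pragma: no cover
        raise FitError(f"dissociation fit failed at [P]={sg.analyte_conc:g} M") from e
    return float(popt[1])


def _fit_association(sg: Sensorgram) -> float:
    """k_obs from a single-exponential fit of one association phase."""
    assoc = sg.select("association")
    t = assoc.time - assoc.time[0]
    R = assoc.response
    Req0 = max(float(R[-1]), np.finfo(float).tiny)
    # time to half-plateau as a rate initialiser
    half_idx = int(np.argmin(np.abs(R - Req0 / 2.0)))
    t_half = t[half_idx] if t[half_idx] > 0 else (t[1] if len(t) > 1 else 1.0)
    kobs0 = np.log(2.0) / t_half
    try:
        popt, _ = optimize.curve_fit(association_response, t, R,
                                     p0=[Req0, kobs0], maxfev=10000)
    except RuntimeError as e:  # pragma: no cover
        raise FitError(f"association fit failed at [P]={sg.analyte_conc:g} M") from e
    return float(popt[1])


def fit_kinetics(sensorgrams: Sequence[Sensorgram]) -> KineticFit:
    """Separate association/dissociation kinetic analysis (1:1 Langmuir).

    ``k_d`` is the mean of per-curve single-exponential dissociation rates.
    Each association phase yields a ``k_obs``; linear regression of
    ``k_obs`` on [P] gives ``k_a`` (slope).  The regression intercept should
    agree with the fitted ``k_d`` — a useful internal-consistency check.
    Requires at least two distinct concentrations.
    """
    concs = [sg.analyte_conc for sg in sensorgrams]
    if len(set(concs)) < 2:
        raise FitError("need sensorgrams at >= 2 distinct concentrations for k_a")

    k_d_per_curve = {}
    k_obs = {}
    for sg in sensorgrams:
        k_d_per_curve[sg.analyte_conc] = _fit_dissociation(sg)
        k_obs[sg.analyte_conc] = _fit_association(sg)

    k_d = float(np.mean(list(k_d_per_curve.values())))
    xs = np.array(list(k_obs.keys()))
    ys = np.array(list(k_obs.values()))
    reg = stats.linregress(xs, ys)
    if reg.slope <= 0:
        raise FitError("k_obs does not increase with [P]; cannot estimate k_a")
    return KineticFit(k_a=float(reg.slope), k_d=k_d, k_obs=k_obs,
                      k_obs_intercept=float(reg.intercept),
                      k_d_per_curve=k_d_per_curve)
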