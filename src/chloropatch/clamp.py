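"""Reversal-potential and intracellular-chloride estimation.

The gramicidin perforated patch leaves native intracellular chloride
intact, so the reversal potential of the GABA_A current (E_GABA) equals
the chloride equilibrium potential. The workflow implemented here:

1. measure the peak GABA-evoked current at each command potential
   (:func:`peak_gaba_current`), baseline-subtracted, inward negative;
2. correct each command potential for the series-resistance voltage drop
   V_corr = V_com − I_clamp·R_s (:func:`correct_series_resistance`),
   where I_clamp is the total clamp current at the response peak;
3. fit the peak I–V relation with a straight line and read E_GABA at the
   zero crossing (:class:`ReversalPotentialEstimator`);
4. convert E_GABA to [Cl−]i with the Nernst equation for a monovalent
   anion, [Cl−]i = [Cl−]o · exp(E_GABA·F / (R·T))
   (:func:`chloride_from_nernst`).

Unit bookkeeping is explicit throughout: mV, pA, MΩ, with
1 pA × 1 MΩ = 10⁻³ mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .trace import Trace

__all__ = [
    "NernstParams", "IVPoint", "ReversalFit", "ChlorideEstimate",
    "ClampMeta", "CorrectedPotential", "ReversalPotentialEstimator",
    "correct_series_resistance", "peak_gaba_current", "iv_points_from_traces",
    "estimate_reversal", "chloride_from_nernst", "nernst_potential",
    "chloride_from_solution", "apply_ljp", "estimate_chloride",
    "CHLORIDE_STOICHIOMETRY",
]

FARADAY = sc.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT = sc.R  # J/(mol·K)


@dataclass(frozen=True)
class NernstParams:
    """Constants for the chloride Nernst relation.

    Defaults: extracellular chloride from the standard ACSF recipe
    (132.5 mM) and a 30 °C perfusate (303.15 K). The valence is fixed at
    −1 for chloride.
    """

    cl_out_mm: float = 132.5
    temperature_k: float = 303.15
    gas_constant: float = GAS_CONSTANT
    faraday: float = FARADAY
    valence: int = -1

    def __post_init__(self) -> None:
        if not self.cl_out_mm > 0:
            raise ValueError("[Cl-]o must be positive")
        if not self.temperature_k > 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.valence != -1:
            raise ValueError("valence is fixed at -1 for chloride")

    @property
    def slope_mv(self) -> float:
        """RT/F in millivolts (≈ 26.1 mV at 30 °C)."""
        return 1000.0 * self.gas_constant * self.temperature_k / self.faraday


def correct_series_resistance(v_com_mv: float, i_clamp_pa: float,
                              r_s_mohm: float) -> float:
    """Membrane potential corrected for the series-resistance drop.

    V_corr = V_com − I_clamp·R_s with exact unit handling:
    1 pA × 1 MΩ = 10⁻³ mV.
    """
    if r_s_mohm < 0:
        raise ValueError("series resistance must be non-negative")
    return v_com_mv - i_clamp_pa * r_s_mohm * 1e-3


@dataclass
class IVPoint:
    """One point of a peak-current I–V relation.

    ``i_peak_pa`` is the baseline-subtracted peak GABA-evoked current
    (inward negative) — the ordinate of the fit. ``i_total_pa`` is the
    total clamp current at the peak (holding + evoked), the current that
    actually flows through the series resistance and therefore the one
    used in the V_corr correction; if omitted the evoked peak is used.
    """

    v_com_mv: float
    i_peak_pa: float
    r_s_mohm: float = 0.0
    i_total_pa: float | None = None
    v_corr_mv: float = field(init=False)

    def __post_init__(self) -> None:
        i_for_drop = self.i_total_pa if self.i_total_pa is not None \
            else self.i_peak_pa
        self.v_corr_mv = correct_series_resistance(
            self.v_com_mv, i_for_drop, self.r_s_mohm)


def peak_gaba_current(trace: Trace, stim_time: float,
                      baseline_window: float = 0.1,
                      response_window: float = 0.1,
                      smooth_ms: float = 1.0) -> float:
    """Signed peak of the baseline-subtracted response (inward negative).

    Baseline is the mean over ``baseline_window`` seconds immediately
    before ``stim_time``; the peak is the extremum of (trace − baseline)
    within ``response_window`` seconds after the stimulus. A short boxcar
    (``smooth_ms``) suppresses sample noise before the extremum search.
    """
    peak, _total, _base = _peak_details(trace, stim_time, baseline_window,
                                        response_window, smooth_ms)
    return peak


def _peak_details(trace: Trace, stim_time: float, baseline_window: float,
                  response_window: float, smooth_ms: float,
                  ) -> tuple[float, float, float]:
    if baseline_window <= 0 or response_window <= 0:
        raise ValueError("windows must be positive")
    base = trace.window(stim_time - baseline_window, stim_time)
    resp = trace.window(stim_time, stim_time + response_window)
    x = resp
    if smooth_ms > 0:
        w = max(int(round(smooth_ms / 1000.0 * trace.sampling_rate)), 1)
        if w > 1:
            # edge-replicating boxcar: a zero-padded convolution would
            # drag the window edges toward 0 and fake an extremum there
            from scipy.ndimage import uniform_filter1d
            x = uniform_filter1d(resp, size=w, mode="nearest")
    baseline = float(base.mean())
    delta = x - baseline
    idx = int(np.argmax(np.abs(delta)))
    return float(delta[idx]), float(x[idx]), baseline


def iv_points_from_traces(traces: dict[float, Trace], stim_time: float,
                          r_s_mohm: float, baseline_window: float = 0.1,
                          response_window: float = 0.1,
                          smooth_ms: float = 1.0) -> list[IVPoint]:
    """Build Rs-corrected I–V points from per-potential response traces."""
    points = []
    for v_com, trace in sorted(traces.items()):
        peak, total, _ = _peak_details(trace, stim_time, baseline_window,
                                       response_window, smooth_ms)
        points.append(IVPoint(v_com_mv=v_com, i_peak_pa=peak,
                              r_s_mohm=r_s_mohm, i_total_pa=total))
    return points


@dataclass
class ReversalFit:
    """Diagnostics of the straight-line I–V fit."""

    slope_ns: float
    intercept_pa: float
    residual_rms_pa: float
    v_span_mv: tuple[float, float]
    extrapolated: bool
    n_points: int


class ReversalPotentialEstimator(RegressorMixin, BaseEstimator):
    """Least-squares straight line through peak I–V points.

    The GABA_A current near its reversal is approximately ohmic, so
    E_GABA is read off as the zero crossing of a linear fit of peak
    current (pA) against corrected membrane potential (mV). A slope that
    is not strictly positive (non-physical conductance) is an error, as
    is extrapolating the crossing more than ``max_extrapolation_mv``
    beyond the sampled span.

    Attributes (after ``fit``): ``slope_ns_``, ``intercept_pa_``,
    ``e_rev_mv_``, ``fit_`` (a :class:`ReversalFit`).
    """

    def __init__(self, max_extrapolation_mv: float = 10.0):
        self.max_extrapolation_mv = max_extrapolation_mv

    def fit(self, X, y):
        """Fit I = slope·V + intercept.

        X: corrected potentials in mV, shape (n,) or (n, 1).
        y: peak currents in pA, shape (n,).
        """
        v = np.asarray(X, dtype=float).reshape(-1)
        i = np.asarray(y, dtype=float).reshape(-1)
        if v.size != i.size:
            raise ValueError("X and y must have equal length")
        if np.unique(v).size < 2:
            raise ValueError("need >= 2 distinct potentials to fit a line")
        slope, intercept = np.polyfit(v, i, 1)
        if slope <= 0:
            raise ValueError(
                "non-physical fit: slope (conductance) must be positive")
        e_rev = -intercept / slope
        lo, hi = float(v.min()), float(v.max())
        over = max(lo - e_rev, e_rev - hi, 0.0)
        if over > self.max_extrapolation_mv:
            raise ValueError(
                f"reversal {e_rev:.1f} mV extrapolates {over:.1f} mV beyond "
                f"the sampled span [{lo:.1f}, {hi:.1f}] mV")
        resid = i - (slope * v + intercept)
        self.slope_ns_ = float(slope)          # pA/mV = nS
        self.intercept_pa_ = float(intercept)
        self.e_rev_mv_ = float(e_rev)
        self.fit_ = ReversalFit(
            slope_ns=self.slope_ns_, intercept_pa=self.intercept_pa_,
            residual_rms_pa=float(np.sqrt(np.mean(resid ** 2))),
            v_span_mv=(lo, hi), extrapolated=over > 0, n_points=v.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_ns_")
        v = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ns_ * v + self.intercept_pa_


def estimate_reversal(points: list[IVPoint],
                      max_extrapolation_mv: float = 10.0,
                      ) -> tuple[float, ReversalFit]:
    """E_GABA (mV) and fit diagnostics from Rs-corrected I–V points."""
    est = ReversalPotentialEstimator(max_extrapolation_mv)
    est.fit([p.v_corr_mv for p in points], [p.i_peak_pa for p in points])
    return est.e_rev_mv_, est.fit_


def chloride_from_nernst(e_gaba_mv: float,
                         params: NernstParams = NernstParams()) -> float:
    """[Cl−]i (mM) from E_GABA via the Nernst equation (z = −1).

    [Cl−]i = [Cl−]o · exp(E_GABA / (RT/F)); strictly increasing in
    E_GABA, equal to [Cl−]o at 0 mV.
    """
    return params.cl_out_mm * math.exp(e_gaba_mv / params.slope_mv)


def nernst_potential(cl_in_mm: float,
                     params: NernstParams = NernstParams()) -> float:
    """Chloride equilibrium potential (mV); inverse of
    :func:`chloride_from_nernst`."""
    if not cl_in_mm > 0:
        raise ValueError("[Cl-]i must be positive")
    return params.slope_mv * math.log(cl_in_mm / params.cl_out_mm)


# Chloride ions released per formula unit for the salts that appear in
# standard ACSF / pipette recipes. Anything absent must be declared
# explicitly by the caller — unknown salts are never silently ignored.
CHLORIDE_STOICHIOMETRY: dict[str, int] = {
    "NaCl": 1, "KCl": 1, "CsCl": 1, "HCl": 1, "LiCl": 1, "choline-Cl": 1,
    "CaCl2": 2, "MgCl2": 2, "BaCl2": 2, "CoCl2": 2,
    "NaH2PO4": 0, "NaHCO3": 0, "MgSO4": 0, "Mg2SO4": 0, "CaSO4": 0,
    "glucose": 0, "sucrose": 0, "HEPES": 0, "EGTA": 0, "EGTA-KOH": 0,
    "K-CH3SO3": 0, "K-gluconate": 0, "Cs-methanesulfonate": 0,
    "Mg-ATP": 0, "Na2-GTP": 0, "Na2GTP": 0, "QX314": 0,
}


def chloride_from_solution(recipe: dict[str, float],
                           stoichiometry: dict[str, int] | None = None,
                           ) -> float:
    """Total chloride (mM) delivered by a solution recipe.

    ``recipe`` maps salt names to concentrations in mM. Salts outside
    the built-in table must be supplied via ``stoichiometry``; an
    undeclared salt raises rather than guessing. Example: standard ACSF
    (126 NaCl, 2.5 KCl, 2.0 CaCl₂, …) → 132.5 mM.
    """
    table = dict(CHLORIDE_STOICHIOMETRY)
    if stoichiometry:
        table.update(stoichiometry)
    total = 0.0
    for salt, conc in recipe.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {salt}")
        if salt not in table:
            raise KeyError(
                f"unknown salt '{salt}': declare its chloride "
                f"stoichiometry explicitly")
        total += conc * table[salt]
    return total


@dataclass(frozen=True)
class ClampMeta:
    """Recording metadata: junction potential, holding, temperature."""

    liquid_junction_potential_mv: float = 10.5
    holding_potential_mv: float | None = None
    temperature_c: float = 30.0


@dataclass(frozen=True)
class CorrectedPotential:
    """A potential that has already been junction-corrected.

    Carrying the applied LJP as provenance lets :func:`apply_ljp` refuse
    to correct twice.
    """

    mv: float
    ljp_mv: float


def apply_ljp(v_measured_mv: float | CorrectedPotential,
              meta: ClampMeta | float) -> CorrectedPotential:
    """Junction-correct a measured potential: corrected = measured − LJP.

    With the +10.5 mV junction potential of the recording solutions this
    makes reported potentials more negative (−51.1 mV → −61.6 mV).
    Passing an already-corrected value raises.
    """
    if isinstance(v_measured_mv, CorrectedPotential):
        raise ValueError("potential already junction-corrected; "
                         "refusing to correct twice")
    ljp = meta.liquid_junction_potential_mv if isinstance(meta, ClampMeta) \
        else float(meta)
    return CorrectedPotential(mv=float(v_measured_mv) - ljp, ljp_mv=ljp)


@dataclass
class ChlorideEstimate:
    """E_GABA with its Nernst-derived intracellular chloride."""

    e_gaba_mv: float
    cl_in_mm: float
    params: NernstParams
    fit: ReversalFit | None = None


def estimate_chloride(points: list[IVPoint],
                      params: NernstParams = NernstParams(),
                      ) -> ChlorideEstimate:
    """Full I–V → E_GABA → [Cl−]i pipeline on Rs-corrected points."""
    e_gaba, fit = estimate_reversal(points)
    return ChlorideEstimate(e_gaba_mv=e_gaba,
                            cl_in_mm=chloride_from_nernst(e_gaba, params),
                            params=params, fit=fit)
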