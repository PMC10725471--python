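"""Curve fits and quantifications for the biochemical/cellular readouts.

Covers the one-site specific-binding isotherm (microscale thermophoresis
K_D), the constrained four-parameter logistic for fluorescence-
polarization competition (IC50 with fixed top/bottom anchors), the
two-state Boltzmann melt curve for cellular thermal-shift data (Tm and
delta-Tm), Bliss-independence synergy scoring of dose-by-dose viability
matrices, size-exclusion-chromatography monomer/dimer/oligomer fraction
percentages and molecular-weight calibration, and AUC-normalised
mitochondrial-depolarization percentages.

All fits are plain least squares (scipy ``curve_fit``) with documented,
deterministic initial values; results carry parameters, standard
errors, the residual sum of squares and a convergence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingIsotherm",
    "MeltCurve",
    "DoseMatrix",
    "SynergyMap",
    "SECProfile",
    "DepolarizationTraces",
    "CurveFitResult",
    "fit_one_site",
    "fit_competitive_4pl",
    "normalize_melt",
    "normalize_and_fit_melt",
    "delta_tm",
    "bliss_synergy",
    "sec_quantify",
    "sec_mw_calibrate",
    "depolarization_percent",
    "CETSA_GRADIENT_C",
    "CETSA_ANCHOR_C",
]

# CETSA heating gradient (deg C) and the room-temperature anchor used
# for normalisation (anchor maps to 100%, the hottest point to 0%).
CETSA_GRADIENT_C = (50.0, 52.1, 55.4, 59.4, 64.9, 69.2, 72.1, 74.0)
CETSA_ANCHOR_C = 25.0

# SEC fraction windows: monomer and dimer split the straddling C6
# fraction half/half; the oligomer window is optional.
SEC_MONOMER_FRACTIONS = ("C7", "C8", "C9")
SEC_DIMER_FRACTIONS = ("C3", "C4", "C5")
SEC_OLIGOMER_FRACTIONS = ("C2", "C1", "B1", "B2")
SEC_SPLIT_FRACTION = "C6"


@dataclass
class CurveFitResult:
    model_name: str
    parameters: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class BindingIsotherm:
    """Titration of ligand concentration (nM) against binding response."""

    concentrations: np.ndarray  # nM, strictly increasing
    response: np.ndarray  # fraction bound or raw signal
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.shape != self.response.shape:
            raise ValueError("concentration/response length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


def _one_site(L: np.ndarray, kd: float, bmax: float, baseline: float) -> np.ndarray:
    return bmax * L / (kd + L) + baseline


def fit_one_site(isotherm: BindingIsotherm) -> CurveFitResult:
    """One-site specific binding: response = Bmax*[L]/(K_D+[L]) + baseline.

    Initialisation: K_D at the concentration nearest half-maximal
    response, Bmax at the response range, baseline at the minimum.
    K_D is boxed to [1e-3, 1e7] nM; a fit pinned at either box edge is
    flagged.
    """
    L, y = isotherm.concentrations, isotherm.response
    if L.size < 5:
        raise ValueError("need at least 5 titration points")
    if L.max() / L.min() < 100:
        raise ValueError("titration must span at least 2 orders of magnitude")
    flags: list[str] = []
    span = y.max() - y.min()
    half = y.min() + span / 2
    kd0 = float(L[np.argmin(np.abs(y - half))])
    p0 = [kd0, span if span > 0 else 1.0, float(y.min())]
    lo = [1e-3, -np.inf, -np.inf]
    hi = [1e7, np.inf, np.inf]
    try:
        popt, pcov = curve_fit(_one_site, L, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return CurveFitResult("one_site", dict(zip(("K_D", "B_max", "baseline"), p0)),
                              {}, float("nan"), False, ["no convergence"])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    kd, bmax, baseline = popt
    rss = float(np.sum((_one_site(L, *popt) - y) ** 2))
    if kd <= lo[0] * 1.001 or kd >= hi[0] * 0.999:
        flags.append("K_D at box bound")
        converged = False
    if span > 0 and abs(bmax) < 0.05 * span:
        flags.append("B_max near zero: no dynamic range")
    if span == 0:
        flags.append("zero dynamic range")
        converged = False
    return CurveFitResult(
        "one_site",
        {"K_D": float(kd), "B_max": float(bmax), "baseline": float(baseline)},
        {"K_D": float(perr[0]), "B_max": float(perr[1]), "baseline": float(perr[2])},
        rss,
        converged,
        flags,
    )


def fit_competitive_4pl(
    concentrations: np.ndarray,
    response: np.ndarray,
    top_fixed: float,
    bottom_fixed: float,
) -> CurveFitResult:
    """Four-parameter logistic with fixed top and bottom plateaus.

    response = bottom + (top - bottom) / (1 + (x / IC50)^h); only IC50
    and the Hill slope h are free.  The anchors come from the saturated
    and probe-only polarization controls.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    flags: list[str] = []
    span = top_fixed - bottom_fixed
    if span == 0:
        raise ValueError("top and bottom anchors are equal")
    # fraction of the window actually traversed by the data
    traversed = (np.max(y) - np.min(y)) / abs(span)
    if traversed < 0.1:
        flags.append("response spans <10% of the anchor window: IC50 unidentifiable")

    def model(x, ic50, h):
        return bottom_fixed + span / (1 + (x / ic50) ** h)

    mid = bottom_fixed + span / 2
    ic50_0 = float(x[np.argmin(np.abs(y - mid))])
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[ic50_0, 1.0],
            bounds=([1e-6, 0.05], [1e9, 20.0]), maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return CurveFitResult("competitive_4pl", {"IC50": ic50_0, "hill": 1.0},
                              {}, float("nan"), False, flags + ["no convergence"])
    if flags:
        converged = False
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    return CurveFitResult(
        "competitive_4pl",
        {"IC50": float(popt[0]), "hill": float(popt[1]),
         "top": float(top_fixed), "bottom": float(bottom_fixed)},
        {"IC50": float(perr[0]), "hill": float(perr[1])},
        rss,
        converged,
        flags,
    )


@dataclass
class MeltCurve:
    """Thermal-denaturation signal versus temperature.

    ``anchors`` are the (low, high) temperatures whose signals define
    100% and 0% after normalisation; both must be present among the
    measured temperatures.
    """

    temperatures: np.ndarray  # deg C, strictly increasing
    signal: np.ndarray
    anchors: tuple[float, float] = (CETSA_ANCHOR_C, 74.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperature/signal length mismatch")


def _anchor_signal(curve: MeltCurve, temp: float) -> float:
    i = np.where(np.isclose(curve.temperatures, temp))[0]
    if i.size == 0:
        raise ValueError(f"anchor temperature {temp} not measured")
    return float(curve.signal[i[0]])


def normalize_melt(curve: MeltCurve) -> MeltCurve:
    """Rescale so the low anchor maps to 100% and the high anchor to 0%."""
    lo_sig = _anchor_signal(curve, curve.anchors[0])
    hi_sig = _anchor_signal(curve, curve.anchors[1])
    if lo_sig == hi_sig:
        raise ValueError("anchor signals are equal; cannot normalise")
    pct = 100.0 * (curve.signal - hi_sig) / (lo_sig - hi_sig)
    return MeltCurve(curve.temperatures, pct, curve.anchors, curve.label)


def _boltzmann(T: np.ndarray, tm: float, k: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp((T - tm) / k))


def normalize_and_fit_melt(curve: MeltCurve) -> CurveFitResult:
    """Anchor-normalise and fit the two-state Boltzmann sigmoid.

    f(T) = 100 / (1 + exp((T - Tm)/k)); Tm is the inflection point.  A
    warning flag is raised when the normalised signal rises with
    temperature by more than 10 percentage points anywhere (melting
    should be monotone down, up to noise).
    """
    norm = normalize_melt(curve)
    flags: list[str] = []
    if np.any(np.diff(norm.signal) > 10.0):
        flags.append("non-monotone melt beyond noise")
    T, y = norm.temperatures, norm.signal
    mid_idx = int(np.argmin(np.abs(y - 50.0)))
    p0 = [float(T[mid_idx]), 2.0]
    try:
        popt, pcov = curve_fit(
            _boltzmann, T, y, p0=p0,
            bounds=([T.min() - 20, 0.05], [T.max() + 20, 50.0]), maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return CurveFitResult("boltzmann_melt", {"Tm": p0[0], "k": p0[1]},
                              {}, float("nan"), False, flags + ["no convergence"])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    rss = float(np.sum((_boltzmann(T, *popt) - y) ** 2))
    return CurveFitResult(
        "boltzmann_melt",
        {"Tm": float(popt[0]), "k": float(popt[1])},
        {"Tm": float(perr[0]), "k": float(perr[1])},
        rss,
        converged,
        flags,
    )


def delta_tm(fit_treated: CurveFitResult, fit_control: CurveFitResult) -> float:
    """Melting-point decrease, control minus treated (destabilisation > 0)."""
    return fit_control.parameters["Tm"] - fit_treated.parameters["Tm"]


@dataclass
class DoseMatrix:
    """Dose-by-dose loss-of-viability grid including zero-dose marginals."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    effect: np.ndarray  # fraction in [0, 1], shape (len(doses_a), len(doses_b))
    agents: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        if self.effect.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("effect shape does not match dose axes")
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ValueError("dose grids must start with a zero dose")
        if np.any(self.effect < 0) or np.any(self.effect > 1):
            raise ValueError("effects must lie in [0, 1]")


@dataclass
class SynergyMap:
    expected: np.ndarray  # Bliss-independent surface
    score: np.ndarray  # observed - expected, per cell
    summary: float  # mean score over cells with both doses nonzero


def bliss_synergy(matrix: DoseMatrix) -> SynergyMap:
    """Bliss independence: expected = fA + fB - fA*fB from the marginals.

    The single-agent marginals are the zero-dose row/column of the
    observed grid, so zero-dose cells score 0 by construction.  Positive
    scores indicate synergy, negative antagonism.
    """
    fa = matrix.effect[:, 0]  # effect of A alone, over doses_a
    fb = matrix.effect[0, :]  # effect of B alone, over doses_b
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    score = matrix.effect - expected
    interior = np.ix_(matrix.doses_a > 0, matrix.doses_b > 0)
    summary = float(score[interior].mean()) if score[interior].size else 0.0
    return SynergyMap(expected, score, summary)


@dataclass
class SECProfile:
    """Band intensity per labelled elution fraction (arbitrary units)."""

    fraction_labels: list[str]
    intensity: np.ndarray
    elution_volumes: np.ndarray | None = None  # ml, optional

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.fraction_labels) != self.intensity.size:
            raise ValueError("label/intensity length mismatch")
        if len(set(self.fraction_labels)) != len(self.fraction_labels):
            raise ValueError("fraction labels must be unique")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def get(self, label: str) -> float:
        try:
            return float(self.intensity[self.fraction_labels.index(label)])
        except ValueError:
            return 0.0


def sec_quantify(profile: SECProfile) -> dict[str, float]:
    """Percent monomer / dimer / oligomer from fraction windows.

    %monomer = (C6/2 + C7 + C8 + C9) / total * 100
    %dimer   = (C3 + C4 + C5 + C6/2) / total * 100
    %oligomer sums the (optional) C2/C1/B1/B2 window.  ``total`` is the
    summed intensity of every reported fraction.
    """
    for lab in SEC_MONOMER_FRACTIONS + SEC_DIMER_FRACTIONS + (SEC_SPLIT_FRACTION,):
        if lab not in profile.fraction_labels:
            raise ValueError(f"fraction {lab} missing from profile")
    total = float(profile.intensity.sum())
    if total <= 0:
        raise ValueError("zero total intensity")
    half_c6 = profile.get(SEC_SPLIT_FRACTION) / 2
    monomer = half_c6 + sum(profile.get(l) for l in SEC_MONOMER_FRACTIONS)
    dimer = half_c6 + sum(profile.get(l) for l in SEC_DIMER_FRACTIONS)
    oligomer = sum(profile.get(l) for l in SEC_OLIGOMER_FRACTIONS)
    return {
        "monomer_pct": 100.0 * monomer / total,
        "dimer_pct": 100.0 * dimer / total,
        "oligomer_pct": 100.0 * oligomer / total,
    }


def sec_mw_calibrate(
    standards: Sequence[tuple[float, float]],
) -> Callable[[float], tuple[float, bool]]:
    """Log-linear molecular-weight calibration from elution standards.

    Fits log10(MW kDa) against elution volume (ml); returns an estimator
    ``volume -> (MW kDa, extrapolated)`` where the flag marks queries
    outside the standards' volume range.
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    vols = np.array([s[0] for s in standards], dtype=float)
    mws = np.array([s[1] for s in standards], dtype=float)
    if len(set(vols.tolist())) != vols.size:
        raise ValueError("duplicate standard volumes")
    slope, intercept = np.polyfit(vols, np.log10(mws), 1)
    lo, hi = vols.min(), vols.max()

    def estimate(volume: float) -> tuple[float, bool]:
        mw = float(10 ** (slope * volume + intercept))
        return mw, not (lo <= volume <= hi)

    return estimate


@dataclass
class DepolarizationTraces:
    """JC-1 style fluorescence time courses on a shared grid (minutes)."""

    time_min: np.ndarray
    samples: Mapping[str, np.ndarray]
    dmso: np.ndarray  # solvent-only control (0% depolarization)
    cccp: np.ndarray  # uncoupler control (100% depolarization)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.time_min.size < 2:
            raise ValueError("need at least 2 time points")
        self.dmso = np.asarray(self.dmso, dtype=float)
        self.cccp = np.asarray(self.cccp, dtype=float)
        for name, trace in [("dmso", self.dmso), ("cccp", self.cccp)] + list(
            self.samples.items()
        ):
            if np.asarray(trace).shape != self.time_min.shape:
                raise ValueError(f"trace {name!r} not on the common time grid")


def depolarization_percent(
    traces: DepolarizationTraces,
) -> dict[str, dict[str, object]]:
    """AUC-normalised percent depolarization per sample.

    percent = 100 * (AUC_DMSO - AUC_sample) / (AUC_DMSO - AUC_CCCP);
    trapezoidal AUC over the common grid.  Values outside [0, 100] are
    reported as-is with a flag, never clipped.
    """
    auc = lambda y: float(np.trapezoid(y, traces.time_min))
    auc_dmso, auc_cccp = auc(traces.dmso), auc(traces.cccp)
    if auc_dmso == auc_cccp:
        raise ValueError("DMSO and CCCP AUCs are equal: no dynamic range")
    out: dict[str, dict[str, object]] = {}
    for name, trace in traces.samples.items():
        pct = 100.0 * (auc_dmso - auc(np.asarray(trace, dtype=float))) / (
            auc_dmso - auc_cccp
        )
        out[name] = {"percent": pct, "out_of_range": not (0.0 <= pct <= 100.0)}
    return out
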