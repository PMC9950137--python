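"""Enzyme-kinetics analysis for flavoprotein monooxygenase characterisation.

Covers the standard bench analyses around a flavin-dependent monooxygenase:

- steady-state Michaelis-Menten fits of initial rates (coenzyme and
  substrate saturation), with k_cat and catalytic efficiency in s-1 mM-1;
- observed rates from NAD(P)H depletion at 340 nm (eps340 = 6.22 mM-1 cm-1),
  including uncoupling rates measured without substrate;
- single-exponential fits of stopped-flow traces (flavin reduction k_red,
  single-wavelength oxidation phases);
- global deconvolution of time x wavelength stopped-flow matrices into a
  two-step sequential process a ->(k1) b ->(k2) c by variable projection
  (species spectra are linear at fixed rate constants), resolving the
  C4a-(hydro)peroxyflavin intermediate spectrum;
- hyperbolic oxygen-affinity fits (K_M^O2);
- substrate-depletion conversions normalised to an internal standard;
- melting temperatures from the derivative of a melt curve; and
- holoenzyme quantitation from FAD absorbance (eps450 = 11.3 mM-1 cm-1).

Standard errors come from the covariance at the least-squares optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

logger = logging.getLogger(__name__)

EPSILON_NADPH_340 = 6.22  # mM^-1 cm^-1
EPSILON_FAD_450 = 11.3  # mM^-1 cm^-1

_UNIT_TO_MM = {"M": 1e3, "mM": 1.0, "uM": 1e-3, "µM": 1e-3, "nM": 1e-6}


class FitError(RuntimeError):
    pass


@dataclass
class InitialRateDataset:
    """Initial rates at varied concentrations of one species."""

    conc: np.ndarray
    rate: np.ndarray
    conc_unit: str = "uM"
    rate_unit: str = "s-1"
    enzyme_conc_uM: float | None = None
    replicate: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.conc.shape != self.rate.shape:
            raise ValueError("conc and rate differ in shape")
        if (self.conc < 0).any():
            raise ValueError("negative concentration")
        if self.conc_unit not in _UNIT_TO_MM:
            raise ValueError(f"unknown concentration unit {self.conc_unit!r}")


@dataclass
class MMFit:
    """Michaelis-Menten fit: v = Vmax * S / (K_M + S)."""

    km: float
    km_se: float
    vmax: float
    vmax_se: float
    conc_unit: str
    kcat: float | None = None
    kcat_se: float | None = None
    efficiency: float | None = None  # k_cat / K_M in s-1 mM-1
    efficiency_se: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)
    warnings: list[str] = field(default_factory=list)


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(dataset: InitialRateDataset) -> MMFit:
    """Unweighted nonlinear least-squares Michaelis-Menten fit.

    When the dataset carries an enzyme concentration (uM) and rates in s-1
    units of turnover, k_cat = Vmax and the catalytic efficiency
    k_cat / K_M is reported in s-1 mM-1.  When rates are Vmax-style
    (not normalised), supply enzyme_conc_uM and rate units consistent with
    concentration per second.
    """
    S, v = dataset.conc, dataset.rate
    if len(np.unique(S)) < 4:
        raise FitError("need at least 4 distinct concentrations")
    warns = []
    vmax0 = float(np.max(v)) or 1.0
    half = vmax0 / 2.0
    km0 = float(S[np.argmin(np.abs(v - half))]) or float(np.median(S[S > 0]))
    try:
        popt, pcov = optimize.curve_fit(
            _mm, S, v, p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
            xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    vmax_se, km_se = np.sqrt(np.diag(pcov))
    if km > S.max():
        warns.append("K_M above the highest tested concentration (extrapolated)")
    if km < S.min():
        warns.append("K_M below the lowest tested concentration (extrapolated)")
    if km_se > km:
        warns.append("low-information design: SE(K_M) exceeds K_M")
    fit = MMFit(
        km=km, km_se=km_se, vmax=vmax, vmax_se=vmax_se,
        conc_unit=dataset.conc_unit, residuals=v - _mm(S, *popt), warnings=warns,
    )
    km_mM = km * _UNIT_TO_MM[dataset.conc_unit]
    km_mM_se = km_se * _UNIT_TO_MM[dataset.conc_unit]
    if dataset.rate_unit == "s-1":
        kcat, kcat_se = vmax, vmax_se
    elif dataset.enzyme_conc_uM:
        # rate in concentration-units per second; normalise by [E]
        kcat = vmax * _UNIT_TO_MM[dataset.conc_unit] / (
            dataset.enzyme_conc_uM * 1e-3
        )
        kcat_se = vmax_se * _UNIT_TO_MM[dataset.conc_unit] / (
            dataset.enzyme_conc_uM * 1e-3
        )
    else:
        kcat = kcat_se = None
    if kcat is not None:
        fit.kcat, fit.kcat_se = kcat, kcat_se
        fit.efficiency = kcat / km_mM
        # first-order error propagation for the ratio
        fit.efficiency_se = fit.efficiency * np.sqrt(
            (kcat_se / kcat) ** 2 + (km_mM_se / km_mM) ** 2
        )
    return fit


# ---------------------------------------------------------------------------
# Initial-rate extraction from 340 nm traces


def _initial_linear_slope(
    t: np.ndarray, A: np.ndarray, r2_min: float = 0.995,
    max_depletion: float = 0.10, min_points: int = 5,
) -> tuple[float, int]:
    """Slope of the longest initial segment that is linear (R^2 >= r2_min)
    and spans at most ``max_depletion`` of the total observed change.

    Within the selected window a quadratic is fitted and its derivative at
    the first time point reported, correcting the small first-order bias a
    straight line picks up from downward curvature."""
    t = np.asarray(t, float)
    A = np.asarray(A, float)
    total = abs(A[-1] - A[0])
    if total < 1e-12 or np.std(A) < 1e-12:
        return 0.0, len(t)  # flat trace
    best = None
    for n in range(min_points, len(t) + 1):
        x, y = t[:n], A[:n]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        depleted = abs(y[-1] - y[0]) / total
        if r2 >= r2_min and (depleted <= max_depletion or n == min_points):
            best = (slope, n)
        elif best is not None and r2 < r2_min:
            break
    if best is None:
        raise FitError("no initial linear segment found")
    slope, n = best
    if n >= 8:
        coeffs = np.polyfit(t[:n] - t[0], A[:n], 2)
        slope = coeffs[1]  # dA/dt at the window start
    return slope, n


def rate_from_A340(
    t,
    absorbance,
    epsilon: float = EPSILON_NADPH_340,
    path_length: float = 1.0,
    enzyme_conc_uM: float | None = None,
) -> float:
    """Observed rate from an NAD(P)H depletion trace at 340 nm.

    The initial linear slope (|dA/dt|) is converted with Beer-Lambert
    (epsilon in mM-1 cm-1) to mM/s and, when the enzyme concentration (uM)
    is given, normalised to a turnover rate in s-1.  Run without substrate
    this measures the uncoupling rate.
    """
    slope, _ = _initial_linear_slope(np.asarray(t), np.asarray(absorbance))
    rate_mM_s = abs(slope) / (epsilon * path_length)
    if enzyme_conc_uM is None:
        return rate_mM_s
    return rate_mM_s / (enzyme_conc_uM * 1e-3)


# ---------------------------------------------------------------------------
# Exponential fits


@dataclass
class ExpFit:
    """Single-exponential fit A(t) = A_inf + dA * exp(-k t)."""

    k: float
    k_se: float
    a0: float
    a_inf: float
    residuals: np.ndarray = field(repr=False, default=None)
    runs_pvalue: float | None = None
    warnings: list[str] = field(default_factory=list)


def _runs_test_pvalue(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test (normal approximation) on residual signs.
    Small p suggests structure left in the residuals (e.g. a second phase)."""
    from scipy.stats import norm

    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n1 = int((signs > 0).sum())
    n2 = int((signs < 0).sum())
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int((signs[1:] != signs[:-1]).sum())
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def fit_single_exponential(t, absorbance) -> ExpFit:
    """Fit one exponential phase to a stopped-flow trace.

    Used for flavin reduction (k_red) and single-wavelength oxidation
    phases (k_obs); a runs test on the residuals flags biphasic traces that
    should go to the sequential two-step model instead.
    """
    t = np.asarray(t, float)
    A = np.asarray(absorbance, float)
    a_inf0 = A[-1]
    da0 = A[0] - a_inf0
    span = abs(da0)
    if span < 1e-15:
        raise FitError("trace has no amplitude")
    # time at which ~63% of the change has happened
    frac = np.abs(A - A[0]) / span
    idx = np.argmax(frac >= 0.632) if (frac >= 0.632).any() else len(t) - 1
    k0 = 1.0 / max(t[idx], t[1] if len(t) > 1 else 1.0)

    def model(t, a_inf, da, k):
        return a_inf + da * np.exp(-k * t)

    try:
        popt, pcov = optimize.curve_fit(
            model, t, A, p0=[a_inf0, da0, k0],
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    a_inf, da, k = popt
    k_se = np.sqrt(pcov[2, 2])
    resid = A - model(t, *popt)
    p_runs = _runs_test_pvalue(resid)
    warns = []
    if p_runs < 0.01 and np.std(resid) > 1e-12:
        warns.append(
            "systematic residuals (runs test p = %.2g); consider the "
            "sequential two-step model" % p_runs
        )
    return ExpFit(
        k=k, k_se=k_se, a0=a_inf + da, a_inf=a_inf,
        residuals=resid, runs_pvalue=p_runs, warnings=warns,
    )


# ---------------------------------------------------------------------------
# Two-step sequential deconvolution (variable projection)


@dataclass
class StoppedFlowMatrix:
    """Time x wavelength absorbance matrix from a photodiode-array run."""

    times: np.ndarray  # s, strictly increasing
    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # (n_times, n_wavelengths)
    truth: dict | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, float))
        if self.absorbance.shape != (len(self.times), len(self.wavelengths)):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.times)} times x {len(self.wavelengths)} wavelengths"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.absorbance).all():
            raise ValueError("non-finite absorbance")


@dataclass
class SequentialFit:
    """Two-step sequential fit a ->(k1) b ->(k2) c of a PDA matrix.

    Identifiability convention: k1 > k2 (the label-swapped solution fits the
    data equally well with permuted spectra).  ``spectra`` rows are the
    fitted species spectra of a, b (the intermediate) and c.
    """

    k1: float
    k1_se: float
    k2: float
    k2_se: float
    spectra: np.ndarray  # (3, n_wavelengths)
    wavelengths: np.ndarray
    residual_norm: float
    intermediate_lambda_max: float | None = None
    warnings: list[str] = field(default_factory=list)


def sequential_concentrations(k1: float, k2: float, t: np.ndarray) -> np.ndarray:
    """Closed-form species fractions of a ->(k1) b ->(k2) c, columns a,b,c.

    The degenerate case k1 == k2 uses the confluent limit b = k1 t e^{-k1 t}.
    """
    t = np.asarray(t, float)
    ca = np.exp(-k1 * t)
    if abs(k1 - k2) / max(k1, 1e-300) < 1e-6:
        cb = k1 * t * np.exp(-k1 * t)
    else:
        cb = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    cc = 1.0 - ca - cb
    return np.column_stack([ca, cb, cc])


def intermediate_peak_time(k1: float, k2: float) -> float:
    """Time at which the intermediate b peaks: ln(k1/k2) / (k1 - k2)."""
    if abs(k1 - k2) / max(k1, 1e-300) < 1e-6:
        return 1.0 / k1
    return float(np.log(k1 / k2) / (k1 - k2))


def _varpro_residual(logk: np.ndarray, t: np.ndarray, A: np.ndarray):
    k1, k2 = np.exp(logk)
    C = sequential_concentrations(k1, k2, t)
    S, *_ = np.linalg.lstsq(C, A, rcond=None)
    return (C @ S - A).ravel(), S


def fit_sequential_two_step(matrix: StoppedFlowMatrix) -> SequentialFit:
    """Globally fit a two-step sequential model to a PDA matrix.

    Species spectra are linear parameters at fixed (k1, k2) and are solved
    by least squares inside the objective (variable projection); the outer
    optimisation over log(k1, k2) is restarted from a grid of rate pairs
    spanning the decades of the time grid.  Standard errors come from the
    Jacobian of the projected residual at the optimum.
    """
    t, A = matrix.times, matrix.absorbance
    warns = []
    span = t[-1] / max(t[0], 1e-12)
    if span < 100:
        warns.append("time grid spans < 2 decades; rates may be poorly separated")
    lo, hi = 1.0 / t[-1], 1.0 / max(t[0], 1e-12)
    grid = np.log(np.geomspace(lo, hi, 5))
    best = None
    for lk1 in grid:
        for lk2 in grid:
            if lk2 >= lk1:
                continue
            res = optimize.least_squares(
                lambda p: _varpro_residual(p, t, A)[0],
                x0=[lk1, lk2], method="lm", max_nfev=4000,
                xtol=1e-13, ftol=1e-14, gtol=1e-14,
            )
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise FitError("no admissible starting point for the sequential fit")
    k1, k2 = np.exp(best.x)
    if k1 < k2:  # enforce the identifiability convention
        res2 = optimize.least_squares(
            lambda p: _varpro_residual(p, t, A)[0],
            x0=[np.log(k2), np.log(k1)], method="lm", max_nfev=4000,
            xtol=1e-13, ftol=1e-14, gtol=1e-14,
        )
        best = res2 if res2.cost <= best.cost * (1 + 1e-9) else best
        k1, k2 = np.exp(best.x)
        if k1 < k2:
            k1, k2 = k2, k1
            best.x = np.log([k1, k2])
    resid, spectra = _varpro_residual(best.x, t, A)
    dof = max(resid.size - (2 + spectra.size), 1)
    s2 = float(resid @ resid) / dof
    JTJ = best.jac.T @ best.jac
    try:
        cov_log = s2 * np.linalg.inv(JTJ)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(2, np.nan)
        warns.append("singular Jacobian; rate SEs unavailable")
    k1_se, k2_se = k1 * se_log[0], k2 * se_log[1]  # delta method from log scale
    if spectra.min() < -0.05 * max(abs(spectra).max(), 1e-12):
        warns.append("fitted species spectra have substantially negative regions")
    lam_max = float(matrix.wavelengths[np.argmax(spectra[1])]) if len(
        matrix.wavelengths
    ) > 1 else None
    return SequentialFit(
        k1=float(k1), k1_se=float(k1_se), k2=float(k2), k2_se=float(k2_se),
        spectra=spectra, wavelengths=matrix.wavelengths,
        residual_norm=float(np.sqrt(resid @ resid)),
        intermediate_lambda_max=lam_max, warnings=warns,
    )


# ---------------------------------------------------------------------------
# Oxygen affinity


@dataclass
class O2Fit:
    km_o2: float
    km_o2_se: float
    k_max: float
    k_max_se: float
    saturated: bool = False
    warnings: list[str] = field(default_factory=list)


def fit_oxygen_affinity(o2_conc, k_obs) -> O2Fit:
    """Hyperbolic fit k_obs = k_max [O2] / (K_M^O2 + [O2]).

    Units follow the input concentration axis.  If the fitted K_M^O2 falls
    below the lowest tested concentration the design is saturated and the
    estimate is only an upper bound; the fit is flagged accordingly.
    """
    o2 = np.asarray(o2_conc, float)
    k = np.asarray(k_obs, float)
    if len(np.unique(o2)) < 4:
        raise FitError("need at least 4 distinct O2 concentrations")
    ds = InitialRateDataset(conc=o2, rate=k, conc_unit="mM", rate_unit="s-1")
    mm = fit_michaelis_menten(ds)
    saturated = mm.km < o2.min()
    warns = list(mm.warnings)
    if saturated:
        warns.append(
            "K_M^O2 below the lowest tested [O2]; design saturated, value "
            "is an upper-bound estimate"
        )
    return O2Fit(
        km_o2=mm.km, km_o2_se=mm.km_se, k_max=mm.vmax, k_max_se=mm.vmax_se,
        saturated=saturated, warnings=warns,
    )


# ---------------------------------------------------------------------------
# Conversions, melting temperature, holoenzyme


def conversion_percent(
    sample_substrate_area: float,
    sample_is_area: float,
    control_substrate_area: float,
    control_is_area: float,
) -> float:
    """Substrate-depletion conversion normalised to an internal standard:

    100 * (1 - (A_substrate/A_IS)_sample / (A_substrate/A_IS)_control),
    clamped to [0, 100] with a warning outside that range.
    """
    if sample_is_area <= 0 or control_is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if control_substrate_area <= 0:
        raise ValueError("control substrate area must be positive")
    ratio = (sample_substrate_area / sample_is_area) / (
        control_substrate_area / control_is_area
    )
    value = 100.0 * (1.0 - ratio)
    if value < 0.0 or value > 100.0:
        warnings.warn(
            f"conversion {value:.1f}% outside [0, 100]; clamped", stacklevel=2
        )
    return float(np.clip(value, 0.0, 100.0))


@dataclass
class MeltResult:
    tm: float | None
    secondary: list[float]
    no_transition: bool = False


def melting_temperature(
    temperature, fluorescence, smooth_window: int = 7
) -> MeltResult:
    """Melting temperature from the maximum of the smoothed first derivative
    dF/dT of an unfolding curve (ThermoFAD-style readout).

    The curve is smoothed with a Savitzky-Golay filter (window
    ``smooth_window`` points, quadratic); interior derivative peaks are
    ranked by height, the tallest reported as T_m and the rest as secondary
    transitions.  A curve with no interior peak is flagged "no transition".
    """
    T = np.asarray(temperature, float)
    F = np.asarray(fluorescence, float)
    if len(T) < 20:
        raise ValueError("need at least 20 points on the melt curve")
    win = min(smooth_window if smooth_window % 2 else smooth_window + 1, len(T) - 1)
    if win < 5:
        win = 5
    dF = signal.savgol_filter(
        F, window_length=win, polyorder=2, deriv=1,
        delta=float(np.mean(np.diff(T))),
    )
    scale = np.max(np.abs(dF))
    if scale < 1e-12:
        return MeltResult(tm=None, secondary=[], no_transition=True)
    peaks, props = signal.find_peaks(dF, height=0.2 * scale)
    peaks = peaks[(peaks > 0) & (peaks < len(T) - 1)]
    if len(peaks) == 0:
        return MeltResult(tm=None, secondary=[], no_transition=True)
    order = np.argsort(dF[peaks])[::-1]
    ranked = peaks[order]
    return MeltResult(
        tm=float(T[ranked[0]]),
        secondary=[float(T[p]) for p in ranked[1:]],
    )


def holoenzyme_concentration(a450: float, path_length: float = 1.0) -> float:
    """Holoenzyme (bound FAD) concentration in uM from absorbance at 450 nm,
    via Beer-Lambert with eps_FAD = 11.3 mM-1 cm-1."""
    if a450 < 0:
        raise ValueError(f"negative absorbance {a450}")
    if path_length <= 0:
        raise ValueError(f"path length must be positive, got {path_length}")
    return a450 / (EPSILON_FAD_450 * path_length) * 1e3
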