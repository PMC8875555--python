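"""Quantitative analysis of enzyme-inhibition and thermal-shift assays.

Dose–response data (normalised enzyme activity versus inhibitor
concentration) are fit to a two-parameter logistic with fixed asymptotes,

    v([I]) = 1 / (1 + ([I]/IC50)^h),

IC50 is converted to the inhibition constant with the Cheng–Prusoff relation
Ki = IC50 / (1 + [S]/Km) for competitive inhibition, and uncertainty is
propagated by Monte-Carlo refitting under multiplicative Gaussian noise.
Differential scanning fluorimetry melt curves are fit to a Boltzmann sigmoid
inside a temperature window to extract the melting temperature Tm; a ligand
is called a significant binder when its Tm shift exceeds three standard
deviations of the reference replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayConditions:
    """Enzyme-assay conditions needed for the Cheng–Prusoff conversion.

    substrate_conc and km in molar; enzyme_conc is informational only.
    """

    substrate_conc: float = 1e-3  # 1 mM substrate
    km: float | None = None       # per-enzyme, must be supplied for Ki
    enzyme_conc: float = 5e-9     # 5 nM enzyme

    def __post_init__(self) -> None:
        if self.substrate_conc <= 0:
            raise ValueError("substrate_conc must be > 0")
        if self.km is not None and self.km <= 0:
            raise ValueError("km must be > 0")


@dataclass
class DoseResponseDataset:
    """Normalised enzyme activity versus inhibitor concentration (molar)."""

    concentrations_M: np.ndarray
    responses: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations_M = np.asarray(self.concentrations_M, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations_M.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if len(self.concentrations_M) < 5:
            raise ValueError("need at least 5 concentration points")
        if np.any(self.concentrations_M <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations_M) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)


@dataclass
class MeltCurve:
    """A DSF melt trace: fluorescence (arbitrary units) versus temperature (degC)."""

    temperatures_C: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures_C.shape != self.fluorescence.shape:
            raise ValueError("temperatures and fluorescence must have equal length")


@dataclass
class FitDiagnostics:
    converged: bool
    residual_norm: float
    n_points: int
    message: str = ""


def _logistic(conc: np.ndarray, log10_ic50: float, hill: float) -> np.ndarray:
    return 1.0 / (1.0 + (conc / 10.0 ** log10_ic50) ** hill)


class DoseResponseModel(BaseEstimator):
    """Two-parameter logistic dose–response fit (top fixed at 1, bottom at 0).

    Fitted attributes: ``ic50_`` (molar), ``hill_``, ``diagnostics_``.
    Initialisation is multi-start over a log-spaced IC50 grid spanning the
    measured concentration range, so a single bad start cannot trap the fit.
    """

    def __init__(self, n_starts: int = 7, hill_bounds: tuple = (0.1, 10.0)):
        self.n_starts = n_starts
        self.hill_bounds = hill_bounds

    def fit(self, concentrations, responses):
        conc = np.asarray(concentrations, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if conc.ndim != 1 or conc.shape != resp.shape:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if len(conc) < 5:
            raise ValueError("need at least 5 concentration points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        order = np.argsort(conc)
        conc, resp = conc[order], resp[order]
        if np.any(np.diff(conc) == 0):
            raise ValueError("concentrations must be distinct")

        lo, hi = np.log10(conc.min()) - 1, np.log10(conc.max()) + 1
        starts = np.linspace(lo, hi, self.n_starts)
        h_lo, h_hi = self.hill_bounds
        best = None
        for s in starts:
            try:
                res = least_squares(
                    lambda p: _logistic(conc, p[0], p[1]) - resp,
                    x0=[s, 1.0],
                    bounds=([lo - 2, h_lo], [hi + 2, h_hi]),
                )
            except Exception:  # numerical failure on one start is not fatal
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("dose-response fit failed from every start")
        self.ic50_ = float(10.0 ** best.x[0])
        self.hill_ = float(best.x[1])
        self.diagnostics_ = FitDiagnostics(
            converged=bool(best.success),
            residual_norm=float(np.sqrt(2 * best.cost)),
            n_points=len(conc),
            message=str(best.message),
        )
        # the model is monotone decreasing; flag grossly non-monotone data
        if np.corrcoef(np.log10(conc), resp)[0, 1] > 0:
            logger.warning("responses increase with concentration; fit suspect")
        return self

    def predict(self, concentrations) -> np.ndarray:
        conc = np.asarray(concentrations, dtype=float)
        return _logistic(conc, np.log10(self.ic50_), self.hill_)


def fit_dose_response(data, responses=None) -> tuple[float, float, FitDiagnostics]:
    """Functional wrapper: returns (ic50 in molar, hill, diagnostics).

    Accepts either a :class:`DoseResponseDataset` or two arrays.
    """
    if isinstance(data, DoseResponseDataset):
        conc, resp = data.concentrations_M, data.responses
    else:
        conc, resp = data, responses
    model = DoseResponseModel().fit(conc, resp)
    return model.ic50_, model.hill_, model.diagnostics_


def cheng_prusoff(ic50: float, conditions: AssayConditions) -> float:
    """Ki = IC50 / (1 + [S]/Km) for a competitive inhibitor.

    Km must be supplied explicitly; there is no defensible default.
    """
    if conditions.km is None:
        raise ValueError("Km is required for the Cheng-Prusoff conversion")
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    return ic50 / (1.0 + conditions.substrate_conc / conditions.km)


@dataclass
class InhibitionFit:
    """Point estimate and Monte-Carlo uncertainty for one inhibition assay."""

    ic50: float
    hill: float
    ki: float
    ki_sd: float
    n_cycles_converged: int = 0
    diagnostics: FitDiagnostics | None = None


def monte_carlo_ki(
    concentrations,
    responses=None,
    conditions: AssayConditions | None = None,
    n_cycles: int = 100,
    rel_noise: float = 0.05,
    replicate_sd=None,
    seed: int = 0,
) -> InhibitionFit:
    """Ki with Monte-Carlo uncertainty from repeated noisy refits.

    Each cycle perturbs every response with Gaussian noise of standard
    deviation max(rel_noise * |response|, replicate SD when given) — i.e. at
    least ``rel_noise`` relative uncertainty — refits the logistic, and
    converts to Ki.  Returns the mean and SD over converged cycles.  Errors
    out if more than half the cycles fail to converge.
    """
    if isinstance(concentrations, DoseResponseDataset):
        dataset = concentrations
        if isinstance(responses, AssayConditions) and conditions is None:
            conditions = responses  # dataset-first calling convention
        concentrations, responses = dataset.concentrations_M, dataset.responses
        if replicate_sd is None:
            replicate_sd = dataset.replicate_sd
    if conditions is None:
        raise ValueError("assay conditions are required")
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    base = DoseResponseModel().fit(conc, resp)
    base_ki = cheng_prusoff(base.ic50_, conditions)
    sd = rel_noise * np.abs(resp)
    if replicate_sd is not None:
        sd = np.maximum(sd, np.asarray(replicate_sd, dtype=float))
    rng = np.random.default_rng(seed)
    kis = []
    for _ in range(n_cycles):
        noisy = resp + rng.normal(0.0, 1.0, size=resp.shape) * sd
        try:
            m = DoseResponseModel().fit(conc, noisy)
        except (RuntimeError, ValueError):
            continue
        if not m.diagnostics_.converged:
            continue
        kis.append(cheng_prusoff(m.ic50_, conditions))
    if len(kis) < n_cycles / 2:
        raise RuntimeError(
            f"only {len(kis)}/{n_cycles} Monte-Carlo cycles converged"
        )
    kis = np.asarray(kis)
    return InhibitionFit(
        ic50=base.ic50_,
        hill=base.hill_,
        ki=float(kis.mean()),
        ki_sd=float(kis.std(ddof=1)) if len(kis) > 1 else 0.0,
        n_cycles_converged=len(kis),
        diagnostics=base.diagnostics_,
    )


def _boltzmann(T: np.ndarray, tm: float, slope: float, low: float, high: float) -> np.ndarray:
    return low + (high - low) / (1.0 + np.exp((tm - T) / slope))


class BoltzmannTmModel(BaseEstimator):
    """Boltzmann sigmoid fit of a DSF melt curve inside a temperature window.

    F(T) = B + (A - B) / (1 + exp((Tm - T)/s)); the curve rises from the
    folded baseline B to the unfolded plateau A with midpoint Tm and width s.
    Data are min–max normalised within the window before fitting.  Fitted
    attributes: ``tm_``, ``slope_``, ``plateau_low_``, ``plateau_high_``
    (on the normalised scale), ``at_window_edge_``, ``diagnostics_``.
    """

    def __init__(self, window: tuple = (40.0, 68.0), edge_tol: float = 0.5):
        self.window = window
        self.edge_tol = edge_tol

    def fit(self, temperatures, fluorescence):
        T = np.asarray(temperatures, dtype=float)
        F = np.asarray(fluorescence, dtype=float)
        if T.shape != F.shape or T.ndim != 1:
            raise ValueError("temperatures and fluorescence must be equal-length 1-D")
        lo, hi = self.window
        mask = (T >= lo) & (T <= hi)
        if mask.sum() < 10:
            raise ValueError(
                f"need at least 10 points inside the {lo}-{hi} degC window"
            )
        Tw, Fw = T[mask], F[mask]
        order = np.argsort(Tw)
        Tw, Fw = Tw[order], Fw[order]
        span = Fw.max() - Fw.min()
        if span == 0:
            raise ValueError("flat fluorescence signal in the fit window")
        Fn = (Fw - Fw.min()) / span

        # midpoint guess: first crossing of the half-amplitude
        above = np.flatnonzero(Fn >= 0.5)
        tm0 = Tw[above[0]] if len(above) else 0.5 * (lo + hi)
        res = least_squares(
            lambda p: _boltzmann(Tw, *p) - Fn,
            x0=[tm0, 2.0, float(Fn[:3].mean()), float(Fn[-3:].mean())],
            bounds=([lo, 0.05, -0.5, 0.5], [hi, 20.0, 0.5, 1.5]),
        )
        self.tm_ = float(res.x[0])
        self.slope_ = float(res.x[1])
        self.plateau_low_ = float(res.x[2])
        self.plateau_high_ = float(res.x[3])
        self.at_window_edge_ = bool(
            self.tm_ < lo + self.edge_tol or self.tm_ > hi - self.edge_tol
        )
        if self.at_window_edge_:
            logger.warning("fitted Tm %.2f degC lies at the window edge", self.tm_)
        self.diagnostics_ = FitDiagnostics(
            converged=bool(res.success),
            residual_norm=float(np.sqrt(2 * res.cost)),
            n_points=int(mask.sum()),
            message=str(res.message),
        )
        return self

    def predict(self, temperatures) -> np.ndarray:
        T = np.asarray(temperatures, dtype=float)
        return _boltzmann(T, self.tm_, self.slope_, self.plateau_low_, self.plateau_high_)


@dataclass
class TmFit:
    tm: float
    slope: float
    plateau_low: float
    plateau_high: float
    at_window_edge: bool
    diagnostics: FitDiagnostics


def fit_boltzmann_tm(temperatures, fluorescence=None, window=(40.0, 68.0)) -> TmFit:
    """Functional wrapper around :class:`BoltzmannTmModel`.

    Accepts either a :class:`MeltCurve` or two arrays.
    """
    if isinstance(temperatures, MeltCurve):
        curve = temperatures
        temperatures, fluorescence = curve.temperatures_C, curve.fluorescence
    m = BoltzmannTmModel(window=window).fit(temperatures, fluorescence)
    return TmFit(
        tm=m.tm_, slope=m.slope_, plateau_low=m.plateau_low_,
        plateau_high=m.plateau_high_, at_window_edge=m.at_window_edge_,
        diagnostics=m.diagnostics_,
    )


def delta_tm_call(sample_tm: float, reference_tms) -> tuple[float, bool]:
    """Tm shift versus reference replicates, with a 3-sigma significance call.

    delta_tm = sample_tm - mean(reference); significant iff |delta_tm| exceeds
    3 x SD of the reference replicates (sample SD, n-1).  Requires at least
    three replicates.
    """
    ref = np.asarray(reference_tms, dtype=float)
    if ref.size < 3:
        raise ValueError("need at least 3 reference replicate Tm values")
    delta = float(sample_tm - ref.mean())
    sd = float(ref.std(ddof=1))
    return delta, bool(abs(delta) > 3.0 * sd)
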