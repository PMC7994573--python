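"""Two-state analysis of chemical and thermal unfolding curves.

Chemical unfolding: the raw signal y (e.g. CD at 222 nm) is converted to the
fraction denatured f_D = (y - y_N)/(y_D - y_N), the apparent equilibrium
constant K = f_D/(1 - f_D) gives per-point free energies dG = -RT ln K inside
the transition window, and ordinary least squares of dG against denaturant
concentration extrapolates to 0 M: dG0 = intercept, m-value = -slope.

Thermal unfolding: the melting temperature is the midpoint of a four-parameter
sigmoid fitted to signal vs temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .params import KB_KCAL

R_KCAL = KB_KCAL  # gas constant, kcal/(mol*K)


@dataclass
class UnfoldingCurve:
    x: np.ndarray               # denaturant (M) or temperature (K), ascending
    y: np.ndarray               # raw signal, arbitrary units
    y_N: float | None = None    # native baseline
    y_D: float | None = None    # denatured baseline
    temperature: float = 293.15  # K, for chemical curves

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    def with_baselines(self, n_edge: int = 3) -> "UnfoldingCurve":
        """Fill missing scalar baselines from the curve edges (mean of n_edge points)."""
        y_N = self.y_N if self.y_N is not None else float(self.y[:n_edge].mean())
        y_D = self.y_D if self.y_D is not None else float(self.y[-n_edge:].mean())
        return UnfoldingCurve(self.x, self.y, y_N, y_D, self.temperature)


@dataclass
class UnfoldingFit:
    dG0: float                  # kcal/mol at 0 M denaturant
    m_value: float              # kcal/mol/M
    se_dG0: float
    se_m: float
    points_used: np.ndarray     # indices into the curve
    R: float = R_KCAL


def fraction_denatured(curve: UnfoldingCurve) -> np.ndarray:
    """f_D = (y - y_N)/(y_D - y_N) per point (unclipped)."""
    c = curve.with_baselines()
    if c.y_D == c.y_N:
        raise ValueError("degenerate baselines: y_N == y_D")
    return (c.y - c.y_N) / (c.y_D - c.y_N)


def free_energy_points(f_d: np.ndarray, temperature: float,
                       window: tuple[float, float] = (0.05, 0.95),
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point dG = -RT ln(f_D/(1-f_D)) restricted to the transition window.

    Returns (indices kept, dG values in kcal/mol).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    f_d = np.asarray(f_d, float)
    keep = np.where((f_d >= window[0]) & (f_d <= window[1]))[0]
    if keep.size == 0:
        raise ValueError("no points inside the transition window "
                         f"[{window[0]}, {window[1]}]")
    K = f_d[keep] / (1.0 - f_d[keep])
    dG = -R_KCAL * temperature * np.log(K)
    return keep, dG


def linear_extrapolation(conc: np.ndarray, dG: np.ndarray,
                         points_used: np.ndarray | None = None) -> UnfoldingFit:
    """OLS of dG vs denaturant: dG0 = intercept, m-value = -slope, with SEs."""
    conc = np.asarray(conc, float)
    dG = np.asarray(dG, float)
    if conc.size < 2:
        raise ValueError("need at least two points for linear extrapolation")
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations equal; design is singular")
    res = stats.linregress(conc, dG)
    if points_used is None:
        points_used = np.arange(conc.size)
    return UnfoldingFit(dG0=float(res.intercept), m_value=float(-res.slope),
                        se_dG0=float(res.intercept_stderr), se_m=float(res.stderr),
                        points_used=np.asarray(points_used))


def fit_chemical_unfolding(curve: UnfoldingCurve,
                           window: tuple[float, float] = (0.05, 0.95)) -> UnfoldingFit:
    """Full pipeline: baselines -> f_D -> dG points -> linear extrapolation."""
    f_d = fraction_denatured(curve)
    keep, dG = free_energy_points(f_d, curve.temperature, window)
    return linear_extrapolation(curve.x[keep], dG, points_used=keep)


@dataclass
class MeltingFit:
    tm_celsius: float | None
    params: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    no_transition: bool = False
    converged: bool = True


def _sigmoid(T, y_n, y_d, tm, slope):
    arg = np.clip((tm - T) / slope, -700.0, 700.0)
    return y_n + (y_d - y_n) / (1.0 + np.exp(arg))


def melting_temperature(curve: UnfoldingCurve) -> MeltingFit:
    """Tm (deg C) as the midpoint of a four-parameter sigmoid fit.

    The temperature axis may be K or deg C; Tm is reported on the Celsius scale
    (converted when the axis looks like Kelvin, i.e. all values > 150).
    A fitted amplitude below 3x the residual scale sets the no-transition flag;
    non-convergence is flagged, never raised.
    """
    T, y = curve.x, curve.y
    if T.size < 6:
        raise ValueError("need at least six points spanning a transition")
    span = y.max() - y.min()
    p0 = [y[0], y[-1], float(T[np.argmin(np.abs(y - (y[0] + y[-1]) / 2))]),
          max(np.ptp(T) / 20.0, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(_sigmoid, T, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning):
        return MeltingFit(tm_celsius=None, no_transition=True, converged=False)
    resid = y - _sigmoid(T, *popt)
    rnorm = float(np.sqrt(np.mean(resid ** 2)))
    amplitude = abs(popt[1] - popt[0])
    no_transition = bool(amplitude < 3.0 * max(rnorm, 1e-12 * max(span, 1.0)))
    tm = float(popt[2])
    if T.min() > 150.0:  # axis in Kelvin
        tm -= 273.15
    in_range = T.min() <= popt[2] <= T.max()
    return MeltingFit(
        tm_celsius=None if no_transition or not in_range else tm,
        params={"y_n": float(popt[0]), "y_d": float(popt[1]),
                "tm_axis_units": float(popt[2]), "slope": float(popt[3])},
        residual_norm=rnorm, no_transition=no_transition or not in_range)


def average_replicates(x: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average replicate signal columns; returns (x, mean, per-point SD)."""
    ys = np.atleast_2d(np.asarray(ys, float))
    if ys.shape[1] != np.asarray(x).size:
        ys = ys.T
    return np.asarray(x, float), ys.mean(axis=0), ys.std(axis=0, ddof=1 if ys.shape[0] > 1 else 0)
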