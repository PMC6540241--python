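"""1:1 epitope-paratope binding: isotherm, Kd fitting, SVD species analysis.

The binding model is a single-site mass-action equilibrium

    A + B  <=>  AB,      Kd = [A][B] / [AB]

with one species ("labeled", total concentration L held constant through a
titration) observed while the partner ("titrant", total T varied) is added.
The complex concentration follows from the quadratic mass balance; the
observed signal is affine in the complex concentration

    y(T) = baseline + s_free * (L - AB) + s_complex * AB
         = intercept + slope * AB(L, T, Kd)

which covers fluorescence (complex emits), MST (fraction-bound response) and
plate-absorbance (MPEIA) titrations alike — the three modes differ only in
their endpoint parameterisation, never in the isotherm.

Kd fitting profiles the two linear coefficients out (for fixed Kd they solve
a 2-parameter linear least-squares problem), scans a coarse log10-Kd grid
for the best profiled fit, then polishes all three parameters jointly with a
trust-region nonlinear least-squares step.  The standard error of Kd comes
from the local curvature at the optimum via the delta method.

Spectral species counting: singular values of a wavelength x titration-point
intensity matrix above a noise-aware threshold count the spectrally active
species (a 1:1 titration with one emitting free species and one emitting
complex has rank 2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SignalMode",
    "BindingModel1to1",
    "TitrationSeries",
    "BindingFit",
    "SpectraMatrix",
    "DilutionLadder",
    "complex_concentration",
    "serial_dilution",
    "mst_model",
    "simulate_titration",
    "fit_kd",
    "svd_species_count",
    "simulate_spectra",
]


class SignalMode(enum.Enum):
    FLUORESCENCE = "fluorescence"
    MST = "mst"
    MPEIA = "mpeia"

    @classmethod
    def parse(cls, text: "str | SignalMode") -> "SignalMode":
        if isinstance(text, SignalMode):
            return text
        try:
            return cls(str(text).lower())
        except ValueError:
            raise ValueError(f"unknown signal mode {text!r}") from None


def complex_concentration(total_a, total_b, kd):
    """Equilibrium complex concentration of a 1:1 binding pair.

    Solves Kd*AB = (A - AB)(B - AB) for the physically valid root,

        AB = 2*A*B / (S + sqrt(S^2 - 4*A*B)),   S = A + B + Kd,

    a form that stays numerically stable near full saturation (it avoids the
    catastrophic cancellation of the textbook (S - sqrt(...))/2 root).
    Accepts scalars or arrays (micromolar); 0 <= AB <= min(A, B).
    """
    A = np.asarray(total_a, dtype=float)
    B = np.asarray(total_b, dtype=float)
    Kd = np.asarray(kd, dtype=float)
    if np.any(A < 0) or np.any(B < 0):
        raise ValueError("total concentrations must be non-negative")
    if np.any(Kd <= 0):
        raise ValueError("Kd must be positive")
    S = A + B + Kd
    disc = S * S - 4.0 * A * B
    denom = S + np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(invalid="ignore"):
        ab = np.where(denom > 0, 2.0 * A * B / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.minimum(ab, np.minimum(A, B))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DilutionLadder:
    """A geometric serial-dilution design: top, top/f, ..., n_points values."""

    top: float
    factor: float
    n_points: int

    def __post_init__(self) -> None:
        if self.top <= 0:
            raise ValueError("top concentration must be positive")
        if self.factor <= 1:
            raise ValueError("dilution factor must exceed 1")
        if self.n_points < 1:
            raise ValueError("need at least one point")


def serial_dilution(ladder: DilutionLadder) -> np.ndarray:
    """Concentration vector of a serial dilution, descending from the top.

    >>> serial_dilution(DilutionLadder(70.0, 2.0, 7))[-1]
    1.09375
    """
    return ladder.top / ladder.factor ** np.arange(ladder.n_points, dtype=float)


@dataclass(frozen=True)
class BindingModel1to1:
    """Signal-generating 1:1 model: Kd plus affine signal coefficients.

    kd is in micromolar; s_free and s_complex are signal per micromolar of
    free labeled species and of complex respectively (arbitrary units);
    baseline is a signal offset.
    """

    kd: float
    s_free: float = 0.0
    s_complex: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")

    def signal(self, labeled_total, titrant_totals) -> np.ndarray:
        ab = complex_concentration(labeled_total, np.asarray(titrant_totals, float), self.kd)
        free = labeled_total - ab
        return self.baseline + self.s_free * free + self.s_complex * ab


def mst_model(kd: float, labeled_total: float, baseline: float = 0.0,
              amplitude: float = 1.0) -> BindingModel1to1:
    """MST-style parameterisation: signal = baseline + amplitude * fraction bound.

    Fraction bound is AB / L, so this maps onto the affine model with
    s_free = 0 and s_complex = amplitude / L.
    """
    if labeled_total <= 0:
        raise ValueError("labeled_total must be positive")
    return BindingModel1to1(kd=kd, s_free=0.0,
                            s_complex=amplitude / labeled_total, baseline=baseline)


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: constant labeled species, varied titrant, a signal."""

    labeled_total: float
    titrant_totals: np.ndarray
    signal: np.ndarray
    mode: SignalMode = SignalMode.FLUORESCENCE

    def __post_init__(self) -> None:
        t = np.asarray(self.titrant_totals, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("titrant_totals and signal must be equal-length vectors")
        if t.size < 6:
            raise ValueError(f"need at least 6 titration points, got {t.size}")
        d = np.diff(t)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("titrant concentrations must be strictly monotone")
        if np.any(t <= 0) or self.labeled_total <= 0:
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "titrant_totals", t)
        object.__setattr__(self, "signal", y)
        object.__setattr__(self, "mode", SignalMode.parse(self.mode))


def simulate_titration(
    model: BindingModel1to1,
    labeled_total: float,
    titrant_totals: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    mode: "str | SignalMode" = SignalMode.FLUORESCENCE,
) -> TitrationSeries:
    """Simulate a titration under the 1:1 model with multiplicative noise.

    Each noise-free signal value is multiplied by (1 + eps) with
    eps ~ Normal(0, noise_cv^2), drawn from a generator seeded with ``seed``
    (same seed, same series).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t = np.asarray(titrant_totals, dtype=float)
    clean = model.signal(labeled_total, t)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + rng.normal(0.0, noise_cv, size=t.shape)) if noise_cv > 0 else clean
    return TitrationSeries(labeled_total=labeled_total, titrant_totals=t,
                           signal=noisy, mode=mode)


@dataclass(frozen=True)
class BindingFit:
    """Result of a 1:1 Kd fit."""

    kd_hat: float
    kd_se: float
    r2: float
    converged: bool
    residuals: np.ndarray
    intercept: float
    slope: float
    message: str = ""


_KD_GRID = np.logspace(-3, 4, 29)  # µM; profiled-SSE scan range


def _profile_linear(ab: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Best (intercept, slope) and SSE for fixed complex-concentration curve."""
    X = np.column_stack([np.ones_like(ab), ab])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_kd(series: TitrationSeries, start: Optional[float] = None) -> BindingFit:
    """Fit the dissociation constant of a 1:1 titration.

    Fits (log10 Kd, intercept, slope) by nonlinear least squares on the
    exact mass-action curve.  With the labeled total constant, baseline and
    the two endpoint sensitivities collapse onto an intercept and a slope on
    the complex concentration, so these three parameters are the full
    identifiable set.  When no ``start`` is given, a coarse log-spaced Kd
    grid (1e-3 to 1e4 µM) is profiled first and the best grid point seeds
    the refinement.  The reported standard error is the asymptotic
    (curvature-based) error mapped to the Kd scale; unidentifiable data
    (e.g. a flat signal) yields ``converged=False`` with a non-finite or
    meaningless SE rather than a silent estimate.
    """
    L = series.labeled_total
    t = series.titrant_totals
    y = series.signal
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct titrant levels")

    def curve(log10_kd: float) -> np.ndarray:
        return complex_concentration(L, t, 10.0 ** log10_kd)

    if start is not None:
        if start <= 0:
            raise ValueError("starting Kd must be positive")
        seeds = [np.log10(start)]
    else:
        sse_grid = [_profile_linear(curve(np.log10(kd)), y)[2] for kd in _KD_GRID]
        seeds = [np.log10(_KD_GRID[int(np.argmin(sse_grid))])]

    def residual(theta: np.ndarray) -> np.ndarray:
        b0, b1 = theta[1], theta[2]
        return b0 + b1 * curve(theta[0]) - y

    best = None
    for lk in seeds:
        b0, b1, _ = _profile_linear(curve(lk), y)
        res = least_squares(residual, x0=[lk, b0, b1], method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res

    theta = best.x
    resid = residual(theta)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    # asymptotic covariance from the Jacobian at the optimum
    dof = max(y.size - 3, 1)
    s2 = sse / dof
    J = best.jac
    kd_hat = float(10.0 ** theta[0])
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_log10 = float(np.sqrt(max(cov[0, 0], 0.0)))
        kd_se = kd_hat * np.log(10.0) * se_log10
    except np.linalg.LinAlgError:
        kd_se = float("inf")

    identifiable = bool(np.isfinite(kd_se)) and abs(theta[2]) > 0
    converged = bool(best.success and identifiable)
    return BindingFit(kd_hat=kd_hat, kd_se=kd_se, r2=float(r2),
                      converged=converged, residuals=resid,
                      intercept=float(theta[1]), slope=float(theta[2]),
                      message=best.message)


@dataclass(frozen=True)
class SpectraMatrix:
    """Intensities on a wavelength x titration-point grid."""

    wavelengths: np.ndarray
    titration_points: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        p = np.asarray(self.titration_points)
        m = np.asarray(self.intensities, dtype=float)
        if m.shape != (w.size, p.size):
            raise ValueError("intensity matrix shape must be (wavelengths, points)")
        if not np.all(np.isfinite(m)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "titration_points", p)
        object.__setattr__(self, "intensities", m)


def svd_species_count(spectra: SpectraMatrix, noise_level: float = 0.0,
                      rel_tol: float = 0.01) -> int:
    """Number of spectrally active species in a titration spectra matrix.

    Counts singular values exceeding
    ``max(noise_level * sqrt(n_rows * n_cols), rel_tol * s_max)``: the first
    term absorbs white measurement noise, the second discards numerically
    negligible components.  A rank-2 matrix — free species plus complex along
    a 1:1 titration — reports two species.
    """
    m = spectra.intensities
    if m.shape[0] < 3 or m.shape[1] < 3:
        raise ValueError("spectra matrix must be at least 3x3")
    s = np.linalg.svd(m, compute_uv=False)
    threshold = max(noise_level * np.sqrt(m.size), rel_tol * s[0])
    return int(np.sum(s > threshold))


def simulate_spectra(
    model: BindingModel1to1,
    labeled_total: float,
    titrant_totals: Sequence[float],
    wavelengths: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    two_species: bool = True,
) -> SpectraMatrix:
    """Synthetic emission spectra along a titration.

    Free labeled species and complex each carry a Gaussian emission profile
    (peaks at 340 and 365 nm, widths 22 and 28 nm); column j mixes them with
    weights (L - AB_j) and AB_j from the 1:1 isotherm.  With
    ``two_species=False`` only the complex emits, producing a rank-1 matrix.
    Additive Gaussian noise of standard deviation ``noise_sd`` is applied.
    """
    wl = np.asarray(wavelengths if wavelengths is not None else np.arange(300.0, 451.0, 2.0))
    t = np.asarray(titrant_totals, dtype=float)
    ab = complex_concentration(labeled_total, t, model.kd)
    free = labeled_total - ab
    prof_free = np.exp(-0.5 * ((wl - 340.0) / 22.0) ** 2)
    prof_complex = np.exp(-0.5 * ((wl - 365.0) / 28.0) ** 2)
    m = np.outer(prof_complex, ab)
    if two_species:
        m = m + 0.6 * np.outer(prof_free, free)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = m + rng.normal(0.0, noise_sd, size=m.shape)
    return SpectraMatrix(wavelengths=wl, titration_points=np.arange(t.size), intensities=m)
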