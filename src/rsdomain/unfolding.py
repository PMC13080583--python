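"""FirbY-W two-state unfolding analysis with log-normal band deconvolution.

Chemical denaturation of a Tyr/Trp-containing protein is followed by the
fluorescence intensity ratio of the tyrosine band to the tryptophan band
(FirbY-W).  Each emission spectrum (280-400 nm) is deconvoluted into two
asymmetric log-normal bands; the ratio of their peak intensities reports
the folding equilibrium.  Across urea concentration x the ratio follows
the two-state model

    FirbY-W(x) = (D * exp((m*x - dG)/RT) + N) / (exp((m*x - dG)/RT) + 1)

with native/denatured baselines N and D, m-value m (kcal/mol/M) and the
unfolding free energy dG (kcal/mol) at R = 1.987e-3 kcal/(mol K) and the
working temperature T.  The transition midpoint is C_m = dG/m.

The spectral band shape is the four-parameter asymmetric log-normal used in
protein-fluorescence deconvolution (amplitude A, peak position p, full width
at half maximum w, asymmetry rho > 1), written in wavelength with a finite
blue-side support edge b = p - w*rho/(rho^2 - 1):

    I(lam) = A * exp(-(ln 2 / ln^2 rho) * ln^2((lam - b)/(p - b)))   lam > b
    I(lam) = 0                                                       lam <= b
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 295.0  # K

# physical emission-peak windows used to keep band assignment stable
TYR_PEAK_BOUNDS = (295.0, 312.0)
TRP_PEAK_BOUNDS = (325.0, 360.0)

__all__ = [
    "LogNormalBand",
    "EmissionSpectrum",
    "UnfoldingSeries",
    "UnfoldingFitResult",
    "DeconvolutionResult",
    "eval_lognormal_band",
    "lognormal_band_area",
    "deconvolute_spectrum",
    "compute_firby_ratio",
    "eval_unfolding_ratio",
    "fit_unfolding",
    "read_spectra_tsv",
    "write_spectra_tsv",
]


@dataclass
class LogNormalBand:
    """Asymmetric log-normal emission band (amplitude at the mode)."""

    amplitude: float
    peak_position: float  # nm
    width: float  # FWHM, nm
    asymmetry: float  # dimensionless, > 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.asymmetry <= 1:
            raise ValueError("asymmetry must be > 1")

    @property
    def support_edge(self) -> float:
        """Blue-side wavelength below which the band is exactly zero."""
        rho = self.asymmetry
        return self.peak_position - self.width * rho / (rho * rho - 1.0)


@dataclass
class EmissionSpectrum:
    wavelength: np.ndarray  # nm, strictly increasing
    intensity: np.ndarray
    urea: float  # M

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength/intensity length mismatch")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")


@dataclass
class UnfoldingSeries:
    urea: np.ndarray  # M
    ratio: np.ndarray  # FirbY-W, dimensionless

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.urea.shape != self.ratio.shape:
            raise ValueError("urea/ratio length mismatch")
        if np.any(self.urea < 0) or np.any(self.urea > 8):
            raise ValueError("urea must lie in [0, 8] M")


@dataclass
class UnfoldingFitResult:
    dg: float  # kcal/mol
    m_value: float  # kcal/mol/M
    n_base: float
    d_base: float
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KCAL
    dg_stderr: float | None = None
    converged: bool = True
    non_identifiable: bool = False
    residual_rms: float = 0.0

    @property
    def midpoint(self) -> float:
        """Transition midpoint C_m = dG / m (M)."""
        return self.dg / self.m_value

    def to_dict(self) -> dict:
        return {
            "dG_kcal_mol": self.dg,
            "m_kcal_mol_M": self.m_value,
            "N_baseline": self.n_base,
            "D_baseline": self.d_base,
            "temperature_K": self.temperature,
            "dG_stderr": self.dg_stderr,
            "midpoint_M": self.midpoint if self.m_value else None,
            "converged": self.converged,
            "non_identifiable": self.non_identifiable,
            "residual_rms": self.residual_rms,
        }


@dataclass
class DeconvolutionResult:
    tyr_band: LogNormalBand
    trp_band: LogNormalBand
    residual_rms: float
    converged: bool = True


def eval_lognormal_band(
    band: LogNormalBand, wavelength: float | np.ndarray
) -> float | np.ndarray:
    """Band intensity at the given wavelength(s); exactly zero at and below
    the finite blue-side support edge."""
    lam = np.asarray(wavelength, dtype=float)
    b = band.support_edge
    scale = band.peak_position - b
    k = math.log(2.0) / math.log(band.asymmetry) ** 2
    out = np.zeros_like(lam)
    inside = lam > b
    if np.any(inside):
        u = np.log((lam[inside] - b) / scale)
        out[inside] = band.amplitude * np.exp(-k * u * u)
    return float(out) if np.isscalar(wavelength) else out


def lognormal_band_area(band: LogNormalBand) -> float:
    """Closed-form integral of the band over its full support.

    With u = ln((lam-b)/(p-b)) the integral becomes a Gaussian moment:
    A*(p-b) * sqrt(pi/k) * exp(1/(4k)), k = ln2 / ln^2(rho).
    """
    k = math.log(2.0) / math.log(band.asymmetry) ** 2
    scale = band.peak_position - band.support_edge
    return band.amplitude * scale * math.sqrt(math.pi / k) * math.exp(1.0 / (4.0 * k))


def _band_from_params(p: lmfit.Parameters, prefix: str) -> LogNormalBand:
    return LogNormalBand(
        amplitude=float(p[f"{prefix}amp"].value),
        peak_position=float(p[f"{prefix}peak"].value),
        width=float(p[f"{prefix}width"].value),
        asymmetry=float(p[f"{prefix}asym"].value),
    )


def deconvolute_spectrum(
    spectrum: EmissionSpectrum,
    init: tuple[LogNormalBand, LogNormalBand] | None = None,
) -> DeconvolutionResult:
    """Least-squares two-band (Tyr + Trp) decomposition of one spectrum.

    The tyrosine band peak is constrained to 295-312 nm and the tryptophan
    band to 325-360 nm, which both enforces the ordering
    tyr.peak < trp.peak and prevents band swapping.  Initial guesses, if
    supplied, are sorted by peak position so a permuted pair gives the
    identical result.
    """
    if init is not None:
        init = tuple(sorted(init, key=lambda band: band.peak_position))  # type: ignore[assignment]
        tyr0, trp0 = init
    else:
        peak_guess = float(spectrum.intensity.max()) or 1.0
        tyr0 = LogNormalBand(0.5 * peak_guess, 303.0, 30.0, 1.3)
        trp0 = LogNormalBand(0.8 * peak_guess, 340.0, 55.0, 1.4)

    params = lmfit.Parameters()
    params.add("tyr_amp", value=max(tyr0.amplitude, 1e-12), min=0.0)
    params.add(
        "tyr_peak",
        value=float(np.clip(tyr0.peak_position, *TYR_PEAK_BOUNDS)),
        min=TYR_PEAK_BOUNDS[0],
        max=TYR_PEAK_BOUNDS[1],
    )
    params.add("tyr_width", value=tyr0.width, min=5.0, max=120.0)
    params.add("tyr_asym", value=tyr0.asymmetry, min=1.05, max=3.0)
    params.add("trp_amp", value=max(trp0.amplitude, 1e-12), min=0.0)
    params.add(
        "trp_peak",
        value=float(np.clip(trp0.peak_position, *TRP_PEAK_BOUNDS)),
        min=TRP_PEAK_BOUNDS[0],
        max=TRP_PEAK_BOUNDS[1],
    )
    params.add("trp_width", value=trp0.width, min=5.0, max=150.0)
    params.add("trp_asym", value=trp0.asymmetry, min=1.05, max=3.0)

    lam = spectrum.wavelength
    obs = spectrum.intensity

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = eval_lognormal_band(_band_from_params(p, "tyr_"), lam) + eval_lognormal_band(
            _band_from_params(p, "trp_"), lam
        )
        return model - obs

    result = lmfit.minimize(residual, params, method="leastsq")
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return DeconvolutionResult(
        tyr_band=_band_from_params(result.params, "tyr_"),
        trp_band=_band_from_params(result.params, "trp_"),
        residual_rms=rms,
        converged=bool(result.success),
    )


def compute_firby_ratio(
    tyr_band: LogNormalBand, trp_band: LogNormalBand, mode: str = "peak"
) -> float:
    """Tyr/Trp fluorescence intensity ratio.

    ``mode='peak'`` (default) uses peak intensities (band amplitudes);
    ``mode='area'`` uses integrated band areas.
    """
    if mode not in ("peak", "area"):
        raise ValueError("mode must be 'peak' or 'area'")
    if trp_band.amplitude == 0:
        raise ZeroDivisionError("Trp band amplitude is zero; FirbY-W undefined")
    if mode == "peak":
        return tyr_band.amplitude / trp_band.amplitude
    return lognormal_band_area(tyr_band) / lognormal_band_area(trp_band)


def eval_unfolding_ratio(
    x: float | np.ndarray,
    dg: float,
    m_value: float,
    n_base: float,
    d_base: float,
    temperature: float = DEFAULT_TEMPERATURE,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> float | np.ndarray:
    """Two-state FirbY-W ratio at urea concentration x (M)."""
    rt = gas_constant * temperature
    e = np.exp((m_value * np.asarray(x, dtype=float) - dg) / rt)
    out = (d_base * e + n_base) / (e + 1.0)
    return float(out) if np.isscalar(x) else out


def _unfolding_residual(p: lmfit.Parameters, x: np.ndarray, y: np.ndarray, t: float) -> np.ndarray:
    return (
        eval_unfolding_ratio(
            x, p["dg"].value, p["m"].value, p["n"].value, p["d"].value, temperature=t
        )
        - y
    )


def fit_unfolding(
    series: UnfoldingSeries, temperature: float = DEFAULT_TEMPERATURE
) -> UnfoldingFitResult:
    """Fit the two-state model with free (dG, m, N, D).

    Multi-start least squares over a small grid of dG starting values keeps
    the fit robust when the folded baseline lies outside the sampled urea
    range (destabilised constructs with dG < 0 are mostly unfolded even at
    0 M urea).  An all-folded or all-unfolded series carries no transition
    and is flagged non-identifiable.
    """
    x = series.urea
    y = series.ratio
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")

    span = float(y.max() - y.min())
    scale = max(abs(float(np.mean(y))), 1.0)
    if span < 1e-6 * scale:
        return UnfoldingFitResult(
            dg=math.nan,
            m_value=math.nan,
            n_base=float(np.mean(y)),
            d_base=float(np.mean(y)),
            temperature=temperature,
            converged=False,
            non_identifiable=True,
        )

    best = None
    for dg0 in (-2.0, -0.5, 0.5, 1.0, 2.0, 3.0, 5.0):
        params = lmfit.Parameters()
        params.add("dg", value=dg0)
        params.add("m", value=1.0, min=1e-3, max=20.0)
        params.add("n", value=float(y[np.argmin(x)]))
        params.add("d", value=float(y[np.argmax(x)]))
        try:
            res = lmfit.minimize(
                _unfolding_residual, params, args=(x, y, temperature), method="leastsq"
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("unfolding fit failed from every starting point")

    rms = float(np.sqrt(np.mean(best.residual**2)))
    fitted_span = abs(float(best.params["d"].value - best.params["n"].value))
    non_ident = fitted_span < 3.0 * rms or not best.success
    stderr = best.params["dg"].stderr
    return UnfoldingFitResult(
        dg=float(best.params["dg"].value),
        m_value=float(best.params["m"].value),
        n_base=float(best.params["n"].value),
        d_base=float(best.params["d"].value),
        temperature=temperature,
        dg_stderr=float(stderr) if stderr is not None else None,
        converged=bool(best.success),
        non_identifiable=non_ident,
        residual_rms=rms,
    )


def write_spectra_tsv(
    spectra: Sequence[EmissionSpectrum], path: str | Path, header_comment: str | None = None
) -> None:
    """Write spectra as TSV (wavelength_nm, intensity, urea_M)."""
    frames = [
        pd.DataFrame(
            {"wavelength_nm": s.wavelength, "intensity": s.intensity, "urea_M": s.urea}
        )
        for s in spectra
    ]
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_spectra_tsv(path: str | Path) -> list[EmissionSpectrum]:
    table = pd.read_csv(path, sep="\t", comment="#")
    spectra = []
    for urea, grp in table.groupby("urea_M"):
        grp = grp.sort_values("wavelength_nm")
        spectra.append(
            EmissionSpectrum(
                wavelength=grp["wavelength_nm"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                urea=float(urea),
            )
        )
    spectra.sort(key=lambda s: s.urea)
    return spectra
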