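"""Ligand-depletion fluorescence-polarization binding isotherm.

In an FP titration a fixed, low concentration of fluorescent probe
(total concentration ``L_T``, here 10 nM in the study design) is titrated
with increasing total titrant ``P_T``.  Because the probe concentration is
not negligible relative to the dissociation constant, the bound fraction
must be obtained from the exact solution of the 1:1 binding quadratic
rather than the hyperbolic approximation:

    theta = ((P_T + L_T + K_D) - sqrt((P_T + L_T + K_D)^2 - 4 P_T L_T))
            / (2 L_T)

    FP = F_min + (F_max - F_min) * theta

``theta`` is the fraction of probe bound, so FP interpolates between the
free-probe polarization ``F_min`` and the saturated value ``F_max``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "TitrationCurve",
    "BindingFitResult",
    "eval_isotherm",
    "fit_isotherm",
    "classify_determinability",
    "read_titration_tsv",
    "write_titration_tsv",
]


@dataclass
class TitrationCurve:
    """One FP titration series: total titrant (nM) vs polarization (mP)."""

    titrant_total: np.ndarray
    polarization: np.ndarray
    probe_total: float
    replicate_id: int = 0
    # generating parameters, populated by the simulator for recovery tests
    true_params: dict | None = None

    def __post_init__(self) -> None:
        self.titrant_total = np.asarray(self.titrant_total, dtype=float)
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.titrant_total.shape != self.polarization.shape:
            raise ValueError("titrant and polarization series differ in length")
        if np.any(self.titrant_total < 0):
            raise ValueError("titrant concentrations must be >= 0")
        if not self.probe_total > 0:
            raise ValueError("probe_total must be > 0")


@dataclass
class BindingFitResult:
    """Result of fitting the ligand-depletion isotherm.

    ``kd_sd`` is the standard deviation of per-replicate K_D estimates when
    two or more replicates were fit, otherwise the asymptotic standard error
    of the single fit; ``kd_sd_kind`` records which.
    """

    kd: float
    fmin: float
    fmax: float
    kd_sd: float
    converged: bool
    determinable: bool
    kd_stderr: float | None = None
    residual_rms: float = 0.0
    top_titrant: float = 0.0
    kd_sd_kind: str = "asymptotic"
    replicate_kds: list[float] = field(default_factory=list)
    determinability_reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.kd,
            "fmin_mP": self.fmin,
            "fmax_mP": self.fmax,
            "kd_sd_nM": self.kd_sd,
            "kd_sd_kind": self.kd_sd_kind,
            "kd_stderr_nM": self.kd_stderr,
            "converged": self.converged,
            "determinable": self.determinable,
            "residual_rms_mP": self.residual_rms,
            "top_titrant_nM": self.top_titrant,
            "replicate_kds_nM": self.replicate_kds,
            "determinability_reasons": self.determinability_reasons,
        }


def eval_isotherm(
    pt: float | np.ndarray,
    lt: float,
    kd: float,
    fmin: float,
    fmax: float,
) -> float | np.ndarray:
    """Evaluate the exact 1:1 isotherm FP(P_T) with ligand depletion.

    Parameters are total titrant ``pt`` (nM), total probe ``lt`` (nM),
    dissociation constant ``kd`` (nM) and the polarization baselines
    (mP).  ``lt == 0`` is evaluated as the analytic limit
    ``theta = pt / (pt + kd)``.
    """
    pt_arr = np.asarray(pt, dtype=float)
    if np.any(pt_arr < 0) or kd < 0:
        raise ValueError("pt and kd must be >= 0")
    if lt < 0:
        raise ValueError("lt must be >= 0")
    if lt == 0:
        with np.errstate(invalid="ignore"):
            theta = np.where(pt_arr + kd > 0, pt_arr / (pt_arr + kd), 0.0)
    else:
        s = pt_arr + lt + kd
        disc = np.maximum(s * s - 4.0 * pt_arr * lt, 0.0)
        # 2*pt/(s + sqrt(disc)) is algebraically (s - sqrt(disc))/(2*lt)
        # but avoids catastrophic cancellation at large pt.
        theta = 2.0 * pt_arr / (s + np.sqrt(disc))
    fp = fmin + (fmax - fmin) * theta
    return float(fp) if np.isscalar(pt) else fp


def _fit_single(curve: TitrationCurve) -> tuple[lmfit.minimizer.MinimizerResult, float]:
    fp = curve.polarization
    pt = curve.titrant_total
    if not np.all(np.isfinite(fp)) or not np.all(np.isfinite(pt)):
        raise ValueError("non-finite values in titration data")
    if len(pt) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")

    span = float(fp.max() - fp.min())
    # half-span crossing as the K_D guess; robust for monotone curves
    half = fp.min() + 0.5 * span
    above = pt[fp >= half]
    kd0 = float(above.min()) if above.size and above.min() > 0 else float(np.median(pt[pt > 0]))

    params = lmfit.Parameters()
    params.add("kd", value=max(kd0, 1e-3), min=1e-3, max=1e9)
    params.add("fmin", value=float(fp.min()))
    params.add("fmax", value=float(fp.max()))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return (
            eval_isotherm(pt, curve.probe_total, p["kd"].value, p["fmin"].value, p["fmax"].value)
            - fp
        )

    result = lmfit.minimize(residual, params, method="leastsq")
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return result, rms


def fit_isotherm(
    curves: TitrationCurve | Sequence[TitrationCurve],
) -> BindingFitResult:
    """Fit the ligand-depletion isotherm with free (K_D, F_min, F_max).

    Accepts a single curve or a replicate set.  Replicates are fit
    independently; the reported K_D is their mean and ``kd_sd`` their
    sample standard deviation, matching the study's replicate-SD
    convention.  For a single curve ``kd_sd`` falls back to the
    asymptotic standard error.
    """
    if isinstance(curves, TitrationCurve):
        curves = [curves]
    curves = list(curves)
    if not curves:
        raise ValueError("no curves supplied")

    fits = [_fit_single(c) for c in curves]
    kds = [float(r.params["kd"].value) for r, _ in fits]
    converged = all(r.success for r, _ in fits)

    # headline numbers from the first-replicate fit when single, pooled means otherwise
    kd = float(np.mean(kds))
    fmin = float(np.mean([r.params["fmin"].value for r, _ in fits]))
    fmax = float(np.mean([r.params["fmax"].value for r, _ in fits]))
    rms = float(np.mean([rms for _, rms in fits]))
    stderr = fits[0][0].params["kd"].stderr

    if len(fits) >= 2:
        kd_sd = float(np.std(kds, ddof=1))
        kd_sd_kind = "replicate"
    else:
        kd_sd = float(stderr) if stderr is not None and math.isfinite(stderr) else 0.0
        kd_sd_kind = "asymptotic"

    top = float(max(c.titrant_total.max() for c in curves))
    result = BindingFitResult(
        kd=kd,
        fmin=fmin,
        fmax=fmax,
        kd_sd=kd_sd,
        converged=converged,
        determinable=True,
        kd_stderr=float(stderr) if stderr is not None else None,
        residual_rms=rms,
        top_titrant=top,
        kd_sd_kind=kd_sd_kind,
        replicate_kds=kds,
    )
    result.determinable = classify_determinability(result, top)
    return result


def classify_determinability(fit: BindingFitResult, top_titrant: float) -> bool:
    """Three-way rule for calling an affinity "too weak to be determined".

    The fit is non-determinable when it failed to converge, when the fitted
    K_D exceeds the highest titrant concentration used (the estimate would
    be an extrapolation), or when the fitted signal span is smaller than
    three times the residual RMS (no resolvable binding signal).
    """
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("fit did not converge")
    if fit.kd > top_titrant:
        reasons.append("fitted Kd exceeds top titrant concentration")
    span = fit.fmax - fit.fmin
    if span <= 0 or span < 3.0 * fit.residual_rms:
        reasons.append("signal span below 3x residual RMS")
    fit.determinability_reasons = reasons
    return not reasons


def write_titration_tsv(curves: Sequence[TitrationCurve], path: str | Path) -> None:
    """Write curves as TSV (titrant_nM, FP_mP, replicate) with a header
    comment recording the probe concentration and generating parameters."""
    curves = list(curves)
    lines = [f"# probe_nM={curves[0].probe_total}"]
    if curves[0].true_params:
        lines.append("# generating=" + json.dumps(curves[0].true_params, sort_keys=True))
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "titrant_nM": c.titrant_total,
                    "FP_mP": c.polarization,
                    "replicate": c.replicate_id,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_titration_tsv(path: str | Path) -> list[TitrationCurve]:
    """Read a TSV written by :func:`write_titration_tsv` (or hand-made with
    the same columns) back into one curve per replicate id."""
    probe = None
    true_params = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# probe_nM="):
                probe = float(line.split("=", 1)[1])
            elif line.startswith("# generating="):
                true_params = json.loads(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    if probe is None:
        raise ValueError("TSV lacks '# probe_nM=' header comment")
    table = pd.read_csv(path, sep="\t", comment="#")
    curves = []
    for rep, grp in table.groupby("replicate"):
        curves.append(
            TitrationCurve(
                titrant_total=grp["titrant_nM"].to_numpy(),
                polarization=grp["FP_mP"].to_numpy(),
                probe_total=probe,
                replicate_id=int(rep),
                true_params=true_params,
            )
        )
    return curves
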