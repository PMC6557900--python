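"""Steady-state SPR and single-site ITC affinity fitting.

SPR: equilibrium responses on a concentration series are fit to the 1:1
Langmuir isotherm R_eq(C) = Rmax * C / (KD + C); fits are triaged into
``quantified`` / ``weak`` / ``n.d.`` depending on signal strength and whether
saturation was approached within the tested concentration range.

ITC: per-injection heats are modelled with the standard one-set-of-sites
(Wiseman) isotherm, including the instrument displacement correction for
sample expelled from the fixed-volume cell, and fit by trust-region least
squares over (N, KD, dH, offset).  The Wiseman c-value (c = N*[cell]/KD)
controls identifiability: the stoichiometry N is flagged low-confidence when
c < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SprTitration",
    "SprStatus",
    "SprFit",
    "ItcProtocol",
    "ItcFit",
    "fit_spr_steady_state",
    "classify_spr_signal",
    "itc_expected_heats",
    "fit_itc",
    "read_spr_csv",
    "read_itc_csv",
    "SPR_ASSAY_CONCENTRATIONS_UM",
]

# 7-point, ~3x-spaced analyte dilution series (uM) used throughout
SPR_ASSAY_CONCENTRATIONS_UM = (0.08, 0.25, 0.7, 2.2, 6.7, 20.0, 60.0)

# kcal -> ucal when concentrations are uM and volumes ul:
# Q[ucal] = dH[kcal/mol] * conc[uM] * V[ul] * 1e-3
_UCAL_SCALE = 1e-3


class SprStatus(str, Enum):
    QUANTIFIED = "quantified"
    WEAK = "weak"
    ND = "n.d."


@dataclass(frozen=True)
class SprTitration:
    """Analyte concentrations (uM) and steady-state responses (RU)."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.size != r.size:
            raise ValueError("concentrations and responses differ in length")
        if c.size < 3:
            raise ValueError("need at least 3 concentrations")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(c).size != c.size:
            raise ValueError("concentrations must be distinct")


@dataclass(frozen=True)
class SprFit:
    KD: float
    Rmax: float
    rss: float
    status: SprStatus
    converged: bool = True


@dataclass(frozen=True)
class ItcProtocol:
    """Injection schedule and cell contents of a titration.

    Defaults mirror a standard small-cell calorimeter run: 50 uM macromolecule
    in a 200 ul cell titrated with 750 uM titrant as a 0.4 ul priming
    injection (discarded from analysis) followed by 19 x 2 ul injections at
    298 K.
    """

    cell_conc: float = 50.0
    syringe_conc: float = 750.0
    V0: float = 200.0
    injection_volumes: tuple[float, ...] = (0.4,) + (2.0,) * 19
    first_injection_discarded: bool = True
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.cell_conc <= 0 or self.syringe_conc <= 0 or self.V0 <= 0:
            raise ValueError("concentrations and cell volume must be positive")
        if len(self.injection_volumes) == 0 or min(self.injection_volumes) <= 0:
            raise ValueError("injection volumes must be positive")

    def totals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Displacement-corrected totals after each injection.

        dV_cum is the cumulative injected volume; the standard fixed-cell
        convention is Mt = cell*(1 - dV/(2 V0)) and
        Xt = syringe*(dV/V0)*(1 - dV/(2 V0)).
        """
        dv = np.asarray(self.injection_volumes, dtype=float)
        dv_cum = np.cumsum(dv)
        mt = self.cell_conc * (1.0 - dv_cum / (2.0 * self.V0))
        xt = self.syringe_conc * (dv_cum / self.V0) * (1.0 - dv_cum / (2.0 * self.V0))
        return dv, mt, xt


@dataclass(frozen=True)
class ItcFit:
    N: float
    KD: float
    dH: float
    offset: float
    rss: float
    c_value: float
    low_confidence_N: bool


# ---------------------------------------------------------------------------
# SPR


def _langmuir(c: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    return rmax * c / (kd + c)


def fit_spr_steady_state(tit: SprTitration) -> SprFit:
    """Least-squares fit of the steady-state 1:1 isotherm.

    Exact on noiseless input.  Non-convergence is reported as status ``weak``
    rather than raised, matching how unsaturated titrations are triaged.
    """
    c = np.asarray(tit.concentrations, dtype=float)
    r = np.asarray(tit.responses, dtype=float)

    rmax0 = max(float(np.max(r)), 1e-6) * 1.5
    kd0 = float(np.median(c))

    def resid(p: np.ndarray) -> np.ndarray:
        return _langmuir(c, p[0], p[1]) - r

    sol = least_squares(
        resid, np.array([kd0, rmax0]),
        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    kd, rmax = (float(v) for v in sol.x)
    fit = SprFit(KD=kd, Rmax=rmax, rss=float(np.sum(sol.fun**2)),
                 status=SprStatus.QUANTIFIED, converged=bool(sol.success))
    noise = tit.noise_sd if tit.noise_sd is not None else _estimate_noise(sol.fun)
    status = classify_spr_signal(tit, fit, noise)
    return SprFit(KD=kd, Rmax=rmax, rss=fit.rss, status=status,
                  converged=fit.converged)


def _estimate_noise(residuals: np.ndarray) -> float:
    return float(np.std(residuals)) if residuals.size > 2 else 0.0


def classify_spr_signal(tit: SprTitration, fit: SprFit, noise_sd: float) -> SprStatus:
    """Triage a steady-state fit.

    ``n.d.``: maximum response below 3x the response noise (no signal);
    ``weak``: signal present but saturation not achieved — fitted KD beyond
    the highest tested concentration, or the fit did not converge;
    ``quantified`` otherwise.
    """
    max_resp = float(np.max(np.asarray(tit.responses, dtype=float)))
    if noise_sd > 0 and max_resp < 3.0 * noise_sd:
        return SprStatus.ND
    if not fit.converged or fit.KD > max(tit.concentrations):
        return SprStatus.WEAK
    return SprStatus.QUANTIFIED


# ---------------------------------------------------------------------------
# ITC


def _wiseman_cumulative(mt: np.ndarray, xt: np.ndarray, n: float, kd: float,
                        dh: float, v0: float) -> np.ndarray:
    """Cumulative heat content (ucal) after each injection.

    Q = (N Mt dH V0 / 2) * [A - sqrt(A^2 - 4 Xt/(N Mt))],
    A = 1 + Xt/(N Mt) + KD/(N Mt).
    """
    nmt = n * mt
    a = 1.0 + xt / nmt + kd / nmt
    disc = np.maximum(a * a - 4.0 * xt / nmt, 0.0)
    return _UCAL_SCALE * (nmt * dh * v0 / 2.0) * (a - np.sqrt(disc))


def itc_expected_heats(protocol: ItcProtocol, N: float, KD: float, dH: float,
                       offset: float = 0.0) -> np.ndarray:
    """Per-injection heats (ucal) under the one-set-of-sites model.

    dQ_i = Q_i - Q_{i-1} + (dV_i/V0)*(Q_i + Q_{i-1})/2 + offset, where the
    middle term compensates for bound complex expelled with the displaced
    cell volume.  ``offset`` models the residual heat of dilution per
    injection.  All injections are returned, including any priming injection
    the fit later discards.
    """
    if N <= 0 or KD <= 0:
        raise ValueError("N and KD must be positive")
    dv, mt, xt = protocol.totals()
    q = _wiseman_cumulative(mt, xt, N, KD, dH, protocol.V0)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / protocol.V0) * (q + q_prev) / 2.0 + offset
    return dq


def fit_itc(protocol: ItcProtocol, heats: Sequence[float]) -> ItcFit:
    """Fit (N, KD, dH, offset) to per-injection heats by least squares.

    The priming injection is excluded when the protocol flags it discarded.
    KD is optimised on a log scale; on failure the fit restarts from three
    spread-out initialisations before giving up.
    """
    y = np.asarray(list(heats), dtype=float)
    dv, mt, xt = protocol.totals()
    if y.size != dv.size:
        raise ValueError(
            f"{y.size} heats but protocol defines {dv.size} injections"
        )
    keep = np.ones(y.size, dtype=bool)
    if protocol.first_injection_discarded:
        keep[0] = False
    if keep.sum() < 5:
        raise ValueError("need at least 5 analysable injections")

    def model(params: np.ndarray) -> np.ndarray:
        n, log_kd, dh, offs = params
        q = _wiseman_cumulative(mt, xt, n, 10.0 ** log_kd, dh, protocol.V0)
        q_prev = np.concatenate([[0.0], q[:-1]])
        dq = q - q_prev + (dv / protocol.V0) * (q + q_prev) / 2.0 + offs
        return dq[keep] - y[keep]

    dh0 = float(np.sum(y[keep]) / (protocol.cell_conc * protocol.V0 * _UCAL_SCALE))
    starts = [
        np.array([1.0, math.log10(protocol.cell_conc / 10.0), dh0, 0.0]),
        np.array([1.0, math.log10(protocol.cell_conc), dh0, 0.0]),
        np.array([0.5, math.log10(protocol.cell_conc * 10.0), 2.0 * dh0, 0.0]),
    ]
    best = None
    for x0 in starts:
        sol = least_squares(
            model, x0,
            bounds=([1e-3, -6.0, -np.inf, -np.inf], [100.0, 6.0, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:  # pragma: no cover
        raise RuntimeError("ITC fit failed to converge from all initialisations")
    n, log_kd, dh, offs = best.x
    kd = 10.0 ** log_kd
    c = n * protocol.cell_conc / kd
    return ItcFit(N=float(n), KD=float(kd), dH=float(dh), offset=float(offs),
                  rss=float(np.sum(best.fun**2)), c_value=float(c),
                  low_confidence_N=bool(c < 1.0))


# ---------------------------------------------------------------------------
# CSV I/O


def read_spr_csv(path: str | Path) -> dict[int, SprTitration]:
    """Read SPR titrations (columns: conc_uM, response_RU[, replicate])."""
    df = pd.read_csv(path)
    required = {"conc_uM", "response_RU"}
    if not required.issubset(df.columns):
        raise ValueError(f"SPR CSV needs columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return {
        int(rep): SprTitration(
            concentrations=tuple(grp["conc_uM"].astype(float)),
            responses=tuple(grp["response_RU"].astype(float)),
        )
        for rep, grp in df.groupby("replicate", sort=True)
    }


def read_itc_csv(path: str | Path) -> pd.DataFrame:
    """Read ITC heats (columns: injection_index, volume_ul, heat_ucal)."""
    df = pd.read_csv(path)
    required = {"injection_index", "volume_ul", "heat_ucal"}
    if not required.issubset(df.columns):
        raise ValueError(f"ITC CSV needs columns {sorted(required)}")
    return df.sort_values("injection_index").reset_index(drop=True)
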