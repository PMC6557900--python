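"""Mass-action binding equilibria for the protein / spy / competitor system.

Two coupled 1:1 equilibria share the free-protein pool::

    P + L <-> PL    KD = [P][L]/[PL]     (protein-spy reporter complex)
    P + I <-> PI    Ki = [P][I]/[PI]     (protein-competitor complex)

All concentrations are total or free concentrations in micromolar; unit
conversion is the caller's job.  The two-component problem has a closed-form
quadratic solution; the three-component problem is solved by monotone
bracketed root-finding on the free-protein concentration, with the cubic
closed form retained only as an independent test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "TwoComponentSystem",
    "CompetitionSystem",
    "SpeciesState",
    "solve_two_component",
    "solve_competition_forward",
    "infer_competitor_bound",
    "ki_from_species",
    "competition_cubic_roots",
]

#: inferred species within this distance (uM) outside the feasible interval
#: are clamped and flagged; larger violations raise DomainError.
CLAMP_TOL_UM = 1e-6


class DomainError(ValueError):
    """Input outside the physically meaningful domain."""


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value < 0:
            raise DomainError(f"{name} must be finite and non-negative, got {value}")


@dataclass(frozen=True)
class TwoComponentSystem:
    """Totals for the protein-spy pair: P0, L0 and the spy KD, all in uM."""

    P0: float
    L0: float
    KD: float

    def __post_init__(self) -> None:
        _check_nonneg(P0=self.P0, L0=self.L0, KD=self.KD)
        if self.KD <= 0:
            raise DomainError(f"KD must be positive, got {self.KD}")


@dataclass(frozen=True)
class CompetitionSystem:
    """Totals for protein, spy and competitor plus both dissociation constants (uM)."""

    P0: float
    L0: float
    I0: float
    KD: float
    Ki: float

    def __post_init__(self) -> None:
        _check_nonneg(P0=self.P0, L0=self.L0, I0=self.I0, KD=self.KD, Ki=self.Ki)
        if self.KD <= 0:
            raise DomainError(f"KD must be positive, got {self.KD}")
        if self.Ki <= 0:
            raise DomainError(f"Ki must be positive, got {self.Ki}")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (uM) of all five species."""

    Pfree: float
    Lfree: float
    Ifree: float
    PL: float
    PI: float

    def mass_balance_residuals(self, sys: CompetitionSystem) -> tuple[float, float, float]:
        """Absolute residuals of the three conservation laws (uM)."""
        return (
            self.Pfree + self.PL + self.PI - sys.P0,
            self.Lfree + self.PL - sys.L0,
            self.Ifree + self.PI - sys.I0,
        )


def solve_two_component(P0: float, L0: float, KD: float) -> float:
    """Equilibrium PL for P + L <-> PL from totals; smaller quadratic root.

    PL = (P0 + L0 + KD - sqrt((P0 + L0 + KD)^2 - 4 P0 L0)) / 2

    The smaller root is the physical one (0 <= PL <= min(P0, L0)).
    """
    _check_nonneg(P0=P0, L0=L0, KD=KD)
    if KD <= 0:
        raise DomainError(f"KD must be positive, got {KD}")
    if P0 == 0.0 or L0 == 0.0:
        return 0.0
    s = P0 + L0 + KD
    disc = s * s - 4.0 * P0 * L0
    assert disc >= 0.0, "binding quadratic discriminant negative for valid input"
    # subtraction-safe form: smaller root via product/larger-root
    larger = (s + math.sqrt(disc)) / 2.0
    pl = P0 * L0 / larger
    return min(pl, P0, L0)


def solve_competition_forward(sys: CompetitionSystem) -> SpeciesState:
    """Unique equilibrium of the three-component competition system.

    Roots f(Pf) = Pf*(1 + L0/(KD+Pf) + I0/(Ki+Pf)) - P0 on [0, P0]; f is
    strictly increasing so the bracketed root is unique.  Degenerate totals
    short-circuit to the analytic state.
    """
    P0, L0, I0, KD, Ki = sys.P0, sys.L0, sys.I0, sys.KD, sys.Ki
    if P0 == 0.0:
        return SpeciesState(0.0, L0, I0, 0.0, 0.0)
    if L0 == 0.0 and I0 == 0.0:
        return SpeciesState(P0, 0.0, 0.0, 0.0, 0.0)

    def f(pf: float) -> float:
        return pf * (1.0 + L0 / (KD + pf) + I0 / (Ki + pf)) - P0

    try:
        pf = brentq(f, 0.0, P0, xtol=1e-300, rtol=1e-15, maxiter=200)
    except Exception as exc:  # pragma: no cover - guarded by monotonicity
        raise RuntimeError(
            f"competition solver failed to converge for {sys!r}: {exc}"
        ) from exc
    # Newton polish in extended precision so PL/PI are correctly rounded even
    # in ill-conditioned corners (tight binding, near-zero displacement)
    ld = np.longdouble
    pfl, p0l, l0l, i0l, kdl, kil = ld(pf), ld(P0), ld(L0), ld(I0), ld(KD), ld(Ki)
    for _ in range(3):
        g = pfl * (1 + l0l / (kdl + pfl) + i0l / (kil + pfl)) - p0l
        deriv = 1 + l0l * kdl / (kdl + pfl) ** 2 + i0l * kil / (kil + pfl) ** 2
        step = g / deriv
        if pfl - step > 0:
            pfl -= step
    pl = float(pfl * l0l / (kdl + pfl))
    pi = float(pfl * i0l / (kil + pfl))
    pf = float(pfl)
    return SpeciesState(Pfree=pf, Lfree=L0 - pl, Ifree=I0 - pi, PL=pl, PI=pi)


def infer_competitor_bound(
    P0: float, L0: float, KD: float, PL: float
) -> tuple[float, bool]:
    """Invert the spy-displacement relation: bound competitor PI from observed PL.

    Closed form: PI = (P0*L0 - (P0 + L0 + KD)*PL + PL^2) / (L0 - PL),
    evaluated in the cancellation-safe factorisation
    PI = (P0 - PL) - KD*PL/(L0 - PL) with extended-precision arithmetic
    (PI can be orders of magnitude below the individual terms).

    Returns ``(PI, clamped)``.  PI marginally outside [0, P0 - PL] (within
    CLAMP_TOL_UM, as produced by measurement noise) is clamped with the flag
    set; gross violations raise :class:`DomainError`.
    """
    _check_nonneg(P0=P0, L0=L0, KD=KD, PL=PL)
    if PL >= min(P0, L0):
        raise DomainError(
            f"PL={PL} uM is not below min(P0, L0)=min({P0}, {L0}); "
            "no feasible competitor concentration"
        )
    ld = np.longdouble
    pll = ld(PL)
    pi = float((ld(P0) - pll) - ld(KD) * pll / (ld(L0) - pll))
    clamped = False
    if pi < 0.0:
        if pi < -CLAMP_TOL_UM:
            raise DomainError(
                f"inferred PI={pi} uM is negative beyond tolerance: PL={PL} exceeds "
                "the no-competitor value PL0 (super-stoichiometric / no displacement)"
            )
        pi, clamped = 0.0, True
    upper = P0 - PL
    if pi > upper:
        if pi - upper > CLAMP_TOL_UM:
            raise DomainError(
                f"inferred PI={pi} uM exceeds available protein P0-PL={upper} uM"
            )
        pi, clamped = upper, True
    return pi, clamped


def ki_from_species(P0: float, I0: float, PI: float, PL: float) -> float:
    """Competitor dissociation constant from equilibrium species concentrations.

    Ki = (P0 - PI - PL) * (I0 - PI) / PI, in uM.
    """
    _check_nonneg(P0=P0, I0=I0, PI=PI, PL=PL)
    if PI == 0.0:
        raise DomainError("Ki undetermined: PI = 0 (no displacement)")
    if PI > I0 * (1.0 + 1e-12):
        raise DomainError(f"PI={PI} exceeds total competitor I0={I0}")
    if PI == I0:
        # competitor fully bound even as Ifree -> 0: Ki = 0 regardless of PL
        return 0.0
    if PI + PL > P0 * (1.0 + 1e-12):
        raise DomainError(f"PI + PL = {PI + PL} exceeds total protein P0={P0}")
    ki = (P0 - PI - PL) * (I0 - PI) / PI
    return max(ki, 0.0)


def competition_cubic_roots(sys: CompetitionSystem) -> float:
    """Free protein by the closed-form cubic; test oracle only.

    Expanding the mass balance gives
    Pf^3 + a2 Pf^2 + a1 Pf + a0 = 0 with
    a2 = KD + Ki + L0 + I0 - P0,
    a1 = KD*Ki + Ki*(L0 - P0) + KD*(I0 - P0),
    a0 = -KD*Ki*P0.
    Numerically fragile for extreme parameters; the production path is the
    bracketed root-finder in :func:`solve_competition_forward`.
    """
    P0, L0, I0, KD, Ki = sys.P0, sys.L0, sys.I0, sys.KD, sys.Ki
    a2 = KD + Ki + L0 + I0 - P0
    a1 = KD * Ki + Ki * (L0 - P0) + KD * (I0 - P0)
    a0 = -KD * Ki * P0
    roots = np.roots([1.0, a2, a1, a0])
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    feasible = real[(real >= -1e-12) & (real <= P0 * (1 + 1e-12))]
    if feasible.size == 0:  # pragma: no cover
        raise RuntimeError(f"no feasible cubic root for {sys!r}: {roots}")
    return float(np.clip(feasible[0], 0.0, P0))
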