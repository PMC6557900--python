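"""Seeded generators for every assay modality the analysis pipeline consumes.

Each generator is a pure function of its parameters and a seed (or an
explicit ``numpy.random.Generator``), producing data with the statistical
structure the corresponding fitter assumes:

* CPMG relaxation series under two-state fast exchange: the observed decay
  rate is the population-weighted average R2_obs = (1-fb) R2_free + fb
  R2_bound of the free and bound spy rates, with the bound fraction fb taken
  from the mass-action equilibrium solver.
* Displacement integral triplets (IF, IP, II) for competitor panels with
  known true Ki, 4 replicates by default.
* Steady-state SPR concentration-response tables on the 7-point assay
  dilution series.
* Single-site ITC titrations under a 0.4 ul + 19 x 2 ul injection protocol.
* Deterministic toy coordinate models for the interface metrics.

Default assay conditions mirror the displacement experiment the package
models: 5 uM protein, 100 uM spy (KD 50 uM, R2 3 -> 11 s^-1 on binding),
competitor 10 uM (GHR-derived peptides) or 50 uM (EpoR-derived), read out at
a 0.133 s CPMG delay.  Default noise levels (CPMG 1% multiplicative, SPR
1 RU additive, ITC 2% of the largest heat, panel log-sd 0.05) are documented
assumptions, not measured instrument values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import gemmi

from .binding_fits import (
    ItcProtocol,
    SprTitration,
    itc_expected_heats,
    SPR_ASSAY_CONCENTRATIONS_UM,
)
from .equilibria import (
    CompetitionSystem,
    TwoComponentSystem,
    solve_competition_forward,
    solve_two_component,
)
from .interface import Atom, StructureModel
from .nmr import (
    CpmgSeries,
    DEFAULT_CPMG_DELAY_S,
    DEFAULT_L0_UM,
    DEFAULT_P0_UM,
    DEFAULT_SPY_KD_UM,
)

__all__ = [
    "GeneratorConfig",
    "gen_cpmg_series",
    "gen_displacement_panel",
    "gen_spr_titration",
    "gen_itc_titration",
    "gen_toy_complex",
    "write_structure",
    "R2_FREE_S1",
    "R2_BOUND_S1",
    "T2_DELAYS_S",
]

# Spy transverse relaxation: 3 s^-1 free in solution, 11 s^-1 observed in the
# presence of protein under the reference condition (5 uM protein, 100 uM spy,
# KD 50 uM, ~3.3% spy bound).  Under fast-exchange population mixing the
# observed rate is R2_obs = (1-fb) R2_free + fb R2_bound, so the intrinsic
# bound-state rate consistent with those two observations is
# R2_bound = (R2_obs_protein - (1-fb0) R2_free) / fb0 ~ 246 s^-1 (exchange-
# broadened bound state).
R2_FREE_S1 = 3.0
R2_OBS_PROTEIN_S1 = 11.0
_FB_REFERENCE = 3.2958896017208446 / 100.0  # PL0/L0 at the reference condition
R2_BOUND_S1 = (R2_OBS_PROTEIN_S1 - (1.0 - _FB_REFERENCE) * R2_FREE_S1) / _FB_REFERENCE
# relaxation-delay schedule of the T2 measurement
T2_DELAYS_S = (0.05, 0.1, 0.2, 0.4, 0.8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise model and replicate count shared by all generators.

    seed: base RNG seed (every generator is deterministic given it);
    cpmg_noise_sd: multiplicative intensity noise on peak integrals;
    spr_noise_sd_ru: additive response noise (RU);
    itc_noise_frac: heat noise as a fraction of the largest |heat|;
    panel_log_sd: extra inter-replicate lognormal spread on true affinities;
    n_replicates: independent experiments per condition.
    """

    seed: int = 0
    cpmg_noise_sd: float = 0.01
    spr_noise_sd_ru: float = 1.0
    itc_noise_frac: float = 0.02
    panel_log_sd: float = 0.05
    n_replicates: int = 4

    def __post_init__(self) -> None:
        for name in ("cpmg_noise_sd", "spr_noise_sd_ru", "itc_noise_frac",
                     "panel_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _bound_fraction(system: TwoComponentSystem | CompetitionSystem) -> float:
    """Fraction of spy bound, fb = PL/L0, from the equilibrium solver."""
    if isinstance(system, CompetitionSystem):
        if system.L0 == 0:
            return 0.0
        return solve_competition_forward(system).PL / system.L0
    if system.L0 == 0:
        return 0.0
    return solve_two_component(system.P0, system.L0, system.KD) / system.L0


def gen_cpmg_series(
    system: TwoComponentSystem | CompetitionSystem,
    R2_free: float = R2_FREE_S1,
    R2_bound: float = R2_BOUND_S1,
    delays: Sequence[float] = T2_DELAYS_S,
    config: GeneratorConfig = GeneratorConfig(),
    I0: float = 1000.0,
    label: str = "",
    rng: np.random.Generator | None = None,
) -> CpmgSeries:
    """Mono-exponential CPMG series at the fast-exchange observed rate.

    R2_obs = (1 - fb) R2_free + fb R2_bound with fb from the equilibrium
    solver; I(t) = I0 exp(-t R2_obs) (1 + eps), eps ~ N(0, cpmg_noise_sd).
    """
    if not (R2_bound >= R2_free > 0):
        raise ValueError("need R2_bound >= R2_free > 0")
    fb = _bound_fraction(system)
    r2_obs = (1.0 - fb) * R2_free + fb * R2_bound
    t = np.asarray(delays, dtype=float)
    clean = I0 * np.exp(-t * r2_obs)
    rng = config.rng(stream=1) if rng is None else rng
    noisy = clean * (1.0 + rng.normal(0.0, config.cpmg_noise_sd, size=t.size)) \
        if config.cpmg_noise_sd > 0 else clean
    return CpmgSeries(delays=tuple(t), intensities=tuple(noisy), label=label)


def gen_displacement_panel(
    true_ki: Mapping[str, float],
    config: GeneratorConfig = GeneratorConfig(),
    P0: float = DEFAULT_P0_UM,
    L0: float = DEFAULT_L0_UM,
    KD_spy: float = DEFAULT_SPY_KD_UM,
    I0_comp: float = 10.0,
    delay_s: float = DEFAULT_CPMG_DELAY_S,
    R2_free: float = R2_FREE_S1,
    R2_bound: float = R2_BOUND_S1,
    I0_signal: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic displacement table for a peptide panel with known true Ki.

    The IF / IP endpoint integrals follow the fast-exchange exponential
    attenuation at the single read-out delay; the competitor integral II is
    placed between them in proportion to the remaining bound-spy fraction
    PL/PL0 — the linearity the displacement relation assumes — so the
    noiseless table round-trips exactly through the Ki pipeline.  Each
    replicate re-measures all three integrals with fresh multiplicative
    noise, and the effective affinity of each replicate carries lognormal
    inter-replicate scatter (``panel_log_sd``) modelling day-to-day sample
    variability on top of the integral noise.

    Returns ``(table, truth)``: the displacement table in the schema the
    Ki reader expects, and the per-peptide ground-truth Ki.
    """
    rng = config.rng(stream=2)
    pl0 = solve_two_component(P0, L0, KD_spy)
    if_clean = I0_signal * math.exp(-delay_s * R2_free)
    r2_p = (1.0 - pl0 / L0) * R2_free + (pl0 / L0) * R2_bound
    ip_clean = I0_signal * math.exp(-delay_s * r2_p)

    rows = []
    truth_rows = []
    for pid, ki in true_ki.items():
        if ki <= 0:
            raise ValueError(f"{pid}: true Ki must be positive")
        truth_rows.append({"peptide_id": pid, "Ki_true_uM": ki})
        for rep in range(1, config.n_replicates + 1):
            ki_rep = ki * math.exp(rng.normal(0.0, config.panel_log_sd)) \
                if config.panel_log_sd > 0 else ki
            state = solve_competition_forward(
                CompetitionSystem(P0=P0, L0=L0, I0=I0_comp, KD=KD_spy, Ki=ki_rep)
            )
            f = state.PL / pl0
            ii_clean = if_clean - (if_clean - ip_clean) * f
            noise = rng.normal(0.0, config.cpmg_noise_sd, size=3) \
                if config.cpmg_noise_sd > 0 else np.zeros(3)
            rows.append({
                "peptide_id": pid,
                "IF": if_clean * (1.0 + noise[0]),
                "IP": ip_clean * (1.0 + noise[1]),
                "II": ii_clean * (1.0 + noise[2]),
                "P0_uM": P0, "L0_uM": L0, "KD_spy_uM": KD_spy, "I0_uM": I0_comp,
                "replicate": rep,
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_spr_titration(
    KD: float,
    Rmax: float,
    concentrations: Sequence[float] = SPR_ASSAY_CONCENTRATIONS_UM,
    config: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> SprTitration:
    """Steady-state 1:1 responses with additive Gaussian noise."""
    if KD <= 0 or Rmax <= 0:
        raise ValueError("KD and Rmax must be positive")
    c = np.asarray(concentrations, dtype=float)
    clean = Rmax * c / (KD + c)
    rng = config.rng(stream=3) if rng is None else rng
    noisy = clean + rng.normal(0.0, config.spr_noise_sd_ru, size=c.size) \
        if config.spr_noise_sd_ru > 0 else clean
    return SprTitration(concentrations=tuple(c), responses=tuple(noisy),
                        noise_sd=config.spr_noise_sd_ru or None)


def gen_itc_titration(
    protocol: ItcProtocol,
    N: float,
    KD: float,
    dH: float,
    offset: float = 0.0,
    config: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-injection heats (ucal) with Gaussian noise scaled to the signal."""
    clean = itc_expected_heats(protocol, N, KD, dH, offset)
    if config.itc_noise_frac == 0:
        return clean
    rng = config.rng(stream=4) if rng is None else rng
    sd = config.itc_noise_frac * float(np.max(np.abs(clean)))
    return clean + rng.normal(0.0, sd, size=clean.size)


# ---------------------------------------------------------------------------
# toy structures


def _atom(chain: str, resname: str, resnum: int, name: str, element: str,
          xyz: tuple[float, float, float]) -> Atom:
    return Atom(chain_id=chain, residue_name=resname, residue_number=resnum,
                atom_name=name, element=element, xyz=xyz)


def gen_toy_complex(preset: str) -> StructureModel:
    """Deterministic toy coordinate models for interface-metric tests.

    Presets:
      ``single_sphere``   one carbon atom (analytic SASA);
      ``far_dimer``       two 3-atom chains 100 A apart (zero BSA);
      ``touching_dimer``  two 3-atom chains in van der Waals contact;
      ``hbond_pair``      chains presenting an N-H...O=C geometry at 2.9 A;
      ``hydrophobic_pair`` two apolar carbons 4.0 A apart.
    """
    if preset == "single_sphere":
        return StructureModel(atoms=(
            _atom("A", "LIG", 1, "C1", "C", (0.0, 0.0, 0.0)),
        ))
    if preset in ("far_dimer", "touching_dimer"):
        gap = 100.0 if preset == "far_dimer" else 3.6
        chain_a = (
            _atom("A", "ALA", 1, "C1", "C", (0.0, 0.0, 0.0)),
            _atom("A", "ALA", 1, "C2", "C", (1.5, 0.0, 0.0)),
            _atom("A", "ALA", 1, "C3", "C", (0.0, 1.5, 0.0)),
        )
        chain_b = (
            _atom("B", "ALA", 1, "C1", "C", (gap, 0.0, 0.0)),
            _atom("B", "ALA", 1, "C2", "C", (gap + 1.5, 0.0, 0.0)),
            _atom("B", "ALA", 1, "C3", "C", (gap, 1.5, 0.0)),
        )
        return StructureModel(atoms=chain_a + chain_b)
    if preset == "hbond_pair":
        # donor N (antecedent C) ... acceptor O (antecedent C), linear along x
        return StructureModel(atoms=(
            _atom("A", "RES", 1, "C", "C", (-1.4, 0.0, 0.0)),
            _atom("A", "RES", 1, "N", "N", (0.0, 0.0, 0.0)),
            _atom("B", "RES", 1, "O", "O", (2.9, 0.0, 0.0)),
            _atom("B", "RES", 1, "C", "C", (4.1, 0.0, 0.0)),
        ))
    if preset == "hydrophobic_pair":
        return StructureModel(atoms=(
            _atom("A", "LIG", 1, "C1", "C", (0.0, 0.0, 0.0)),
            _atom("B", "LIG", 1, "C1", "C", (4.0, 0.0, 0.0)),
        ))
    raise ValueError(f"unknown toy preset {preset!r}")


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to PDB or mmCIF (by file extension)."""
    st = gemmi.Structure()
    st.name = "toy"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
        key = (a.chain_id, a.residue_number)
        res = residues.get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            residues[key] = res
            ch.add_residue(res)
            res = ch[-1]
            residues[key] = res
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.occ = a.occupancy
        res.add_atom(at)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
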