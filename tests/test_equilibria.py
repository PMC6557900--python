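"""Mass-action equilibrium solvers: closed forms, root-finding, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sh2bind.equilibria import (
    CompetitionSystem,
    DomainError,
    TwoComponentSystem,
    competition_cubic_roots,
    infer_competitor_bound,
    ki_from_species,
    solve_competition_forward,
    solve_two_component,
)


def bisect_oracle(sys: CompetitionSystem, iters: int = 200) -> float:
    """Naive bisection on f(Pf) = Pf(1 + L0/(KD+Pf) + I0/(Ki+Pf)) - P0."""
    f = lambda pf: pf * (1 + sys.L0 / (sys.KD + pf) + sys.I0 / (sys.Ki + pf)) - sys.P0
    lo, hi = 0.0, sys.P0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    pf = 0.5 * (lo + hi)
    return pf * sys.L0 / (sys.KD + pf)


class TestTwoComponent:
    @pytest.mark.parametrize(
        "p0, l0, kd, expected",
        [
            (5.0, 100.0, 50.0, 3.2958896017208446),  # quadratic smaller root
            (5.0, 0.0, 50.0, 0.0),                   # no ligand
            (5.0, 100.0, 1e-9, 5.0),                 # stoichiometric limit
        ],
    )
    def test_examples(self, p0, l0, kd, expected):
        assert solve_two_component(p0, l0, kd) == pytest.approx(expected, rel=1e-7)

    def test_mass_action_residual(self):
        pl = solve_two_component(5.0, 100.0, 50.0)
        assert abs((5.0 - pl) * (100.0 - pl) / pl - 50.0) < 1e-10

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, -1, 1), (1, 1, 0), (1, 1, -2)])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            solve_two_component(*bad)

    @given(
        p0=st.floats(1e-3, 1e3), l0=st.floats(1e-3, 1e3), kd=st.floats(1e-3, 1e4)
    )
    @settings(max_examples=200, derandomize=True)
    def test_root_is_physical_and_consistent(self, p0, l0, kd):
        pl = solve_two_component(p0, l0, kd)
        assert 0.0 <= pl <= min(p0, l0)
        if pl > 1e-12:
            assert (p0 - pl) * (l0 - pl) / pl == pytest.approx(kd, rel=1e-8)


class TestCompetitionForward:
    def test_inert_competitor_reduces_to_two_component(self):
        state = solve_competition_forward(CompetitionSystem(5, 100, 10, 50, 1e12))
        assert state.PL == pytest.approx(solve_two_component(5, 100, 50), rel=1e-9)
        assert state.PI == pytest.approx(0.0, abs=1e-9)

    def test_zero_competitor_reduces_to_two_component(self):
        state = solve_competition_forward(CompetitionSystem(5, 100, 0, 50, 1.0))
        assert state.PL == pytest.approx(3.2958896017208446, rel=1e-9)
        assert state.PI == 0.0

    def test_reference_competition_state(self):
        state = solve_competition_forward(CompetitionSystem(5, 100, 10, 50, 4.134))
        assert state.PL == pytest.approx(2.000, abs=5e-4)
        assert state.PI == pytest.approx(1.9796, abs=5e-4)

    def test_species_invariants_random_systems(self, rng):
        for _ in range(2000):
            sys = CompetitionSystem(
                P0=float(10 ** rng.uniform(-2, 2)),
                L0=float(10 ** rng.uniform(-2, 3)),
                I0=float(10 ** rng.uniform(-2, 3)),
                KD=float(10 ** rng.uniform(-3, 4)),
                Ki=float(10 ** rng.uniform(-3, 4)),
            )
            s = solve_competition_forward(sys)
            assert min(s.Pfree, s.Lfree, s.Ifree, s.PL, s.PI) >= 0
            rp, rl, ri = s.mass_balance_residuals(sys)
            assert abs(rp) <= 1e-9 * max(sys.P0, 1.0)
            assert abs(rl) <= 1e-9 * max(sys.L0, 1.0)
            assert abs(ri) <= 1e-9 * max(sys.I0, 1.0)
            if s.PL > 0:
                assert s.Pfree * s.Lfree / s.PL == pytest.approx(sys.KD, rel=1e-8)
            if s.PI > 0:
                assert s.Pfree * s.Ifree / s.PI == pytest.approx(sys.Ki, rel=1e-8)

    def test_agrees_with_bisection_oracle_on_log_grid(self):
        for kd in np.logspace(-3, 4, 8):
            for ki in np.logspace(-3, 4, 8):
                sys = CompetitionSystem(5.0, 100.0, 10.0, float(kd), float(ki))
                pl = solve_competition_forward(sys).PL
                assert abs(pl - bisect_oracle(sys)) < 1e-8

    def test_agrees_with_cubic_closed_form(self):
        for kd in (0.1, 5.0, 500.0):
            for ki in (0.5, 20.0, 1e3):
                sys = CompetitionSystem(5.0, 100.0, 10.0, kd, ki)
                pf_cubic = competition_cubic_roots(sys)
                assert solve_competition_forward(sys).Pfree == pytest.approx(
                    pf_cubic, rel=1e-7
                )

    def test_monotone_in_competitor_and_ki(self):
        pls = [
            solve_competition_forward(CompetitionSystem(5, 100, i0, 50, 4.0)).PL
            for i0 in np.linspace(0, 100, 30)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(pls, pls[1:]))  # PL falls with I0
        pls = [
            solve_competition_forward(CompetitionSystem(5, 100, 10, 50, ki)).PL
            for ki in np.logspace(-3, 4, 30)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(pls, pls[1:]))  # PL rises with Ki

    def test_weak_binding_linearization(self):
        # KD -> infinity: PL approaches P0*L0/KD
        p0, l0 = 5.0, 100.0
        kd = 1e4 * max(p0, l0)
        pl = solve_competition_forward(CompetitionSystem(p0, l0, 0.0, kd, 1.0)).PL
        assert pl == pytest.approx(p0 * l0 / kd, rel=1e-2)

    def test_degenerate_totals(self):
        s = solve_competition_forward(CompetitionSystem(0.0, 100.0, 10.0, 50.0, 1.0))
        assert (s.PL, s.PI, s.Pfree) == (0.0, 0.0, 0.0)
        s = solve_competition_forward(CompetitionSystem(5.0, 0.0, 0.0, 50.0, 1.0))
        assert (s.PL, s.PI) == (0.0, 0.0)


class TestInversion:
    @pytest.mark.parametrize(
        "pl, expected",
        [
            (2.0, 1.9795918367346939),
            (3.2958896017208446, 0.0),   # PL equals PL0, nothing displaced
            (0.0, 5.0),                  # complete displacement sequesters protein
        ],
    )
    def test_closed_form(self, pl, expected):
        pi, _ = infer_competitor_bound(5.0, 100.0, 50.0, pl)
        assert pi == pytest.approx(expected, abs=1e-9)

    def test_substitution_reproduces_pl(self):
        pi, _ = infer_competitor_bound(5.0, 100.0, 50.0, 2.0)
        p0_eff = 5.0 - pi
        s = p0_eff + 100.0 + 50.0
        pl_back = (s - np.sqrt(s * s - 4 * p0_eff * 100.0)) / 2
        assert pl_back == pytest.approx(2.0, rel=1e-10)

    def test_infeasible_pl_raises(self):
        with pytest.raises(DomainError):
            infer_competitor_bound(5.0, 100.0, 50.0, 5.0)
        with pytest.raises(DomainError):  # PL above PL0 -> negative PI
            infer_competitor_bound(5.0, 100.0, 50.0, 3.4)

    def test_marginal_overshoot_is_clamped(self):
        pl0 = solve_two_component(5.0, 100.0, 50.0)
        pi, clamped = infer_competitor_bound(5.0, 100.0, 50.0, pl0 + 1e-9)
        assert pi == 0.0 and clamped


class TestKiFromSpecies:
    @pytest.mark.parametrize(
        "p0, i0, pi, pl, expected",
        [
            (5.0, 10.0, 1.9796, 2.0, 4.134),
            (5.0, 10.0, 0.5, 3.0, 28.5),
        ],
    )
    def test_arithmetic(self, p0, i0, pi, pl, expected):
        assert ki_from_species(p0, i0, pi, pl) == pytest.approx(expected, rel=1e-3)

    def test_saturated_competitor_gives_zero(self):
        assert ki_from_species(5.0, 10.0, 10.0, 0.0) == 0.0

    def test_errors(self):
        with pytest.raises(DomainError):
            ki_from_species(5.0, 10.0, 0.0, 2.0)
        with pytest.raises(DomainError):
            ki_from_species(5.0, 10.0, 11.0, 0.0)
        with pytest.raises(DomainError):
            ki_from_species(5.0, 10.0, 4.0, 2.0)


def test_forward_inverse_round_trip_recovers_ki(rng):
    """PL from the forward solver -> inversion -> Ki reproduces the input Ki."""
    for _ in range(300):
        sys = CompetitionSystem(
            P0=5.0,
            L0=100.0,
            I0=float(10 ** rng.uniform(0, 2)),
            KD=50.0,
            Ki=float(10 ** rng.uniform(-2, 3)),
        )
        state = solve_competition_forward(sys)
        pi, _ = infer_competitor_bound(sys.P0, sys.L0, sys.KD, state.PL)
        ki = ki_from_species(sys.P0, sys.I0, pi, state.PL)
        assert ki == pytest.approx(sys.Ki, rel=1e-8)
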