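"""Discrete cell-file model: RHS structure, division, steady profiles."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import rootga as rg
from rootga.cellfile import (
    CellFileState,
    _divide,
    _jac_sparsity,
    _make_ctx,
    _pack_rhs,
    assemble_rhs,
    initial_state,
    snapshot_profile,
)
from rootga.growth import SteadyTemplate
from rootga.params import (
    CatabolismRates,
    EnzymeActivityProfile,
    MembranePermeabilities,
    PlasmodesmataParams,
    SupplyRates,
    Zone,
    ZONES,
)


def closed_params(params, *, delta4=0.0, delta12=0.0, s_qcz=0.0, p_plas=0.0,
                  ga2ox_mult=1.0):
    """Parameter variant with no growth, no membranes, optional sinks."""
    g = replace(params.growth, meristem_rer=0.0,
                ez_rer_x=np.array([240.0, 950.0]), ez_rer=np.array([0.0, 0.0]))
    zeros = (0.0,) * 5
    enz = EnzymeActivityProfile(
        ga20ox={z: 0.0 for z in ZONES},
        ga3ox={z: 0.0 for z in ZONES},
        ga2ox_ga12={z: ga2ox_mult for z in ZONES},
        ga2ox_ga9ga4={z: ga2ox_mult for z in ZONES},
    )
    return params.with_(
        growth=g,
        enzymes=enz,
        membranes=MembranePermeabilities(zeros, zeros, zeros, zeros),
        plasmodesmata=PlasmodesmataParams(p_plas=p_plas),
        supply=SupplyRates(s_qcz=s_qcz, d_phloem=0.0, d_apo=0.0,
                           apoplast_area_fraction=0.0),
        catabolism=CatabolismRates(delta12=delta12, delta9=0.0, delta4=delta4),
    )


def single_cell_state(params, length=10.0, conc=None):
    a = params.cross_area
    v = length * a
    cyt = np.zeros((1, 5)) if conc is None else np.array([conc], dtype=float)
    return CellFileState(
        vc=np.array([0.65 * v]), vv=np.array([0.35 * v]), birth=np.array([length / 2]),
        cyt=cyt, vac=np.zeros((1, 5)), apo=np.zeros((2, 5)),
    )


def integrate(params, state, t_end, rtol=1e-10):
    ctx = _make_ctx(params, None, state.n_cells, state.birth)
    rhs = _pack_rhs(ctx)
    sol = solve_ivp(rhs, (0, t_end), state.pack(), method="BDF",
                    jac_sparsity=_jac_sparsity(state.n_cells), rtol=rtol, atol=1e-12)
    return CellFileState.unpack(sol.y[:, -1], state.n_cells, state.birth, t_end)


class TestAssembleRhs:
    def test_closed_cell_linear_decay(self, params):
        # only GA4 catabolism: c(t) = c0 exp(-delta4 t)
        p = closed_params(params, delta4=0.3)
        st = single_cell_state(p, conc=[0, 0, 0, 0, 8.0])
        out = integrate(p, st, 5.0)
        assert out.cyt[0, 4] == pytest.approx(8.0 * np.exp(-0.3 * 5.0), rel=1e-6)

    def test_constant_supply_linear_sink_steady_state(self, params):
        # GA12 source s and degradation delta: steady c = s/delta
        p = closed_params(params, delta12=0.5, s_qcz=4.0)
        st = single_cell_state(p)  # cell sits in the QCZ
        out = integrate(p, st, 60.0)
        assert out.cyt[0, 0] == pytest.approx(4.0 / 0.5, rel=1e-5)

    def test_two_cells_coupled_by_plasmodesmata_converge_to_mean(self, params):
        p = closed_params(params, p_plas=50.0)
        a = p.cross_area
        v = 10.0 * a
        st = CellFileState(
            vc=np.full(2, 0.65 * v), vv=np.full(2, 0.35 * v), birth=np.full(2, 5.0),
            cyt=np.array([[0, 0, 0, 0, 12.0], [0, 0, 0, 0, 2.0]], dtype=float),
            vac=np.zeros((2, 5)), apo=np.zeros((3, 5)),
        )
        vc = 0.65 * v
        k = 50.0 * a * (2 / vc)
        t = 1.5 / k
        out = integrate(p, st, t)
        mean = 7.0
        expected_hi = mean + 5.0 * np.exp(-k * t)
        assert out.cyt[0, 4] == pytest.approx(expected_hi, rel=1e-4)
        out2 = integrate(p, st, 30.0 / k)
        assert out2.cyt[:, 4] == pytest.approx([mean, mean], rel=1e-6)

    def test_rhs_amount_balance_closes_to_machine_precision(self, params, template):
        # d(total amount)/dt must equal supply - degradation exactly
        rng = np.random.default_rng(7)
        st = initial_state(params, template)
        st.cyt[:] = rng.uniform(0, 50, st.cyt.shape)
        st.vac[:] = rng.uniform(0, 50, st.vac.shape)
        st.apo[:] = rng.uniform(0, 5, st.apo.shape)
        dstate, rates = assemble_rhs(st, params)
        va = params.cross_area * params.wall_thickness
        d_amount = (
            np.sum(dstate.cyt * st.vc[:, None] + st.cyt * dstate.vc[:, None])
            + np.sum(dstate.vac * st.vv[:, None] + st.vac * dstate.vv[:, None])
            + np.sum(dstate.apo * va)
        )
        expected = rates["supply"] - rates["degradation"]
        assert d_amount == pytest.approx(expected, rel=1e-12)

    def test_intensive_scaling_invariance(self, params, template):
        # doubling every volume and flux area leaves concentration dynamics
        # unchanged
        st = initial_state(params, template)
        rng = np.random.default_rng(3)
        st.cyt[:] = rng.uniform(0, 30, st.cyt.shape)
        d1, _ = assemble_rhs(st, params)
        p2 = params.with_(cross_area=2 * params.cross_area)
        st2 = CellFileState(vc=2 * st.vc, vv=2 * st.vv, birth=st.birth,
                            cyt=st.cyt.copy(), vac=st.vac.copy(), apo=st.apo.copy())
        d2, _ = assemble_rhs(st2, p2)
        assert d2.cyt == pytest.approx(d1.cyt, rel=1e-10)
        assert d2.vac == pytest.approx(d1.vac, rel=1e-10)

    def test_zero_permeabilities_decouple_compartments(self, params, template):
        p = closed_params(params)
        st = initial_state(p, template)
        rng = np.random.default_rng(5)
        st.cyt[:] = rng.uniform(0, 30, st.cyt.shape)
        st.vac[:] = rng.uniform(0, 30, st.vac.shape)
        st.apo[:] = rng.uniform(0, 3, st.apo.shape)
        d, _ = assemble_rhs(st, p)
        assert np.all(d.vac == 0.0)
        assert np.all(d.apo == 0.0)

    def test_invalid_state_raises(self, params):
        st = single_cell_state(params)
        st.vc[0] = -1.0
        with pytest.raises(FloatingPointError):
            assemble_rhs(st, params)


class TestDivision:
    def test_split_preserves_length_and_concentrations(self, params):
        a = params.cross_area
        length = 9.0  # above twice the prescribed birth length at its position
        v = length * a
        st = CellFileState(
            vc=np.array([0.65 * v]), vv=np.array([0.35 * v]), birth=np.array([4.0]),
            cyt=np.array([[1.0, 2, 3, 4, 5.0]]), vac=np.array([[5, 4, 3, 2, 1.0]]),
            apo=np.zeros((2, 5)),
        )
        ctx = _make_ctx(params, None, 1, st.birth)
        out = _divide(st, ctx)
        assert out.n_cells == 2
        assert out.lengths(a).sum() == pytest.approx(9.0, rel=1e-12)
        assert np.all(out.cyt[0] == st.cyt[0]) and np.all(out.cyt[1] == st.cyt[0])
        assert np.all(out.vac[0] == st.vac[0])
        assert out.apo.shape == (3, 5)
        assert np.all(out.apo[1] == 0.0)  # fresh wall starts empty

    def test_no_split_below_threshold(self, params):
        st = single_cell_state(params, length=6.0)
        ctx = _make_ctx(params, None, 1, st.birth)
        assert _divide(st, ctx) is st


class TestSnapshotProfile:
    def test_uniform_concentrations_give_constant_field(self, params, template):
        st = initial_state(params, template)
        st.cyt[:] = 3.0
        prof = snapshot_profile(st, np.linspace(10, 900, 50), params.cross_area)
        assert np.all(prof.cyt == 3.0)

    def test_midpoint_grid_recovers_cell_values(self, params, template):
        st = initial_state(params, template)
        rng = np.random.default_rng(0)
        st.cyt[:] = rng.uniform(0, 10, st.cyt.shape)
        l = st.lengths(params.cross_area)
        mids = st.ends(params.cross_area) - 0.5 * l
        prof = snapshot_profile(st, mids, params.cross_area)
        assert prof.cyt == pytest.approx(st.cyt)

    def test_out_of_range_grid_rejected(self, params, template):
        st = initial_state(params, template)
        with pytest.raises(ValueError):
            snapshot_profile(st, np.array([1e5]), params.cross_area)

    def test_refinement_consistency(self, params, template):
        st = initial_state(params, template)
        rng = np.random.default_rng(1)
        st.cyt[:] = rng.uniform(0, 10, st.cyt.shape)
        g1 = np.linspace(5, 900, 200)
        g2 = np.linspace(5, 900, 400)
        p1 = snapshot_profile(st, g1, params.cross_area)
        p2 = snapshot_profile(st, g2, params.cross_area)
        jump = np.max(np.abs(np.diff(st.cyt[:, 4])))
        assert np.max(np.abs(np.interp(g1, g2, p2.cyt[:, 4]) - p1.cyt[:, 4])) <= jump


class TestSteadyRun:
    def test_zero_supply_gives_zero_profile(self, params):
        p = params.with_(supply=replace(params.supply, s_qcz=0.0, d_phloem=0.0))
        prof = rg.run_to_steady_profile(p, rtol=1e-6, min_windows=2)
        assert np.max(np.abs(prof.cyt)) < 1e-6

    def test_baseline_nonnegative_and_rising_into_ez(self, discrete_baseline, params):
        prof = discrete_baseline
        assert np.min(prof.cyt) >= -1e-9
        dz = params.zones.dz_end
        seg = (prof.x >= dz - 50) & (prof.x <= dz + 100)
        ga4 = prof.ga4()
        fit = np.polyfit(prof.x[seg], ga4[seg], 1)
        assert fit[0] > 0.0  # positive slope across the meristem/EZ transition

    def test_mass_balance_within_tenth_of_percent(self, discrete_baseline):
        mb = discrete_baseline.meta["mass_balance"]
        assert mb["rel_error"] < 1e-3

    def test_homogeneous_static_file_equilibrates_uniformly(self, params, template):
        # no growth, uniform parameters, no supply gradient: steady state
        # is spatially uniform
        p = closed_params(params, p_plas=100.0)
        xs = np.linspace(0, 300, 50)
        tpl = SteadyTemplate(x=xs, l=np.full(50, 10.0), v=np.zeros(50),
                             phi=np.full(50, 0.35), rer=np.zeros(50))
        st = initial_state(p, tpl)
        st = CellFileState(vc=st.vc[:12], vv=st.vv[:12], birth=st.birth[:12],
                           cyt=st.cyt[:12], vac=st.vac[:12], apo=st.apo[:13])
        rng = np.random.default_rng(11)
        st.cyt[:] = rng.uniform(1, 9, st.cyt.shape)
        out = integrate(p, st, 500.0, rtol=1e-10)
        mean = np.mean(out.cyt, axis=0)
        assert np.max(np.abs(out.cyt - mean)) < 1e-6 * max(mean.max(), 1.0)
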