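"""Continuum solver: effective coefficients, closed forms, convergence."""

from dataclasses import replace

import numpy as np
import pytest

import rootga as rg
from rootga import continuum as C
from rootga.growth import SteadyTemplate
from rootga.params import (
    CatabolismRates,
    EnzymeActivityProfile,
    MembranePermeabilities,
    PlasmodesmataParams,
    SupplyRates,
    ZONES,
)

from test_cellfile import closed_params


def flat_template(l=10.0, phi=0.35, length=1100.0, n=200):
    xs = np.linspace(0, length, n)
    return SteadyTemplate(x=xs, l=np.full(n, l), v=np.zeros(n),
                          phi=np.full(n, phi), rer=np.zeros(n))


class TestEffectiveCoefficients:
    def test_no_transport_pathways_gives_zero_diffusivity(self, params):
        zeros = (0.0,) * 5
        p = params.with_(
            membranes=MembranePermeabilities(zeros, zeros, zeros, zeros),
            plasmodesmata=PlasmodesmataParams(p_plas=0.0),
        )
        coeffs = rg.effective_coefficients(p)
        assert np.all(coeffs.d == 0.0)

    def test_diffusivity_strictly_increasing_in_pplas(self, params):
        c1 = rg.effective_coefficients(params)
        p2 = params.with_(plasmodesmata=PlasmodesmataParams(p_plas=2 * params.plasmodesmata.p_plas))
        c2 = rg.effective_coefficients(p2)
        assert np.all(c2.d > c1.d - 1e-12)
        assert np.all(c2.d[:, 0] > c1.d[:, 0])

    def test_velocity_matches_template(self, params, template):
        coeffs = rg.effective_coefficients(params, template=template)
        assert coeffs.v == pytest.approx(template.interp("v", coeffs.x), rel=1e-9)

    def test_pulse_relaxation_recovers_symplastic_diffusivity(self, params):
        # independent oracle: variance growth of a pulse in a static uniform
        # file equals 2 D t.  With the vacuole decoupled, the cytoplasmic
        # concentration spreads at D = P_plas l / (1 - phi): the amount
        # diffusivity P_plas l divided by the cytoplasmic capacity, exactly
        # the ratio of flux and capacity terms in the continuum equations
        from scipy.integrate import solve_ivp

        from rootga.cellfile import CellFileState, _jac_sparsity, _make_ctx, _pack_rhs
        from rootga.cellfile import initial_state

        p = closed_params(params, p_plas=60.0)
        tpl = flat_template(l=10.0, length=600.0)
        st = initial_state(p, tpl)
        n = st.n_cells
        mids = st.ends(p.cross_area) - 0.5 * st.lengths(p.cross_area)
        st.cyt[:, 0] = np.exp(-((mids - 300.0) / 30.0) ** 2)
        ctx = _make_ctx(p, None, n, st.birth)
        rhs = _pack_rhs(ctx)
        t_end = 4.0
        sol = solve_ivp(rhs, (0, t_end), st.pack(), method="BDF",
                        jac_sparsity=_jac_sparsity(n), rtol=1e-9, atol=1e-12)
        out = CellFileState.unpack(sol.y[:, -1], n, st.birth, t_end)

        def variance(c):
            w = c / np.sum(c)
            mu = np.sum(w * mids)
            return np.sum(w * (mids - mu) ** 2)

        d_obs = (variance(out.cyt[:, 0]) - variance(st.cyt[:, 0])) / (2 * t_end)
        assert d_obs == pytest.approx(60.0 * 10.0 / 0.65, rel=0.05)


class TestSolveSteady:
    def test_zero_supply_gives_zero_solution(self, params):
        p = params.with_(supply=replace(params.supply, s_qcz=0.0, d_phloem=0.0))
        sol = rg.solve_steady(p)
        assert np.max(np.abs(sol.cyt)) < 1e-9

    def test_uniform_supply_uniform_sink_closed_form(self, params):
        # v = 0, no transport coupling, uniform supply s and sink delta:
        # c = s/delta everywhere
        p = closed_params(params, delta12=0.5)
        p = p.with_(supply=replace(p.supply, s_qcz=2.0, d_phloem=0.0))
        tpl = flat_template()
        sc = rg.ScenarioConfig(uniform_supply=True)
        sol = rg.solve_steady(p, sc, template=tpl)
        s_uniform = 2.0 * p.zones.qcz_end / p.zones.domain_end
        assert sol.cyt[:, 0] == pytest.approx(s_uniform / 0.5, rel=1e-8)

    def test_localized_source_decays_with_sqrt_d_over_mu(self, params):
        # Green's-function length scale away from the QCZ source
        p = closed_params(params, delta12=0.4, s_qcz=10.0, p_plas=100.0)
        tpl = flat_template(l=10.0, phi=0.35)
        sol = rg.solve_steady(p, template=tpl, nx=1101)
        lam = np.sqrt(100.0 * 10.0 / (0.65 * 0.4))  # D / ((1-phi) delta)
        x = sol.x
        c = sol.cyt[:, 0]
        m = (x > 200) & (x < 500)  # far field, away from source and boundary
        slope = np.polyfit(x[m], np.log(c[m]), 1)[0]
        assert -1.0 / slope == pytest.approx(lam, rel=0.02)

    def test_small_diffusivity_stays_positive(self, params):
        # Péclet guard: strongly advection-dominated solve must not
        # oscillate into negative concentrations
        p = params.with_(plasmodesmata=PlasmodesmataParams(p_plas=0.5))
        sol = rg.solve_steady(p)
        assert np.min(sol.cyt) >= -1e-9

    def test_warm_start_returns_same_solution(self, params, continuum_baseline):
        sol2 = rg.solve_steady(params, warm_start=continuum_baseline)
        assert sol2.cyt == pytest.approx(continuum_baseline.cyt, abs=1e-7)

    def test_mass_balance_closes(self, params, continuum_baseline):
        mb = rg.mass_balance(params, continuum_baseline)
        assert mb["rel_error"] < 1e-3
        assert mb["supply"] > 0

    def test_flux_continuity_at_zone_boundaries(self, params, continuum_baseline):
        # total flux -D c' + v (1-phi) c is smooth across the DZ/EZ boundary
        # (finite-volume construction); check no jump beyond local variation
        sol = continuum_baseline
        x = sol.x
        tpl = rg.build_steady_template(params.growth, params.zones,
                                       params.birth_length_range)
        d = params.plasmodesmata.p_plas * tpl.interp("l", x)
        v = tpl.interp("v", x)
        phi = tpl.interp("phi", x)
        c = sol.cyt[:, 4]
        flux = -d * np.gradient(c, x) + v * (1 - phi) * c
        i = np.searchsorted(x, params.zones.dz_end)
        local = np.abs(np.diff(flux[i - 5 : i + 5]))
        assert np.max(local) < 0.2 * (np.max(np.abs(flux[i - 5 : i + 5])) + 1e-12)


class TestMeshConvergence:
    def test_manufactured_solution_second_order(self, params):
        # method of manufactured solutions on a smooth scalar problem:
        # GA4 with constant coefficients, forcing chosen for a cosine field
        import sympy as sp

        length = params.zones.domain_end
        delta = 0.4
        d_coeff = 180.0 * 10.0
        xs = sp.symbols("x")
        c_star = 20 * (1 + sp.cos(sp.pi * xs / length))
        v_expr = 0.1 * xs  # smooth velocity, v(0)=0
        phi = 0.35
        flux = -d_coeff * sp.diff(c_star, xs) + v_expr * (1 - phi) * c_star
        forcing = (sp.diff(flux, xs) + (1 - phi) * delta * c_star) / (1 - phi)
        f_num = sp.lambdify(xs, forcing, "numpy")
        c_num = sp.lambdify(xs, c_star, "numpy")

        p = closed_params(params, p_plas=180.0)
        p = p.with_(catabolism=CatabolismRates(0.0, 0.0, delta))
        errs = []
        for nx in (70, 139, 277, 553):
            grid = np.linspace(0, length, nx)
            tpl = SteadyTemplate(
                x=grid, l=np.full(nx, 10.0), v=0.1 * grid,
                phi=np.full(nx, phi), rer=np.full(nx, 0.1),
            )
            prob = C._build_problem(4, p, None, tpl, grid, np.asarray(f_num(grid)))
            z, rn = C._newton_banded(prob, np.zeros(3 * nx), 1e-10)
            err = z[0::3] - c_num(grid)
            errs.append(np.sqrt(np.trapezoid(err**2, grid)))
        orders = [np.log2(e0 / e1) for e0, e1 in zip(errs[:-1], errs[1:])]
        assert all(1.7 < o < 2.3 for o in orders)

    def test_baseline_errors_decrease_monotonically(self, params):
        report = rg.mesh_convergence_report(params, levels=(139, 277, 553, 1105))
        diffs = report["l2_diffs"]
        assert all(d1 < d0 for d0, d1 in zip(diffs[:-1], diffs[1:]))


class TestCrossModelConsistency:
    def test_pplas_comparative_statics_sign_agrees(
        self, params, discrete_baseline, discrete_pplas3, continuum_baseline
    ):
        # tripling plasmodesmatal permeability changes the GA4 profile in
        # the same direction in both solvers at every probed position
        from rootga.scenarios import builtin_scenarios, effective_params

        sc = builtin_scenarios()["h2o2"]
        cont3 = rg.solve_steady(effective_params(params, sc), sc)
        probes = np.array([50.0, 150.0, 300.0, 450.0])
        d_disc = (np.interp(probes, discrete_pplas3.x, discrete_pplas3.ga4())
                  - np.interp(probes, discrete_baseline.x, discrete_baseline.ga4()))
        d_cont = (np.interp(probes, cont3.x, cont3.ga4())
                  - np.interp(probes, continuum_baseline.x, continuum_baseline.ga4()))
        assert np.all(np.sign(d_disc) == np.sign(d_cont))
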