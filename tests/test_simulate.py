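"""ODE compilation, protocols, conversions, solver properties."""

import numpy as np
import pytest

from vegfnet.modelio import read_model
from vegfnet.simulate import (CompiledModel, Protocol, ProtocolEvent,
                              UnitError, count_to_density, density_to_count,
                              ligand_to_nM, nM_to_unit, vegf_protocol,
                              tsp1_then_vegf_protocol)


class TestConversions:
    def test_zero_is_zero(self):
        assert ligand_to_nM(0.0, "nM") == 0.0
        assert ligand_to_nM(0.0, "ng/ml", 38.4) == 0.0

    def test_tsp1_round_trip(self):
        v = ligand_to_nM(2.0, "nM")
        assert nM_to_unit(v, "nM") == 2.0

    def test_vegf_ng_per_ml(self):
        # 50 ng/ml of a 38.4 kDa homodimer: 50e-6 g/L / 38400 g/mol
        expect = 50e-6 / 38400 * 1e9
        assert ligand_to_nM(50.0, "ng/ml", 38.4) == pytest.approx(expect)
        assert nM_to_unit(expect, "ng/ml", 38.4) == pytest.approx(50.0)

    def test_pM(self):
        assert ligand_to_nM(250.0, "pM") == pytest.approx(0.25)

    def test_unknown_unit(self):
        with pytest.raises(UnitError):
            ligand_to_nM(1.0, "furlongs")

    def test_density_round_trip(self):
        c = density_to_count(5.0, 1400.0)
        assert c == 7000.0
        assert count_to_density(c, 1400.0) == pytest.approx(5.0)


class TestProtocol:
    def test_event_time_ordering_enforced(self):
        with pytest.raises(ValueError):
            Protocol(events=[ProtocolEvent(100, "set_ligand", "VEGF", 1.0),
                             ProtocolEvent(50, "set_ligand", "TSP1", 1.0)])

    def test_fold_scaling_positive(self):
        with pytest.raises(ValueError):
            Protocol(events=[ProtocolEvent(0, "scale_param", "kint", -1.0)])

    def test_from_dict_round_trip(self):
        d = {"duration_min": 50, "dt_out_s": 10,
             "events": [{"time_min": 0, "set_ligand": "TSP1", "value": 2,
                         "unit": "nM"},
                        {"time_min": 10, "set_ligand": "VEGF", "value": 50,
                         "unit": "ng/ml"}],
             "overrides": {"fold_deg": 10}}
        pro = Protocol.from_dict(d)
        assert pro.duration == 3000.0
        assert len(pro.events) == 2
        assert pro.overrides == {"fold_deg": 10.0}


@pytest.fixture(scope="module")
def toy_cm(toy_model_text):
    return CompiledModel(read_model(toy_model_text))


class TestBuildOde:
    def test_equilibrium_has_zero_derivatives(self, toy_cm):
        """A+B<->AB at its analytic equilibrium: all derivatives vanish."""
        ps = toy_cm.model.params
        kon, koff = ps.get("kon"), ps.get("koff")
        l0, r0 = ps.get("L0"), ps.get("R0")
        # solve kon*L*R = koff*C with totals
        from scipy.optimize import brentq
        c = brentq(lambda c: kon * (l0 - c) * (r0 - c) - koff * c, 0,
                   min(l0, r0))
        rhs, jac = toy_cm.build_ode(ps)
        labels = toy_cm.network.labels
        y = np.zeros(toy_cm.n_state)
        for i, lab in enumerate(labels):
            if "." in lab.split(":")[1]:
                y[i] = c
            elif lab.endswith("L(r)"):
                y[i] = l0 - c
            else:
                y[i] = r0 - c
        d = rhs(0.0, y)
        assert np.allclose(d[:3], 0.0, atol=1e-10)

    def test_jacobian_matches_finite_differences(self, toy_cm, rng):
        ps = toy_cm.model.params
        rhs, jac = toy_cm.build_ode(ps)
        y = np.abs(rng.normal(1.0, 0.5, toy_cm.n_state))
        J = jac(0.0, y)
        eps = 1e-6
        for j in range(3):   # network block columns
            yp = y.copy()
            yp[j] += eps
            col = (rhs(0, yp) - rhs(0, y)) / eps
            assert np.allclose(J[:3, j], col[:3], rtol=1e-5, atol=1e-7)

    def test_full_model_jacobian_network_block(self, compiled, model, rng):
        ps = model.params
        rhs, jac = compiled.build_ode(ps)
        y = compiled.initial_state(ps)
        y[:compiled.n_s] += np.abs(rng.normal(0, 5.0, compiled.n_s))
        J = jac(0.0, y)
        cols = rng.integers(0, compiled.n_s, size=5)
        f0 = rhs(0, y)
        for j in cols:
            h = 1e-4 * max(abs(y[j]), 1.0)
            yp = y.copy()
            yp[j] += h
            col = (rhs(0, yp) - f0) / h
            assert np.allclose(J[:compiled.n_s, j], col[:compiled.n_s],
                               rtol=5e-4, atol=1e-6)


class TestRunProtocol:
    def test_no_stimulus_flat_baseline(self, compiled, model):
        pro = Protocol(events=[], duration=600.0, dt_out=30.0)
        tr = compiled.run_protocol(pro, model.params)
        assert tr.max("pR2") == pytest.approx(0.0, abs=1e-6)
        r2 = tr["R2_total_frac"]
        assert np.allclose(r2, 1.0, atol=1e-6)
        assert abs(tr.final("Ca_c") - tr["Ca_c"][0]) < 1e-4

    def test_conservation_with_degradation_disabled(self, compiled, model):
        ps = model.params.with_overrides(kdeg0=0.0)
        tr = compiled.run_protocol(vegf_protocol(duration_min=30), ps)
        r2 = tr["R2_total"]
        assert np.max(np.abs(r2 - r2[0])) < 1e-5 * r2[0]
        cd47 = tr["CD47_total"]
        assert np.max(np.abs(cd47 - cd47[0])) < 1e-5 * cd47[0]

    def test_total_r2_nonincreasing_with_degradation(self, compiled, model):
        tr = compiled.run_protocol(vegf_protocol(duration_min=60),
                                   model.params)
        r2 = tr["R2_total"]
        assert np.all(np.diff(r2) <= 1e-6 * r2[0])

    def test_fraction_observables_bounded(self, compiled, model):
        tr = compiled.run_protocol(vegf_protocol(duration_min=40),
                                   model.params)
        for name in ("R2_total_frac", "R2_surf_frac", "pR2_frac"):
            assert np.all(tr[name] >= -1e-6)
            assert np.all(tr[name] <= 1.0 + 1e-6)

    def test_event_preserves_state_continuity(self, compiled, model):
        """State is continuous across the VEGF-addition event except the
        clamped ligand itself."""
        pro = tsp1_then_vegf_protocol(tsp1_nM=2.0, pre_min=5.0, vegf_min=5.0,
                                      dt_out=2.0)
        tr = compiled.run_protocol(pro, model.params)
        i = np.searchsorted(tr.t, 300.0)
        for name in ("R2_total", "R2_surf", "CD47_total", "Ca_c"):
            before, after = tr[name][i - 1], tr[name][i + 1]
            assert abs(after - before) < 0.02 * max(abs(before), 1e-6) + 1e-6

    def test_grid_refinement_stability(self, compiled, model):
        """Tightening tolerances changes reported observables by < 0.1%."""
        pro = vegf_protocol(duration_min=20)
        a = compiled.run_protocol(pro, model.params, rtol=1e-7, atol=1e-9)
        b = compiled.run_protocol(pro, model.params, rtol=3.16e-8, atol=5e-10)
        for name in ("R2_total_frac", "pR2_frac", "Ca_c"):
            scale = np.max(np.abs(a[name])) or 1.0
            assert np.max(np.abs(a[name] - b[name])) < 1e-3 * scale

    def test_missing_ligand_species_raises(self, toy_cm):
        from vegfnet.simulate import SimulationError
        pro = vegf_protocol(duration_min=1)
        with pytest.raises(SimulationError, match="clamped ligand"):
            toy_cm.run_protocol(pro)
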