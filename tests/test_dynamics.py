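import numpy as np
import pytest

from gctetra.dynamics import (
    edc_damping,
    emit_observables,
    propagate_trajectory,
    run_ensemble,
    sample_wigner,
    select_initial_states,
    tdba_coupling,
)
from gctetra.errors import EmptyEnsembleError, InvalidCompositionError, InvalidModelError
from gctetra.model import (
    DiabaticConfig,
    DiabaticModel,
    Mode,
    SimConfig,
    zero_coupling_model,
)
from gctetra.records import PhaseSpaceSample
from gctetra.topology import nonalternating_tetramer
from gctetra.units import HBAR


class TestWigner:
    def test_empty_request(self, nonalt_model):
        assert sample_wigner(nonalt_model, 0, seed=1) == []

    def test_variance_matches_closed_form(self):
        """Sample variance of one mode agrees with hbar/(2 omega)."""
        topo = nonalternating_tetramer()
        omega = 0.3
        model = DiabaticModel(
            topology=topo,
            modes=(Mode(omega, "m"),),
            configs=(
                DiabaticConfig("ground", "ground", None, None, 0.0, (0.0,), 0.0),
                DiabaticConfig("LE1", "le", 1, 1, 5.0, (0.0,), 1.0),
            ),
            coupling=np.zeros((2, 2)),
        )
        n = 100_000
        samples = sample_wigner(model, n, seed=3)
        xs = np.array([s.x[0] for s in samples])
        ps = np.array([s.p[0] for s in samples])
        var_x = HBAR / (2 * omega)
        var_p = HBAR * omega / 2
        # a sample variance of n gaussians has SE ~ var*sqrt(2/n)
        assert abs(xs.var() - var_x) < 3 * var_x * np.sqrt(2 / n)
        assert abs(ps.var() - var_p) < 3 * var_p * np.sqrt(2 / n)

    def test_seeded_determinism(self, nonalt_model):
        a = sample_wigner(nonalt_model, 5, seed=9)
        b = sample_wigner(nonalt_model, 5, seed=9)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.x, s2.x)
            np.testing.assert_array_equal(s1.p, s2.p)


class TestStateSelection:
    def make_sample(self, energies, strengths):
        k = len(energies)
        return PhaseSpaceSample(
            x=np.zeros(1), p=np.zeros(1),
            energies=np.asarray(energies, float),
            strengths=np.asarray(strengths, float),
        )

    def test_forced_choice(self):
        samples = [self.make_sample([4.9, 7.0], [0.5, 1.0]) for _ in range(20)]
        kept = select_initial_states(samples, 4.9, 0.5, seed=1)
        assert len(kept) == 20
        assert all(s.initial_state == 1 for s in kept)

    def test_strength_proportional_assignment(self):
        n = 10_000
        samples = [self.make_sample([4.8, 5.0], [1.0, 3.0]) for _ in range(n)]
        kept = select_initial_states(samples, 4.9, 0.5, seed=2)
        frac_s2 = np.mean([s.initial_state == 2 for s in kept])
        assert abs(frac_s2 - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)

    def test_all_dark_window_dropped(self):
        samples = [self.make_sample([4.9], [0.0]) for _ in range(5)]
        with pytest.warns(UserWarning):
            assert select_initial_states(samples, 4.9, 0.5, seed=1) == []


class TestTDBA:
    def test_constant_gap_gives_zero(self):
        assert tdba_coupling(1.0, 1.0, 1.0, 0.5) == 0.0

    def test_quadratic_gap_matches_analytic_curvature(self):
        """gap(t) = a + b t^2 has curvature 2b, so sigma = 0.5*sqrt(2b/a)
        exactly (the 3-point stencil is exact on quadratics)."""
        a, b, dt = 0.8, 0.05, 0.5
        t = 10.0
        gaps = [a + b * (t - k * dt) ** 2 for k in (0, 1, 2)]
        sigma = tdba_coupling(gaps[0], gaps[1], gaps[2], dt)
        assert sigma == pytest.approx(0.5 * np.sqrt(2 * b / gaps[0]), rel=1e-12)

    def test_negative_curvature_clamped(self):
        assert tdba_coupling(0.9, 1.0, 1.0, 0.5) == 0.0

    def test_nonpositive_gap_flagged(self):
        with pytest.warns(UserWarning):
            assert tdba_coupling(0.0, 1.0, 1.0, 0.5) == 0.0


class TestEDC:
    def test_zero_elapsed_time(self):
        assert edc_damping(5.0, 4.0, 0.5, dt=0.0, alpha=2.7) == 1.0

    def test_stated_arithmetic(self):
        """|dE|=0.1, E_kin=0.1, alpha=0.1 with hbar=1 gives tau=20."""
        factor = edc_damping(5.1, 5.0, 0.1, dt=1.0, alpha=0.1, hbar=1.0)
        assert factor == pytest.approx(np.exp(-1.0 / 20.0), rel=1e-12)

    def test_degenerate_states_not_damped(self):
        assert edc_damping(5.0, 5.0, 0.5, dt=0.5, alpha=2.7) == 1.0

    def test_renormalization_identity(self, rng):
        """Damping all non-active amplitudes then rescaling the active one
        restores unit norm exactly."""
        c = rng.normal(size=5) + 1j * rng.normal(size=5)
        c /= np.linalg.norm(c)
        active = 2
        for j in range(5):
            if j != active:
                c[j] *= edc_damping(5.0 + 0.1 * j, 5.2, 0.3, 0.5, 2.7)
        rest = sum(abs(c[j]) ** 2 for j in range(5) if j != active)
        c[active] *= np.sqrt((1 - rest) / abs(c[active]) ** 2)
        assert abs(np.linalg.norm(c) - 1.0) < 1e-12


class TestEmitObservables:
    def test_pure_local_excitation_channel(self, nonalt_model):
        C = nonalt_model.n_configs
        comp = np.zeros((C, 1))
        comp[1, 0] = 1.0  # LE1
        _, omega, nto = emit_observables(nonalt_model, comp, np.zeros(nonalt_model.n_modes))
        assert omega[0, 0, 0] == 1.0
        assert omega[0].sum() == 1.0

    def test_pure_charge_transfer_channel(self, nonalt_model):
        C = nonalt_model.n_configs
        ct_idx = next(
            i for i, cfg in enumerate(nonalt_model.configs)
            if cfg.kind == "ct" and cfg.hole == 1 and cfg.electron == 3
        )
        comp = np.zeros((C, 1))
        comp[ct_idx, 0] = 1.0
        _, omega, _ = emit_observables(nonalt_model, comp, np.zeros(nonalt_model.n_modes))
        assert omega[0, 0, 2] == 1.0

    def test_mixed_composition_matches_direct_sum(self, nonalt_model, rng):
        C = nonalt_model.n_configs
        comp = rng.normal(size=(C, 2))
        comp /= np.linalg.norm(comp, axis=0)
        _, omega, nto = emit_observables(nonalt_model, comp, np.zeros(nonalt_model.n_modes))
        for m in range(2):
            ref = np.zeros((4, 4))
            for d, cfg in enumerate(nonalt_model.configs):
                if cfg.hole is not None:
                    ref[cfg.hole - 1, cfg.electron - 1] += comp[d, m] ** 2
            np.testing.assert_allclose(omega[m], ref, atol=1e-12)
            np.testing.assert_allclose(
                np.sort(nto[m])[::-1], np.sort(comp[1:, m] ** 2)[::-1], atol=1e-12
            )

    def test_unnormalized_composition_rejected(self, nonalt_model):
        comp = np.full((nonalt_model.n_configs, 1), 0.5)
        with pytest.raises(InvalidCompositionError):
            emit_observables(nonalt_model, comp, np.zeros(nonalt_model.n_modes))


class TestPropagation:
    def test_zero_coupling_limit(self):
        """Symmetry-forbidden mixing: no hops, constant active state, and
        total-energy drift below 1e-6 eV over the whole trajectory."""
        model = zero_coupling_model()
        config = SimConfig(max_time_fs=500.0, seed=4)
        samples = select_initial_states(sample_wigner(model, 6, 4), 4.9, 2.0, 4)
        for i, s in enumerate(samples):
            rec = propagate_trajectory(model, s, config, seed=100 + i)
            assert len(rec.hops) == 0
            assert np.all(rec.active == rec.active[0])
            assert rec.ground_truth["etot_drift_ev"] <= 1e-6

    def test_quantum_norm_conserved(self, small_ensemble):
        _, _, _, records = small_ensemble
        for rec in records:
            norms = rec.populations.sum(axis=1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    def test_hop_energy_balance(self, small_ensemble):
        """Kinetic + potential energy before and after every accepted hop
        agree to 1e-10 eV (exact momentum rescaling)."""
        _, _, _, records = small_ensemble
        n_hops = 0
        for rec in records:
            for before, after in rec.ground_truth["hop_energy_balance"]:
                assert abs(before - after) < 1e-10
                n_hops += 1
        assert n_hops > 0

    def test_requires_excited_initial_state(self, nonalt_model):
        s = PhaseSpaceSample(
            x=np.zeros(nonalt_model.n_modes), p=np.zeros(nonalt_model.n_modes),
            energies=np.zeros(nonalt_model.n_excited),
            strengths=np.zeros(nonalt_model.n_excited),
        )
        with pytest.raises(InvalidModelError):
            propagate_trajectory(nonalt_model, s, SimConfig())

    def test_energies_sorted_and_active_changes_logged(self, small_ensemble):
        _, _, _, records = small_ensemble
        for rec in records:
            rec.validate()


class TestRunEnsemble:
    def test_empty_ensemble(self, nonalt_model):
        config = SimConfig(ensemble_size=0, seed=1)
        manifest, records = run_ensemble(nonalt_model, config)
        assert manifest.n_trajectories == 0 and records == []

    def test_seeded_determinism(self, nonalt_model):
        config = SimConfig(ensemble_size=3, seed=77, max_time_fs=300.0)
        m1, r1 = run_ensemble(nonalt_model, config)
        m2, r2 = run_ensemble(nonalt_model, config)
        for e1, e2 in zip(m1.entries, m2.entries):
            assert e1 == e2
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.energies, b.energies)
            np.testing.assert_array_equal(a.geometry, b.geometry)

    def test_manifest_matches_records(self, small_ensemble):
        _, _, manifest, records = small_ensemble
        assert manifest.n_trajectories == len(records)
        for e, r in zip(manifest.entries, records):
            assert e.trajectory_id == r.trajectory_id
            assert e.termination_time_fs == r.termination_time_fs
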