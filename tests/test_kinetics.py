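import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gctetra.errors import EmptyEnsembleError, UndefinedDecayError
from gctetra.kinetics import (
    arrival_histogram,
    ensemble_report,
    fit_decay,
    occupation_curves,
)
from gctetra.records import EnsembleManifest, ManifestEntry, TrajectoryRecord


def two_state_record(tid, n_steps, active, term_reason="gap"):
    times = np.arange(n_steps) * 0.5
    return TrajectoryRecord(
        trajectory_id=tid,
        times=times,
        energies=np.tile([0.0, 5.0, 5.5], (n_steps, 1)),
        active=np.full(n_steps, active, dtype=int),
        termination_time_fs=float(times[-1]),
        termination_reason=term_reason,
    )


class TestOccupation:
    def test_hand_case_half_terminates(self):
        """One of two trajectories reaches S0 at 100 fs: the ground-state
        fraction steps from 0 to 0.5 there."""
        r1 = two_state_record("a", 201, active=1)           # terminates at 100 fs
        r2 = two_state_record("b", 401, active=2, term_reason="max-time")
        occ = occupation_curves([r1, r2])
        s0 = occ.fractions[:, 0]
        assert s0[occ.times < 100.0].max() == 0.0
        assert np.all(s0[occ.times >= 100.0] == 0.5)

    def test_initial_fractions_match_initial_states(self):
        recs = [two_state_record(f"t{i}", 11, active=1 + (i % 2)) for i in range(10)]
        occ = occupation_curves(recs)
        assert occ.fractions[0, 1] == pytest.approx(0.5)
        assert occ.fractions[0, 2] == pytest.approx(0.5)

    def test_conservation_and_monotone_ground_state(self, small_ensemble):
        _, _, _, records = small_ensemble
        occ = occupation_curves(records)
        np.testing.assert_allclose(occ.fractions.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(occ.fractions[:, 0]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            occupation_curves([])


class TestDecayFit:
    def test_single_arrival_mle(self):
        fit = fit_decay(np.array([80.0]))
        assert fit.tau_fs == pytest.approx(80.0)

    def test_uncensored_recovery(self):
        rng = np.random.default_rng(7)
        tau = 100.0
        arr = rng.exponential(tau, size=10_000)
        fit = fit_decay(arr)
        assert abs(fit.tau_fs - tau) < 3 * tau / np.sqrt(len(arr))

    def test_censored_recovery_matches_numerical_mle(self):
        """The closed-form censored estimator agrees with direct numerical
        maximization of the censored exponential log-likelihood."""
        rng = np.random.default_rng(11)
        tau = 100.0
        draws = rng.exponential(tau, size=4000)
        cutoff = 2 * tau
        arr = draws[draws <= cutoff]
        cen = np.full((draws > cutoff).sum(), cutoff)
        fit = fit_decay(arr, cen)
        assert abs(fit.tau_fs - tau) < 3 * fit.se_fs

        def nll(t):
            return len(arr) * np.log(t) + arr.sum() / t + cen.sum() / t

        res = minimize_scalar(nll, bounds=(1.0, 1000.0), method="bounded")
        assert fit.tau_fs == pytest.approx(res.x, rel=1e-4)

    def test_curve_lsq_agrees_with_mle(self):
        rng = np.random.default_rng(3)
        tau = 80.0
        arr = rng.exponential(tau, size=5000)
        mle = fit_decay(arr)
        lsq = fit_decay(arr, method="curve-LSQ")
        assert abs(mle.tau_fs - lsq.tau_fs) < 3 * np.hypot(mle.se_fs, max(lsq.se_fs, 1.0))

    def test_no_arrivals_rejected(self):
        with pytest.raises(UndefinedDecayError):
            fit_decay(np.array([]), np.array([50.0, 60.0]))

    def test_histogram_integrates_to_event_count(self):
        rng = np.random.default_rng(5)
        arr = rng.exponential(70.0, size=500)
        hist = arrival_histogram(arr)
        assert hist["count"].sum() == 500


class TestReport:
    def test_report_on_synthetic_ensemble(self, small_ensemble):
        _, _, manifest, records = small_ensemble
        doc = ensemble_report(manifest, records=records)
        assert doc["n_trajectories"] == manifest.n_trajectories
        assert "censored_MLE" in doc["decay"]
        assert "curve_LSQ" in doc["decay"]
        assert doc["pt"] == "unavailable"
        fracs = doc["initial_state_fractions"]
        assert sum(fracs.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            ensemble_report(EnsembleManifest(tag="x", entries=[]))

    def test_missing_channels_marked(self):
        entries = [
            ManifestEntry("a", None, 1, 100.0, "gap"),
            ManifestEntry("b", None, 1, 120.0, "gap"),
        ]
        doc = ensemble_report(EnsembleManifest(tag="x", entries=entries))
        assert doc["patterns"] == "unavailable"
        assert doc["character_timeline"] == "unavailable"
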