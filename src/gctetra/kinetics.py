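"""Ensemble kinetics: adiabatic occupation curves and decay-constant fits.

The adiabatic occupation of state *m* at time *t* is the fraction of
trajectories whose active state is *m*; a trajectory that has terminated
(reached the ground state) contributes to the S0 channel from its
termination time onward, so the S0 occupation is nondecreasing and the
fractions sum to one on the whole grid.

Ground-state arrival times are modelled as exponential.  Two estimators of
the time constant are provided:

* ``censored-MLE`` (default): under right censoring the exponential MLE is
  ``tau_hat = (sum of all observed times, censored included) / n_uncensored``
  with standard error ``tau_hat / sqrt(n_uncensored)``;
* ``curve-LSQ``: least-squares fit of the S0 occupation curve against
  ``1 - exp(-(t - t0)/tau)`` with optional latency ``t0 >= 0`` (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from gctetra.errors import EmptyEnsembleError, UndefinedDecayError


@dataclass
class OccupationCurve:
    """Per-state trajectory fractions on a common time grid.

    ``fractions[:, 0]`` is the ground-state channel; column ``m`` is the
    adiabatic state ``m``.
    """

    times: np.ndarray           # (T,) fs
    fractions: np.ndarray       # (T, n_states)

    def as_frame(self) -> pd.DataFrame:
        cols = {"time_fs": self.times}
        for m in range(self.fractions.shape[1]):
            cols[f"S{m}"] = self.fractions[:, m]
        return pd.DataFrame(cols)


@dataclass
class DecayFit:
    tau_fs: float
    se_fs: float
    estimator: str              # "censored-MLE" | "curve-LSQ"
    n_events: int
    n_censored: int
    t0_fs: float = 0.0


def occupation_curves(records) -> OccupationCurve:
    """Occupation curve of an ensemble of TrajectoryRecords.

    The grid is the union of all classical steps up to the longest
    trajectory.  An unterminated trajectory keeps contributing its last
    active state to the end of its own grid and is held there (max-time
    trajectories are still formally in the excited manifold, so their final
    active state is extended; this keeps the fractions summing to one).
    """
    records = list(records)
    if not records:
        raise EmptyEnsembleError("occupation curve of an empty ensemble")
    grid = np.unique(np.concatenate([np.asarray(r.times) for r in records]))
    n_states = max(r.n_states for r in records)
    counts = np.zeros((len(grid), n_states))
    for r in records:
        term = r.terminated
        t_end = r.termination_time_fs
        idx = np.searchsorted(np.asarray(r.times), grid, side="right") - 1
        idx = np.clip(idx, 0, r.n_steps - 1)
        states = np.asarray(r.active)[idx]
        if term:
            states = np.where(grid >= t_end, 0, states)
        counts[np.arange(len(grid)), states] += 1.0
    return OccupationCurve(times=grid, fractions=counts / len(records))


def fit_decay(
    arrivals: np.ndarray,
    censored: np.ndarray | None = None,
    method: str = "censored-MLE",
    occupation: OccupationCurve | None = None,
    with_latency: bool = False,
) -> DecayFit:
    """Estimate the exponential decay constant of ground-state arrivals.

    ``arrivals`` are uncensored S0 arrival times (fs); ``censored`` are final
    times of trajectories that never reached S0.  ``curve-LSQ`` fits the S0
    occupation curve instead (built from the arrival/censoring times when
    ``occupation`` is not supplied).
    """
    arrivals = np.asarray(arrivals, dtype=float)
    censored = np.asarray([] if censored is None else censored, dtype=float)
    n_unc, n_cen = len(arrivals), len(censored)
    if method == "censored-MLE":
        if n_unc == 0:
            raise UndefinedDecayError("no uncensored arrivals: tau undefined")
        tau = float((arrivals.sum() + censored.sum()) / n_unc)
        return DecayFit(
            tau_fs=tau,
            se_fs=tau / np.sqrt(n_unc),
            estimator="censored-MLE",
            n_events=n_unc,
            n_censored=n_cen,
        )
    if method == "curve-LSQ":
        if occupation is None:
            n = n_unc + n_cen
            if n == 0:
                raise UndefinedDecayError("no trajectories to fit")
            grid = np.unique(np.concatenate([[0.0], arrivals, censored]))
            frac = np.array([(arrivals <= t).sum() / n for t in grid])
            times, s0 = grid, frac
        else:
            times, s0 = occupation.times, occupation.fractions[:, 0]
        if len(times) < 5:
            raise UndefinedDecayError("need at least 5 grid points for curve fitting")
        tau0 = max(float(np.trapezoid(1.0 - s0, times)), 1e-3)
        if with_latency:
            def model(t, tau, t0):
                return np.where(t > t0, 1.0 - np.exp(-(t - t0) / tau), 0.0)

            popt, pcov = curve_fit(
                model, times, s0, p0=[tau0, 0.0],
                bounds=([1e-6, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
            tau, t0 = float(popt[0]), float(popt[1])
            se = float(np.sqrt(pcov[0, 0]))
        else:
            def model(t, tau):
                return 1.0 - np.exp(-t / tau)

            popt, pcov = curve_fit(
                model, times, s0, p0=[tau0], bounds=([1e-6], [np.inf]), maxfev=10000
            )
            tau, t0 = float(popt[0]), 0.0
            se = float(np.sqrt(pcov[0, 0]))
        return DecayFit(
            tau_fs=tau, se_fs=se, estimator="curve-LSQ",
            n_events=n_unc, n_censored=n_cen, t0_fs=t0,
        )
    raise ValueError(f"unknown estimator {method!r}")


def arrival_histogram(arrivals: np.ndarray, bin_width_fs: float = 25.0) -> pd.DataFrame:
    """Histogram of ground-state arrival times; counts sum to n_uncensored."""
    arrivals = np.asarray(arrivals, dtype=float)
    if len(arrivals) == 0:
        return pd.DataFrame(columns=["t_lo_fs", "t_hi_fs", "count"])
    hi = np.ceil(arrivals.max() / bin_width_fs) * bin_width_fs
    edges = np.arange(0.0, hi + bin_width_fs, bin_width_fs)
    counts, edges = np.histogram(arrivals, bins=edges)
    return pd.DataFrame(
        {"t_lo_fs": edges[:-1], "t_hi_fs": edges[1:], "count": counts}
    )


def ensemble_report(
    manifest,
    records=None,
    pt_summary: dict | None = None,
    pattern_table: pd.DataFrame | None = None,
    strand_table: pd.DataFrame | None = None,
    character_counts: pd.DataFrame | None = None,
) -> dict:
    """Consolidated machine-readable summary of all analysis stages.

    Sections whose inputs are unavailable are marked with an explicit
    ``"unavailable"`` marker rather than omitted silently.
    """
    if manifest.n_trajectories == 0:
        raise EmptyEnsembleError("cannot report on an empty ensemble")
    arrivals, censored = manifest.arrival_times()
    report: dict = {
        "sequence_tag": manifest.tag,
        "n_trajectories": manifest.n_trajectories,
        "n_reached_ground": int(len(arrivals)),
        "initial_state_fractions": {},
        "decay": {},
        "pt": "unavailable",
        "patterns": "unavailable",
        "strand_character": "unavailable",
        "character_timeline": "unavailable",
    }
    states = [e.initial_state for e in manifest.entries if e.initial_state is not None]
    for s in sorted(set(states)):
        report["initial_state_fractions"][f"S{s}"] = states.count(s) / len(states)
    if len(arrivals):
        mle = fit_decay(arrivals, censored, method="censored-MLE")
        report["decay"]["censored_MLE"] = {
            "tau_fs": mle.tau_fs, "se_fs": mle.se_fs,
            "n_events": mle.n_events, "n_censored": mle.n_censored,
        }
        occ = occupation_curves(records) if records is not None else None
        try:
            lsq = fit_decay(arrivals, censored, method="curve-LSQ", occupation=occ)
            report["decay"]["curve_LSQ"] = {
                "tau_fs": lsq.tau_fs, "se_fs": lsq.se_fs,
                "n_events": lsq.n_events, "n_censored": lsq.n_censored,
            }
        except UndefinedDecayError as exc:
            report["decay"]["curve_LSQ"] = f"unavailable: {exc}"
        report["arrival_histogram"] = arrival_histogram(arrivals).to_dict("list")
    if pt_summary is not None:
        report["pt"] = {
            k: v for k, v in pt_summary.items() if k != "scatter"
        }
    if pattern_table is not None:
        report["patterns"] = pattern_table.to_dict("records")
    if strand_table is not None:
        report["strand_character"] = strand_table.to_dict("records")
    if character_counts is not None:
        report["character_timeline"] = character_counts.to_dict("records")
    return report
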