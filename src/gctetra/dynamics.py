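"""DC-FSSH propagation and synthetic-ensemble generation.

Public operations:

* :func:`sample_wigner` — ground-state harmonic Wigner sampling of
  mass-weighted coordinates and momenta;
* :func:`select_initial_states` — excitation-window selection of initial
  excited states in proportion to the oscillator-strength proxies;
* :func:`tdba_coupling`, :func:`edc_damping` — the Baeck-An coupling
  estimate and the energy-based decoherence damping factor (unit-testable
  building blocks of the kernel);
* :func:`propagate_trajectory` — one surface-hopping trajectory;
* :func:`emit_observables` — map an adiabatic composition to the
  analysis-facing geometry frame, Omega matrices and NTO weights;
* :func:`run_ensemble` — full ensemble with manifest and ground-truth logs.
"""

from __future__ import annotations

import warnings

import numpy as np

from gctetra import _kernels
from gctetra.classify import Thresholds, classify_state, sampling_times
from gctetra.errors import (
    EmptyEnsembleError,
    IntegrationFailure,
    InvalidCompositionError,
    InvalidModelError,
)
from gctetra.model import DiabaticModel, SimConfig
from gctetra.records import (
    EnsembleManifest,
    HopEvent,
    ManifestEntry,
    PhaseSpaceSample,
    TrajectoryRecord,
)
from gctetra.units import HBAR


def sample_wigner(model: DiabaticModel, n: int, seed: int) -> list[PhaseSpaceSample]:
    """Draw ``n`` phase-space points from the ground-state Wigner density.

    Each mode is sampled independently: ``x ~ N(0, sqrt(hbar/(2 omega)))``
    and ``p ~ N(0, sqrt(hbar omega / 2))`` in mass-weighted units.  Vertical
    excitation energies and strength proxies are evaluated at every point.
    """
    omegas = model.omegas
    if np.any(omegas <= 0):
        raise InvalidModelError("all mode frequencies must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5737]))
    sx = np.sqrt(HBAR / (2.0 * omegas))
    sp = np.sqrt(HBAR * omegas / 2.0)
    out = []
    f_conf = model.strengths
    for _ in range(n):
        x = rng.normal(0.0, sx)
        p = rng.normal(0.0, sp)
        E, U = model.adiabatic(x)
        vert = E[1:] - E[0]
        strength = (U[:, 1:] ** 2).T @ f_conf
        out.append(PhaseSpaceSample(x=x, p=p, energies=vert, strengths=strength))
    return out


def select_initial_states(
    samples: list[PhaseSpaceSample],
    center: float,
    half_width: float,
    seed: int,
) -> list[PhaseSpaceSample]:
    """Assign initial excited states inside the excitation window.

    For each sample, states with vertical energy in ``[center - half_width,
    center + half_width]`` are eligible; one is drawn with probability
    proportional to its strength proxy.  Samples with no eligible state (or
    all-zero strengths in the window) are dropped.
    """
    if center <= 0 or half_width <= 0:
        raise InvalidModelError("window center and half-width must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5e1e]))
    kept: list[PhaseSpaceSample] = []
    for s in samples:
        in_win = np.abs(s.energies - center) <= half_width
        w = np.where(in_win, s.strengths, 0.0)
        tot = w.sum()
        if tot <= 0:
            continue
        state = int(rng.choice(len(w), p=w / tot)) + 1
        s.initial_state = state
        kept.append(s)
    if samples and not kept:
        warnings.warn("excitation window selected no initial conditions", stacklevel=2)
    return kept


def tdba_coupling(gap_now: float, gap_prev: float, gap_prev2: float, dt: float) -> float:
    """Baeck-An coupling magnitude (1/fs) from the three most recent gaps.

    Returns ``0.5*sqrt(gap''/gap)`` with the curvature from the 3-point
    backward difference; 0 when the curvature-to-gap ratio is nonpositive.
    A nonpositive current gap flags near-degeneracy (the termination rule,
    not the coupling, handles true crossings) and also returns 0.
    """
    if dt <= 0:
        raise InvalidModelError("dt must be positive")
    if gap_now <= 0:
        warnings.warn("nonpositive gap: near-degeneracy flagged, coupling set to 0", stacklevel=2)
        return 0.0
    return float(_kernels.tdba_sigma(gap_now, gap_prev, gap_prev2, dt))


def edc_damping(
    state_energy: float,
    active_energy: float,
    kinetic_energy: float,
    dt: float,
    alpha: float,
    hbar: float = HBAR,
) -> float:
    """Energy-based decoherence damping factor in (0, 1].

    ``tau = hbar/|dE| * (1 + alpha/E_kin)``; returns ``exp(-dt/tau)``.
    Degenerate states (``dE == 0``) are not damped.
    """
    if kinetic_energy <= 0:
        raise InvalidModelError("kinetic energy must be positive")
    de = abs(state_energy - active_energy)
    if de == 0.0:
        return 1.0
    tau = hbar / de * (1.0 + alpha / kinetic_energy)
    return float(np.exp(-dt / tau))


def _hole_electron_indicator(model: DiabaticModel) -> np.ndarray:
    """(C, F, F) indicator: config d -> one-hot at (hole, electron)."""
    F = model.topology.n_fragments
    T = np.zeros((model.n_configs, F, F))
    for d, cfg in enumerate(model.configs):
        if cfg.hole is not None:
            T[d, cfg.hole - 1, cfg.electron - 1] = 1.0
    return T


def emit_observables(
    model: DiabaticModel,
    composition: np.ndarray,
    coordinates: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analysis-facing observables from one adiabatic composition table.

    ``composition`` holds normalized eigenvectors (diabatic basis) of the
    excited states as columns, shape (C, n_exc).  Returns the geometry
    frame, the per-state Omega matrices ``Omega_AB(m) = sum_{d: h=A,e=B}
    |U_dm|^2`` and the per-state NTO weight lists (per-configuration
    squared amplitudes, descending).
    """
    comp = np.asarray(composition, dtype=float)
    norms = (comp ** 2).sum(axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise InvalidCompositionError("composition columns must be normalized eigenvectors")
    T = _hole_electron_indicator(model)
    u2 = comp ** 2                                   # (C, n_exc)
    omega = np.einsum("dm,dij->mij", u2, T)
    nto = np.sort(u2[1:, :].T, axis=1)[:, ::-1]      # exclude the ground config
    frame = model.geometry_frame(np.asarray(coordinates))
    return frame, omega, nto


def _proton_truth(model: DiabaticModel, times: np.ndarray, x_traj: np.ndarray) -> dict:
    """Ground-truth proton-coordinate crossings and final custody per bond."""
    crossings = []
    permanent: dict[str, bool] = {}
    for hb in model.hbonds:
        r = x_traj[:, hb.mode_index]
        # H within 1.1 A of the donor again <=> d0 + gain*r <= 1.1
        r_rev = (1.1 - hb.donor_h_eq_A) / hb.gain
        on_donor = True
        for i in range(len(r)):
            if on_donor and r[i] >= hb.r_star:
                crossings.append(
                    {"bond_id": hb.bond_id, "label": hb.label,
                     "time_fs": float(times[i]), "reverse": False}
                )
                on_donor = False
            elif not on_donor and r[i] <= r_rev:
                crossings.append(
                    {"bond_id": hb.bond_id, "label": hb.label,
                     "time_fs": float(times[i]), "reverse": True}
                )
                on_donor = True
        # permanent <=> the last event was a forward transfer and the H still
        # satisfies the 1.1 A acceptor criterion at the final frame
        final_acc_dist = hb.donor_acceptor_A - (hb.donor_h_eq_A + hb.gain * r[-1])
        permanent[hb.bond_id] = bool((not on_donor) and final_acc_dist <= 1.1)
    return {"crossings": crossings, "permanent_by_bond": permanent}


def propagate_trajectory(
    model: DiabaticModel,
    sample: PhaseSpaceSample,
    config: SimConfig,
    trajectory_id: str = "traj",
    seed: int | None = None,
    drift_tolerance_ev: float = 1.5,
    with_truth: bool = True,
) -> TrajectoryRecord:
    """Propagate one DC-FSSH trajectory from a selected phase-space sample."""
    if sample.initial_state is None or sample.initial_state < 1:
        raise InvalidModelError("sample must carry an excited initial state")
    seed = config.seed if seed is None else seed
    max_steps = int(round(config.max_time_fs / config.dt_fs))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF55]))
    uniforms = rng.random(max_steps)
    n, reason, E, act, x_traj, ucomp, pops, etot, hop_log = _kernels.propagate_kernel(
        model.epsilons,
        model.kappas,
        model.omegas ** 2,
        model.coupling,
        np.asarray(sample.x, dtype=float),
        np.asarray(sample.p, dtype=float),
        int(sample.initial_state),
        config.dt_fs,
        config.n_substeps,
        HBAR,
        config.alpha_ev,
        config.termination_gap_ev,
        max_steps,
        config.frustrated_hop_policy == "reject-invert",
        uniforms,
    )
    times = np.arange(n) * config.dt_fs
    hops = [
        HopEvent(
            time_fs=float(row[0] * config.dt_fs),
            from_state=int(row[1]),
            to_state=int(row[2]),
            accepted=row[3] == 1.0,
            kind="reassignment" if row[3] == 2.0 else "hop",
        )
        for row in hop_log
    ]
    # energy-drift guard between accepted hops
    seg_bounds = [0] + [int(row[0]) for row in hop_log if row[3] == 1.0] + [n - 1]
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if b > a + 1:
            seg = etot[a + 1 : b + 1]
            drift = np.max(np.abs(seg - seg[0]))
            if drift > drift_tolerance_ev:
                step_at = a + 1 + int(np.argmax(np.abs(seg - seg[0])))
                raise IntegrationFailure(
                    f"{trajectory_id}: total-energy drift {drift:.2e} eV at step {step_at}"
                )
    # observables
    T = _hole_electron_indicator(model)
    omega = np.einsum("tdm,dij->tmij", ucomp, T)
    nto = np.sort(ucomp[:, 1:, :].transpose(0, 2, 1), axis=2)[:, :, ::-1]
    geometry = None
    elements = None
    if model.hbonds:
        geometry = np.stack([model.geometry_frame(x_traj[i]) for i in range(n)])
        elements = model.elements
    truth = None
    if with_truth:
        truth = _proton_truth(model, times, x_traj) if model.hbonds else {}
        truth["hop_energy_balance"] = [
            [float(row[4]), float(row[5])] for row in hop_log if row[3] == 1.0
        ]
        truth["etot_drift_ev"] = float(np.max(np.abs(etot - etot[0]))) if n > 1 else 0.0
    rec = TrajectoryRecord(
        trajectory_id=trajectory_id,
        times=times,
        energies=E,
        active=act.astype(int),
        termination_time_fs=float(times[-1]),
        termination_reason="gap" if reason == _kernels.REASON_GAP else "max-time",
        hops=hops,
        populations=pops,
        total_energy=etot,
        geometry=geometry,
        elements=elements,
        omega=omega,
        nto=nto,
        ground_truth=truth,
        seed=seed,
        initial_state=int(sample.initial_state),
    )
    if with_truth and truth is not None:
        truth["character_timeline"] = _truth_timeline(rec)
    return rec


def _truth_timeline(rec: TrajectoryRecord) -> list[dict]:
    """Generator-side character labels at the analysis cadence."""
    th = Thresholds()
    out = []
    for ts in sampling_times(rec.final_time_fs):
        i = int(np.argmin(np.abs(rec.times - ts)))
        d = rec.descriptors_at(i)
        out.append({"time_fs": float(ts), "label": classify_state(d, th)})
    return out


def run_ensemble(
    model: DiabaticModel,
    config: SimConfig,
    out=None,
    overwrite: bool = False,
) -> tuple[EnsembleManifest, list[TrajectoryRecord]]:
    """Generate a full synthetic ensemble (sampling, selection, propagation).

    Returns the manifest and the trajectory records; when ``out`` is given
    the ensemble is also written to disk in the standard layout.  Bitwise
    reproducible for a fixed config seed.
    """
    n = config.ensemble_size
    tag = model.meta.get("tag", model.topology.tag)
    manifest = EnsembleManifest(tag=tag, entries=[])
    records: list[TrajectoryRecord] = []
    if n > 0:
        oversample = max(3 * n, n + 20)
        samples = sample_wigner(model, oversample, seed=config.seed)
        selected = select_initial_states(
            samples, config.window_center_ev, config.window_halfwidth_ev, seed=config.seed
        )
        if len(selected) < n:
            raise EmptyEnsembleError(
                f"only {len(selected)} of {oversample} samples fall in the excitation window"
            )
        ss = np.random.SeedSequence([config.seed, 0xE25])
        traj_seeds = ss.generate_state(n) % (2**31 - 1)
        for i in range(n):
            tid = f"traj_{i:04d}"
            rec = propagate_trajectory(
                model, selected[i], config, trajectory_id=tid, seed=int(traj_seeds[i])
            )
            records.append(rec)
            manifest.entries.append(
                ManifestEntry(
                    trajectory_id=tid,
                    seed=int(traj_seeds[i]),
                    initial_state=rec.initial_state,
                    termination_time_fs=rec.termination_time_fs,
                    termination_reason=rec.termination_reason,
                    path=tid,
                )
            )
    if out is not None:
        from gctetra.io import write_ensemble

        write_ensemble(manifest, records, out, overwrite=overwrite)
    return manifest, records


def run_mixture_ensemble(
    models: list[DiabaticModel],
    weights,
    config: SimConfig,
) -> tuple[EnsembleManifest, list[TrajectoryRecord]]:
    """Ensemble with a configured route mixture.

    Each trajectory draws one model from ``models`` with probability
    proportional to ``weights`` (e.g. single-route models from
    :func:`gctetra.model.single_route_model`), then samples its own initial
    condition and propagates.  The drawn route index and the model's route
    metadata are logged in the trajectory ground truth, so recovery of the
    configured mixture by the analysis stages can be checked against the
    multinomial draw.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(models) or np.any(weights < 0) or weights.sum() <= 0:
        raise InvalidModelError("weights must be nonnegative and match the models")
    p = weights / weights.sum()
    n = config.ensemble_size
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x313]))
    draws = rng.choice(len(models), size=n, p=p)
    ss = np.random.SeedSequence([config.seed, 0xE25])
    traj_seeds = ss.generate_state(max(n, 1)) % (2**31 - 1)
    tag = models[0].meta.get("tag", models[0].topology.tag)
    manifest = EnsembleManifest(tag=tag, entries=[])
    records: list[TrajectoryRecord] = []
    for i in range(n):
        model = models[int(draws[i])]
        tid = f"traj_{i:04d}"
        sel: list[PhaseSpaceSample] = []
        attempt = 0
        while not sel and attempt < 20:
            samples = sample_wigner(model, 8, seed=int(traj_seeds[i]) + attempt)
            sel = select_initial_states(
                samples, config.window_center_ev, config.window_halfwidth_ev,
                seed=int(traj_seeds[i]) + attempt,
            )
            attempt += 1
        if not sel:
            raise EmptyEnsembleError(f"{tid}: no initial condition inside the window")
        rec = propagate_trajectory(
            model, sel[0], config, trajectory_id=tid, seed=int(traj_seeds[i])
        )
        if rec.ground_truth is not None:
            rec.ground_truth["configured_route"] = {
                "index": int(draws[i]),
                **model.meta.get("route", {}),
            }
        records.append(rec)
        manifest.entries.append(
            ManifestEntry(
                trajectory_id=tid,
                seed=int(traj_seeds[i]),
                initial_state=rec.initial_state,
                termination_time_fs=rec.termination_time_fs,
                termination_reason=rec.termination_reason,
                path=tid,
            )
        )
    return manifest, records
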