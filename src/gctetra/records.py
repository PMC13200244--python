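"""In-memory containers for surface-hopping trajectories and ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gctetra.descriptors import DescriptorSet, NTOWeights, OmegaMatrix, describe_state
from gctetra.errors import CapabilityError, MalformedTrajectoryError


@dataclass
class PhaseSpaceSample:
    """One Wigner-sampled phase-space point with vertical excitation data.

    ``x`` and ``p`` are mass-weighted coordinates/momenta; ``energies`` are
    the vertical excitation energies of the excited adiabatic states (eV,
    relative to the ground state at the same geometry) and ``strengths`` the
    corresponding oscillator-strength proxies.  ``initial_state`` (1-based
    excited-state index) is assigned by the excitation-window selection.
    """

    x: np.ndarray
    p: np.ndarray
    energies: np.ndarray
    strengths: np.ndarray
    initial_state: int | None = None


@dataclass
class HopEvent:
    """A hop attempt or a trivial-crossing index reassignment.

    ``kind`` is ``"hop"`` for fewest-switches attempts (``accepted`` tells
    whether the momentum rescale succeeded) or ``"reassignment"`` when the
    active-state index changed only because the energy ordering swapped at
    an unresolved crossing while the physical surface was followed.
    """

    time_fs: float
    from_state: int
    to_state: int
    accepted: bool
    kind: str = "hop"


@dataclass
class TrajectoryRecord:
    """One surface-hopping trajectory on the common analysis time grid.

    Adiabatic state 0 is the ground state (lowest at every step); the active
    state is always an excited state (1..n_exc).  Optional channels
    (``populations``, ``geometry``, ``omega``, ``nto``) are ``None`` when the
    source did not provide them; stages that need them raise
    :class:`~gctetra.errors.CapabilityError`.
    """

    trajectory_id: str
    times: np.ndarray                   # (n,) fs
    energies: np.ndarray                # (n, n_states) eV, ascending per step
    active: np.ndarray                  # (n,) adiabatic index of the active state
    termination_time_fs: float
    termination_reason: str             # "gap" | "max-time"
    hops: list[HopEvent] = field(default_factory=list)
    populations: np.ndarray | None = None   # (n, n_exc) |c|^2
    total_energy: np.ndarray | None = None  # (n,) kinetic + active potential, eV
    geometry: np.ndarray | None = None      # (n, n_atoms, 3) Å
    elements: tuple[str, ...] | None = None
    omega: np.ndarray | None = None         # (n, n_exc, F, F)
    nto: np.ndarray | None = None           # (n, n_exc, n_amp)
    ground_truth: dict | None = None
    seed: int | None = None
    initial_state: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.times)

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]

    @property
    def final_time_fs(self) -> float:
        return float(self.times[-1])

    @property
    def terminated(self) -> bool:
        return self.termination_reason == "gap"

    def descriptors_at(self, step: int, state: int | None = None) -> DescriptorSet:
        """Descriptor set of ``state`` (default: the active state) at a step."""
        if self.omega is None:
            raise CapabilityError(
                f"trajectory {self.trajectory_id}: transition-density channel unavailable"
            )
        s = int(self.active[step]) if state is None else state
        om = OmegaMatrix(self.omega[step, s - 1], state=s, time_fs=float(self.times[step]))
        lam = None
        if self.nto is not None:
            lams = self.nto[step, s - 1]
            if lams.sum() > 0:
                lam = NTOWeights(lams, state=s, time_fs=float(self.times[step]))
        return describe_state(om, lam)

    def validate(self) -> None:
        """Check structural invariants; raise MalformedTrajectoryError."""
        n = self.n_steps
        tid = self.trajectory_id
        if self.energies.shape[0] != n or self.active.shape[0] != n:
            raise MalformedTrajectoryError(f"{tid}: channel lengths disagree")
        if np.any(np.diff(self.energies, axis=1) < -1e-9):
            raise MalformedTrajectoryError(f"{tid}: state energies not ordered")
        if self.termination_time_fs > self.times[-1] + 1e-9:
            raise MalformedTrajectoryError(f"{tid}: termination time beyond the grid")
        hop_steps = {
            int(np.argmin(np.abs(self.times - h.time_fs)))
            for h in self.hops
            if h.accepted or h.kind == "reassignment"
        }
        changes = np.nonzero(np.diff(self.active))[0]
        for i in changes:
            if (i + 1) not in hop_steps and (i) not in hop_steps:
                raise MalformedTrajectoryError(
                    f"{tid}: active state changed at step {i + 1} without a logged hop"
                )
        if self.geometry is not None and self.geometry.shape[0] != n:
            raise MalformedTrajectoryError(f"{tid}: geometry frame count mismatch")
        if self.omega is not None and self.omega.shape[0] != n:
            raise MalformedTrajectoryError(f"{tid}: omega frame count mismatch")


@dataclass
class ManifestEntry:
    trajectory_id: str
    seed: int | None
    initial_state: int | None
    termination_time_fs: float
    termination_reason: str
    path: str | None = None


@dataclass
class EnsembleManifest:
    """Index of an ensemble: the unit over which all statistics are taken."""

    tag: str
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.trajectory_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise MalformedTrajectoryError("duplicate trajectory ids in manifest")

    @property
    def n_trajectories(self) -> int:
        return len(self.entries)

    def arrival_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(uncensored ground-state arrival times, censored final times) in fs."""
        arr = [e.termination_time_fs for e in self.entries if e.termination_reason == "gap"]
        cen = [e.termination_time_fs for e in self.entries if e.termination_reason != "gap"]
        return np.asarray(arr, dtype=float), np.asarray(cen, dtype=float)
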