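"""Proton-transfer event detection on Watson-Crick hydrogen bonds.

A transfer event is recorded at the first frame where the hydrogen reaches
X–H ≤ 1.1 Å on the opposite base (X = N or O of the Watson-Crick pair).
Hydrogen custody follows a two-sided state machine: the H initially belongs
to the donor; once the acceptor-side criterion is met the H is reassigned to
the acceptor, so a later return within 1.1 Å of the original donor is a new
event in the reverse direction.  Three bond types are distinguished:

* ``NN_central``        — guanine N1 -> cytosine N3 (central bond);
* ``NO_amino_carbonyl`` — guanine amino N2 -> cytosine carbonyl O2;
* ``CG_reverse``        — cytosine amino N4 -> guanine O6.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gctetra.errors import RegistryError, UndefinedPermanenceError
from gctetra.records import TrajectoryRecord

BOND_LABELS = ("NN_central", "NO_amino_carbonyl", "CG_reverse")
DEFAULT_THRESHOLD_A = 1.1


@dataclass(frozen=True)
class HBond:
    """One Watson-Crick hydrogen bond in the atom registry."""

    label: str
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    donor_fragment: int
    acceptor_fragment: int


@dataclass(frozen=True)
class HBondRegistry:
    bonds: tuple[HBond, ...]

    def validate(self, n_atoms: int, elements=None) -> None:
        for b in self.bonds:
            for idx in (b.donor_atom, b.hydrogen_atom, b.acceptor_atom):
                if not 0 <= idx < n_atoms:
                    raise RegistryError(f"bond {b.label}: atom index {idx} out of range")
            if elements is not None:
                if elements[b.donor_atom] not in ("N", "O"):
                    raise RegistryError(f"bond {b.label}: donor must be N or O")
                if elements[b.acceptor_atom] not in ("N", "O"):
                    raise RegistryError(f"bond {b.label}: acceptor must be N or O")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HBondRegistry":
        data = yaml.safe_load(Path(path).read_text())
        return cls(bonds=tuple(HBond(**b) for b in data["bonds"]))

    def to_yaml(self, path: str | Path) -> None:
        data = {"bonds": [vars(b) for b in self.bonds]}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class PTEvent:
    """One detected proton-transfer crossing."""

    trajectory_id: str
    bond_label: str
    time_fs: float
    donor_fragment: int      # fragment the H left in this event
    acceptor_fragment: int   # fragment the H arrived on
    reverse: bool            # True when the H returned to its original base
    final_time_fs: float
    permanent: bool | None = None


def detect_pt_events(
    traj: TrajectoryRecord,
    registry: HBondRegistry,
    threshold: float = DEFAULT_THRESHOLD_A,
) -> list[PTEvent]:
    """Detect all transfer events of a trajectory, in time order per bond.

    Multiple events per bond are allowed; forward and reverse events
    alternate by construction of the custody state machine.
    """
    if traj.geometry is None:
        from gctetra.errors import CapabilityError

        raise CapabilityError(
            f"trajectory {traj.trajectory_id}: no geometry channel; PT detection unavailable"
        )
    geom = traj.geometry
    registry.validate(geom.shape[1], traj.elements)
    events: list[PTEvent] = []
    tf = traj.final_time_fs
    for bond in registry.bonds:
        h = geom[:, bond.hydrogen_atom]
        d_don = np.linalg.norm(h - geom[:, bond.donor_atom], axis=1)
        d_acc = np.linalg.norm(h - geom[:, bond.acceptor_atom], axis=1)
        on_donor_side = True
        for i in range(traj.n_steps):
            if on_donor_side and d_acc[i] <= threshold:
                events.append(
                    PTEvent(
                        trajectory_id=traj.trajectory_id,
                        bond_label=bond.label,
                        time_fs=float(traj.times[i]),
                        donor_fragment=bond.donor_fragment,
                        acceptor_fragment=bond.acceptor_fragment,
                        reverse=False,
                        final_time_fs=tf,
                    )
                )
                on_donor_side = False
            elif not on_donor_side and d_don[i] <= threshold:
                events.append(
                    PTEvent(
                        trajectory_id=traj.trajectory_id,
                        bond_label=bond.label,
                        time_fs=float(traj.times[i]),
                        donor_fragment=bond.acceptor_fragment,
                        acceptor_fragment=bond.donor_fragment,
                        reverse=True,
                        final_time_fs=tf,
                    )
                )
                on_donor_side = True
    events.sort(key=lambda e: (e.time_fs, e.bond_label))
    return events


def classify_permanence(
    events: list[PTEvent],
    traj: TrajectoryRecord,
    registry: HBondRegistry,
    threshold: float = DEFAULT_THRESHOLD_A,
) -> list[PTEvent]:
    """Flag each event permanent iff its target side still holds the H at the end.

    Permanence is only defined once the trajectory has terminated (reached
    the ground state).  An event is permanent when, at the final frame, the
    transferred hydrogen satisfies the ≤ threshold criterion with respect to
    the acceptor side of that event's direction.
    """
    if not traj.terminated:
        raise UndefinedPermanenceError(
            f"trajectory {traj.trajectory_id} did not terminate; permanence undefined"
        )
    by_key = {(b.label, b.donor_fragment, b.acceptor_fragment): b for b in registry.bonds}
    geom_last = traj.geometry[-1]
    out = []
    for ev in events:
        if ev.reverse:
            bond = by_key[(ev.bond_label, ev.acceptor_fragment, ev.donor_fragment)]
        else:
            bond = by_key[(ev.bond_label, ev.donor_fragment, ev.acceptor_fragment)]
        h = geom_last[bond.hydrogen_atom]
        target_atom = bond.donor_atom if ev.reverse else bond.acceptor_atom
        dist = float(np.linalg.norm(h - geom_last[target_atom]))
        out.append(replace(ev, permanent=dist <= threshold))
    return out


def has_permanent_pt(events: list[PTEvent]) -> bool:
    """A trajectory has a permanent PT iff any forward event is permanent.

    A permanent *reverse* event means the proton ended up back on its
    original base, which is exactly the no-permanent-transfer outcome.
    """
    return any(ev.permanent and not ev.reverse for ev in events)


def pt_statistics(
    events_by_traj: dict[str, list[PTEvent]],
    diagonal_window_fs: float = 50.0,
) -> dict:
    """Ensemble-level PT summary for one sequence tag.

    Percentages are per trajectory: a trajectory counts once for each bond
    type it exhibits (forward events only).  Also returns the PT-time vs
    final-time scatter table and the fraction of forward events within
    ``diagonal_window_fs`` of the trajectory's final time.
    """
    n_traj = len(events_by_traj)
    summary: dict = {
        "n_trajectories": n_traj,
        "bond_type_pct": {},
        "n_no_permanent_pt": 0,
        "diagonal_fraction": None,
        "scatter": None,
    }
    if n_traj == 0:
        import warnings

        warnings.warn("empty ensemble: PT summary is empty", stacklevel=2)
        return summary
    for label in BOND_LABELS:
        n_with = sum(
            any(ev.bond_label == label and not ev.reverse for ev in evs)
            for evs in events_by_traj.values()
        )
        summary["bond_type_pct"][label] = 100.0 * n_with / n_traj
    summary["n_no_permanent_pt"] = sum(
        not has_permanent_pt(evs) for evs in events_by_traj.values()
    )
    rows = [
        {
            "trajectory_id": ev.trajectory_id,
            "bond_label": ev.bond_label,
            "time_fs": ev.time_fs,
            "final_time_fs": ev.final_time_fs,
            "reverse": ev.reverse,
            "permanent": ev.permanent,
        }
        for evs in events_by_traj.values()
        for ev in evs
    ]
    scatter = pd.DataFrame(
        rows,
        columns=["trajectory_id", "bond_label", "time_fs", "final_time_fs", "reverse", "permanent"],
    )
    summary["scatter"] = scatter
    fwd = scatter[~scatter["reverse"]]
    if len(fwd):
        close = (fwd["final_time_fs"] - fwd["time_fs"]).abs() <= diagonal_window_fs
        summary["diagonal_fraction"] = float(close.mean())
    return summary
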