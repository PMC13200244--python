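"""On-disk ensemble layout and the external-dialect adapter.

Standard layout (one directory per ensemble)::

    out/
      manifest.json               # sequence tag + per-trajectory index
      traj_0000/
        geometry.xyz              # multi-frame XYZ (atom count / comment / rows)
        states.csv                # time_fs, E0_eV..EN_eV, active_state, pop_S*
        omega.json                # per step, per excited state: F x F matrix + NTO weights
        hops.csv                  # time_fs, from_state, to_state, accepted
        truth.json                # generator ground-truth log (when present)

Floats are serialized at full precision (shortest round-trip repr), so a
write/read cycle is the identity on every typed field.  Trajectories are
loaded lazily so large ensembles stream on modest memory.  Units on disk
are fs / eV / Å throughout; converters are applied only at the external
dialect boundary.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gctetra.errors import (
    DialectConfigError,
    GCTetraError,
    MalformedTrajectoryError,
    MissingFileError,
)
from gctetra.records import EnsembleManifest, HopEvent, ManifestEntry, TrajectoryRecord

FORMAT_TAG = "gctetra-ensemble-1"
AU_TIME_FS = 0.02418884254
AU_ENERGY_EV = 27.211386245988


def _fmt(v: float) -> str:
    return repr(float(v))


# ---------------------------------------------------------------------------
# multi-frame XYZ
# ---------------------------------------------------------------------------

def write_xyz(path: Path, elements, frames: np.ndarray, times_fs: np.ndarray) -> None:
    n_atoms = frames.shape[1]
    lines = []
    for t, frame in zip(times_fs, frames):
        lines.append(str(n_atoms))
        lines.append(f"t= {_fmt(t)} fs")
        for el, (xx, yy, zz) in zip(elements, frame):
            lines.append(f"{el} {_fmt(xx)} {_fmt(yy)} {_fmt(zz)}")
    path.write_text("\n".join(lines) + "\n")


def read_xyz(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a multi-frame XYZ file; returns (elements, frames (T, N, 3))."""
    lines = path.read_text().splitlines()
    frames = []
    elements: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise MalformedTrajectoryError(f"{path}: bad atom-count line {i + 1}") from exc
        if i + 1 >= len(lines):
            raise MalformedTrajectoryError(f"{path}: truncated frame at line {i + 1}")
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise MalformedTrajectoryError(f"{path}: truncated frame at line {i + 1}")
        frame = np.empty((n_atoms, 3))
        els = []
        for a, row in enumerate(block):
            parts = row.split()
            if len(parts) != 4:
                raise MalformedTrajectoryError(f"{path}: malformed atom row at line {i + 3 + a}")
            els.append(parts[0])
            frame[a] = [float(p) for p in parts[1:]]
        if not elements:
            elements = els
        elif els != elements:
            raise MalformedTrajectoryError(f"{path}: element order changes between frames")
        frames.append(frame)
        i += 2 + n_atoms
    if not frames:
        raise MalformedTrajectoryError(f"{path}: no frames")
    return tuple(elements), np.stack(frames)


# ---------------------------------------------------------------------------
# standard layout
# ---------------------------------------------------------------------------

def _write_record(rec: TrajectoryRecord, tdir: Path) -> None:
    tdir.mkdir(parents=True, exist_ok=True)
    n_states = rec.n_states
    cols: dict[str, np.ndarray] = {"time_fs": rec.times}
    for m in range(n_states):
        cols[f"E{m}_eV"] = rec.energies[:, m]
    cols["active_state"] = rec.active
    if rec.populations is not None:
        for j in range(rec.populations.shape[1]):
            cols[f"pop_S{j + 1}"] = rec.populations[:, j]
    if rec.total_energy is not None:
        cols["Etot_eV"] = rec.total_energy
    pd.DataFrame(cols).to_csv(tdir / "states.csv", index=False, float_format="%.17g")
    hops = pd.DataFrame(
        [
            {
                "time_fs": h.time_fs,
                "from_state": h.from_state,
                "to_state": h.to_state,
                "accepted": int(h.accepted),
                "kind": h.kind,
            }
            for h in rec.hops
        ],
        columns=["time_fs", "from_state", "to_state", "accepted", "kind"],
    )
    hops.to_csv(tdir / "hops.csv", index=False, float_format="%.17g")
    if rec.geometry is not None:
        write_xyz(tdir / "geometry.xyz", rec.elements, rec.geometry, rec.times)
    if rec.omega is not None:
        payload = {
            "states": list(range(1, rec.omega.shape[1] + 1)),
            "omega": rec.omega.tolist(),
            "nto": rec.nto.tolist() if rec.nto is not None else None,
        }
        (tdir / "omega.json").write_text(json.dumps(payload))
    if rec.ground_truth is not None:
        (tdir / "truth.json").write_text(json.dumps(rec.ground_truth, sort_keys=True))


def write_ensemble(
    manifest: EnsembleManifest,
    records: Sequence[TrajectoryRecord],
    out: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write an ensemble in the standard layout; idempotent for equal input."""
    out = Path(out)
    ids = {e.trajectory_id for e in manifest.entries}
    if {r.trajectory_id for r in records} != ids:
        raise GCTetraError("records do not match manifest ids")
    mpath = out / "manifest.json"
    if mpath.exists() and not overwrite:
        raise GCTetraError(f"{mpath} exists; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    by_id = {r.trajectory_id: r for r in records}
    entries = []
    for e in manifest.entries:
        path = e.path or e.trajectory_id
        _write_record(by_id[e.trajectory_id], out / path)
        entries.append(
            {
                "id": e.trajectory_id,
                "seed": e.seed,
                "initial_state": e.initial_state,
                "termination_time_fs": e.termination_time_fs,
                "termination_reason": e.termination_reason,
                "path": path,
            }
        )
    doc = {"format": FORMAT_TAG, "sequence_tag": manifest.tag, "trajectories": entries}
    mpath.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return out


def _read_record(entry: ManifestEntry, tdir: Path) -> TrajectoryRecord:
    tid = entry.trajectory_id
    spath = tdir / "states.csv"
    if not spath.exists():
        raise MissingFileError(f"{tid}: missing {spath}")
    df = pd.read_csv(spath, float_precision="round_trip")
    e_cols = sorted(
        (c for c in df.columns if c.startswith("E") and c.endswith("_eV") and c[1:-3].isdigit()),
        key=lambda c: int(c[1:-3]),
    )
    pop_cols = sorted(
        (c for c in df.columns if c.startswith("pop_S")), key=lambda c: int(c[5:])
    )
    times = df["time_fs"].to_numpy()
    energies = df[e_cols].to_numpy()
    active = df["active_state"].to_numpy(dtype=int)
    populations = df[pop_cols].to_numpy() if pop_cols else None
    total_energy = df["Etot_eV"].to_numpy() if "Etot_eV" in df.columns else None
    hops = []
    hpath = tdir / "hops.csv"
    if hpath.exists():
        for _, row in pd.read_csv(hpath, float_precision="round_trip").iterrows():
            hops.append(
                HopEvent(
                    time_fs=float(row["time_fs"]),
                    from_state=int(row["from_state"]),
                    to_state=int(row["to_state"]),
                    accepted=bool(row["accepted"]),
                    kind=str(row.get("kind", "hop")),
                )
            )
    geometry = None
    elements = None
    gpath = tdir / "geometry.xyz"
    if gpath.exists():
        elements, geometry = read_xyz(gpath)
        if geometry.shape[0] != len(times):
            raise MalformedTrajectoryError(
                f"{tid}: {geometry.shape[0]} XYZ frames vs {len(times)} state rows"
            )
    omega = None
    nto = None
    opath = tdir / "omega.json"
    if opath.exists():
        payload = json.loads(opath.read_text())
        omega = np.asarray(payload["omega"], dtype=float)
        if payload.get("nto") is not None:
            nto = np.asarray(payload["nto"], dtype=float)
        if omega.shape[0] != len(times):
            raise MalformedTrajectoryError(
                f"{tid}: {omega.shape[0]} omega steps vs {len(times)} state rows"
            )
    truth = None
    tpath = tdir / "truth.json"
    if tpath.exists():
        truth = json.loads(tpath.read_text())
    rec = TrajectoryRecord(
        trajectory_id=tid,
        times=times,
        energies=energies,
        active=active,
        termination_time_fs=entry.termination_time_fs,
        termination_reason=entry.termination_reason,
        hops=hops,
        populations=populations,
        total_energy=total_energy,
        geometry=geometry,
        elements=elements,
        omega=omega,
        nto=nto,
        ground_truth=truth,
        seed=entry.seed,
        initial_state=entry.initial_state,
    )
    rec.validate()
    return rec


class LazyTrajectories(Sequence):
    """Sequence of TrajectoryRecords loaded from disk on access."""

    def __init__(self, root: Path, entries: list[ManifestEntry]):
        self._root = root
        self._entries = entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        e = self._entries[i]
        tdir = self._root / (e.path or e.trajectory_id)
        if not tdir.exists():
            raise MissingFileError(f"{e.trajectory_id}: missing directory {tdir}")
        return _read_record(e, tdir)


def read_ensemble(path: str | Path) -> tuple[EnsembleManifest, LazyTrajectories]:
    """Read an ensemble written by :func:`write_ensemble` (lazy records)."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise MissingFileError(f"no manifest.json under {root}")
    doc = json.loads(mpath.read_text())
    entries = [
        ManifestEntry(
            trajectory_id=t["id"],
            seed=t.get("seed"),
            initial_state=t.get("initial_state"),
            termination_time_fs=float(t["termination_time_fs"]),
            termination_reason=t["termination_reason"],
            path=t.get("path", t["id"]),
        )
        for t in doc["trajectories"]
    ]
    manifest = EnsembleManifest(tag=doc.get("sequence_tag", ""), entries=entries)
    return manifest, LazyTrajectories(root, entries)


# ---------------------------------------------------------------------------
# external dialect adapter
# ---------------------------------------------------------------------------

def read_external_dialect(
    path: str | Path, mapping: dict | str | Path
) -> tuple[EnsembleManifest, list[TrajectoryRecord]]:
    """Best-effort adapter for externally produced surface-hopping output.

    ``mapping`` (dict or YAML file) declares which files hold which roles::

        sequence_tag: nonalternating
        trajectory_glob: "TRAJ*"          # subdirectories, one per trajectory
        energies:
          file: energies.dat              # whitespace table
          time_column: 0
          state_columns: [1, 2, 3, 4]     # ground first
          active_column: 5
          time_unit: au | fs
          energy_unit: au | ev
        geometries:
          file: dyn.xyz                   # optional
        termination_reason: gap           # applied to every trajectory

    Channels absent from the archive (transition densities, NTO weights) are
    marked unavailable; downstream stages that need them raise a capability
    error instead of fabricating data.
    """
    root = Path(path)
    if not isinstance(mapping, dict):
        mapping = yaml.safe_load(Path(mapping).read_text())
    missing_roles = [k for k in ("trajectory_glob", "energies") if k not in mapping]
    if missing_roles:
        raise DialectConfigError(f"mapping leaves roles undeclared: {missing_roles}")
    emap = mapping["energies"]
    for key in ("file", "time_column", "state_columns", "active_column"):
        if key not in emap:
            raise DialectConfigError(f"energies mapping missing {key!r}")
    t_scale = AU_TIME_FS if emap.get("time_unit", "fs") == "au" else 1.0
    e_scale = AU_ENERGY_EV if emap.get("energy_unit", "ev") == "au" else 1.0
    reason = mapping.get("termination_reason", "gap")
    records: list[TrajectoryRecord] = []
    entries: list[ManifestEntry] = []
    for tdir in sorted(root.glob(mapping["trajectory_glob"])):
        tid = tdir.name
        epath = tdir / emap["file"]
        if not epath.exists():
            from gctetra.errors import CapabilityError

            raise CapabilityError(f"{tid}: energies file {epath} not found")
        try:
            table = np.loadtxt(epath, ndmin=2)
        except ValueError as exc:
            raise MalformedTrajectoryError(f"{tid}: cannot parse {epath}") from exc
        needed = [emap["time_column"], *emap["state_columns"], emap["active_column"]]
        if table.shape[1] <= max(needed):
            raise DialectConfigError(
                f"{tid}: {epath} has {table.shape[1]} columns, mapping needs {max(needed) + 1}"
            )
        times = table[:, emap["time_column"]] * t_scale
        energies = table[:, emap["state_columns"]] * e_scale
        active = table[:, emap["active_column"]].astype(int)
        geometry = None
        elements = None
        gmap = mapping.get("geometries")
        if gmap:
            gpath = tdir / gmap["file"]
            if gpath.exists():
                elements, geometry = read_xyz(gpath)
                if geometry.shape[0] != len(times):
                    raise MalformedTrajectoryError(
                        f"{tid}: geometry frame count mismatch in {gpath}"
                    )
        rec = TrajectoryRecord(
            trajectory_id=tid,
            times=times,
            energies=energies,
            active=active,
            termination_time_fs=float(times[-1]),
            termination_reason=reason,
            geometry=geometry,
            elements=elements,
        )
        records.append(rec)
        entries.append(
            ManifestEntry(
                trajectory_id=tid,
                seed=None,
                initial_state=int(active[0]) if len(active) else None,
                termination_time_fs=float(times[-1]),
                termination_reason=reason,
                path=tid,
            )
        )
    manifest = EnsembleManifest(tag=mapping.get("sequence_tag", "external"), entries=entries)
    return manifest, records
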