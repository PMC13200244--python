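"""Excited-state character classification in the CT/PR descriptor plane.

Five character classes partition the plane:

* ``local_excitation`` — CT ≤ 0.2 and PR ≤ 1.25 (electron and hole on one
  fragment);
* ``exciton``          — CT ≤ 0.2 and PR > 1.25 (coherent local excitations
  on several fragments);
* ``excimer``          — 0.2 < CT < 0.8 (mixed local/charge-transfer
  superposition);
* ``charge_resonance`` — CT ≥ 0.8 with PR > 1.75 or PR_NTO > 1.25
  (symmetric charge exchange, no net transfer);
* ``charge_transfer``  — CT ≥ 0.8 otherwise.

``timeline`` samples a trajectory's active state at the analysis cadence:
every 10 fs up to 50 fs, every 50 fs afterwards, plus the final step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gctetra.descriptors import DescriptorSet
from gctetra.errors import CapabilityError, InvalidModelError

LABELS = (
    "local_excitation",
    "exciton",
    "excimer",
    "charge_transfer",
    "charge_resonance",
)


@dataclass(frozen=True)
class Thresholds:
    """Descriptor-plane boundaries (config-overridable)."""

    ct_low: float = 0.2
    ct_high: float = 0.8
    pr_le: float = 1.25
    pr_cr: float = 1.75
    pr_nto: float = 1.25

    def __post_init__(self) -> None:
        if not (0.0 < self.ct_low < self.ct_high < 1.0):
            raise InvalidModelError("need 0 < ct_low < ct_high < 1")
        if not (1.0 < self.pr_le < self.pr_cr):
            raise InvalidModelError("need 1 < pr_le < pr_cr")


def classify_state(d: DescriptorSet, th: Thresholds = Thresholds()) -> str:
    """Map one descriptor set to exactly one character label.

    When the charge-resonance branch is reached without a PR_NTO value the
    decision falls back on PR alone (a warning notes the reduced evidence).
    """
    if d.ct <= th.ct_low:
        return "local_excitation" if d.pr <= th.pr_le else "exciton"
    if d.ct < th.ct_high:
        return "excimer"
    if d.pr_nto is None:
        warnings.warn(
            "PR_NTO unavailable: charge-resonance assignment based on PR alone",
            stacklevel=2,
        )
        return "charge_resonance" if d.pr > th.pr_cr else "charge_transfer"
    if d.pr > th.pr_cr or d.pr_nto > th.pr_nto:
        return "charge_resonance"
    return "charge_transfer"


def sampling_times(
    t_final: float,
    early_step: float = 10.0,
    switch: float = 50.0,
    late_step: float = 50.0,
) -> np.ndarray:
    """Analysis cadence: {0, 10, ..., 50, 100, 150, ...} ∪ {t_final}."""
    early = np.arange(0.0, min(switch, t_final) + 1e-9, early_step)
    late = np.arange(switch + late_step, t_final + 1e-9, late_step)
    ts = np.concatenate([early, late, [t_final]])
    return np.unique(np.round(ts, 9))


def timeline(
    traj,
    th: Thresholds = Thresholds(),
    early_step: float = 10.0,
    switch: float = 50.0,
    late_step: float = 50.0,
) -> pd.DataFrame:
    """Character timeline of a trajectory's active state at the cadence.

    Returns a DataFrame with columns ``time_fs, state, ct, pr, pr_nto,
    label``.  Sample times between recorded steps use the nearest step.
    """
    if traj.omega is None:
        raise CapabilityError(
            f"trajectory {traj.trajectory_id}: no transition-density channel; "
            "character timeline unavailable"
        )
    times = np.asarray(traj.times)
    rows = []
    for ts in sampling_times(float(times[-1]), early_step, switch, late_step):
        i = int(np.argmin(np.abs(times - ts)))
        d = traj.descriptors_at(i)
        rows.append(
            {
                "time_fs": ts,
                "state": int(traj.active[i]),
                "ct": d.ct,
                "pr": d.pr,
                "pr_nto": d.pr_nto,
                "label": classify_state(d, th),
            }
        )
    return pd.DataFrame(rows)
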