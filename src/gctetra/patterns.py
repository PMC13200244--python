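"""Joint proton/electron-transfer pattern classification.

Each proton-transfer event is joined with the electron/hole localization of
the active state at the event time (argmax of the fragment hole and electron
weights) and classified into:

* ``hat_paired``        — hole on the PT donor and electron on the PT
  acceptor: electron and proton leave the same base and arrive on the same
  base (net hydrogen-atom transfer / ESHT);
* ``shared_e_acceptor`` — electron on the PT acceptor, hole elsewhere: the
  cytosine accepts both electron and proton (PCET, acceptor-shared);
* ``shared_h_donor``    — hole on the PT donor, electron elsewhere: the
  guanine donates both (PCET, donor-shared);
* ``other``             — residual class.

The strand character of the underlying electron transfer follows from the
topology of the hole and electron fragments: WC partners -> ``interstrand``,
stacked neighbours -> ``intrastrand``, diagonal partners -> ``diagonal``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gctetra.descriptors import DescriptorSet
from gctetra.pt import PTEvent
from gctetra.topology import FragmentTopology

PRIMARY_LABELS = ("hat_paired", "shared_e_acceptor", "shared_h_donor", "other")


@dataclass(frozen=True)
class PatternLabel:
    primary: str            # one of PRIMARY_LABELS
    strand_character: str   # "interstrand" | "intrastrand" | "diagonal" | "local"
    hole_fragment: int
    electron_fragment: int


def assign_pattern(
    event: PTEvent, d: DescriptorSet, topo: FragmentTopology
) -> PatternLabel:
    """Classify one PT event from the descriptor set at the event time."""
    hole = d.hole_fragment
    elec = d.electron_fragment
    hole_is_donor = hole == event.donor_fragment
    elec_is_acceptor = elec == event.acceptor_fragment
    if hole_is_donor and elec_is_acceptor:
        primary = "hat_paired"
    elif elec_is_acceptor:
        primary = "shared_e_acceptor"
    elif hole_is_donor:
        primary = "shared_h_donor"
    else:
        primary = "other"
    rel = topo.relation(hole, elec)
    if rel == "wc":
        strand = "interstrand"
    elif rel == "stacked":
        strand = "intrastrand"
    elif rel == "diagonal":
        strand = "diagonal"
    else:
        strand = "local"
    return PatternLabel(
        primary=primary,
        strand_character=strand,
        hole_fragment=hole,
        electron_fragment=elec,
    )


def binomial_se_pct(p: float, n: int) -> float:
    """Binomial standard error of a fraction, in percentage points."""
    return 100.0 * float(np.sqrt(p * (1.0 - p) / n))


def pattern_statistics(labels: list[PatternLabel]) -> pd.DataFrame:
    """Fractions of each primary pattern with binomial standard errors.

    Denominators are PT events, not trajectories.  Returns a DataFrame with
    columns ``label, count, pct, se_pct``; fractions sum to 1 over the four
    primary labels.
    """
    n = len(labels)
    if n == 0:
        warnings.warn("no labeled PT events: empty pattern summary", stacklevel=2)
        return pd.DataFrame(columns=["label", "count", "pct", "se_pct"])
    rows = []
    for lab in PRIMARY_LABELS:
        k = sum(pl.primary == lab for pl in labels)
        p = k / n
        rows.append(
            {"label": lab, "count": k, "pct": 100.0 * p, "se_pct": binomial_se_pct(p, n)}
        )
    return pd.DataFrame(rows)


def strand_character_statistics(labels: list[PatternLabel]) -> pd.DataFrame:
    """Fractions of each electron-transfer strand character among PT events."""
    n = len(labels)
    if n == 0:
        return pd.DataFrame(columns=["character", "count", "pct", "se_pct"])
    rows = []
    for ch in ("interstrand", "intrastrand", "diagonal", "local"):
        k = sum(pl.strand_character == ch for pl in labels)
        p = k / n
        rows.append(
            {"character": ch, "count": k, "pct": 100.0 * p, "se_pct": binomial_se_pct(p, n)}
        )
    return pd.DataFrame(rows)


def se_consistency_scan(
    reported: list[tuple[float, float]], n_min: int = 5, n_max: int = 60
) -> tuple[int, float]:
    """Find the single event count best explaining reported (pct, ±se_pct) pairs.

    For each candidate n, computes the binomial SE implied by each reported
    fraction and the worst absolute deviation from the reported SE; returns
    the n minimizing that worst deviation, together with the deviation.
    Useful to check that a set of printed ± values share one denominator.
    """
    best_n, best_dev = n_min, float("inf")
    for n in range(n_min, n_max + 1):
        dev = max(
            abs(binomial_se_pct(pct / 100.0, n) - se)
            for pct, se in reported
        )
        if dev < best_dev:
            best_n, best_dev = n, dev
    return best_n, best_dev
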