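"""Fragment-partitioned one-electron transition-density-matrix descriptors.

An excited state's 1-TDM, partitioned over nucleobase fragments, yields a
nonnegative F×F weight matrix ``Omega`` whose entry ``Omega[A, B]`` measures
hole-on-A / electron-on-B character.  The descriptors computed here are the
standard exciton-analysis set:

* ``CT``    — total off-diagonal weight, the net electron-hole fragment
  separation (0 = purely local, 1 = fully charge-separated);
* ``PR_h``, ``PR_e``, ``PR`` — inverse participation ratios of the hole and
  electron fragment weights (effective number of fragments hosting each),
  with ``PR`` their mean;
* ``POS_h``, ``POS_e`` — weight-averaged fragment positions (1-based index
  in declared topology order);
* ``PR_NTO`` — effective number of natural-transition-orbital pairs,
  ``(sum λ)² / sum λ²``;
* ``S_HE``, ``Z_HE`` — Shannon entropy (bits) of the normalized NTO weights
  and the effective number of entangled hole-electron states ``2**S_HE``.

All descriptors are invariant under an overall positive rescaling of the
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gctetra.errors import InvalidWeightsError, UndefinedStateError


@dataclass(frozen=True)
class OmegaMatrix:
    """Fragment-pair transition-density weights for one state at one time."""

    matrix: np.ndarray          # (F, F), nonnegative; [A, B] = hole A, electron B
    state: int = 1
    time_fs: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise UndefinedStateError("Omega matrix must be square")
        if np.any(m < 0):
            raise UndefinedStateError("Omega matrix entries must be nonnegative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_fragments(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class NTOWeights:
    """Nonincreasing nonnegative transition amplitudes for one state."""

    lams: np.ndarray
    state: int = 1
    time_fs: float = 0.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.lams, dtype=float)
        if np.any(lam < 0):
            raise InvalidWeightsError("NTO amplitudes must be nonnegative")
        if lam.sum() <= 0:
            raise InvalidWeightsError("NTO amplitudes must not all vanish")
        object.__setattr__(self, "lams", np.sort(lam)[::-1])


@dataclass(frozen=True)
class DescriptorSet:
    """All descriptors for one electronic state at one time."""

    ct: float
    hole_weights: np.ndarray
    electron_weights: np.ndarray
    pr_h: float
    pr_e: float
    pr: float
    pos_h: float
    pos_e: float
    hole_fragment: int
    electron_fragment: int
    pr_nto: float | None = None
    s_he: float | None = None
    z_he: float | None = None
    state: int = 1
    time_fs: float = 0.0


def fragment_weights(omega: OmegaMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize Omega and return (normalized matrix, hole, electron weights).

    ``h[A] = sum_B w[A, B]`` and ``e[B] = sum_A w[A, B]`` with
    ``w = Omega / sum(Omega)``; all three sum to 1 exactly after
    normalization.
    """
    total = omega.matrix.sum()
    if total <= 0:
        raise UndefinedStateError("all-zero Omega matrix: state character undefined")
    w = omega.matrix / total
    return w, w.sum(axis=1), w.sum(axis=0)


def excitation_descriptors(omega: OmegaMatrix) -> DescriptorSet:
    """CT, participation ratios and average positions from an Omega matrix."""
    w, h, e = fragment_weights(omega)
    ct = float(w.sum() - np.trace(w))
    pr_h = float(1.0 / np.sum(h * h))
    pr_e = float(1.0 / np.sum(e * e))
    idx = np.arange(1, omega.n_fragments + 1, dtype=float)
    return DescriptorSet(
        ct=ct,
        hole_weights=h,
        electron_weights=e,
        pr_h=pr_h,
        pr_e=pr_e,
        pr=0.5 * (pr_h + pr_e),
        pos_h=float(np.dot(idx, h)),
        pos_e=float(np.dot(idx, e)),
        hole_fragment=int(np.argmax(h)) + 1,
        electron_fragment=int(np.argmax(e)) + 1,
        state=omega.state,
        time_fs=omega.time_fs,
    )


def resonance_descriptors(lams: NTOWeights) -> tuple[float, float, float]:
    """(PR_NTO, S_HE, Z_HE) from the NTO amplitude spectrum.

    ``PR_NTO = (sum λ)² / sum λ²``; ``S_HE`` is the Shannon entropy in bits of
    the normalized amplitudes (with 0·log0 := 0) and ``Z_HE = 2**S_HE``.
    """
    lam = lams.lams
    total = lam.sum()
    pr_nto = float(total * total / np.sum(lam * lam))
    p = lam / total
    nz = p[p > 0]
    s_he = float(-np.sum(nz * np.log2(nz)))
    return pr_nto, s_he, float(2.0 ** s_he)


def describe_state(omega: OmegaMatrix, lams: NTOWeights | None = None) -> DescriptorSet:
    """Full descriptor set; NTO-derived fields are None when ``lams`` is absent."""
    d = excitation_descriptors(omega)
    if lams is None:
        return d
    pr_nto, s_he, z_he = resonance_descriptors(lams)
    return DescriptorSet(
        ct=d.ct,
        hole_weights=d.hole_weights,
        electron_weights=d.electron_weights,
        pr_h=d.pr_h,
        pr_e=d.pr_e,
        pr=d.pr,
        pos_h=d.pos_h,
        pos_e=d.pos_e,
        hole_fragment=d.hole_fragment,
        electron_fragment=d.electron_fragment,
        pr_nto=pr_nto,
        s_he=s_he,
        z_he=z_he,
        state=d.state,
        time_fs=d.time_fs,
    )


def directed_ct(omega: OmegaMatrix, hole_fragments, electron_fragments) -> float:
    """Directed charge-transfer weight, e.g. the G-block -> C-block character.

    Sums the normalized weight over hole fragments in ``hole_fragments`` and
    electron fragments in ``electron_fragments`` (1-based indices).
    """
    w, _, _ = fragment_weights(omega)
    hi = np.asarray(hole_fragments, dtype=int) - 1
    ei = np.asarray(electron_fragments, dtype=int) - 1
    return float(w[np.ix_(hi, ei)].sum())
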