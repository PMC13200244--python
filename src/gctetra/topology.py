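"""Fragment topology of the stacked (GC)2 tetramer.

Four nucleobase fragments, two per strand.  Each fragment has a Watson-Crick
partner on the opposite strand, a pi-stacked neighbour on its own strand and a
diagonal partner (opposite strand, not hydrogen-bonded).  Two sequence
arrangements are supported:

* ``nonalternating`` — both guanines on strand 1 (G1,G2 / C3,C4);
* ``alternating``    — each strand carries one G and one C (G1,C2 / C3,G4).
"""

from __future__ import annotations

from dataclasses import dataclass

from gctetra.errors import InvalidModelError


@dataclass(frozen=True)
class Fragment:
    """One nucleobase fragment, indexed 1..F."""

    index: int
    base: str           # "G" or "C"
    strand: int         # 1 or 2
    wc_partner: int
    stacked_neighbor: int
    diagonal_partner: int


@dataclass(frozen=True)
class FragmentTopology:
    """Topology of the four-fragment tetramer.

    Invariants checked on construction: the WC partnership is a symmetric
    involution pairing exactly one G with one C, strand ids split the
    fragments into two pairs, stacked neighbours share a strand, and diagonal
    partners are on opposite strands without being WC partners.
    """

    fragments: tuple[Fragment, ...]
    tag: str  # "alternating" | "nonalternating"

    def __post_init__(self) -> None:
        by_index = {f.index: f for f in self.fragments}
        if sorted(by_index) != list(range(1, len(self.fragments) + 1)):
            raise InvalidModelError("fragment indices must be 1..F without gaps")
        strands: dict[int, list[int]] = {}
        for f in self.fragments:
            strands.setdefault(f.strand, []).append(f.index)
            partner = by_index.get(f.wc_partner)
            if partner is None or partner.wc_partner != f.index:
                raise InvalidModelError("WC partnership must be a symmetric involution")
            if {f.base, partner.base} != {"G", "C"}:
                raise InvalidModelError("WC partners must pair one G with one C")
            if partner.strand == f.strand:
                raise InvalidModelError("WC partners must lie on opposite strands")
            neigh = by_index.get(f.stacked_neighbor)
            if neigh is None or neigh.strand != f.strand or neigh.index == f.index:
                raise InvalidModelError("stacked neighbours must share a strand")
            diag = by_index.get(f.diagonal_partner)
            if diag is None or diag.strand == f.strand or diag.index == f.wc_partner:
                raise InvalidModelError(
                    "diagonal partners must be cross-strand and distinct from the WC partner"
                )
        if len(strands) != 2 or any(len(v) != len(self.fragments) // 2 for v in strands.values()):
            raise InvalidModelError("strand ids must partition the fragments into two pairs")

    # -- convenience -------------------------------------------------------

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment(self, index: int) -> Fragment:
        return self.fragments[index - 1]

    @property
    def g_fragments(self) -> tuple[int, ...]:
        return tuple(f.index for f in self.fragments if f.base == "G")

    @property
    def c_fragments(self) -> tuple[int, ...]:
        return tuple(f.index for f in self.fragments if f.base == "C")

    @property
    def wc_pairs(self) -> tuple[tuple[int, int], ...]:
        """(G, C) Watson-Crick pairs, G first, ordered by G index."""
        return tuple(
            (f.index, f.wc_partner) for f in self.fragments if f.base == "G"
        )

    def relation(self, a: int, b: int) -> str | None:
        """Topological relation between two fragments.

        Returns ``"wc"``, ``"stacked"``, ``"diagonal"`` or ``None`` (a == b).
        """
        fa = self.fragment(a)
        if a == b:
            return None
        if fa.wc_partner == b:
            return "wc"
        if fa.stacked_neighbor == b:
            return "stacked"
        if fa.diagonal_partner == b:
            return "diagonal"
        return None

    def ct_channels(self) -> tuple[tuple[int, int, str], ...]:
        """Allowed G->C charge-transfer channels as (hole, electron, relation)."""
        out = []
        for g in self.g_fragments:
            for c in self.c_fragments:
                rel = self.relation(g, c)
                if rel is not None:
                    out.append((g, c, rel))
        return tuple(out)


def nonalternating_tetramer() -> FragmentTopology:
    """GG/CC arrangement: strand 1 = G1,G2; strand 2 = C3,C4."""
    return FragmentTopology(
        fragments=(
            Fragment(1, "G", 1, wc_partner=3, stacked_neighbor=2, diagonal_partner=4),
            Fragment(2, "G", 1, wc_partner=4, stacked_neighbor=1, diagonal_partner=3),
            Fragment(3, "C", 2, wc_partner=1, stacked_neighbor=4, diagonal_partner=2),
            Fragment(4, "C", 2, wc_partner=2, stacked_neighbor=3, diagonal_partner=1),
        ),
        tag="nonalternating",
    )


def alternating_tetramer() -> FragmentTopology:
    """GC/CG arrangement: strand 1 = G1,C2; strand 2 = C3,G4."""
    return FragmentTopology(
        fragments=(
            Fragment(1, "G", 1, wc_partner=3, stacked_neighbor=2, diagonal_partner=4),
            Fragment(2, "C", 1, wc_partner=4, stacked_neighbor=1, diagonal_partner=3),
            Fragment(3, "C", 2, wc_partner=1, stacked_neighbor=4, diagonal_partner=2),
            Fragment(4, "G", 2, wc_partner=2, stacked_neighbor=3, diagonal_partner=1),
        ),
        tag="alternating",
    )


def topology_for(tag: str) -> FragmentTopology:
    if tag == "alternating":
        return alternating_tetramer()
    if tag == "nonalternating":
        return nonalternating_tetramer()
    raise InvalidModelError(f"unknown sequence tag {tag!r}")
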