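"""Enumeration of protonation microstates over N exchangeable sites.

A microstate is an occupancy bit-vector over the user's ordered site list
(1 = protonated). Removing protons from the fully protonated reference in all
2^N combinations spans N+1 charge states with binomial(N, k) protomers at k
bound protons. The deprotonation graph connecting them is the N-dimensional
hypercube. Spatial symmetry is deliberately not used to deduplicate states:
symmetry-equivalent protomers are retained (they carry the statistical
factors of the macroscopic ladder) and can only be *annotated* as equivalent
for reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .errors import CapacityError, InputError

__all__ = [
    "Microstate",
    "MicrostateSet",
    "DeprotonationEdge",
    "enumerate_microstates",
    "deprotonation_edges",
    "annotate_symmetry_equivalents",
]

#: Hard cap on site count; 2^20 states is already beyond any practical DFT run.
MAX_SITES = 20


@dataclass(frozen=True)
class Microstate:
    """One assignment of protons to the exchangeable sites."""

    occupancy: tuple[int, ...]
    charge: int

    @property
    def id(self) -> str:
        """Canonical bitstring in user site order, e.g. ``"1011"``."""
        return "".join(str(b) for b in self.occupancy)

    @property
    def n_protons(self) -> int:
        return sum(self.occupancy)

    def protonated_sites(self, labels: Sequence[str]) -> list[str]:
        return [lab for lab, bit in zip(labels, self.occupancy) if bit]


@dataclass(frozen=True)
class DeprotonationEdge:
    """Donor loses the proton at ``site`` to become acceptor."""

    donor: Microstate
    acceptor: Microstate
    site: str


@dataclass
class MicrostateSet:
    """All 2^N microstates in deterministic order.

    Order is descending proton count, lexicographic bitstring within each
    count — so the fully protonated reference comes first and the fully
    deprotonated state last.
    """

    site_labels: tuple[str, ...]
    reference_charge: int
    states: tuple[Microstate, ...]
    #: reporting-only marks: annotation name -> ids of symmetry-equivalent states
    symmetry_annotations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[Microstate]:
        return iter(self.states)

    def by_charge(self) -> dict[int, list[Microstate]]:
        out: dict[int, list[Microstate]] = {}
        for s in self.states:
            out.setdefault(s.charge, []).append(s)
        return out

    def get(self, microstate_id: str) -> Microstate:
        for s in self.states:
            if s.id == microstate_id:
                return s
        raise KeyError(microstate_id)

    def to_frame(self) -> pd.DataFrame:
        """Roster table: microstate, charge, n_protons, sites_protonated."""
        return pd.DataFrame(
            [
                {
                    "microstate": s.id,
                    "charge": s.charge,
                    "n_protons": s.n_protons,
                    "sites_protonated": ",".join(
                        s.protonated_sites(self.site_labels)
                    ),
                }
                for s in self.states
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_microstates(
    site_labels: Sequence[str], reference_charge: int
) -> MicrostateSet:
    """Enumerate all 2^N protonation microstates.

    ``reference_charge`` is the net charge of the fully protonated species;
    each removed proton lowers the charge by one.
    """
    labels = tuple(str(lab) for lab in site_labels)
    if len(set(labels)) != len(labels):
        raise InputError("site labels must be distinct")
    n = len(labels)
    if n > MAX_SITES:
        raise CapacityError(
            f"{n} sites would give 2^{n} microstates; the enumeration is "
            f"capped at {MAX_SITES} sites — split the problem or reduce the "
            "site list"
        )
    states = [
        Microstate(occ, reference_charge - (n - sum(occ)))
        for occ in itertools.product((0, 1), repeat=n)
    ]
    states.sort(key=lambda s: (-s.n_protons, s.id))
    return MicrostateSet(labels, int(reference_charge), tuple(states))


def deprotonation_edges(ms_set: MicrostateSet) -> list[DeprotonationEdge]:
    """All single-deprotonation transitions: the hypercube's N*2^(N-1) edges.

    Deterministic order: donors in set order, sites in user order within each
    donor.
    """
    index = {s.occupancy: s for s in ms_set.states}
    edges: list[DeprotonationEdge] = []
    for donor in ms_set.states:
        for i, bit in enumerate(donor.occupancy):
            if not bit:
                continue
            occ = list(donor.occupancy)
            occ[i] = 0
            edges.append(
                DeprotonationEdge(donor, index[tuple(occ)], ms_set.site_labels[i])
            )
    return edges


def annotate_symmetry_equivalents(
    ms_set: MicrostateSet, groups: dict[str, Sequence[str]]
) -> MicrostateSet:
    """Mark groups of symmetry-equivalent microstates for reporting.

    No deduplication is ever performed — every state stays in the set; the
    annotation only travels with the roster so reports can flag redundancy.
    """
    known = {s.id for s in ms_set.states}
    annotations = dict(ms_set.symmetry_annotations)
    for name, ids in groups.items():
        unknown = set(ids) - known
        if unknown:
            raise InputError(
                f"annotation {name!r} references unknown microstates: "
                f"{sorted(unknown)}"
            )
        annotations[str(name)] = tuple(ids)
    return MicrostateSet(
        ms_set.site_labels, ms_set.reference_charge, ms_set.states, annotations
    )
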