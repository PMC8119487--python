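"""Pedigree graph and variant genotype observations.

A pedigree is a set of individuals with optional father/mother links,
sex, and an affection status for the phenotype under study (here,
postlingual progressive hearing loss).  A ``VariantObservation``
attaches heterozygous / reference / untyped genotype calls for a single
candidate variant to pedigree members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

__all__ = ["Individual", "Pedigree", "VariantObservation"]

AFFECTION_STATES = ("yes", "no", "unknown")
GENOTYPES = ("het", "ref", "untyped")


@dataclass
class Individual:
    id: str
    sex: str = "unknown"  # male / female / unknown
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affected: str = "unknown"  # yes / no / unknown
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"{self.id}: invalid sex {self.sex!r}")
        if self.affected not in AFFECTION_STATES:
            raise ValueError(f"{self.id}: invalid affection state {self.affected!r}")


class Pedigree:
    """Validated family graph.

    Checks on construction: referenced parents exist, fathers are male
    and mothers female (unknown sex is tolerated), and parent links are
    acyclic.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        proband_id: Optional[str] = None,
        family_id: str = "",
    ) -> None:
        self.members: Dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.members:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        self.family_id = family_id
        if proband_id is not None and proband_id not in self.members:
            raise ValueError(f"proband {proband_id!r} not in pedigree")
        self.proband_id = proband_id
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for pid, role, want_sex in (
                (ind.father_id, "father", "male"),
                (ind.mother_id, "mother", "female"),
            ):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise ValueError(
                        f"individual {ind.id!r} references missing {role} {pid!r}"
                    )
                parent = self.members[pid]
                if parent.sex not in (want_sex, "unknown"):
                    raise ValueError(
                        f"{role} {pid!r} of {ind.id!r} has sex {parent.sex!r}"
                    )
                g.add_edge(pid, ind.id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cyclic parentage: {cycle}")
        self._graph = g

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.members

    def children_of(self, parent_id: str) -> List[str]:
        return sorted(self._graph.successors(parent_id))

    def parents_of(self, child_id: str) -> Tuple[Optional[str], Optional[str]]:
        ind = self.members[child_id]
        return ind.father_id, ind.mother_id

    def transmissions(self) -> List[Tuple[str, str]]:
        """All parent -> offspring edges in the pedigree."""
        return sorted(self._graph.edges())


@dataclass
class VariantObservation:
    """Genotype calls for one variant across pedigree members.

    ``variant_id`` is free text, conventionally the HGVS c./p. strings.
    Individuals absent from ``genotypes`` are untyped.
    """

    variant_id: str
    genotypes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValueError(f"{ind}: invalid genotype {g!r}")

    def genotype(self, individual_id: str) -> str:
        return self.genotypes.get(individual_id, "untyped")

    def validate_against(self, ped: Pedigree) -> None:
        unknown = sorted(set(self.genotypes) - set(ped.members))
        if unknown:
            raise ValueError(
                f"genotyped individuals not in pedigree {ped.family_id!r}: {unknown}"
            )
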