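"""Partitions of specimens (or populations) into delimited blocks.

Every evidence stream in the pipeline — GMYC entities, morphometric
clusters, mating-compatibility components, host association — is reduced to
a :class:`Partition` before congruence is assessed, so that streams of
different origin become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

from sklearn.metrics import adjusted_rand_score

__all__ = ["Partition"]


@dataclass
class Partition:
    """A disjoint assignment of elements to blocks.

    Parameters
    ----------
    assignment
        Mapping element -> block id. Block ids are arbitrary hashables;
        only the induced grouping matters.
    provenance
        Which evidence stream produced the partition
        (``molecular | gmyc | morpho | mating | host | consensus | truth``).
    """

    assignment: dict[Hashable, Hashable]
    provenance: str = ""
    singleton_flags: dict[Hashable, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)

    @property
    def elements(self) -> list:
        return list(self.assignment)

    def blocks(self) -> dict[Hashable, set]:
        out: dict[Hashable, set] = {}
        for el, b in self.assignment.items():
            out.setdefault(b, set()).add(el)
        return out

    @property
    def n_blocks(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, elements: Iterable[Hashable]) -> list:
        """Block ids in a caller-supplied element order (KeyError if absent)."""
        return [self.assignment[e] for e in elements]

    def restrict(self, elements: Iterable[Hashable]) -> "Partition":
        keep = set(elements)
        return Partition(
            {e: b for e, b in self.assignment.items() if e in keep},
            provenance=self.provenance,
        )

    def lift(self, membership: Mapping[Hashable, Hashable], provenance: str | None = None) -> "Partition":
        """Lift a population-level partition to specimens.

        ``membership`` maps specimen -> population; each specimen inherits
        the block of its population.
        """
        return Partition(
            {sp: self.assignment[pop] for sp, pop in membership.items()},
            provenance=provenance if provenance is not None else self.provenance,
        )

    @classmethod
    def from_labels(
        cls, elements: Iterable[Hashable], labels: Iterable[Hashable], provenance: str = ""
    ) -> "Partition":
        return cls(dict(zip(elements, labels, strict=True)), provenance=provenance)

    def ari(self, other: "Partition") -> float:
        """Adjusted Rand index against ``other`` (same element set required)."""
        if set(self.assignment) != set(other.assignment):
            raise ValueError("partitions are over different element sets")
        order = sorted(self.assignment, key=str)
        a = _as_int_labels([self.assignment[e] for e in order])
        b = _as_int_labels([other.assignment[e] for e in order])
        return float(adjusted_rand_score(a, b))


def _as_int_labels(labels: list) -> list[int]:
    seen: dict = {}
    return [seen.setdefault(x, len(seen)) for x in labels]
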