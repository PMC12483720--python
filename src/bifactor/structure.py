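"""Bi-factor structure container: the partition of variables onto group factors."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BiFactorStructure"]


@dataclass
class BiFactorStructure:
    """Clusters I_1..I_G of variables loading on each group factor.

    Variable indices are 1-based, matching the conventional item numbering in
    questionnaire data.  Variables appearing in no cluster load on the general
    factor only and are listed in ``unassigned``.
    """

    clusters: list[frozenset[int]]
    J: int
    unassigned: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.clusters = [frozenset(c) for c in self.clusters]
        seen: set[int] = set()
        for g, cluster in enumerate(self.clusters, start=1):
            for j in cluster:
                if not (1 <= j <= self.J):
                    raise ValueError(f"variable index {j} outside 1..{self.J}")
                if j in seen:
                    raise ValueError(
                        f"variable {j} assigned to more than one cluster "
                        f"(second occurrence in cluster {g})"
                    )
                seen.add(j)
        self.unassigned = frozenset(range(1, self.J + 1)) - seen

    @property
    def G(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[int, int]:
        """Map variable index -> 1-based group label (0 for unassigned)."""
        out = {j: 0 for j in range(1, self.J + 1)}
        for g, cluster in enumerate(self.clusters, start=1):
            for j in cluster:
                out[j] = g
        return out

    def to_dict(self) -> dict:
        """JSON-ready mapping of group index to sorted variable indices."""
        return {
            "J": self.J,
            "clusters": {str(g + 1): sorted(c) for g, c in enumerate(self.clusters)},
            "unassigned": sorted(self.unassigned),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiFactorStructure":
        G = len(d["clusters"])
        clusters = [frozenset(d["clusters"][str(g + 1)]) for g in range(G)]
        return cls(clusters=clusters, J=int(d["J"]))
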