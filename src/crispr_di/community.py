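"""Strain and community data model plus spacer-protospacer matching primitives.

A host strain carries an ordered CRISPR array of spacers (leader end first);
a viral strain carries a vector of protospacer alleles. A spacer and the
protospacer allele it targets share one opaque integer identifier, so
matching is identifier equality — the simulator only ever creates spacers
by copying protospacer alleles, and the empirical pipeline maps spacers to
protospacers explicitly before building a community.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


@dataclass(frozen=True)
class HostStrain:
    """A host genotype: ordered spacer array plus population weight.

    ``spacers`` is leader-end first; ``proportion`` is the fraction of the
    host population, ``density`` (cells/mL) is only meaningful in
    simulation contexts.
    """

    strain_id: int
    spacers: tuple[int, ...]
    proportion: float = 0.0
    density: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacers", tuple(self.spacers))
        if len(set(self.spacers)) != len(self.spacers):
            raise ValueError(
                f"host strain {self.strain_id}: duplicate spacer identifiers"
            )
        if not -1e-9 <= self.proportion <= 1 + 1e-9:
            raise ValueError(
                f"host strain {self.strain_id}: proportion {self.proportion} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class ViralStrain:
    """A viral genotype: protospacer allele vector plus population weight."""

    strain_id: int
    protospacers: tuple[int, ...]
    proportion: float = 0.0
    density: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacers", tuple(self.protospacers))
        if not -1e-9 <= self.proportion <= 1 + 1e-9:
            raise ValueError(
                f"viral strain {self.strain_id}: proportion {self.proportion} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class Community:
    """Host and viral strain sets at one time point.

    All immunity metrics are evaluated on a Community whose proportions sum
    to one on each side; :func:`normalize_community` builds one from raw
    abundances.
    """

    hosts: tuple[HostStrain, ...]
    viruses: tuple[ViralStrain, ...]
    time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hosts", tuple(self.hosts))
        object.__setattr__(self, "viruses", tuple(self.viruses))
        for side, strains in (("host", self.hosts), ("virus", self.viruses)):
            ids = [s.strain_id for s in strains]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {side} strain ids")

    def validate_proportions(self, tol: float = 1e-9) -> None:
        for side, strains in (("host", self.hosts), ("virus", self.viruses)):
            total = sum(s.proportion for s in strains)
            if abs(total - 1.0) > tol:
                raise ValueError(f"{side} proportions sum to {total}, not 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "hosts": [
                {
                    "id": h.strain_id,
                    "spacers": list(h.spacers),
                    "proportion": h.proportion,
                }
                for h in self.hosts
            ],
            "viruses": [
                {
                    "id": v.strain_id,
                    "protospacers": list(v.protospacers),
                    "proportion": v.proportion,
                }
                for v in self.viruses
            ],
        }
        if self.time is not None:
            d["time"] = self.time
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Community":
        hosts = tuple(
            HostStrain(h["id"], tuple(h["spacers"]), float(h["proportion"]))
            for h in d["hosts"]
        )
        viruses = tuple(
            ViralStrain(v["id"], tuple(v["protospacers"]), float(v["proportion"]))
            for v in d["viruses"]
        )
        return cls(hosts, viruses, d.get("time"))

    @classmethod
    def from_json(cls, s: str) -> "Community":
        return cls.from_dict(json.loads(s))


# -- matching primitives --------------------------------------------------


def matched_positions(host: HostStrain, virus: ViralStrain) -> tuple[int, ...]:
    """Protospacer positions of ``virus`` matched by some spacer of ``host``."""
    spacer_set = set(host.spacers)
    return tuple(
        p for p, allele in enumerate(virus.protospacers) if allele in spacer_set
    )


def match_count(host: HostStrain, virus: ViralStrain) -> int:
    """Number of protospacer positions of the virus matched by the host.

    A viral allele occupying several positions counts once per position, so
    this is "number of distinct matched protospacers", not spacer identities.
    """
    return len(matched_positions(host, virus))


def match_presence(host: HostStrain, virus: ViralStrain) -> int:
    """1 if the host matches the virus at all (is immune), else 0."""
    spacer_set = set(host.spacers)
    return int(any(allele in spacer_set for allele in virus.protospacers))


def distributed_indicator(
    host_i: HostStrain, host_j: HostStrain, virus: ViralStrain
) -> int:
    """1 iff the two hosts match *different* protospacers of the same virus.

    Zero when either host has no match, and zero when both hosts match only
    the same single protospacer position. Symmetric in the two hosts.
    """
    a = matched_positions(host_i, virus)
    b = matched_positions(host_j, virus)
    if not a or not b:
        return 0
    return int(len(set(a) | set(b)) >= 2)


def distributed_count(
    host_i: HostStrain, host_j: HostStrain, virus: ViralStrain
) -> int:
    """Count variant: number of ordered position pairs (p, p') with p matched
    by host_i, p' by host_j and p != p'. Exposed for sensitivity analysis;
    the immunity metrics use the binary indicator."""
    a = set(matched_positions(host_i, virus))
    b = set(matched_positions(host_j, virus))
    return len(a) * len(b) - len(a & b)


# -- construction helpers -------------------------------------------------


def normalize_community(
    hosts: Iterable[HostStrain],
    viruses: Iterable[ViralStrain],
    time: float | None = None,
) -> Community:
    """Build a Community from strains with raw abundances.

    ``proportion`` fields are treated as raw non-negative abundances (the
    ``density`` field is used instead when any strain carries a positive
    density); strains with zero abundance are dropped and the remainder
    rescaled to sum to one on each side.
    """

    def _normalize(strains, side):
        strains = list(strains)
        use_density = any(s.density > 0 for s in strains)
        weights = [s.density if use_density else s.proportion for s in strains]
        if any(w < 0 for w in weights):
            raise ValueError(f"negative abundance on {side} side")
        total = sum(weights)
        if total <= 0:
            raise ValueError(f"empty population: {side} side has zero abundance")
        return tuple(
            replace(s, proportion=w / total)
            for s, w in zip(strains, weights)
            if w > 0
        )

    community = Community(
        _normalize(hosts, "host"), _normalize(viruses, "virus"), time
    )
    community.validate_proportions()
    return community


def average_spacers_per_host(community: Community) -> float:
    """Proportion-weighted mean CRISPR array length across host strains."""
    return sum(h.proportion * len(h.spacers) for h in community.hosts)
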