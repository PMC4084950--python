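"""Seeded generators of communities and read sets for testing and demos.

``make_community`` builds communities with prescribed immunity structure
(clonal, all hosts sharing one spacer, or fully distributed immunity where
every host targets a distinct protospacer of every virus). ``make_reads``
emulates shotgun sequencing of CRISPR loci: reads sample loci in proportion
to strain abundance and may be truncated at the leader or trailer end, the
situation the reconstruction pipeline must undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .community import Community, HostStrain, ViralStrain, normalize_community
from .empirical import ReadObservation

Structure = Literal["clonal", "shared_spacer", "fully_distributed", "mixed"]


@dataclass
class FixtureSpec:
    n_hosts: int = 4
    n_viruses: int = 1
    S: int = 10
    P: int = 10
    structure: Structure = "fully_distributed"
    abundance: Literal["equal", "dirichlet"] = "equal"
    dirichlet_alpha: float = 1.0
    seed: int | None = None


def _abundances(spec: FixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.abundance == "equal":
        return np.full(n, 1.0 / n)
    w = rng.dirichlet(np.full(n, spec.dirichlet_alpha))
    # keep all strains present: floor at a tiny proportion and renormalize
    w = np.maximum(w, 1e-6)
    return w / w.sum()


def make_community(spec: FixtureSpec) -> Community:
    """Build a community with the requested immunity structure.

    fully_distributed: host i carries spacer i, and every virus carries
    alleles 0..n_hosts-1 among its P protospacers, so every host pair is
    distributed-immune to every virus. shared_spacer: all hosts carry the
    single spacer 0, which every virus carries. clonal: one host strain.
    """
    rng = np.random.default_rng(spec.seed)
    n_h = 1 if spec.structure == "clonal" else spec.n_hosts
    if spec.structure == "fully_distributed" and spec.n_hosts > spec.P:
        raise ValueError(
            f"fully_distributed needs n_hosts <= P ({spec.n_hosts} > {spec.P})"
        )

    def virus_proto(k: int) -> tuple[int, ...]:
        # first n_h positions carry the shared allele block; the rest are
        # unique junk alleles per virus
        base = list(range(n_h)) if spec.structure != "shared_spacer" else [0] * 1
        filler_start = 1000 + k * spec.P
        proto = list(base)[: spec.P]
        while len(proto) < spec.P:
            proto.append(filler_start + len(proto))
        return tuple(proto)

    if spec.structure == "clonal":
        hosts = [HostStrain(0, (0,), proportion=1.0)]
    elif spec.structure == "shared_spacer":
        hosts = [HostStrain(i, (0,), proportion=0.0) for i in range(n_h)]
    elif spec.structure == "fully_distributed":
        hosts = [HostStrain(i, (i,), proportion=0.0) for i in range(n_h)]
    elif spec.structure == "mixed":
        # half distributed, half sharing spacer 0
        hosts = [
            HostStrain(i, (i if i < n_h // 2 else 0,), proportion=0.0)
            for i in range(n_h)
        ]
    else:
        raise ValueError(f"unknown structure {spec.structure!r}")

    h_props = _abundances(spec, len(hosts), rng)
    v_props = _abundances(spec, spec.n_viruses, rng)
    hosts = [
        HostStrain(h.strain_id, h.spacers, proportion=float(p))
        for h, p in zip(hosts, h_props)
    ]
    viruses = [
        ViralStrain(k, virus_proto(k), proportion=float(v_props[k]))
        for k in range(spec.n_viruses)
    ]
    return normalize_community(hosts, viruses)


def make_random_community(
    rng: np.random.Generator,
    max_hosts: int = 8,
    max_viruses: int = 6,
    max_spacers: int = 6,
    P: int = 8,
    n_alleles: int = 12,
) -> Community:
    """A fully random community for property tests and oracle comparisons."""
    n_h = int(rng.integers(1, max_hosts + 1))
    n_v = int(rng.integers(1, max_viruses + 1))
    hosts = []
    for i in range(n_h):
        n_sp = int(rng.integers(0, max_spacers + 1))
        spacers = tuple(
            int(a) for a in rng.choice(n_alleles, size=n_sp, replace=False)
        )
        hosts.append(HostStrain(i, spacers, proportion=1.0))
    viruses = []
    for k in range(n_v):
        proto = tuple(int(a) for a in rng.integers(0, n_alleles, size=P))
        viruses.append(ViralStrain(k, proto, proportion=1.0))
    h_w = rng.random(n_h) + 0.05
    v_w = rng.random(n_v) + 0.05
    hosts = [
        HostStrain(h.strain_id, h.spacers, density=float(w))
        for h, w in zip(hosts, h_w)
    ]
    viruses = [
        ViralStrain(v.strain_id, v.protospacers, density=float(w))
        for v, w in zip(viruses, v_w)
    ]
    return normalize_community(hosts, viruses)


def make_reads(
    loci: dict[tuple[int, ...], float],
    ancestral: Sequence[int],
    depth: int = 100,
    truncation: float = 0.0,
    seed: int | None = None,
) -> list[ReadObservation]:
    """Sample reads from true loci with optional end truncation.

    ``loci`` maps each true spacer array (leader first) to its abundance.
    Each read samples a locus proportionally, then independently loses the
    leader end or the trailer end with probability ``truncation`` each
    (dropping a uniform positive number of spacers from that end, never
    emptying the read). Spacers absent from ``ancestral`` are flagged novel.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    keys = list(loci)
    weights = np.array([loci[k] for k in keys], float)
    weights = weights / weights.sum()
    ancestral_set = set(ancestral)

    reads = []
    for n in range(depth):
        locus = keys[int(rng.choice(len(keys), p=weights))]
        spacers = list(locus)
        has_leader, has_trailer = True, True
        if truncation > 0 and len(spacers) > 1 and rng.random() < truncation:
            cut = int(rng.integers(1, len(spacers)))
            spacers = spacers[cut:]
            has_leader = False
        if truncation > 0 and len(spacers) > 1 and rng.random() < truncation:
            cut = int(rng.integers(1, len(spacers)))
            spacers = spacers[:-cut]
            has_trailer = False
        reads.append(
            ReadObservation(
                read_id=f"r{n}",
                spacers=tuple(spacers),
                has_leader=has_leader,
                has_trailer=has_trailer,
                novel=tuple(s not in ancestral_set for s in spacers),
            )
        )
    return reads
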