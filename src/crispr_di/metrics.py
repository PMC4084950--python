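"""Distributed-immunity statistics for a host-virus community.

Three population metrics, each an abundance-weighted sum over strains:

* **PDI** (population-wide distributed immunity) scores host-host-virus
  triplets: a triplet contributes when the two hosts are immune to the
  virus via *different* protospacers, weighted by the product of the three
  proportions and an evenness factor sigma that discounts uneven host
  pairs. With n equally abundant, mutually distributed host strains the
  maximum is 1 - 1/n.
* **IDI** (individual distributed immunity) is the abundance-weighted
  average number of distinct protospacers of a viral strain matched by a
  host strain — how many independent ways a typical host is immune.
* **HVI** is the abundance-weighted proportion of host-virus pairs with no
  match at all: the fraction of encounters in which the virus can infect.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

from .community import Community, matched_positions

SigmaVariant = Literal["pairwise", "population"]


@dataclass(frozen=True)
class MetricsResult:
    """PDI/IDI/HVI for one community, with the attainable PDI bound."""

    pdi: float
    idi: float
    hvi: float
    max_pdi: float
    n_host_strains: int

    def to_dict(self) -> dict:
        return asdict(self)


def evenness_factor(n_i: float, n_j: float) -> float:
    """Evenness weight sigma for a host pair: 1 - |Ni - Nj| / max(Ni, Nj).

    Equals 1 for equally abundant strains and decays toward 0 as one strain
    dominates the pair, so rare-against-dominant pairs contribute little.
    """
    if n_i <= 0 or n_j <= 0:
        raise ValueError("evenness_factor requires positive proportions")
    return 1.0 - abs(n_i - n_j) / max(n_i, n_j)


def _sigma_matrix(props: np.ndarray, variant: SigmaVariant) -> np.ndarray:
    """Pairwise sigma weights for all ordered host pairs."""
    ni = props[:, None]
    nj = props[None, :]
    if variant == "pairwise":
        denom = np.maximum(ni, nj)
    elif variant == "population":
        denom = np.full_like(ni + nj, props.max())
    else:
        raise ValueError(f"unknown sigma variant: {variant!r}")
    return 1.0 - np.abs(ni - nj) / denom


def _membership(
    community: Community, alleles: set | None = None
) -> tuple[np.ndarray, dict]:
    """Host-by-allele membership matrix over the given protospacer alleles
    (all alleles seen in the viral population when not restricted)."""
    if alleles is None:
        alleles = {a for v in community.viruses for a in v.protospacers}
    index = {a: i for i, a in enumerate(sorted(alleles))}
    hs = np.zeros((len(community.hosts), len(index)), dtype=bool)
    for i, h in enumerate(community.hosts):
        for sp in h.spacers:
            j = index.get(sp)
            if j is not None:
                hs[i, j] = True
    return hs, index


def _virus_groups(community: Community) -> list[tuple[tuple[int, ...], float]]:
    """Merge viral strains that are metrically interchangeable.

    A metric term depends on virus k only through the set of its alleles
    that some host spacer matches, so strains with distinct alleles and the
    same matched-allele set are merged with summed proportions (splitting a
    strain into identical copies provably leaves all metrics unchanged).
    Strains carrying a duplicated allele keep their full position vector,
    since matched positions then outnumber matched alleles.
    Returns (position vector, total proportion) pairs.
    """
    universe = set()
    for h in community.hosts:
        universe.update(h.spacers)
    groups: dict[tuple, list] = {}
    for virus in community.viruses:
        proto = virus.protospacers
        if len(set(proto)) == len(proto):
            key = tuple(sorted(a for a in proto if a in universe))
            vec = key
        else:
            key = ("dup", virus.strain_id)
            vec = proto
        entry = groups.setdefault(key, [vec, 0.0])
        entry[1] += virus.proportion
    return [(vec, w) for vec, w in groups.values()]


def pdi(community: Community, sigma: SigmaVariant = "pairwise") -> float:
    """Population-wide distributed immunity.

    Sum over ordered host pairs i != j and viral strains k of
    ``Ni * Nj * Vk * sigma(Ni, Nj) * D(Gi, Gj, Hk)`` where D is 1 iff the
    two hosts match different protospacers of virus k (both immune, and
    their matched position sets are not one identical singleton). Returns 0
    for communities with fewer than two host strains.
    """
    return compute_metrics(community, sigma, validate=False).pdi


def max_pdi(
    host_proportions: Sequence[float], sigma: SigmaVariant = "pairwise"
) -> float:
    """Upper bound on PDI given only the host abundance distribution.

    Attained when every host pair is distributed-immune to every virus, in
    which case the viral proportions sum out of the triplet sum leaving
    ``sum_{i != j} Ni * Nj * sigma(Ni, Nj)``. At n equal abundances this is
    exactly 1 - 1/n.
    """
    n = np.asarray(host_proportions, dtype=float)
    if n.size < 2:
        return 0.0
    if np.any(n <= 0):
        raise ValueError("host proportions must be positive")
    sig = _sigma_matrix(n, sigma)
    outer = np.outer(n, n) * sig
    return float(outer.sum() - np.trace(outer))


def idi(community: Community) -> float:
    """Individual distributed immunity: abundance-weighted mean number of
    distinct matched protospacers per host-virus strain pair."""
    total = 0.0
    for h in community.hosts:
        for w in community.viruses:
            total += h.proportion * w.proportion * len(matched_positions(h, w))
    return total


def hvi(community: Community) -> float:
    """Abundance-weighted proportion of host-virus pairs with no match —
    the average fraction of the host population a virus can infect."""
    total = 0.0
    for h in community.hosts:
        spacer_set = set(h.spacers)
        for w in community.viruses:
            immune = any(a in spacer_set for a in w.protospacers)
            if not immune:
                total += h.proportion * w.proportion
    return total


def compute_metrics(
    community: Community, sigma: SigmaVariant = "pairwise",
    validate: bool = True,
) -> MetricsResult:
    """All distributed-immunity metrics for one community snapshot.

    Viral strains are first merged by matched-allele signature (exact; see
    ``_virus_groups``). The distributed indicator is then decomposed as
    "both hosts immune" minus "both hosts single-matched on the same
    position", so the expensive pairwise term reduces to one batched
    quadratic form in the host weight matrix; agrees with the individual
    metric functions to machine precision.
    """
    if validate:
        community.validate_proportions(tol=1e-6)
    hosts = community.hosts
    n = np.array([h.proportion for h in hosts])
    n_strains = len(hosts)
    if not community.viruses or not hosts:
        return MetricsResult(0.0, 0.0, 1.0 if hosts else 0.0,
                             max_pdi(n, sigma) if n_strains >= 2 else 0.0,
                             n_strains)

    groups = _virus_groups(community)
    hs, index = _membership(community, {a for vec, _ in groups for a in vec})
    if n_strains >= 2:
        weights = np.outer(n, n) * _sigma_matrix(n, sigma)
        np.fill_diagonal(weights, 0.0)

    idi_total = 0.0
    hvi_total = 0.0
    imm_rows = []            # per group: which hosts are immune
    group_w = []
    single_buckets = []      # per group: {position column: [host indices]}
    for vec, w in groups:
        if not vec:
            hvi_total += w   # no host matches this group at all
            continue
        cols = [index[a] for a in vec]
        matched = hs[:, cols]
        counts = matched.sum(axis=1)
        idi_total += w * float(n @ counts)
        hvi_total += w * float(n @ (counts == 0))
        if n_strains >= 2:
            imm_rows.append(counts > 0)
            group_w.append(w)
            buckets: dict[int, list[int]] = {}
            for i in np.flatnonzero(counts == 1):
                pos = int(matched[i].argmax())
                buckets.setdefault(pos, []).append(int(i))
            single_buckets.append(buckets)

    pdi_total = 0.0
    if n_strains >= 2 and imm_rows:
        Q = np.array(imm_rows, dtype=np.float64)      # (groups, n_hosts)
        both_immune = ((Q @ weights) * Q).sum(axis=1)
        w_arr = np.asarray(group_w)
        pdi_total = float(w_arr @ both_immune)
        # subtract pairs where both hosts match only the same position
        for w, buckets in zip(group_w, single_buckets):
            for members in buckets.values():
                if len(members) > 1:
                    block = weights[np.ix_(members, members)]
                    pdi_total -= w * float(block.sum())

    return MetricsResult(
        pdi=float(pdi_total),
        idi=float(idi_total),
        hvi=float(hvi_total),
        max_pdi=max_pdi(n, sigma) if n_strains >= 2 else 0.0,
        n_host_strains=n_strains,
    )
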