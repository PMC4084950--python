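"""Estimate distributed immunity from sequencing-derived observations.

Host strains are reconstructed from the spacer content visible on
individual reads of the CRISPR locus (read truncation hides the leader or
trailer end), and viral strains are enumerated from protospacer/PAM escape
SNP frequencies under the assumption that each mutation arose independently.
The resulting community is scored with the same PDI/IDI/HVI metrics as
simulated populations.

Input tables (TSV):

* reads:   read_id, spacers (comma-joined, leader-end first), has_leader,
           has_trailer, novel (comma-joined 0/1 flags per spacer)
* snps:    snp_id, frequency, escaped_protospacer, fixed (0/1)
* map:     spacer, protospacer
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .community import Community, HostStrain, ViralStrain, normalize_community
from .metrics import MetricsResult, SigmaVariant, compute_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadObservation:
    """Spacer content visible on one sequencing read, leader end first."""

    read_id: str
    spacers: tuple[int, ...]
    has_leader: bool
    has_trailer: bool
    novel: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError(f"read {self.read_id}: empty spacer list")
        if len(self.novel) != len(self.spacers):
            raise ValueError(
                f"read {self.read_id}: novelty flags do not align with spacers"
            )


@dataclass(frozen=True)
class SnpRecord:
    """A phage escape mutation: its read frequency and the protospacer
    (or adjacent PAM) it disrupts."""

    snp_id: str
    frequency: float
    escaped_protospacer: int
    fixed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(
                f"SNP {self.snp_id}: frequency {self.frequency} outside [0, 1]"
            )


@dataclass
class EmpiricalCommunity:
    """A Community plus reconstruction provenance."""

    community: Community
    read_counts: dict[tuple[int, ...], int]
    snp_combos: dict[tuple[str, ...], float]


def filter_reads(reads: list[ReadObservation]) -> list[ReadObservation]:
    """Keep reads informative about newly acquired immunity.

    A read is kept when it shows at least two novel spacers, or at least one
    novel spacer together with an ancestral spacer or the leader sequence.
    """
    kept = []
    for r in reads:
        n_novel = sum(r.novel)
        n_ancestral = len(r.novel) - n_novel
        if n_novel >= 2 or (n_novel >= 1 and (n_ancestral >= 1 or r.has_leader)):
            kept.append(r)
    return kept


def _is_prefix(short: tuple, long: tuple) -> bool:
    return len(short) <= len(long) and long[: len(short)] == short


def _is_suffix(short: tuple, long: tuple) -> bool:
    return len(short) <= len(long) and long[len(long) - len(short):] == short


def _is_sublist(short: tuple, long: tuple) -> bool:
    n = len(short)
    return any(long[i : i + n] == short for i in range(len(long) - n + 1))


def reconstruct_loci(
    reads: list[ReadObservation],
    fixed_spacers: tuple[int, ...] = (),
) -> dict[tuple[int, ...], int]:
    """Complete truncated reads into full CRISPR loci and count support.

    Reads showing both ends define complete loci directly. A truncated read
    is merged into the complete group that extends its visible content — the
    read's spacer list must be a prefix of the group's when only the trailer
    is hidden, a suffix when only the leader is hidden, and a contiguous
    sublist when both are; when several groups extend it the most supported
    wins, with ties broken to the lexicographically smallest completed
    locus. A trailer-hidden read no group extends is completed with the
    spacers fixed in the population; a leader-hidden one stands as observed.
    Grouping as aggressively as possible avoids splitting one true type into
    several, which would overstate how distributed the immunity is.
    Returns completed-locus -> read count.
    """
    complete: Counter = Counter()
    partial: list[ReadObservation] = []
    for r in reads:
        if r.has_trailer and r.has_leader:
            complete[r.spacers] += 1
        else:
            partial.append(r)

    counts: Counter = Counter(complete)
    for r in partial:
        if r.has_leader:
            match_fn = _is_prefix
        elif r.has_trailer:
            match_fn = _is_suffix
        else:
            match_fn = _is_sublist
        candidates = [loc for loc in complete if match_fn(r.spacers, loc)]
        if candidates:
            best_support = max(complete[c] for c in candidates)
            best = sorted(c for c in candidates if complete[c] == best_support)
            if len(best) > 1:
                warnings.warn(
                    f"read {r.read_id}: {len(best)} equally supported "
                    "extensions; choosing lexicographically smallest"
                )
            counts[best[0]] += 1
        elif not r.has_trailer:
            tail = tuple(s for s in fixed_spacers if s not in r.spacers)
            counts[r.spacers + tail] += 1
        else:
            counts[r.spacers] += 1
    return dict(counts)


def host_strains_from_reads(
    reads: list[ReadObservation],
    fixed_spacers: tuple[int, ...] = (),
) -> tuple[list[HostStrain], dict[tuple[int, ...], int]]:
    """Filter, reconstruct, and convert to host strains with read-fraction
    proportions."""
    kept = filter_reads(reads)
    if not kept:
        raise ValueError("no reads pass the filter")
    counts = reconstruct_loci(kept, fixed_spacers)
    total = sum(counts.values())
    strains = [
        HostStrain(i, locus, proportion=c / total)
        for i, (locus, c) in enumerate(sorted(counts.items()))
    ]
    return strains, counts


def viral_strains_from_snps(
    snps: list[SnpRecord],
    protospacer_universe: tuple[int, ...],
) -> tuple[list[ViralStrain], dict[tuple[str, ...], float]]:
    """Enumerate viral strains as independent combinations of escape SNPs.

    Fixed SNPs are carried by every strain. Each subset of the segregating
    SNPs is a strain with proportion prod(f) over carried SNPs times
    prod(1-f) over absent ones. A carried SNP replaces its escaped
    protospacer with a sentinel allele no spacer can match.
    """
    fixed = [s for s in snps if s.fixed or s.frequency >= 1.0]
    segregating = [s for s in snps if not (s.fixed or s.frequency >= 1.0)]

    strains: list[ViralStrain] = []
    combos: dict[tuple[str, ...], float] = {}
    sentinel = -1
    for bits in itertools.product([False, True], repeat=len(segregating)):
        carried = fixed + [s for s, b in zip(segregating, bits) if b]
        prob = 1.0
        for s, b in zip(segregating, bits):
            prob *= s.frequency if b else 1.0 - s.frequency
        if prob <= 0.0:
            continue
        escaped = {s.escaped_protospacer for s in carried}
        proto = []
        for p in protospacer_universe:
            if p in escaped:
                proto.append(sentinel)
                sentinel -= 1
            else:
                proto.append(p)
        name = tuple(s.snp_id for s in carried)
        strains.append(
            ViralStrain(len(strains), tuple(proto), proportion=prob)
        )
        combos[name] = prob
    return strains, combos


def estimate_di(
    reads: list[ReadObservation],
    snps: list[SnpRecord],
    spacer_to_protospacer: dict[int, int],
    fixed_spacers: tuple[int, ...] = (),
    sigma: SigmaVariant = "pairwise",
) -> tuple[MetricsResult, EmpiricalCommunity]:
    """Full pipeline: reads + SNP table + spacer map -> DI metrics.

    A host spacer matches a viral strain iff its target protospacer is
    present and un-escaped there; spacers with no protospacer annotation are
    matchless (logged).
    """
    host_raw, counts = host_strains_from_reads(reads, fixed_spacers)
    universe = tuple(sorted(set(spacer_to_protospacer.values())))
    viral_raw, combos = viral_strains_from_snps(snps, universe)

    unmapped_sentinel = -10_000_000
    mapped_hosts = []
    for h in host_raw:
        mapped = []
        for sp in h.spacers:
            if sp in spacer_to_protospacer:
                target = spacer_to_protospacer[sp]
                # two spacers targeting the same protospacer confer one match
                if target not in mapped:
                    mapped.append(target)
            else:
                logger.info("spacer %s has no protospacer annotation; matchless", sp)
                unmapped_sentinel -= 1
                mapped.append(unmapped_sentinel)
        mapped_hosts.append(
            HostStrain(h.strain_id, tuple(mapped), proportion=h.proportion)
        )

    community = normalize_community(mapped_hosts, viral_raw)
    result = compute_metrics(community, sigma)
    return result, EmpiricalCommunity(community, counts, combos)


# -- table IO -------------------------------------------------------------


def reads_from_table(df: pd.DataFrame) -> list[ReadObservation]:
    reads = []
    for _, row in df.iterrows():
        spacers = tuple(int(s) for s in str(row["spacers"]).split(","))
        novel = tuple(bool(int(b)) for b in str(row["novel"]).split(","))
        reads.append(
            ReadObservation(
                read_id=str(row["read_id"]),
                spacers=spacers,
                has_leader=bool(int(row["has_leader"])),
                has_trailer=bool(int(row["has_trailer"])),
                novel=novel,
            )
        )
    return reads


def snps_from_table(df: pd.DataFrame) -> list[SnpRecord]:
    return [
        SnpRecord(
            snp_id=str(row["snp_id"]),
            frequency=float(row["frequency"]),
            escaped_protospacer=int(row["escaped_protospacer"]),
            fixed=bool(int(row.get("fixed", 0))),
        )
        for _, row in df.iterrows()
    ]
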