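"""Serialization of trajectories, communities and summary tables.

Everything is TSV or JSON for diffability. Trajectory TSV columns:
time, strain_id, side, density; the strain registry (genotype per strain
id) travels in a companion JSON file. Numeric fields round-trip at full
precision (repr-level floats).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .community import Community
from .simulator import SimParams, Snapshot, TrajectoryRecord


def provenance_header(seed=None, config: dict | None = None) -> str:
    """Comment lines recording version, config hash and seed."""
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    return (
        f"# crispr-di {__version__}\n"
        f"# config_hash: {cfg_hash}\n"
        f"# seed: {seed}\n"
    )


def write_trajectory(traj: TrajectoryRecord, path: str | Path,
                     seed=None) -> None:
    """Write a trajectory as TSV plus a <path>.registry.json sidecar."""
    path = Path(path)
    rows = []
    for snap in traj.snapshots:
        for sid, d in snap.host_density.items():
            rows.append((snap.time, sid, "host", d))
        for sid, d in snap.viral_density.items():
            rows.append((snap.time, sid, "virus", d))
    df = pd.DataFrame(rows, columns=["time", "strain_id", "side", "density"])
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, traj.params.to_dict()))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    registry = {
        "params": traj.params.to_dict(),
        "outcome": traj.outcome,
        "locus_filled_in_window": traj.locus_filled_in_window,
        "filled_before_end": traj.filled_before_end,
        "n_acquisitions": traj.n_acquisitions,
        "n_mutations": traj.n_mutations,
        "hosts": {str(k): list(v) for k, v in traj.host_registry.items()},
        "viruses": {str(k): list(v) for k, v in traj.viral_registry.items()},
        "snapshot_loci_full": [s.all_loci_full for s in traj.snapshots],
    }
    path.with_suffix(path.suffix + ".registry.json").write_text(
        json.dumps(registry)
    )


def read_trajectory(path: str | Path) -> TrajectoryRecord:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    reg_path = path.with_suffix(path.suffix + ".registry.json")
    if not reg_path.exists():
        raise FileNotFoundError(f"missing registry sidecar: {reg_path}")
    registry = json.loads(reg_path.read_text())
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse trajectory TSV {path}: {exc}") from exc
    required = {"time", "strain_id", "side", "density"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )

    params = SimParams(**registry["params"])
    loci_full = registry["snapshot_loci_full"]
    snapshots = []
    for i, (t, group) in enumerate(df.groupby("time", sort=True)):
        hosts = group[group["side"] == "host"]
        viruses = group[group["side"] == "virus"]
        snapshots.append(
            Snapshot(
                time=float(t),
                host_density=dict(
                    zip(hosts["strain_id"].astype(int), hosts["density"])
                ),
                viral_density=dict(
                    zip(viruses["strain_id"].astype(int), viruses["density"])
                ),
                all_loci_full=bool(loci_full[i]) if i < len(loci_full) else False,
            )
        )
    return TrajectoryRecord(
        params=params,
        snapshots=snapshots,
        host_registry={int(k): tuple(v) for k, v in registry["hosts"].items()},
        viral_registry={int(k): tuple(v) for k, v in registry["viruses"].items()},
        outcome=registry["outcome"],
        locus_filled_in_window=registry["locus_filled_in_window"],
        filled_before_end=registry["filled_before_end"],
        n_acquisitions=registry["n_acquisitions"],
        n_mutations=registry["n_mutations"],
    )


def write_community(community: Community, path: str | Path) -> None:
    Path(path).write_text(community.to_json(indent=1))


def read_community(path: str | Path) -> Community:
    return Community.from_json(Path(path).read_text())


def community_tsv(community: Community) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-file TSV form: one row per strain, spacers comma-joined."""
    hosts = pd.DataFrame(
        {
            "id": [h.strain_id for h in community.hosts],
            "spacers": [",".join(map(str, h.spacers)) for h in community.hosts],
            "proportion": [h.proportion for h in community.hosts],
        }
    )
    viruses = pd.DataFrame(
        {
            "id": [v.strain_id for v in community.viruses],
            "protospacers": [
                ",".join(map(str, v.protospacers)) for v in community.viruses
            ],
            "proportion": [v.proportion for v in community.viruses],
        }
    )
    return hosts, viruses


def community_from_tsv(hosts: pd.DataFrame, viruses: pd.DataFrame) -> Community:
    from .community import HostStrain, ViralStrain

    def _split(s) -> tuple[int, ...]:
        s = str(s).strip()
        return tuple(int(x) for x in s.split(",")) if s and s != "nan" else ()

    hs = tuple(
        HostStrain(int(r["id"]), _split(r["spacers"]), float(r["proportion"]))
        for _, r in hosts.iterrows()
    )
    vs = tuple(
        ViralStrain(int(r["id"]), _split(r["protospacers"]), float(r["proportion"]))
        for _, r in viruses.iterrows()
    )
    return Community(hs, vs)
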