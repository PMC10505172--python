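"""Aggregation of docked peptide:chemokine pose ensembles.

Rather than trusting a single top-ranked docking pose, an ensemble of poses
is reduced to a per-residue weighted proximity profile on the target chain:
each pose contributes its weight (model confidence for AlphaFold-Multimer,
negated free energy for AutoDock CrankPep, 1 for NMR-restrained poses) to
every target residue with any atom within the interface cutoff (5 A,
all-atom) of the binder chain, and the summed profile is normalised so its
maximum is 100.  A complementary contact profile counts cross-chain atom
pairs per binder residue, averaged over poses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "PoseModel",
    "ProximityProfile",
    "ContactProfile",
    "load_pose",
    "load_pose_set",
    "interface_residues",
    "pose_weight",
    "weighted_proximity",
    "contact_profile",
    "map_profile_to_alignment",
]

SOURCES = ("AF_MULTIMER", "ADCP", "NMR_HADDOCK")
DEFAULT_CUTOFF = 5.0


@dataclass
class PoseModel:
    """One docked two-chain pose with its ranking score."""

    pose_id: str
    source: str
    atoms: struc.AtomArray
    target_chain: str
    binder_chain: str
    raw_score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown pose source {self.source!r}")
        chains = set(np.unique(self.atoms.chain_id))
        for chain in (self.target_chain, self.binder_chain):
            if chain not in chains:
                raise ValueError(f"pose {self.pose_id!r}: chain {chain!r} absent")
        if not np.all(np.isfinite(self.atoms.coord)):
            bad = self.atoms[~np.all(np.isfinite(self.atoms.coord), axis=-1)]
            raise ValueError(
                f"pose {self.pose_id!r}: non-finite coordinates at residue "
                f"{bad.chain_id[0]}/{bad.res_id[0]}"
            )

    def chain(self, chain_id: str) -> struc.AtomArray:
        return self.atoms[self.atoms.chain_id == chain_id]

    def residue_ids(self, chain_id: str) -> np.ndarray:
        return np.unique(self.chain(chain_id).res_id)


def load_pose(
    path,
    pose_id: str,
    source: str,
    target_chain: str,
    binder_chain: str,
    raw_score: float | None = None,
    model: int = 1,
) -> PoseModel:
    """Read one pose from a PDB file (MODEL ``model`` if multi-model)."""
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=model)
    return PoseModel(pose_id, source, atoms, target_chain, binder_chain, raw_score)


def load_pose_set(
    poses_dir, scores_tsv, target_chain: str, binder_chain: str
) -> list[PoseModel]:
    """Load poses listed in a sidecar TSV (pose_id, source, raw_score).

    Pose files are ``<pose_id>.pdb`` inside ``poses_dir``.
    """
    scores = pd.read_csv(scores_tsv, sep="\t")
    poses = []
    for row in scores.itertuples(index=False):
        raw = None if pd.isna(row.raw_score) else float(row.raw_score)
        poses.append(
            load_pose(
                Path(poses_dir) / f"{row.pose_id}.pdb",
                str(row.pose_id),
                str(row.source),
                target_chain,
                binder_chain,
                raw,
            )
        )
    return poses


def _cross_chain_pairs(pose: PoseModel, cutoff: float):
    """Atom index pairs (target_atom, binder_atom) within ``cutoff``."""
    target = pose.chain(pose.target_chain)
    binder = pose.chain(pose.binder_chain)
    tree_t = cKDTree(target.coord)
    tree_b = cKDTree(binder.coord)
    pairs = tree_t.query_ball_tree(tree_b, r=cutoff)
    return target, binder, pairs


def interface_residues(
    pose: PoseModel, cutoff: float = DEFAULT_CUTOFF
) -> set[tuple[str, int]]:
    """Residues with any atom within ``cutoff`` of any atom of the other chain."""
    target, binder, pairs = _cross_chain_pairs(pose, cutoff)
    out: set[tuple[str, int]] = set()
    for ti, blist in enumerate(pairs):
        if blist:
            out.add((pose.target_chain, int(target.res_id[ti])))
            for bi in blist:
                out.add((pose.binder_chain, int(binder.res_id[bi])))
    return out


def pose_weight(pose: PoseModel) -> float:
    """Non-negative ranking weight of a pose.

    AlphaFold-Multimer: the confidence score itself.  ADCP: negated free
    energy floored at 0 (lower energy => larger weight).  NMR-restrained
    (HADDOCK) poses carry no score and are weighted equally (1).
    """
    if pose.source == "NMR_HADDOCK":
        return 1.0
    if pose.raw_score is None:
        raise ValueError(f"pose {pose.pose_id!r} ({pose.source}) has no raw score")
    if pose.source == "AF_MULTIMER":
        return float(pose.raw_score)
    return max(0.0, -float(pose.raw_score))


@dataclass
class ProximityProfile:
    """Per-target-residue weighted proximity scores, max normalised to 100."""

    scores: dict[int, float]  # target residue id -> score in [0, 100]
    residue_names: dict[int, str] | None = None

    def to_frame(self) -> pd.DataFrame:
        res_ids = sorted(self.scores)
        names = self.residue_names or {}
        return pd.DataFrame(
            {
                "res_id": res_ids,
                "res_name": [names.get(r, "") for r in res_ids],
                "weighted_score": [self.scores[r] for r in res_ids],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def weighted_proximity(
    poses: list[PoseModel], cutoff: float = DEFAULT_CUTOFF
) -> ProximityProfile:
    """Pose-weight-summed interface membership per target residue.

    score[i] = sum over poses of pose_weight(pose) if residue i is at the
    interface in that pose; the profile is then scaled so its maximum is 100.
    An ensemble with no interface residue anywhere returns all zeros.
    """
    if not poses:
        raise ValueError("need at least one pose")
    ref_ids = poses[0].residue_ids(poses[0].target_chain)
    scores = {int(r): 0.0 for r in ref_ids}
    names: dict[int, str] = {}
    target0 = poses[0].chain(poses[0].target_chain)
    for rid in ref_ids:
        names[int(rid)] = str(target0.res_name[target0.res_id == rid][0])
    for pose in poses:
        ids = pose.residue_ids(pose.target_chain)
        if not np.array_equal(ids, ref_ids):
            raise ValueError(
                f"pose {pose.pose_id!r}: target residue numbering differs "
                "from the first pose"
            )
        w = pose_weight(pose)
        for chain, rid in interface_residues(pose, cutoff):
            if chain == pose.target_chain:
                scores[rid] += w
    max_score = max(scores.values())
    if max_score <= 0:
        import warnings

        warnings.warn("no interface residues in any pose; all-zero profile", stacklevel=2)
        return ProximityProfile(scores, names)
    factor = 100.0 / max_score
    return ProximityProfile({r: s * factor for r, s in scores.items()}, names)


@dataclass
class ContactProfile:
    """Average number of proximal cross-chain contacts per binder residue."""

    contacts: dict[int, float]  # binder residue id -> mean atom-pair count

    def to_frame(self) -> pd.DataFrame:
        res_ids = sorted(self.contacts)
        return pd.DataFrame(
            {"res_id": res_ids, "mean_contacts": [self.contacts[r] for r in res_ids]}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def contact_profile(
    poses: list[PoseModel],
    cutoff: float = DEFAULT_CUTOFF,
    count_residue_pairs: bool = False,
) -> ContactProfile:
    """Proximal-contact counts per binder residue, averaged over poses.

    By default counts cross-chain atom pairs within ``cutoff``; with
    ``count_residue_pairs`` each contacting target residue counts once.
    """
    if not poses:
        raise ValueError("need at least one pose")
    totals: dict[int, float] = {}
    for pose in poses:
        for rid in pose.residue_ids(pose.binder_chain):
            totals.setdefault(int(rid), 0.0)
        target, binder, pairs = _cross_chain_pairs(pose, cutoff)
        for ti, blist in enumerate(pairs):
            for bi in blist:
                rid = int(binder.res_id[bi])
                if count_residue_pairs:
                    continue
                totals[rid] = totals.get(rid, 0.0) + 1.0
        if count_residue_pairs:
            per_res: dict[int, set[int]] = {}
            for ti, blist in enumerate(pairs):
                for bi in blist:
                    per_res.setdefault(int(binder.res_id[bi]), set()).add(
                        int(target.res_id[ti])
                    )
            for rid, tset in per_res.items():
                totals[rid] = totals.get(rid, 0.0) + len(tset)
    n = len(poses)
    return ContactProfile({rid: v / n for rid, v in totals.items()})


def map_profile_to_alignment(
    profile: ProximityProfile, gapped_sequence: str, target_sequence: str,
    gap_chars: str = "-.",
) -> list[float | None]:
    """Carry per-residue scores onto the columns of a gapped alignment row.

    ``gapped_sequence`` with gaps removed must equal ``target_sequence``
    (one-letter codes, one per profile residue in ascending residue order);
    gap columns map to None.
    """
    ungapped = "".join(c for c in gapped_sequence if c not in gap_chars)
    if ungapped != target_sequence:
        for i, (a, b) in enumerate(zip(ungapped, target_sequence)):
            if a != b:
                raise ValueError(
                    f"alignment/profile sequence mismatch at ungapped position "
                    f"{i + 1}: {a!r} != {b!r}"
                )
        raise ValueError(
            f"alignment/profile length mismatch: {len(ungapped)} vs "
            f"{len(target_sequence)}"
        )
    res_ids = sorted(profile.scores)
    if len(res_ids) != len(target_sequence):
        raise ValueError("profile length does not match target sequence")
    out: list[float | None] = []
    it = iter(res_ids)
    for col in gapped_sequence:
        if col in gap_chars:
            out.append(None)
        else:
            out.append(profile.scores[next(it)])
    return out
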