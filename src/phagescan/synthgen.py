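"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates a multi-round phage-display selection: Cys-rich parent
proteins carry one planted chemokine-binding interval each; a tiled peptide
library derives latent relative affinities from overlap with that interval
(attenuated for Cys-mutant tiles); panning is deterministic proportional
enrichment over rounds with multinomial sequencing noise at finite read
depth; reads wrap each 48-nt insert in the demultiplexing and constant-region
amplicon context.  Synthetic docked pose ensembles place a binder chain
against a designated epitope with seeded jitter.  Every stage draws from a
named substream of one master seed, and ground truth is returned alongside
the data so recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .library_design import (
    AMINO_ACIDS,
    DesignedLibrary,
    ProteinRecord,
)
from .ngs_processing import CONST3, CONST5, DEMUX_FWD, DEMUX_REV, CountTable, _revcomp
from .structure_proximity import PoseModel

__all__ = [
    "SyntheticTruth",
    "substream",
    "make_parents",
    "assign_affinities",
    "assign_mutscan_affinities",
    "simulate_panning",
    "simulate_experiment",
    "emit_fastq",
    "make_poses",
]

LN2 = float(np.log(2.0))
#: The conserved epitope motifs of the exemplar peptide, optionally embedded
#: in planted binding intervals.
EPITOPE_MOTIF_N = "EEDDY"
EPITOPE_MOTIF_C = "LTCYF"


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    parents: list[ProteinRecord] = field(default_factory=list)
    #: (parent_id, chemokine_id) -> planted binding interval, 1-based inclusive
    binding_intervals: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    #: (peptide_id, chemokine_id) -> latent relative affinity a > 0
    affinities: dict[tuple[str, str], float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def interval(self, parent_id: str, chemokine_id: str) -> tuple[int, int]:
        return self.binding_intervals[(parent_id, chemokine_id)]


def make_parents(
    n: int = 3,
    length_range: tuple[int, int] = (90, 130),
    cys_count_range: tuple[int, int] = (6, 10),
    seed: int = 0,
    chemokines: tuple[str, ...] = ("CK1", "CK2", "CK3"),
    interval_length: int = 18,
    embed_motifs: bool = True,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Evasin-like parent proteins with one planted binding interval each.

    Sequences are Cys-rich with the requested exact Cys counts; the planted
    interval (>= 16 residues) optionally embeds the conserved EEDDY / LTCYF
    epitope motifs.  The interval is reused for every chemokine of the
    simulated panel (a promiscuously binding region).
    """
    if length_range[0] < 16 or interval_length < 16:
        raise ValueError("parent and planted interval must be >= 16 residues")
    if cys_count_range[1] > length_range[0] - interval_length:
        raise ValueError("infeasible Cys count for the requested lengths")
    rng = substream(seed, "parents")
    non_cys = [aa for aa in AMINO_ACIDS if aa != "C"]
    parents: list[ProteinRecord] = []
    truth = SyntheticTruth(
        params={
            "n": n,
            "length_range": length_range,
            "cys_count_range": cys_count_range,
            "interval_length": interval_length,
            "seed": seed,
        }
    )
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        n_cys = int(rng.integers(cys_count_range[0], cys_count_range[1] + 1))
        start = int(rng.integers(1, length - interval_length + 2))
        seq = [str(rng.choice(non_cys)) for _ in range(length)]
        if embed_motifs:
            motif = EPITOPE_MOTIF_N + "".join(
                str(rng.choice(non_cys))
                for _ in range(interval_length - len(EPITOPE_MOTIF_N) - len(EPITOPE_MOTIF_C))
            ) + EPITOPE_MOTIF_C
            seq[start - 1 : start - 1 + interval_length] = list(motif)
        # place Cys outside the planted interval so its motif stays intact,
        # except the one Cys the C-terminal motif itself carries
        n_motif_cys = seq[start - 1 : start - 1 + interval_length].count("C")
        outside = [
            j for j in range(length) if not (start - 1 <= j < start - 1 + interval_length)
        ]
        cys_sites = rng.choice(outside, size=max(0, n_cys - n_motif_cys), replace=False)
        for j in cys_sites:
            seq[int(j)] = "C"
        parent = ProteinRecord(id=f"EVS{i + 1}", sequence="".join(seq))
        parents.append(parent)
        interval = (start, start + interval_length - 1)
        for ck in chemokines:
            truth.binding_intervals[(parent.id, ck)] = interval
    truth.parents = parents
    return parents, truth


def _overlap_fraction(tile_start: int, tile_len: int, interval: tuple[int, int]) -> float:
    lo = max(tile_start, interval[0])
    hi = min(tile_start + tile_len - 1, interval[1])
    return max(0, hi - lo + 1) / tile_len


def assign_affinities(
    library: DesignedLibrary,
    truth: SyntheticTruth,
    alpha: float = 6 * LN2,
    beta: float = 2 * LN2,
    sigma: float = 0.5,
    seed: int = 0,
) -> SyntheticTruth:
    """Latent relative affinities a(peptide, chemokine) > 0.

    log a = alpha * overlap_fraction(tile, planted interval) + beta *
    cys_intact + eps with eps ~ N(0, sigma), seeded.  Cys->Ala/Ser variants
    have cys_intact = 0, everything else 1.  Defaults give a 2^6-fold affinity
    ratio between full-overlap and non-overlapping tiles and a 2^2-fold
    wild-type advantage over Cys-mutant tiles.
    """
    rng = substream(seed, "affinities")
    chemokines = sorted({ck for (_, ck) in truth.binding_intervals})
    truth.params.update({"alpha": alpha, "beta": beta, "sigma": sigma})
    for member in library.members:
        cys_intact = 0.0 if member.variant_class in ("CYS_TO_ALA", "CYS_TO_SER") else 1.0
        for ck in chemokines:
            interval = truth.binding_intervals.get((member.parent_id, ck))
            overlap = (
                _overlap_fraction(member.start, len(member.sequence), interval)
                if interval
                else 0.0
            )
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            log_a = alpha * overlap + beta * cys_intact + eps
            truth.affinities[(member.peptide_id, ck)] = float(np.exp(log_a))
    return truth


def assign_mutscan_affinities(
    nnk_library: DesignedLibrary,
    key_positions: tuple[int, ...],
    chemokines: tuple[str, ...],
    penalty: float = 2 * LN2,
    sigma: float = 0.5,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Latent affinities for a saturation-mutagenesis library.

    Substitutions at ``key_positions`` are penalised: log a = -penalty for a
    non-wild-type residue at a key position, 0 elsewhere, plus N(0, sigma)
    noise.  The parental peptide keeps log a = 0 (+ noise).
    """
    rng = substream(seed, "mutscan-affinities")
    out: dict[tuple[str, str], float] = {}
    key = set(key_positions)
    for member in nnk_library.members:
        if member.variant_class == "POINT_MUTANT":
            pos = int(member.mutation_label[1:-1])
            log_a = -penalty if pos in key else 0.0
        else:
            log_a = 0.0
        for ck in chemokines:
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            out[(member.peptide_id, ck)] = float(np.exp(log_a + eps))
    return out


def simulate_panning(
    library: DesignedLibrary,
    affinities: dict[str, float],
    rounds: int = 3,
    depth: int = 200_000,
    seed: int = 0,
    sample_id: str = "output",
) -> tuple[CountTable, CountTable]:
    """Multi-round affinity-weighted panning of one chemokine selection.

    ``affinities`` maps peptide_id -> a > 0.  Pool frequencies update
    deterministically (p <- p * a, renormalised) each round; observation
    noise enters only through multinomial sequencing draws of ``depth`` reads
    for the input pool and the final round.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = substream(seed, f"panning:{sample_id}")
    peptide_ids = [m.peptide_id for m in library.members]
    a = np.array([affinities[pid] for pid in peptide_ids], dtype=float)
    if np.any(a <= 0):
        raise ValueError("affinities must be strictly positive")
    p = np.full(len(peptide_ids), 1.0 / len(peptide_ids))
    input_counts = rng.multinomial(depth, p)
    for _ in range(rounds):
        p = p * a
        p /= p.sum()
    output_counts = rng.multinomial(depth, p)
    make = lambda counts, sid: CountTable(
        sample_id=sid,
        counts={pid: int(c) for pid, c in zip(peptide_ids, counts) if c > 0},
    )
    return make(input_counts, "input"), make(output_counts, sample_id)


def simulate_experiment(
    library: DesignedLibrary,
    truth: SyntheticTruth,
    rounds: int = 3,
    depth: int = 200_000,
    seed: int = 0,
) -> tuple[CountTable, dict[str, CountTable]]:
    """One input sample plus one selected output sample per chemokine."""
    chemokines = sorted({ck for (_, ck) in truth.binding_intervals})
    rng = substream(seed, "experiment-input")
    peptide_ids = [m.peptide_id for m in library.members]
    p0 = np.full(len(peptide_ids), 1.0 / len(peptide_ids))
    input_counts = rng.multinomial(depth, p0)
    input_table = CountTable(
        sample_id="input",
        counts={pid: int(c) for pid, c in zip(peptide_ids, input_counts) if c > 0},
    )
    outputs: dict[str, CountTable] = {}
    for ck in chemokines:
        aff = {pid: truth.affinities[(pid, ck)] for pid in peptide_ids}
        _, out = simulate_panning(
            library, aff, rounds=rounds, depth=depth,
            seed=seed, sample_id=ck,
        )
        outputs[ck] = out
    return input_table, outputs


def emit_fastq(
    table: CountTable,
    library: DesignedLibrary,
    fastq1,
    fastq2,
    read_length: int = 250,
    error_rate: float = 0.0,
    seed: int = 0,
) -> None:
    """Write one amplicon read pair per counted molecule.

    Each insert is embedded in the demux + constant-region context; mate 2 is
    the reverse complement of the amplicon.  Substitution errors are applied
    per base at ``error_rate``, seeded.  With ``error_rate=0`` the output
    round-trips exactly through the counting stage.
    """
    inserts = {o.peptide_id: o.insert_nt for o in library.oligos}
    amplicon_len = len(DEMUX_FWD) + len(CONST5) + 48 + len(CONST3) + len(DEMUX_REV)
    if read_length < amplicon_len:
        raise ValueError(
            f"read length {read_length} does not span the {amplicon_len}-nt amplicon"
        )
    rng = substream(seed, f"reads:{table.sample_id}")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = "I" * amplicon_len

    def mutate(seq: str) -> str:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
        return arr.tobytes().decode()

    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        n = 0
        for pid in sorted(table.counts):
            amplicon = DEMUX_FWD + CONST5 + inserts[pid] + CONST3 + DEMUX_REV
            for _ in range(table.counts[pid]):
                n += 1
                r1 = mutate(amplicon) if error_rate > 0 else amplicon
                r2 = mutate(_revcomp(amplicon)) if error_rate > 0 else _revcomp(amplicon)
                rid = f"{table.sample_id}.{n}"
                f1.write(f"@{rid}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{qual}\n")


def make_poses(
    target_size: int = 40,
    binder_length: int = 16,
    epitope: tuple[int, ...] = tuple(range(10, 20)),
    n_poses: int = 5,
    jitter: float = 0.3,
    seed: int = 0,
    source: str = "AF_MULTIMER",
    target_chain: str = "A",
    binder_chain: str = "B",
) -> tuple[list[PoseModel], dict]:
    """Synthetic docked pose ensemble around a designated epitope.

    The target chain is an extended backbone (Calpha every 3.8 A plus a
    pseudo side-chain atom); the binder chain sits 4 A off the epitope
    residues.  Each pose is rigidly displaced by a seeded N(0, jitter)
    translation, and its raw score improves as the displacement shrinks, so
    low-jitter ensembles recover the epitope as the top proximity region.
    """
    if n_poses < 1:
        raise ValueError("need at least one pose")
    epitope = tuple(sorted(epitope))
    if epitope[0] < 1 or epitope[-1] > target_size:
        raise ValueError("epitope outside the target chain")
    rng = substream(seed, "poses")
    spacing = 3.8

    target_coords = []
    for i in range(target_size):
        target_coords.append([spacing * i, 0.0, 0.0])        # CA
        target_coords.append([spacing * i, 1.5, 0.0])        # pseudo side chain
    target_coords = np.array(target_coords)

    binder_base = np.array(
        [
            [spacing * (epitope[j % len(epitope)] - 1), 0.0, 4.0]
            for j in range(binder_length)
        ]
    )

    poses: list[PoseModel] = []
    for p in range(n_poses):
        shift = rng.normal(0.0, jitter, size=3) if jitter > 0 else np.zeros(3)
        displacement = float(np.linalg.norm(shift))
        if source == "AF_MULTIMER":
            score = max(0.1, 0.95 - 0.3 * displacement)
        elif source == "ADCP":
            score = -(20.0 - 5.0 * displacement)
        else:
            score = None
        n_target_atoms = len(target_coords)
        n_atoms = n_target_atoms + binder_length
        atoms = struc.AtomArray(n_atoms)
        atoms.coord = np.vstack([target_coords, binder_base + shift]).astype(np.float32)
        atoms.chain_id = np.array(
            [target_chain] * n_target_atoms + [binder_chain] * binder_length
        )
        atoms.res_id = np.array(
            [i // 2 + 1 for i in range(n_target_atoms)]
            + [j + 1 for j in range(binder_length)]
        )
        atoms.res_name = np.array(["ALA"] * n_target_atoms + ["GLY"] * binder_length)
        atoms.atom_name = np.array(
            ["CA" if i % 2 == 0 else "CB" for i in range(n_target_atoms)]
            + ["CA"] * binder_length
        )
        atoms.element = np.array(["C"] * n_atoms)
        poses.append(
            PoseModel(
                pose_id=f"pose{p + 1}",
                source=source,
                atoms=atoms,
                target_chain=target_chain,
                binder_chain=binder_chain,
                raw_score=score,
            )
        )
    truth = {"epitope": epitope, "jitter": jitter, "seed": seed, "source": source}
    return poses, truth


def write_poses(poses: list[PoseModel], out_dir, scores_tsv) -> None:
    """Write one PDB per pose plus the sidecar score table."""
    import pandas as pd
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pose in poses:
        pdb_file = pdb.PDBFile()
        pdb_file.set_structure(pose.atoms)
        pdb_file.write(str(out_dir / f"{pose.pose_id}.pdb"))
        rows.append(
            {
                "pose_id": pose.pose_id,
                "source": pose.source,
                "raw_score": pose.raw_score if pose.raw_score is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(scores_tsv, sep="\t", index=False)
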