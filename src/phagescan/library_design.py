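"""Design of tiled hexadecapeptide phage-display libraries.

A parent protein (mature sequence, signal peptide removed) is deconstructed
into overlapping 16-residue tiles at single-residue resolution.  Because
unpaired cysteines can compromise display, each Cys-containing tile is
accompanied by two variants in which every Cys is replaced by Ala or by Ser.
Saturation (NNK) mutant libraries and maximally-scrambled negative controls
are designed at the protein level.  Each peptide is back-translated with a
fixed one-codon-per-amino-acid table into a 48-nt insert and wrapped with the
two cloning arms to give an 81-mer oligonucleotide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "ARM5",
    "ARM3",
    "ECOLI_CODONS",
    "ProteinRecord",
    "PeptideVariant",
    "OligoRecord",
    "DesignedLibrary",
    "tile_peptides",
    "make_cys_variants",
    "encode_insert",
    "build_oligo",
    "nnk_mutant_library",
    "osa_distance",
    "design_scrambled",
    "build_library",
]

#: 5' and 3' cloning arms flanking every 48-nt insert (18 + 48 + 15 = 81 nt).
ARM5 = "GCAGCCTCTTCATCTGGC"
ARM3 = "GGTGGAGGATCCGGA"

WINDOW = 16

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Most-used E. coli codon per amino acid; deterministic, stop-free.
ECOLI_CODONS = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class ProteinRecord:
    """A mature parent protein sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideVariant:
    """A designed library member (one 16-mer peptide)."""

    peptide_id: str
    parent_id: str
    start: int  # 1-based position of the first residue in the parent
    sequence: str
    variant_class: str  # WT | CYS_TO_ALA | CYS_TO_SER | POINT_MUTANT | SCRAMBLED
    mutation_label: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW:
            raise ValueError(
                f"peptide {self.peptide_id!r}: length {len(self.sequence)} != {WINDOW}"
            )


@dataclass(frozen=True)
class OligoRecord:
    peptide_id: str
    insert_nt: str
    oligo_nt: str


@dataclass
class DesignedLibrary:
    """A collection of peptide variants with their oligonucleotides."""

    members: list[PeptideVariant] = field(default_factory=list)
    oligos: list[OligoRecord] = field(default_factory=list)

    @property
    def distinct_peptides(self) -> set[str]:
        return {m.sequence for m in self.members}

    def by_id(self, peptide_id: str) -> PeptideVariant:
        for m in self.members:
            if m.peptide_id == peptide_id:
                return m
        raise KeyError(peptide_id)

    def peptide_index(self) -> dict[str, str]:
        """Map 16-mer sequence -> peptide_id (first occurrence wins)."""
        idx: dict[str, str] = {}
        for m in self.members:
            idx.setdefault(m.sequence, m.peptide_id)
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peptide_id": m.peptide_id,
                    "parent_id": m.parent_id,
                    "start": m.start,
                    "sequence": m.sequence,
                    "variant_class": m.variant_class,
                    "mutation_label": m.mutation_label,
                }
                for m in self.members
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignedLibrary":
        lib = cls()
        for row in df.itertuples(index=False):
            lib.add(
                PeptideVariant(
                    peptide_id=str(row.peptide_id),
                    parent_id=str(row.parent_id),
                    start=int(row.start),
                    sequence=str(row.sequence),
                    variant_class=str(row.variant_class),
                    mutation_label="" if pd.isna(row.mutation_label) else str(row.mutation_label),
                )
            )
        return lib

    @classmethod
    def read_tsv(cls, path) -> "DesignedLibrary":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def add(self, member: PeptideVariant, codon_map: dict[str, str] | None = None) -> None:
        self.members.append(member)
        insert = encode_insert(member.sequence, codon_map or ECOLI_CODONS)
        self.oligos.append(OligoRecord(member.peptide_id, insert, build_oligo(insert)))

    def write_oligo_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for o in self.oligos:
                fh.write(f">{o.peptide_id}\n{o.oligo_nt}\n")


def tile_peptides(protein: ProteinRecord, window: int = WINDOW) -> list[PeptideVariant]:
    """All overlapping ``window``-mers of ``protein`` at single-residue offsets.

    Returns L - window + 1 wild-type tiles with 1-based ``start`` coordinates.
    """
    seq = protein.sequence
    if len(seq) < window:
        raise ValueError(
            f"protein {protein.id!r} is shorter ({len(seq)}) than the "
            f"tiling window ({window})"
        )
    return [
        PeptideVariant(
            peptide_id=f"{protein.id}_{start}",
            parent_id=protein.id,
            start=start,
            sequence=seq[start - 1 : start - 1 + window],
            variant_class="WT",
        )
        for start in range(1, len(seq) - window + 2)
    ]


def make_cys_variants(peptide: PeptideVariant) -> list[PeptideVariant]:
    """Cys-free companions of a wild-type tile.

    All Cys residues of the tile are replaced simultaneously, once with Ala
    and once with Ser.  Tiles without Cys yield nothing.
    """
    if peptide.variant_class != "WT":
        raise ValueError("Cys variants are designed from WT tiles only")
    cys_pos = [i for i, aa in enumerate(peptide.sequence) if aa == "C"]
    if not cys_pos:
        return []
    out = []
    for repl, tag in (("A", "CYS_TO_ALA"), ("S", "CYS_TO_SER")):
        seq = peptide.sequence.replace("C", repl)
        label = "+".join(f"C{i + 1}{repl}" for i in cys_pos)
        out.append(
            PeptideVariant(
                peptide_id=f"{peptide.peptide_id}_{tag.lower()}",
                parent_id=peptide.parent_id,
                start=peptide.start,
                sequence=seq,
                variant_class=tag,
                mutation_label=label,
            )
        )
    return out


def encode_insert(peptide: str | PeptideVariant, codon_map: dict[str, str] | None = None) -> str:
    """Back-translate a 16-mer into its 48-nt insert using ``codon_map``."""
    seq = peptide.sequence if isinstance(peptide, PeptideVariant) else peptide
    codon_map = codon_map or ECOLI_CODONS
    parts = []
    for aa in seq:
        try:
            codon = codon_map[aa]
        except KeyError:
            raise KeyError(f"no codon assigned for residue {aa!r}") from None
        if str(Seq(codon).translate()) == "*":
            raise ValueError(f"codon {codon!r} for {aa!r} is a stop codon")
        parts.append(codon)
    insert = "".join(parts)
    assert str(Seq(insert).translate()) == seq
    return insert


def build_oligo(insert: str) -> str:
    """Wrap a 48-nt insert with the two cloning arms (81-mer)."""
    if len(insert) != 48:
        raise ValueError(f"insert must be 48 nt, got {len(insert)}")
    return ARM5 + insert + ARM3


def _nnk_amino_acids() -> set[str]:
    """Amino acids encodable by an NNK codon (stop excluded)."""
    aas = set()
    for n1, n2, k in itertools.product("ACGT", "ACGT", "GT"):
        aa = str(Seq(n1 + n2 + k).translate())
        if aa != "*":
            aas.add(aa)
    return aas


NNK_AMINO_ACIDS = _nnk_amino_acids()  # all 20; TAG (amber) is the only NNK stop


def nnk_mutant_library(peptide: PeptideVariant) -> list[PeptideVariant]:
    """Protein-level NNK saturation scan of a 16-mer.

    Every position is replaced by each NNK-encodable amino acid; the parental
    identity at each position collapses onto the wild-type peptide, and point
    mutants are deduplicated by sequence.  The parental peptide itself is
    included (it is part of the displayed library and is the control in the
    downstream statistics).
    """
    out = [peptide]
    seen = {peptide.sequence}
    for pos in range(WINDOW):
        wt_aa = peptide.sequence[pos]
        for aa in sorted(NNK_AMINO_ACIDS):
            if aa == wt_aa:
                continue
            seq = peptide.sequence[:pos] + aa + peptide.sequence[pos + 1 :]
            if seq in seen:
                continue
            seen.add(seq)
            label = f"{wt_aa}{pos + 1}{aa}"
            out.append(
                PeptideVariant(
                    peptide_id=f"{peptide.peptide_id}_{label}",
                    parent_id=peptide.parent_id,
                    start=peptide.start,
                    sequence=seq,
                    variant_class="POINT_MUTANT",
                    mutation_label=label,
                )
            )
    return out


def osa_distance(a: str, b: str) -> int:
    """Optimal string alignment (restricted Damerau-Levenshtein) distance.

    Edits are insertion, deletion, substitution and transposition of adjacent
    characters, with the restriction that no substring is edited twice.
    """
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=np.int64)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


def design_scrambled(
    peptide: PeptideVariant, n_shuffles: int = 50, seed: int = 0
) -> PeptideVariant:
    """Scrambled negative control: the most-distant of ``n_shuffles`` shuffles.

    Candidates are random permutations of the peptide's residues; the one with
    the maximal OSA distance to the wild-type wins (first maximal candidate in
    generation order on ties).  Deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    residues = list(peptide.sequence)
    best_seq, best_dist = None, -1
    for _ in range(n_shuffles):
        cand = "".join(rng.permutation(residues))
        dist = osa_distance(cand, peptide.sequence)
        if dist > best_dist:
            best_seq, best_dist = cand, dist
    return PeptideVariant(
        peptide_id=f"{peptide.peptide_id}_scr",
        parent_id=peptide.parent_id,
        start=peptide.start,
        sequence=best_seq,
        variant_class="SCRAMBLED",
        mutation_label=f"osa={best_dist}",
    )


def build_library(
    parents: list[ProteinRecord],
    window: int = WINDOW,
    codon_map: dict[str, str] | None = None,
) -> DesignedLibrary:
    """Tile every parent and add Cys->Ala / Cys->Ser variants of each tile."""
    lib = DesignedLibrary()
    for protein in parents:
        for tile in tile_peptides(protein, window):
            lib.add(tile, codon_map)
            for var in make_cys_variants(tile):
                lib.add(var, codon_map)
    return lib
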