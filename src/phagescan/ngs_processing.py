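"""Amplicon read filtering and peptide counting.

Paired-end FASTQ reads of the phage-insert amplicon are joined by read id,
filtered for the demultiplexing motifs and the two constant regions flanking
the 48-nt insert, and counted against the designed library at the translated
peptide level.  Every read pair receives exactly one status; only OK reads are
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_design import DesignedLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "DEMUX_FWD",
    "DEMUX_REV",
    "CONST5",
    "CONST3",
    "ReadPair",
    "InsertObservation",
    "CountTable",
    "join_pairs",
    "extract_insert",
    "count_sample",
    "cloning_efficiency",
    "status_summary",
]

#: Demultiplexing motifs at the amplicon termini (top strand).
DEMUX_FWD = "CTAGCGCT"
DEMUX_REV = "CGCAGACG"

#: Constant regions flanking the insert (top strand): the 5' constant ends in
#: the cloning arm ...TCATCTGGC and the 3' constant begins with the arm
#: GGTGGAGGATCCGGA followed by vector sequence.
CONST5 = "ATGCCTATGCAGCCTCTTCATCTGGC"
CONST3 = (
    "GGTGGAGGATCCGGAGGAGGCGCCGAGGGTGACGATCCCGCAAAAGCGGCCTTTAACTCC"
    "CTGCAAGCCTCAGCGACCGAATATATCGGTTATGCGTGGGCGATGGTTGTTGTCAT"
)

#: Filter statuses, in the order they are assigned.
STATUSES = (
    "MISSING_DEMUX",
    "MISSING_CONSTANT",
    "MATE_MISMATCH",
    "AMBIGUOUS_BASE",
    "WRONG_SIZE",
    "NOT_IN_LIBRARY",
    "OK",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    read1_nt: str
    read2_nt: str


@dataclass(frozen=True)
class InsertObservation:
    read_id: str
    status: str
    insert_nt: str | None = None
    peptide: str | None = None


@dataclass
class CountTable:
    """Per-sample read counts and frequencies over library peptides."""

    sample_id: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        total = self.total
        return {pid: c / total for pid, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "peptide_id": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [freqs[p] for p in self.counts],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, sample_id: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_id=sample_id or Path(path).stem,
            counts=dict(zip(df["peptide_id"].astype(str), df["count"].astype(int))),
        )


def _strip_mate_suffix(read_id: str) -> str:
    head = read_id.split()[0]
    if len(head) > 2 and head[-2] == "/" and head[-1] in "12":
        head = head[:-2]
    return head


def join_pairs(fastq1, fastq2):
    """Yield :class:`ReadPair` objects matched by read id.

    Unpaired reads on either side are dropped (their number is logged).
    """
    with open(fastq1) as f1, open(fastq2) as f2:
        mates1 = {
            _strip_mate_suffix(title): seq
            for title, seq, _ in FastqGeneralIterator(f1)
        }
        n_pairs = 0
        n_unpaired2 = 0
        for title, seq, _ in FastqGeneralIterator(f2):
            rid = _strip_mate_suffix(title)
            mate1 = mates1.pop(rid, None)
            if mate1 is None:
                n_unpaired2 += 1
                continue
            n_pairs += 1
            yield ReadPair(rid, mate1, seq)
    n_dropped = len(mates1) + n_unpaired2
    if n_dropped:
        logger.info(
            "join_pairs: %d pairs, %d unpaired reads dropped", n_pairs, n_dropped
        )


def _insert_candidate(read: str) -> tuple[str | None, str]:
    """Delimit the insert between the two constant regions of one mate.

    Returns (insert-or-None, failure-status) where the status is meaningful
    only when the insert is None.
    """
    if DEMUX_FWD not in read or DEMUX_REV not in read:
        return None, "MISSING_DEMUX"
    i5 = read.find(CONST5)
    i3 = read.find(CONST3)
    if i5 < 0 or i3 < 0 or i3 < i5:
        return None, "MISSING_CONSTANT"
    return read[i5 + len(CONST5) : i3], "OK"


def extract_insert(pair: ReadPair, library: DesignedLibrary | dict[str, str]) -> InsertObservation:
    """Classify one read pair and extract its insert.

    Statuses are assigned in the fixed order MISSING_DEMUX, MISSING_CONSTANT,
    MATE_MISMATCH, AMBIGUOUS_BASE, WRONG_SIZE, NOT_IN_LIBRARY, OK.  Mate 2 is
    reverse-complemented before searching, so both mates are compared on the
    amplicon top strand.  Motifs are matched exactly.
    """
    peptide_index = (
        library if isinstance(library, dict) else library.peptide_index()
    )
    cand1, status1 = _insert_candidate(pair.read1_nt)
    cand2, status2 = _insert_candidate(_revcomp(pair.read2_nt))
    if "MISSING_DEMUX" in (status1, status2):
        return InsertObservation(pair.read_id, "MISSING_DEMUX")
    if "MISSING_CONSTANT" in (status1, status2):
        return InsertObservation(pair.read_id, "MISSING_CONSTANT")
    if cand1 != cand2:
        return InsertObservation(pair.read_id, "MATE_MISMATCH")
    insert = cand1
    if set(insert) - set("ACGT"):
        return InsertObservation(pair.read_id, "AMBIGUOUS_BASE", insert_nt=insert)
    if len(insert) != 48:
        return InsertObservation(pair.read_id, "WRONG_SIZE", insert_nt=insert)
    peptide = str(Seq(insert).translate())
    if peptide not in peptide_index:
        return InsertObservation(
            pair.read_id, "NOT_IN_LIBRARY", insert_nt=insert, peptide=peptide
        )
    return InsertObservation(pair.read_id, "OK", insert_nt=insert, peptide=peptide)


def count_sample(observations, library: DesignedLibrary, sample_id: str = "sample") -> CountTable:
    """Count OK observations against the library at the peptide level."""
    index = library.peptide_index()
    counts: dict[str, int] = {}
    n_obs = 0
    for obs in observations:
        n_obs += 1
        if obs.status != "OK":
            continue
        pid = index[obs.peptide]
        counts[pid] = counts.get(pid, 0) + 1
    if not counts:
        raise ValueError(f"sample {sample_id!r}: no OK observations to count")
    logger.info("count_sample %s: %d/%d reads counted", sample_id, sum(counts.values()), n_obs)
    return CountTable(sample_id=sample_id, counts=counts)


def status_summary(observations) -> pd.DataFrame:
    """Tally of filter statuses (one row per status, fixed order)."""
    tally = {s: 0 for s in STATUSES}
    for obs in observations:
        tally[obs.status] += 1
    return pd.DataFrame({"status": list(tally), "n_reads": list(tally.values())})


def cloning_efficiency(input_table: CountTable, library: DesignedLibrary) -> float:
    """Fraction of designed distinct peptides observed in the input library."""
    designed = library.distinct_peptides
    if not designed:
        raise ValueError("empty designed library")
    id_to_seq = {m.peptide_id: m.sequence for m in library.members}
    observed = {
        id_to_seq[pid]
        for pid, c in input_table.counts.items()
        if c > 0 and pid in id_to_seq
    }
    return len(observed & designed) / len(designed)
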