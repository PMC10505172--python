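"""Peptide enrichment scoring, residue mapping and mutational-scan deltas.

Enrichment E of a peptide after selection is the ratio of its output
frequency to its input frequency, reported as log2E.  Zero counts are handled
by floor substitution so that no log2E is infinite: a peptide missing from the
input library inherits the smallest positive input frequency of the
experiment; in mutagenesis screens a peptide missing from the output likewise
inherits the smallest positive output frequency.  Peptides mapped back to
their parent protein give a per-residue profile (rlog2E, the sum of log2E of
enriched peptides overlapping the residue) whose high regions - above the
upper 95% confidence bound of the protein-wide median - are the regions of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import WINDOW, DesignedLibrary, ProteinRecord
from .ngs_processing import CountTable

__all__ = [
    "EnrichmentTable",
    "ResidueProfile",
    "MutScanEntry",
    "compute_log2E",
    "residue_profile",
    "median_ci",
    "rolling_median",
    "detect_roi",
    "promiscuous_peptides",
    "total_log2E",
    "delta_log2E",
]


@dataclass
class EnrichmentTable:
    """Long-format (peptide, chemokine, log2E) table."""

    entries: pd.DataFrame  # columns: peptide_id, chemokine_id, log2E

    def __post_init__(self) -> None:
        required = {"peptide_id", "chemokine_id", "log2E"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"enrichment table missing columns {sorted(missing)}")
        self.entries["log2E"] = self.entries["log2E"].astype(float)
        if not np.isfinite(self.entries["log2E"]).all():
            raise ValueError("non-finite log2E in enrichment table")

    def write_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "EnrichmentTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def concat(cls, tables: list["EnrichmentTable"]) -> "EnrichmentTable":
        return cls(pd.concat([t.entries for t in tables], ignore_index=True))


@dataclass
class ResidueProfile:
    """Per-residue enrichment profile of one parent protein."""

    parent_id: str
    rlog2E: np.ndarray           # length L, raw per-residue sums
    smoothed: np.ndarray         # length L, NaN at the first/last 3 residues
    median_ci: tuple[float, float]
    roi: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive

    def to_frame(self) -> pd.DataFrame:
        length = len(self.rlog2E)
        in_roi = np.zeros(length, dtype=bool)
        for start, end in self.roi:
            in_roi[start - 1 : end] = True
        return pd.DataFrame(
            {
                "parent_id": self.parent_id,
                "position": np.arange(1, length + 1),
                "rlog2E": self.rlog2E,
                "smoothed": self.smoothed,
                "ci_lower": self.median_ci[0],
                "ci_upper": self.median_ci[1],
                "in_roi": in_roi,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MutScanEntry:
    peptide_id: str
    position: int
    wt_res: str
    mut_res: str
    chemokine_id: str
    log2E: float
    delta_log2E: float


def compute_log2E(
    input_table: CountTable,
    output_tables: CountTable | list[CountTable],
    mode: str = "selection",
) -> EnrichmentTable:
    """log2 enrichment of each peptide in each output sample.

    ``mode='selection'``: peptides never recovered in an output sample are
    omitted for that sample (not-recovered, as opposed to depleted); a peptide
    missing from the input inherits the minimum positive input frequency.
    ``mode='mutagenesis'``: additionally, a zero output frequency inherits the
    minimum positive output frequency of that sample, so every library member
    present in the input receives a finite log2E.
    """
    if mode not in ("selection", "mutagenesis"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(output_tables, CountTable):
        output_tables = [output_tables]
    in_freq = input_table.frequencies
    if not in_freq:
        raise ValueError("all-zero input table")
    min_in = min(f for f in in_freq.values() if f > 0)

    rows = []
    for out_table in output_tables:
        out_freq = out_table.frequencies
        min_out = min(f for f in out_freq.values() if f > 0)
        if mode == "selection":
            peptides = set(out_freq)
        else:
            peptides = set(out_freq) | set(in_freq)
        for pid in sorted(peptides):
            f_in = in_freq.get(pid, 0.0) or min_in
            f_out = out_freq.get(pid, 0.0)
            if f_out == 0.0:
                if mode == "selection":
                    continue
                f_out = min_out
            rows.append(
                {
                    "peptide_id": pid,
                    "chemokine_id": out_table.sample_id,
                    "log2E": float(np.log2(f_out / f_in)),
                }
            )
    return EnrichmentTable(pd.DataFrame(rows))


def rolling_median(values: np.ndarray, window: int = 7) -> np.ndarray:
    """Centered rolling median; positions without a full window are NaN."""
    ser = pd.Series(np.asarray(values, dtype=float))
    return ser.rolling(window, center=True, min_periods=window).median().to_numpy()


def median_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free confidence interval for the median.

    Uses the conservative order-statistic interval [x_(d), x_(n+1-d)] with d
    the largest rank whose binomial(n, 1/2) coverage is at least ``level``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 6:
        raise ValueError(f"n={n} too small for a {level:.0%} median CI")
    d = 0
    for cand in range(1, n // 2 + 1):
        coverage = 1.0 - 2.0 * stats.binom.cdf(cand - 1, n, 0.5)
        if coverage >= level:
            d = cand
        else:
            break
    if d == 0:
        raise ValueError(f"n={n} too small for a {level:.0%} median CI")
    return float(x[d - 1]), float(x[n - d])


def residue_profile(
    table: EnrichmentTable,
    library: DesignedLibrary,
    parent: ProteinRecord,
    window: int = 7,
    ci_level: float = 0.95,
    use_smoothed: bool = True,
) -> ResidueProfile:
    """Map enriched peptides onto their parent protein.

    Only entries with log2E > 0 contribute.  Mutant tiles (Cys variants,
    point mutants) map to the coordinates of their originating wild-type
    tile.  ROIs are maximal runs of residues whose smoothed rlog2E (raw, if
    ``use_smoothed`` is False) strictly exceeds the upper bound of the
    ``ci_level`` confidence interval of the protein-wide median rlog2E.
    """
    length = len(parent.sequence)
    coords = {
        m.peptide_id: (m.start, m.start + len(m.sequence) - 1)
        for m in library.members
        if m.parent_id == parent.id
    }
    if not coords:
        raise ValueError(f"no library tile maps to parent {parent.id!r}")
    rlog2E = np.zeros(length)
    for row in table.entries.itertuples(index=False):
        if row.log2E <= 0:
            continue
        span = coords.get(row.peptide_id)
        if span is None:
            continue
        rlog2E[span[0] - 1 : span[1]] += row.log2E
    smoothed = rolling_median(rlog2E, window)
    ci = median_ci(rlog2E, ci_level)
    profile = ResidueProfile(parent.id, rlog2E, smoothed, ci)
    profile.roi = detect_roi(profile, use_smoothed=use_smoothed)
    return profile


def detect_roi(profile: ResidueProfile, use_smoothed: bool = True) -> list[tuple[int, int]]:
    """Maximal runs of residues strictly above the upper median-CI bound."""
    values = profile.smoothed if use_smoothed else profile.rlog2E
    above = np.zeros(len(values), dtype=bool)
    finite = np.isfinite(values)
    above[finite] = values[finite] > profile.median_ci[1]
    rois: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i + 1
        elif not flag and start is not None:
            rois.append((start, i))
            start = None
    if start is not None:
        rois.append((start, len(above)))
    return rois


def total_log2E(table: EnrichmentTable) -> pd.Series:
    """Sum of log2E over all chemokines, per peptide (missing pairs add 0)."""
    return table.entries.groupby("peptide_id")["log2E"].sum()


def promiscuous_peptides(
    table: EnrichmentTable, min_chemokines: int = 3, threshold: float = 5.0
) -> set[str]:
    """Peptides with log2E strictly above ``threshold`` in >= ``min_chemokines``."""
    df = table.entries
    strong = df[df["log2E"] > threshold]
    n_per_peptide = strong.groupby("peptide_id")["chemokine_id"].nunique()
    return set(n_per_peptide[n_per_peptide >= min_chemokines].index)


def delta_log2E(
    table: EnrichmentTable, library: DesignedLibrary, parent_peptide_id: str
) -> list[MutScanEntry]:
    """Mutant-minus-parental change in log2E per chemokine.

    Positive delta means the mutant binds better than the parental peptide.
    Chemokines for which the parental peptide has no entry are skipped.
    """
    df = table.entries
    parent_rows = df[df["peptide_id"] == parent_peptide_id]
    parent_log2E = dict(zip(parent_rows["chemokine_id"], parent_rows["log2E"]))
    library.by_id(parent_peptide_id)  # raises KeyError if absent
    members = {m.peptide_id: m for m in library.members}

    out: list[MutScanEntry] = []
    skipped: set[str] = set()
    for row in df.itertuples(index=False):
        member = members.get(row.peptide_id)
        if member is None or member.variant_class not in ("POINT_MUTANT", "WT"):
            continue
        if member.variant_class == "WT" and row.peptide_id != parent_peptide_id:
            continue
        base = parent_log2E.get(row.chemokine_id)
        if base is None:
            skipped.add(row.chemokine_id)
            continue
        if member.variant_class == "WT":
            position, wt_res, mut_res = 0, "", ""
        else:
            label = member.mutation_label
            wt_res, mut_res = label[0], label[-1]
            position = int(label[1:-1])
        out.append(
            MutScanEntry(
                peptide_id=row.peptide_id,
                position=position,
                wt_res=wt_res,
                mut_res=mut_res,
                chemokine_id=row.chemokine_id,
                log2E=float(row.log2E),
                delta_log2E=float(row.log2E - base),
            )
        )
    if skipped:
        import warnings

        warnings.warn(
            f"parental peptide missing for chemokines {sorted(skipped)}; skipped",
            stacklevel=2,
        )
    return out
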