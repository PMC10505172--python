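"""Statistics for the saturation-mutagenesis scan and migration assays.

Substitutions are grouped into the classes used for hydrophile / hydrophobe /
alanine scanning (anionic E/D, cationic K/R, hydrophobic L/I/M/V, alanine,
conservative by positive Dayhoff PAM250 score), and each class at each
position is compared with the parental-peptide control using a two-sided
Dunnett many-to-one test.  The Dunnett adjustment is computed by seeded Monte
Carlo over the equicorrelated multivariate t distribution implied by the
group sizes (pooled-variance model), so adjusted p-values are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Align import substitution_matrices

__all__ = [
    "SUBSTITUTION_CLASSES",
    "GroupSummary",
    "MigrationRecord",
    "classify_substitution",
    "group_observations",
    "dunnett_test",
    "dunnett_critical_value",
    "one_way_anova",
    "normalise_migration",
    "correlate_function_binding",
    "significance_stars",
]

#: Residue memberships of the scanning classes.
SUBSTITUTION_CLASSES: dict[str, set[str]] = {
    "ALANINE": {"A"},
    "ANIONIC": {"E", "D"},
    "CATIONIC": {"K", "R"},
    "HYDROPHOBIC": {"L", "I", "M", "V"},
}

_PAM250 = substitution_matrices.load("PAM250")
_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def classify_substitution(wt: str, mut: str, pam250=None) -> set[str]:
    """Class labels of a single substitution; labels are not exclusive.

    WILDTYPE if the residue is unchanged; ALANINE / ANIONIC / CATIONIC /
    HYDROPHOBIC by membership of the mutant residue; CONSERVATIVE when the
    PAM250 score of the exchange is strictly positive.
    """
    if wt not in _STANDARD or mut not in _STANDARD:
        raise ValueError(f"non-standard residue in substitution {wt!r}->{mut!r}")
    if wt == mut:
        return {"WILDTYPE"}
    pam = pam250 if pam250 is not None else _PAM250
    labels = {
        name for name, members in SUBSTITUTION_CLASSES.items() if mut in members
    }
    if pam[wt, mut] > 0:
        labels.add("CONSERVATIVE")
    if not labels:
        labels.add("OTHER")
    return labels


@dataclass
class GroupSummary:
    position: int
    class_name: str
    n_obs: int
    values: np.ndarray
    dunnett_p: float = np.nan
    direction: int = 0  # sign of (group mean - control mean)


def _class_residues(
    class_name: str, wt_aa: str, pam250=None, top_conservative: int | None = None
) -> list[str]:
    """Mutant residues constituting one scanning class at one position."""
    if class_name == "WILDTYPE":
        return [wt_aa]
    if class_name == "CONSERVATIVE":
        pam = pam250 if pam250 is not None else _PAM250
        cands = sorted(aa for aa in _STANDARD if aa != wt_aa and pam[wt_aa, aa] > 0)
        if top_conservative:
            cands.sort(key=lambda aa: (-pam[wt_aa, aa], aa))
            cands = cands[:top_conservative]
        return cands
    members = SUBSTITUTION_CLASSES[class_name]
    return sorted(members - {wt_aa})


def group_observations(
    entries,
    peptide: str,
    n_chemokines: int,
    classes: tuple[str, ...] = ("ALANINE", "CONSERVATIVE", "ANIONIC", "CATIONIC", "HYDROPHOBIC"),
    top_conservative: int | None = None,
) -> list[GroupSummary]:
    """Per-position, per-class observation groups of a mutational scan.

    ``entries`` is an iterable of objects with position / mut_res /
    chemokine_id / log2E attributes (e.g. :class:`~phagescan.enrichment.MutScanEntry`).
    The expected group size is (#class residues excluding the position's
    wild-type identity) x n_chemokines; the wild-type and alanine groups use a
    single residue.
    """
    entries = list(entries)
    by_pos_res: dict[tuple[int, str], list[float]] = {}
    for e in entries:
        by_pos_res.setdefault((e.position, e.mut_res), []).append(e.log2E)

    out: list[GroupSummary] = []
    for pos in range(1, len(peptide) + 1):
        wt_aa = peptide[pos - 1]
        for cls in classes:
            residues = _class_residues(cls, wt_aa, top_conservative=top_conservative)
            values: list[float] = []
            for aa in residues:
                values.extend(by_pos_res.get((pos, aa), []))
            out.append(
                GroupSummary(
                    position=pos,
                    class_name=cls,
                    n_obs=len(values),
                    values=np.asarray(values, dtype=float),
                )
            )
    return out


def expected_group_size(class_name: str, wt_aa: str, n_chemokines: int) -> int:
    """Design group size for one class at one position (excludes WT identity)."""
    if class_name == "WILDTYPE":
        return n_chemokines
    if class_name == "ALANINE":
        return 0 if wt_aa == "A" else n_chemokines
    if class_name == "CONSERVATIVE":
        # one conservative substitution synthesised per position
        return n_chemokines
    return len(SUBSTITUTION_CLASSES[class_name] - {wt_aa}) * n_chemokines


def _dunnett_lambdas(n_control: int, group_sizes: np.ndarray) -> np.ndarray:
    # correlation between contrast i and j is lambda_i * lambda_j
    return np.sqrt(group_sizes / (group_sizes + n_control))


def _max_abs_t_sample(
    lambdas: np.ndarray, df: int, draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte Carlo sample of max_i |T_i| under the many-to-one null.

    T_i = (lambda_i Z0 + sqrt(1 - lambda_i^2) Z_i) / sqrt(chi2_df / df) is the
    equicorrelated multivariate t with df pooled-variance degrees of freedom.
    """
    k = len(lambdas)
    z0 = rng.standard_normal(draws)
    z = rng.standard_normal((draws, k))
    t_num = lambdas * z0[:, None] + np.sqrt(1.0 - lambdas**2) * z
    s = np.sqrt(rng.chisquare(df, draws) / df)
    return np.max(np.abs(t_num), axis=1) / s


def dunnett_statistics(
    control, groups
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled-variance t statistics of each group against the control."""
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(control) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("control and every group need n >= 2")
    all_groups = [control] + groups
    n = np.array([len(g) for g in all_groups])
    df = int(n.sum() - len(all_groups))
    ss = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("zero pooled variance: Dunnett statistics undefined")
    tstats = np.array(
        [
            (g.mean() - control.mean()) / np.sqrt(s2 * (1 / len(g) + 1 / len(control)))
            for g in groups
        ]
    )
    lambdas = _dunnett_lambdas(len(control), n[1:])
    return tstats, lambdas, df


def dunnett_test(
    control,
    groups,
    mc_draws: int = 200_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided Dunnett many-to-one adjusted p-values.

    The family-wise adjustment P(max_j |T_j| >= |t_i|) is evaluated by seeded
    Monte Carlo over the equicorrelated multivariate t implied by the group
    sizes, so results are deterministic given ``seed``.
    """
    tstats, lambdas, df = dunnett_statistics(control, groups)
    rng = np.random.default_rng(seed)
    max_abs_t = _max_abs_t_sample(lambdas, df, mc_draws, rng)
    max_abs_t.sort()
    # p = fraction of null draws with max |T| at least |t_i|
    idx = np.searchsorted(max_abs_t, np.abs(tstats), side="left")
    return (mc_draws - idx) / mc_draws


def dunnett_critical_value(
    n_control: int,
    group_sizes,
    df: int,
    level: float = 0.95,
    mc_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """Critical |t| for family-wise level ``level`` (two-sided, many-to-one)."""
    lambdas = _dunnett_lambdas(n_control, np.asarray(group_sizes, dtype=float))
    rng = np.random.default_rng(seed)
    sample = _max_abs_t_sample(lambdas, df, mc_draws, rng)
    return float(np.quantile(sample, level))


def one_way_anova(groups) -> tuple[float, int, float]:
    """Classical one-way ANOVA: (F, numerator df, p).

    Between/within sums-of-squares decomposition; p from the F distribution
    with (k-1, N-k) degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n_total = sum(len(g) for g in groups)
    if n_total <= k:
        raise ValueError("no within-group degrees of freedom")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("all observations identical: F undefined")
        return float("inf"), df_between, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), df_between, p


@dataclass(frozen=True)
class MigrationRecord:
    chemokine_id: str
    treatment: str
    raw_count: float
    normalised_count: float


def normalise_migration(
    records: pd.DataFrame, chemokine_alone_label: str = "chemokine_alone"
) -> list[MigrationRecord]:
    """Scale migrated-cell counts so the chemokine-alone median is 10000.

    ``records`` needs columns chemokine_id, treatment, raw_count; scaling is
    per chemokine (one experiment each).
    """
    out: list[MigrationRecord] = []
    for chemokine_id, sub in records.groupby("chemokine_id"):
        alone = sub.loc[sub["treatment"] == chemokine_alone_label, "raw_count"]
        if alone.empty:
            raise ValueError(f"{chemokine_id}: no {chemokine_alone_label!r} group")
        med = float(alone.median())
        if med <= 0:
            raise ValueError(f"{chemokine_id}: non-positive chemokine-alone median")
        scale = 10000.0 / med
        for row in sub.itertuples(index=False):
            out.append(
                MigrationRecord(
                    chemokine_id=str(chemokine_id),
                    treatment=str(row.treatment),
                    raw_count=float(row.raw_count),
                    normalised_count=float(row.raw_count) * scale,
                )
            )
    return out


def correlate_function_binding(pairs) -> tuple[float, float]:
    """Spearman correlation between Δmigrated and Δlog2E (rho, two-sided p)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need >= 4 (Δmigrated, Δlog2E) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho), float(p)


def significance_stars(p: float) -> str:
    for cut, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= cut:
            return stars
    return ""
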