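"""Enrichment scoring, residue profiles, median CI, ROI and deltas."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phagescan import enrichment as enr
from phagescan import library_design as ld
from phagescan import synthgen as sg
from phagescan.ngs_processing import CountTable


def table_from(counts_in, counts_out, mode="selection", sample="CK"):
    inp = CountTable("input", counts_in)
    out = CountTable(sample, counts_out)
    return enr.compute_log2E(inp, out, mode=mode)


# ------------------------------------------------------------- log2E

def test_log2e_simple_ratio():
    # freq_out/freq_in = (40/1000)/(10/1000) = 4 -> log2E = 2
    tab = table_from({"p": 10, "q": 990}, {"p": 40, "q": 960})
    row = tab.entries.set_index("peptide_id")
    assert row.loc["p", "log2E"] == pytest.approx(2.0)


def test_log2e_zero_when_frequency_unchanged():
    tab = table_from({"p": 10, "q": 90}, {"p": 10, "q": 90})
    assert tab.entries["log2E"].abs().max() == pytest.approx(0.0)


def test_log2e_input_floor_substitution():
    # peptide 'm' absent from input; min input proportion = 1/1000 = 0.001;
    # freq_out = 0.008 -> log2E = log2(8) = 3 (hand application of the rule)
    counts_in = {"a": 1, "b": 999}
    counts_out = {"m": 8, "a": 992}
    tab = table_from(counts_in, counts_out)
    row = tab.entries.set_index("peptide_id")
    assert row.loc["m", "log2E"] == pytest.approx(3.0)


def test_log2e_mutagenesis_output_floor():
    counts_in = {"a": 50, "b": 25, "c": 25}
    counts_out = {"a": 99, "b": 1}
    tab = table_from(counts_in, counts_out, mode="mutagenesis")
    row = tab.entries.set_index("peptide_id")
    # c missing from output inherits min positive output frequency (0.01)
    assert row.loc["c", "log2E"] == pytest.approx(np.log2(0.01 / 0.25))
    assert np.isfinite(tab.entries["log2E"]).all()


def test_no_infinities_under_floor_rules(rng):
    for _ in range(20):
        n = int(rng.integers(3, 12))
        ids = [f"p{i}" for i in range(n)]
        counts_in = {i: int(c) for i, c in zip(ids, rng.integers(0, 50, n)) if c > 0}
        counts_out = {i: int(c) for i, c in zip(ids, rng.integers(0, 50, n)) if c > 0}
        if not counts_in or not counts_out:
            continue
        for mode in ("selection", "mutagenesis"):
            tab = enr.compute_log2E(
                CountTable("input", counts_in), CountTable("CK", counts_out), mode=mode
            )
            assert np.isfinite(tab.entries["log2E"]).all()


def test_all_zero_input_raises():
    with pytest.raises(ValueError):
        enr.compute_log2E(CountTable("input", {}), CountTable("CK", {"a": 1}))


def test_increasing_output_count_never_lowers_rank():
    counts_in = {"a": 25, "b": 25, "c": 50}
    base = {"a": 10, "b": 40, "c": 50}
    tab0 = table_from(counts_in, base)
    r0 = tab0.entries.set_index("peptide_id")["log2E"].rank()
    boosted = dict(base, a=200)
    tab1 = table_from(counts_in, boosted)
    r1 = tab1.entries.set_index("peptide_id")["log2E"].rank()
    assert r1["a"] >= r0["a"]


# --------------------------------------------------------- rolling median

def test_rolling_median_matches_sorted_window_oracle(rng):
    for _ in range(100):
        x = rng.normal(size=int(rng.integers(7, 40)))
        smoothed = enr.rolling_median(x, 7)
        assert np.isnan(smoothed[:3]).all() and np.isnan(smoothed[-3:]).all()
        for i in range(3, len(x) - 3):
            window = np.sort(x[i - 3 : i + 4])
            assert smoothed[i] == pytest.approx(window[3])


# ------------------------------------------------------------ median CI

def binomial_ci_oracle(x, level=0.95):
    x = np.sort(np.asarray(x, float))
    n = len(x)
    best = None
    for d in range(1, n // 2 + 1):
        cover = 1 - 2 * stats.binom.cdf(d - 1, n, 0.5)
        if cover >= level:
            best = d
    return x[best - 1], x[n - best]


def test_median_ci_order_statistics_1_to_100():
    lo, hi = enr.median_ci(np.arange(1.0, 101.0))
    # symmetric ranks with >= 95% binomial coverage around ranks 50/51
    assert (lo, hi) == binomial_ci_oracle(np.arange(1.0, 101.0))
    assert lo + hi == pytest.approx(101.0)


def test_median_ci_constant_vector():
    assert enr.median_ci(np.full(20, 3.5)) == (3.5, 3.5)


def test_median_ci_shift_invariance(rng):
    x = rng.normal(size=31)
    lo, hi = enr.median_ci(x)
    lo2, hi2 = enr.median_ci(x + 10)
    assert (lo2, hi2) == pytest.approx((lo + 10, hi + 10))


def test_median_ci_small_n_raises():
    with pytest.raises(ValueError):
        enr.median_ci([1.0, 2.0, 3.0])


def test_median_ci_matches_oracle_random(rng):
    for _ in range(25):
        x = rng.normal(size=int(rng.integers(8, 200)))
        assert enr.median_ci(x) == pytest.approx(binomial_ci_oracle(x))


# -------------------------------------------------------- residue profile

def single_tile_library(parent):
    lib = ld.DesignedLibrary()
    lib.add(ld.PeptideVariant("t1", parent.id, 1, parent.sequence[:16], "WT"))
    return lib


def test_single_tile_profile():
    parent = ld.ProteinRecord("P", "EEDDYTAYAPLTCYFT" + "GHIKLMNQRS")
    lib = single_tile_library(parent)
    tab = enr.EnrichmentTable(
        pd.DataFrame([{"peptide_id": "t1", "chemokine_id": "CK", "log2E": 2.0}])
    )
    prof = enr.residue_profile(tab, lib, parent)
    assert np.allclose(prof.rlog2E[:16], 2.0)
    assert np.allclose(prof.rlog2E[16:], 0.0)


def test_negative_entries_contribute_nothing():
    parent = ld.ProteinRecord("P", "EEDDYTAYAPLTCYFT" + "GHIKLMNQRS")
    lib = single_tile_library(parent)
    tab = enr.EnrichmentTable(
        pd.DataFrame([{"peptide_id": "t1", "chemokine_id": "CK", "log2E": -1.0}])
    )
    prof = enr.residue_profile(tab, lib, parent)
    assert np.allclose(prof.rlog2E, 0.0)


def test_rlog2e_matches_double_loop_oracle(rng):
    for _ in range(50):
        length = int(rng.integers(30, 60))
        seq = "".join(rng.choice(list(ld.AMINO_ACIDS), size=length))
        parent = ld.ProteinRecord("P", seq)
        tiles = ld.tile_peptides(parent)
        rows = []
        for t in tiles:
            for ck in ("CK1", "CK2"):
                if rng.random() < 0.5:
                    rows.append(
                        {"peptide_id": t.peptide_id, "chemokine_id": ck,
                         "log2E": float(rng.normal())}
                    )
        if not rows:
            continue
        lib = ld.DesignedLibrary()
        for t in tiles:
            lib.add(t)
        tab = enr.EnrichmentTable(pd.DataFrame(rows))
        prof = enr.residue_profile(tab, lib, parent)
        # brute force: loop over every (entry, residue) pair
        expected = np.zeros(length)
        spans = {t.peptide_id: (t.start, t.start + 15) for t in tiles}
        for row in rows:
            if row["log2E"] <= 0:
                continue
            s, e = spans[row["peptide_id"]]
            for pos in range(1, length + 1):
                if s <= pos <= e:
                    expected[pos - 1] += row["log2E"]
        assert np.allclose(prof.rlog2E, expected)


# ----------------------------------------------------------------- ROI

def profile_with(values, ci_upper):
    values = np.asarray(values, float)
    return enr.ResidueProfile(
        "P", values, enr.rolling_median(values, 7), (0.0, ci_upper)
    )


def test_flat_profile_has_no_roi():
    prof = profile_with(np.ones(40), ci_upper=1.0)
    assert enr.detect_roi(prof) == []


def test_two_blocks_give_two_ordered_intervals():
    x = np.zeros(60)
    x[10:20] = 5.0
    x[40:50] = 5.0
    prof = profile_with(x, ci_upper=1.0)
    rois = enr.detect_roi(prof)
    assert len(rois) == 2
    assert rois[0][0] < rois[1][0]
    for start, end in rois:
        assert start >= 1 and end <= 60


def test_roi_recovers_planted_block(small_study):
    parents, truth, library, input_table, outputs = small_study
    tab = enr.compute_log2E(input_table, list(outputs.values()))
    parent = parents[0]
    prof = enr.residue_profile(tab, library, parent)
    assert prof.roi, "no ROI detected on planted data"
    t_start, t_end = truth.interval(parent.id, "CK1")
    top = max(
        prof.roi,
        key=lambda iv: np.nanmax(prof.smoothed[iv[0] - 1 : iv[1]]),
    )
    inter = max(0, min(top[1], t_end) - max(top[0], t_start) + 1)
    union = (top[1] - top[0] + 1) + (t_end - t_start + 1) - inter
    assert inter / union >= 0.5


def test_raw_thresholding_flag():
    x = np.zeros(40)
    x[5] = 10.0  # single spike: visible raw, erased by the rolling median
    prof = profile_with(x, ci_upper=1.0)
    assert enr.detect_roi(prof, use_smoothed=True) == []
    assert enr.detect_roi(prof, use_smoothed=False) == [(6, 6)]


# ---------------------------------------------------------- promiscuity

def promiscuity_table(values):
    rows = [
        {"peptide_id": "p", "chemokine_id": f"CK{i}", "log2E": v}
        for i, v in enumerate(values)
    ]
    return enr.EnrichmentTable(pd.DataFrame(rows))


def test_promiscuous_strictly_above_threshold():
    assert enr.promiscuous_peptides(promiscuity_table([6, 7, 5.1])) == {"p"}
    assert enr.promiscuous_peptides(promiscuity_table([6, 7, 5.0])) == set()


def test_promiscuous_empty_table():
    tab = enr.EnrichmentTable(
        pd.DataFrame(columns=["peptide_id", "chemokine_id", "log2E"])
    )
    assert enr.promiscuous_peptides(tab) == set()


def test_total_log2e_sums_over_chemokines():
    tab = promiscuity_table([1.0, 2.0, -0.5])
    assert enr.total_log2E(tab)["p"] == pytest.approx(2.5)


# -------------------------------------------------------------- deltas

@pytest.fixture
def mutscan_setup(hd2_tile):
    lib = ld.DesignedLibrary()
    for v in ld.nnk_mutant_library(hd2_tile):
        lib.add(v)
    return lib


def test_delta_log2e_sign_convention(mutscan_setup, hd2_tile):
    lib = mutscan_setup
    mutant = next(m for m in lib.members if m.variant_class == "POINT_MUTANT")
    rows = [
        {"peptide_id": hd2_tile.peptide_id, "chemokine_id": "CK1", "log2E": 6.0},
        {"peptide_id": mutant.peptide_id, "chemokine_id": "CK1", "log2E": 4.0},
    ]
    entries = enr.delta_log2E(
        enr.EnrichmentTable(pd.DataFrame(rows)), lib, hd2_tile.peptide_id
    )
    by_id = {e.peptide_id: e for e in entries}
    assert by_id[mutant.peptide_id].delta_log2E == pytest.approx(-2.0)
    assert by_id[hd2_tile.peptide_id].delta_log2E == pytest.approx(0.0)


def test_delta_log2e_missing_parent_chemokine_warns(mutscan_setup, hd2_tile):
    lib = mutscan_setup
    mutant = next(m for m in lib.members if m.variant_class == "POINT_MUTANT")
    rows = [{"peptide_id": mutant.peptide_id, "chemokine_id": "CKX", "log2E": 4.0}]
    with pytest.warns(UserWarning, match="CKX"):
        entries = enr.delta_log2E(
            enr.EnrichmentTable(pd.DataFrame(rows)), lib, hd2_tile.peptide_id
        )
    assert entries == []


def test_spearman_log2e_tracks_planted_affinity(small_study):
    parents, truth, library, input_table, outputs = small_study
    tab = enr.compute_log2E(input_table, outputs["CK1"])
    merged = tab.entries.set_index("peptide_id")["log2E"]
    planted = {
        pid: np.log(truth.affinities[(pid, "CK1")]) for pid in merged.index
    }
    rho, _ = stats.spearmanr(merged.values, [planted[p] for p in merged.index])
    assert rho > 0
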