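"""Runs of homozygosity, shared segments, haplotype statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recmap.exceptions import InputError
from recmap.genotypes import MISSING
from recmap.roh import (
    DiplotypeCounts,
    call_haplotype_copies,
    carrier_trend,
    cnv_window_logr,
    diplotype_counts,
    fertility_summary,
    haplotype_effect,
    homozygosity_run,
    hwe_chisq,
    shared_segment,
)
from recmap.simulate import (
    SimulationConfig,
    gene_drop,
    implanted_segment,
    simulate_pedigree,
    true_hap_copies,
)

from conftest import make_genotype_matrix


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_force_run(row, anchor, max_het, max_missing):
    """Enumerate every window containing the anchor; keep the longest
    feasible one (ties toward the smallest left index)."""
    m = len(row)
    budget_mis = m if max_missing is None else max_missing
    best = None
    for left in range(anchor + 1):
        for right in range(anchor, m):
            window = row[left : right + 1]
            if (window == 1).sum() <= max_het and (window == MISSING).sum() <= budget_mis:
                length = right - left
                if best is None or length > best[1] - best[0] or (
                    length == best[1] - best[0] and left < best[0]
                ):
                    best = (left, right)
    return best


def and_oracle(case_rows, anchor):
    """Maximal run of all-cases-homozygous around the anchor (per-marker
    AND of homozygosity indicators; missing calls do not break runs)."""
    ok = np.all(np.asarray(case_rows) != 1, axis=0)
    lo = anchor
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = anchor
    while hi + 1 < len(ok) and ok[hi + 1]:
        hi += 1
    return lo, hi


# ---------------------------------------------------------------------------
# homozygosity runs
# ---------------------------------------------------------------------------


def test_all_homozygous_row_spans_chromosome():
    row = np.array([0, 2, 0, 0, 2, 2, 0], dtype=np.int8)
    seg = homozygosity_run(row, anchor_idx=3)
    assert (seg.start_idx, seg.end_idx) == (0, 6)


def test_run_stops_at_heterozygous_marker():
    row = np.zeros(12, dtype=np.int8)
    row[7] = 1
    seg = homozygosity_run(row, anchor_idx=3, max_het=0)
    assert seg.end_idx == 6 and seg.start_idx == 0
    seg = homozygosity_run(row, anchor_idx=3, max_het=1)
    assert seg.end_idx == 11  # one het tolerated, run passes index 7


def test_heterozygous_anchor_rejected():
    row = np.array([0, 1, 0], dtype=np.int8)
    with pytest.raises(InputError, match="not homozygous"):
        homozygosity_run(row, anchor_idx=1)


@pytest.mark.parametrize("max_het", [0, 1, 2])
@pytest.mark.parametrize("max_missing", [None, 0, 1])
def test_run_matches_brute_force_enumeration(max_het, max_missing):
    rng = np.random.default_rng(17)
    for _ in range(40):
        m = int(rng.integers(5, 30))
        row = rng.choice([0, 1, 2, MISSING], size=m, p=[0.4, 0.2, 0.3, 0.1]).astype(np.int8)
        hom = np.flatnonzero((row == 0) | (row == 2))
        if not len(hom):
            continue
        anchor = int(rng.choice(hom))
        seg = homozygosity_run(row, anchor, max_het, max_missing)
        assert (seg.start_idx, seg.end_idx) == brute_force_run(row, anchor, max_het, max_missing)


# ---------------------------------------------------------------------------
# shared segments
# ---------------------------------------------------------------------------


def test_single_case_equals_own_run():
    row = np.zeros(10, dtype=np.int8)
    row[8] = 1
    seg_one = homozygosity_run(row, 2)
    seg_shared = shared_segment(row[None, :], 2)
    assert (seg_shared.start_idx, seg_shared.end_idx) == (seg_one.start_idx, seg_one.end_idx)


def test_staggered_runs_intersect_to_and_oracle():
    rows = np.zeros((5, 20), dtype=np.int8)
    rows[0, 3] = 1
    rows[1, 16] = 1
    rows[2, 2] = 1
    rows[3, 18] = 1
    seg = shared_segment(rows, anchor_idx=10)
    assert (seg.start_idx, seg.end_idx) == and_oracle(rows, 10)


def test_shared_segment_random_fixtures_match_and_oracle():
    rng = np.random.default_rng(5)
    done = 0
    while done < 60:
        m = int(rng.integers(5, 50))
        k = int(rng.integers(1, 6))
        rows = rng.choice([0, 1, 2, MISSING], size=(k, m), p=[0.45, 0.1, 0.35, 0.1]).astype(np.int8)
        hom_all = np.flatnonzero(np.all(rows != 1, axis=0) & np.all(rows != MISSING, axis=0))
        if not len(hom_all):
            continue
        anchor = int(rng.choice(hom_all))
        seg = shared_segment(rows, anchor)
        assert (seg.start_idx, seg.end_idx) == and_oracle(rows, anchor)
        done += 1


def test_shared_segment_uses_marker_map_bounds():
    rows = np.zeros((2, 6), dtype=np.int8)
    rows[0, 0] = 1
    rows[1, 5] = 1
    markers = pd.DataFrame(
        {
            "name": [f"M{i}" for i in range(6)],
            "chrom": "19",
            "pos": [100, 250, 400, 480, 900, 1200],
            "ref": "A",
            "alt": "C",
        }
    )
    seg = shared_segment(rows, 2, markers=markers)
    assert (seg.start_bp, seg.end_bp) == (250, 900)
    assert seg.length_bp == 900 - 250 + 1
    assert seg.n_markers == 4


def test_recovered_segment_bounds_within_one_marker_of_truth():
    """Implanted-IBD fixture: when the delimiting ancestral breakpoints are
    shared by several cases (as they are in a founder population, where
    case-group boundaries stem from the same ancestral recombinations),
    the recovered bounds fall within one marker of the implanted interval
    in >= 90% of 20 seeded fixtures."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        m, k = 60, 8
        a, b = 20, 40  # true shared IBD interval (marker indices)
        freqs = rng.uniform(0.2, 0.8, size=m)
        consensus = (rng.random(m) < freqs).astype(np.int8)
        rows = np.empty((k, m), dtype=np.int8)
        for i in range(k):
            rows[i] = rng.binomial(2, freqs)  # background HWE genotypes
            if i < 4:
                lo_i, hi_i = a, b  # boundary breakpoints shared by 4 cases
            else:
                lo_i = a - int(rng.integers(1, 7))
                hi_i = b + int(rng.integers(1, 7))
            rows[i, lo_i : hi_i + 1] = 2 * consensus[lo_i : hi_i + 1]
        seg = shared_segment(rows, anchor_idx=(a + b) // 2)
        if abs(seg.start_idx - a) <= 1 and abs(seg.end_idx - b) <= 1:
            hits += 1
    assert hits >= 0.9 * n_seeds


def test_population_segment_contains_truth_with_bounded_overshoot():
    """Against full gene-drop truth: the detected shared segment always
    contains the identical-by-descent interval and overshoots it only by
    the few markers needed to reach an informative discordance."""
    overshoots = []
    usable = 0
    for seed in range(12):
        config = SimulationConfig(
            n_founders=500, n_generations=6, n_markers=300,
            chrom_length_bp=3_000_000, missing_rate=0.0, seed=seed,
        )
        ped = simulate_pedigree(config)
        geno = gene_drop(ped, config)
        copies = true_hap_copies(geno)
        cases = np.flatnonzero(copies == 2)
        if len(cases) < 8:
            continue
        usable += 1
        lo_bp, hi_bp = implanted_segment(geno)
        pos = geno.markers["pos"].to_numpy()
        true_lo = int(np.searchsorted(pos, lo_bp, side="left"))
        true_hi = int(np.searchsorted(pos, hi_bp, side="right")) - 1
        anchor = geno.meta["causal_index"]
        seg = shared_segment(geno.calls[cases], anchor, markers=geno.markers)
        assert seg.start_idx <= true_lo and seg.end_idx >= true_hi  # containment
        overshoots.append((true_lo - seg.start_idx) + (seg.end_idx - true_hi))
    assert usable >= 6
    assert np.median(overshoots) <= 6


# ---------------------------------------------------------------------------
# haplotype copy calling
# ---------------------------------------------------------------------------


def _phased_fixture(rng, n=12, m=15):
    """Phased toy: first 3 individuals homozygous for a shared haplotype."""
    consensus = rng.integers(0, 2, size=m).astype(np.int8)
    haps = rng.integers(0, 2, size=(n, 2, m)).astype(np.int8)
    for i in range(3):
        haps[i, 0] = consensus
        haps[i, 1] = consensus
    haps[3, 0] = consensus  # one carrier
    calls = haps.sum(axis=1).astype(np.int8)
    geno = make_genotype_matrix(calls, haplotypes=haps)
    from recmap.roh import Segment

    seg = Segment("19", 1000, m * 1000, 0, m - 1)
    return geno, seg, consensus


def test_cases_called_two_copies_carrier_one():
    rng = np.random.default_rng(2)
    geno, seg, consensus = _phased_fixture(rng)
    call = call_haplotype_copies(geno, seg, [f"I{i:03d}" for i in range(3)])
    assert np.array_equal(call.consensus, consensus)
    assert list(call.copies[:3]) == [2, 2, 2]
    assert call.copies[3] == 1  # consensus + random haplotype
    # random haplotypes essentially never match 15 markers exactly
    assert call.copies[4:].max() <= 1


def test_exact_threshold_engineered_mismatch_decrements():
    rng = np.random.default_rng(3)
    geno, seg, _ = _phased_fixture(rng)
    haps = geno.haplotypes.copy()
    haps[1, 1, 7] ^= 1  # one mismatch on one case haplotype
    geno2 = make_genotype_matrix(haps.sum(axis=1), haplotypes=haps)
    call = call_haplotype_copies(geno2, seg, [f"I{i:03d}" for i in range(3)],
                                 match_threshold=1.0)
    assert call.copies[1] == 1
    relaxed = call_haplotype_copies(geno2, seg, [f"I{i:03d}" for i in range(3)],
                                    match_threshold=0.9)
    assert relaxed.copies[1] == 2


def test_unphased_input_rejected():
    geno = make_genotype_matrix(np.zeros((4, 6), dtype=np.int8))
    from recmap.roh import Segment

    with pytest.raises(InputError, match="phased"):
        call_haplotype_copies(geno, Segment("19", 1, 6, 0, 5), ["I000"])


def test_copies_invariant_to_ordering_and_allele_relabelling():
    rng = np.random.default_rng(9)
    geno, seg, _ = _phased_fixture(rng)
    cases = [f"I{i:03d}" for i in range(3)]
    base = call_haplotype_copies(geno, seg, cases)
    # individual reordering
    perm = rng.permutation(geno.n_individuals)
    shuffled = call_haplotype_copies(geno.subset(individuals=perm), seg, cases)
    lookup = dict(zip(shuffled.ids, shuffled.copies))
    assert all(lookup[i] == c for i, c in zip(base.ids, base.copies))
    # strand-consistent allele relabelling: flip 0<->1 at some markers
    flip = rng.integers(0, 2, size=geno.n_markers).astype(bool)
    haps = geno.haplotypes.copy()
    haps[:, :, flip] ^= 1
    relabelled = make_genotype_matrix(haps.sum(axis=1), haplotypes=haps)
    again = call_haplotype_copies(relabelled, seg, cases)
    assert np.array_equal(again.copies, base.copies)


# ---------------------------------------------------------------------------
# Hardy-Weinberg on diplotype counts
# ---------------------------------------------------------------------------


def test_hwe_female_and_male_cohort_counts():
    """Diplotype counts of the two genotyped cohorts reproduce the
    published goodness-of-fit p-values."""
    _, p_f = hwe_chisq(DiplotypeCounts(1644, 291, 17, "females"))
    assert p_f == pytest.approx(0.303, abs=1e-3)
    _, p_m = hwe_chisq(DiplotypeCounts(6854, 1068, 40, "males"))
    assert p_m == pytest.approx(0.817, abs=1e-3)


def test_hwe_exact_proportions_give_p_one():
    counts = DiplotypeCounts(n0=8100, n1=1800, n2=100)  # q = 0.1 exactly
    chi2, p = hwe_chisq(counts)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("counts", [(1644, 291, 17), (6854, 1068, 40)])
def test_hwe_chisq_matches_parametric_bootstrap(counts):
    """10^6 multinomial draws under the fitted Hardy-Weinberg model give a
    bootstrap p within +-0.02 of the chi-square approximation."""
    n0, n1, n2 = counts
    chi2_obs, p_chi = hwe_chisq(DiplotypeCounts(n0, n1, n2))
    n = n0 + n1 + n2
    q = (2 * n2 + n1) / (2 * n)
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    rng = np.random.default_rng(0)
    draws = rng.multinomial(n, probs, size=1_000_000)
    qs = (2 * draws[:, 2] + draws[:, 1]) / (2 * n)
    exp = np.column_stack([n * (1 - qs) ** 2, 2 * n * qs * (1 - qs), n * qs**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_sim = np.nansum((draws - exp) ** 2 / exp, axis=1)
    p_boot = float((chi2_sim >= chi2_obs - 1e-9).mean())
    assert abs(p_boot - p_chi) < 0.02


def test_hwe_zero_total_rejected():
    with pytest.raises(InputError):
        hwe_chisq(DiplotypeCounts(0, 0, 0))


# ---------------------------------------------------------------------------
# carrier trend
# ---------------------------------------------------------------------------


def test_constant_carrier_frequency_gives_flat_trend():
    rng = np.random.default_rng(4)
    n = 5000
    pheno = pd.DataFrame({"birth_year": rng.integers(1990, 2010, n)})
    copies = rng.binomial(1, 0.13, n)
    slope, p = carrier_trend(pheno, copies)
    assert abs(slope) < 0.005
    assert p > 0.001  # no systematic signal


def test_known_linear_increase_recovered():
    """Implanted 0.003/year increase, n = 19000: slope within +-0.001."""
    rng = np.random.default_rng(8)
    n = 19000
    years = rng.integers(1985, 2010, n)
    prob = 0.08 + 0.003 * (years - 1985)
    copies = rng.binomial(1, prob)
    pheno = pd.DataFrame({"birth_year": years})
    slope, p = carrier_trend(pheno, copies)
    assert slope == pytest.approx(0.003, abs=0.001)
    assert p < 1e-6


def test_two_year_trend_equals_proportion_arithmetic():
    """With two birth years the OLS slope is the frequency difference over
    the year gap (closed form)."""
    pheno = pd.DataFrame({"birth_year": [2000] * 100 + [2010] * 200})
    copies = np.array([1] * 10 + [0] * 90 + [1] * 50 + [0] * 150)
    slope, _ = carrier_trend(pheno, copies)
    f1, f2 = 10 / 100, 50 / 200
    assert slope == pytest.approx((f2 - f1) / 10, rel=1e-12)


def test_constant_birth_year_rejected():
    pheno = pd.DataFrame({"birth_year": [2000] * 10})
    with pytest.raises(InputError, match="constant"):
        carrier_trend(pheno, np.zeros(10))


# ---------------------------------------------------------------------------
# haplotype dosage effect
# ---------------------------------------------------------------------------


def test_trait_equal_to_copies_gives_tiny_p():
    rng = np.random.default_rng(1)
    copies = rng.binomial(2, 0.2, 150).astype(float)
    effect, p = haplotype_effect(copies, copies, np.eye(150))
    assert p < 1e-100


def test_null_trait_p_uniform_over_seeds():
    """No implanted effect: dosage-test p-values over 60 seeded traits are
    uniform (Kolmogorov-Smirnov P > 0.01)."""
    rng = np.random.default_rng(6)
    n = 150
    copies = rng.binomial(2, 0.2, n).astype(float)
    dosages = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(n, 300)).astype(float)
    from recmap.gwas import build_grm

    grm = build_grm(dosages)
    ps = []
    for seed in range(60):
        y = np.random.default_rng(seed).standard_normal(n)
        _, p = haplotype_effect(y, copies, grm)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_zero_implanted_effect_cohort_shows_no_effect():
    """Female-cohort analogue: trait independent of copies, effect within
    noise (|b| < 3 SE)."""
    from recmap.gwas import haplotype_dosage_test

    rng = np.random.default_rng(13)
    n = 400
    copies = rng.binomial(2, 0.085, n).astype(float)
    y = rng.standard_normal(n)
    res = haplotype_dosage_test(y, copies, np.eye(n))
    assert abs(res["effect"]) < 3 * res["se"] + 1e-12


# ---------------------------------------------------------------------------
# CNV window screen
# ---------------------------------------------------------------------------


def test_constant_logr_gives_zero_means():
    logr = np.zeros((6, 9))
    out = cnv_window_logr(logr, ["a"] * 3 + ["b"] * 3, window=3)
    assert np.allclose(out["mean_logr"], 0.0)
    assert set(out["center_marker"]) == set(range(1, 8))


def test_hand_computed_window_means():
    logr = np.array(
        [[0.0, 0.2, 0.4, 0.6, 0.8],
         [0.2, 0.4, 0.6, 0.8, 1.0],
         [-0.3, -0.3, -0.3, -0.3, -0.3]]
    )
    out = cnv_window_logr(logr, ["g1", "g1", "g2"], window=3)
    g1 = out[out["group"] == "g1"].sort_values("center_marker")["mean_logr"].to_numpy()
    # group mean profile of g1 is [0.1, 0.3, 0.5, 0.7, 0.9]
    assert np.allclose(g1, [0.3, 0.5, 0.7])
    g2 = out[out["group"] == "g2"]["mean_logr"].to_numpy()
    assert np.allclose(g2, -0.3)


def test_implanted_deletion_shows_group_gap():
    rng = np.random.default_rng(30)
    n, m = 20, 41
    logr = rng.normal(0.0, 0.05, size=(n, m))
    labels = np.array(["case"] * 8 + ["control"] * 12)
    logr[:8, 15:26] -= 0.5  # deletion in cases only
    out = cnv_window_logr(logr, labels, window=3)
    case = out[out["group"] == "case"].set_index("center_marker")["mean_logr"]
    control = out[out["group"] == "control"].set_index("center_marker")["mean_logr"]
    gap = control - case
    assert gap.loc[20] > 0.4
    assert abs(gap.loc[5]) < 0.1


def test_window_contracts():
    with pytest.raises(InputError):
        cnv_window_logr(np.zeros((2, 5)), ["a", "b"], window=4)
    with pytest.raises(InputError):
        cnv_window_logr(np.zeros((2, 5)), ["a", "b"], window=7)


# ---------------------------------------------------------------------------
# fertility summaries
# ---------------------------------------------------------------------------


def test_published_insemination_arithmetic():
    from recmap.roh import (
        carrier_percent,
        haplotype_frequency_percent,
        inseminations_per_bull,
        percent_successful,
    )

    assert percent_successful(619, 35_671) == 1.74
    assert inseminations_per_bull(35_671, 40) == 892
    assert inseminations_per_bull(15_321_171, 7_962) == 1924
    counts = DiplotypeCounts(n0=7962 - 1068 - 40, n1=1068, n2=40)
    assert carrier_percent(counts) == 13.41
    assert haplotype_frequency_percent(counts) == 7.2


def test_fertility_summary_groups_and_empty_group():
    pheno = pd.DataFrame(
        {
            "mra": [-0.5, -1.0, -27.0, -28.0],
            "nrr56": [65.0, 64.0, 29.0, 30.0],
            "inseminations": [1000, 1200, 900, 880],
            "successes": [300, 350, 15, 16],
        }
    )
    copies = np.array([0, 0, 2, 2])
    out = fertility_summary(pheno, copies)
    assert list(out["n"]) == [2, 0, 2]
    hom = out[out["copies"] == 2].iloc[0]
    assert hom["inseminations"] == 1780
    assert hom["percent_successful"] == round(100 * 31 / 1780, 2)
    assert hom["inseminations_per_bull"] == 890
    het = out[out["copies"] == 1].iloc[0]
    assert np.isnan(het["mra_mean"])  # undefined mean flagged


def test_diplotype_counts_partition():
    copies = np.array([0, 1, 2, 1, 0, 0])
    counts = diplotype_counts(copies, "toy")
    assert (counts.n0, counts.n1, counts.n2) == (3, 2, 1)
    assert counts.n == 6


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=3, max_size=40),
    st.integers(0, 2),
    st.sampled_from([None, 0, 1]),
    st.data(),
)
def test_homozygosity_run_property(row_list, max_het, max_missing, data):
    """The returned run equals exhaustive window enumeration for arbitrary
    call patterns, tolerances and anchors."""
    row = np.array(row_list, dtype=np.int8)
    hom = np.flatnonzero(row != 1)
    if max_missing == 0:
        hom = np.flatnonzero((row != 1) & (row != MISSING))
    if len(hom) == 0:
        return
    anchor = int(data.draw(st.sampled_from(list(hom))))
    seg = homozygosity_run(row, anchor, max_het, max_missing)
    assert (seg.start_idx, seg.end_idx) == brute_force_run(row, anchor, max_het, max_missing)
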