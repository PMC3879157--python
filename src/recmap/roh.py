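"""Autozygosity mapping and haplotype statistics.

Affected individuals of a recessive defect share a homozygous chromosome
segment inherited identical-by-descent from the founder of the mutation.
This module finds each case's run of homozygosity around an anchor marker,
intersects the runs into the shared segment, calls 0/1/2 copies of the
case-defining (consensus) haplotype in phased data, and computes the
descriptive statistics around the mapped haplotype: Hardy-Weinberg
goodness of fit of the diplotype counts, the carrier-frequency trend over
birth years, the mixed-model dosage effect on other traits, a sliding
log R ratio screen for copy-number variants, and insemination-success
summaries per diplotype group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .genotypes import MISSING, GenotypeMatrix
from .qc import hwe_test_counts


@dataclass(frozen=True)
class Segment:
    """Contiguous genomic interval, 1-based inclusive, with marker bounds."""

    chrom: str
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise InputError(f"segment start {self.start_bp} > end {self.end_bp}")
        if self.start_idx > self.end_idx:
            raise InputError("segment marker indices inverted")

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def length_bp(self) -> int:
        """Reported as end - start + 1 (coordinates are authoritative)."""
        return self.end_bp - self.start_bp + 1

    def marker_slice(self) -> slice:
        return slice(self.start_idx, self.end_idx + 1)


@dataclass(frozen=True)
class DiplotypeCounts:
    """Individuals with 0/1/2 copies of the target haplotype in one group."""

    n0: int
    n1: int
    n2: int
    group: str = ""

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def haplotype_freq(self) -> float:
        return (2 * self.n2 + self.n1) / (2.0 * self.n)

    @property
    def carrier_fraction(self) -> float:
        return self.n1 / self.n


@dataclass
class HaplotypeCall:
    """Per-individual consensus-haplotype copies and match fractions."""

    ids: np.ndarray
    copies: np.ndarray  # (n,) in {0, 1, 2}
    match_fraction: np.ndarray  # (n, 2)
    consensus: np.ndarray  # allele sequence over segment markers


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------


def homozygosity_run(
    calls_row: np.ndarray,
    anchor_idx: int,
    max_het: int = 0,
    max_missing: int | None = None,
    markers: pd.DataFrame | None = None,
) -> Segment:
    """Maximal homozygous run through ``anchor_idx`` for one individual.

    The run is the longest contiguous marker window containing the anchor
    with at most ``max_het`` heterozygous and at most ``max_missing``
    missing calls (missing unlimited by default: absent calls should not
    break a run).  Ties on length are broken toward the leftmost window.
    The anchor genotype must be homozygous.
    """
    calls_row = np.asarray(calls_row)
    m = len(calls_row)
    if not 0 <= anchor_idx < m:
        raise InputError(f"anchor index {anchor_idx} outside 0..{m - 1}")
    if calls_row[anchor_idx] == 1:
        raise InputError(f"anchor marker {anchor_idx} not homozygous")
    if calls_row[anchor_idx] == MISSING and max_missing == 0:
        raise InputError(f"anchor marker {anchor_idx} missing with max_missing=0")

    het = (calls_row == 1).astype(int)
    mis = (calls_row == MISSING).astype(int)
    het_cum = np.concatenate([[0], np.cumsum(het)])
    mis_cum = np.concatenate([[0], np.cumsum(mis)])
    mis_budget = m if max_missing is None else max_missing

    def violates(left: int, right: int) -> bool:
        return (
            het_cum[right + 1] - het_cum[left] > max_het
            or mis_cum[right + 1] - mis_cum[left] > mis_budget
        )

    # two pointers: as the window extends left, the feasible right bound
    # can only shrink, so the sweep is linear in m
    right = anchor_idx
    while right + 1 < m and not violates(anchor_idx, right + 1):
        right += 1
    best = (anchor_idx, right)
    for left in range(anchor_idx - 1, -1, -1):
        if violates(left, anchor_idx):
            break
        while right > anchor_idx and violates(left, right):
            right -= 1
        if right - left >= best[1] - best[0]:  # ties toward the leftmost window
            best = (left, right)

    start_idx, end_idx = best
    if markers is not None:
        chrom = str(markers["chrom"].iloc[start_idx])
        start_bp = int(markers["pos"].iloc[start_idx])
        end_bp = int(markers["pos"].iloc[end_idx])
    else:
        chrom, start_bp, end_bp = "0", start_idx + 1, end_idx + 1
    return Segment(chrom, start_bp, end_bp, start_idx, end_idx)


def shared_segment(
    case_calls: np.ndarray,
    anchor_idx: int,
    max_het: int = 0,
    max_missing: int | None = None,
    markers: pd.DataFrame | None = None,
) -> Segment:
    """Marker-index intersection of every case's homozygous run.

    All cases must be homozygous at the anchor; an empty intersection
    raises (it cannot occur when every run contains the anchor, but guards
    degenerate inputs).
    """
    case_calls = np.atleast_2d(np.asarray(case_calls))
    if case_calls.shape[0] == 0:
        raise InputError("no case rows given")
    lo, hi = 0, case_calls.shape[1] - 1
    for row in case_calls:
        seg = homozygosity_run(row, anchor_idx, max_het, max_missing, markers=None)
        lo, hi = max(lo, seg.start_idx), min(hi, seg.end_idx)
    if lo > hi:
        raise InputError("no shared homozygous segment across cases")
    if markers is not None:
        return Segment(
            str(markers["chrom"].iloc[lo]),
            int(markers["pos"].iloc[lo]),
            int(markers["pos"].iloc[hi]),
            lo,
            hi,
        )
    return Segment("0", lo + 1, hi + 1, lo, hi)


# ---------------------------------------------------------------------------
# haplotype calling
# ---------------------------------------------------------------------------


def call_haplotype_copies(
    geno: GenotypeMatrix,
    segment: Segment,
    case_ids,
    match_threshold: float = 1.0,
) -> HaplotypeCall:
    """Count copies of the case consensus haplotype in every individual.

    The consensus is the per-marker majority allele over all case
    haplotypes within the segment (ties toward the reference allele).  An
    individual's copy count is the number of its phased haplotypes whose
    match fraction over non-missing segment markers reaches
    ``match_threshold`` (default: exact match).
    """
    if not geno.phased:
        raise InputError(
            "haplotype calling requires phased input; provide a phased VCF"
        )
    if not 0 < match_threshold <= 1:
        raise InputError("match_threshold must be in (0, 1]")
    sl = segment.marker_slice()
    case_rows = geno.individual_index(case_ids)
    case_haps = geno.haplotypes[case_rows][:, :, sl].reshape(-1, segment.n_markers)
    valid = case_haps != MISSING
    ones = np.where(valid, case_haps, 0).sum(axis=0)
    n_valid = valid.sum(axis=0)
    consensus = (ones * 2 > n_valid).astype(np.int8)  # tie -> 0 (reference)

    haps = geno.haplotypes[:, :, sl]
    observed = haps != MISSING
    agree = (haps == consensus) & observed
    n_obs = observed.sum(axis=2)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, agree.sum(axis=2) / np.maximum(n_obs, 1), 0.0)
    copies = (frac >= match_threshold).sum(axis=1).astype(int)
    return HaplotypeCall(
        ids=geno.ids.copy(),
        copies=copies,
        match_fraction=frac,
        consensus=consensus,
    )


def diplotype_counts(copies, group: str = "") -> DiplotypeCounts:
    copies = np.asarray(copies)
    return DiplotypeCounts(
        n0=int((copies == 0).sum()),
        n1=int((copies == 1).sum()),
        n2=int((copies == 2).sum()),
        group=group,
    )


# ---------------------------------------------------------------------------
# haplotype statistics
# ---------------------------------------------------------------------------


def hwe_chisq(counts: DiplotypeCounts) -> tuple[float, float]:
    """Hardy-Weinberg chi-square (1 df, no continuity correction) on
    diplotype counts; returns (chi2, p)."""
    return hwe_test_counts(counts.n0, counts.n1, counts.n2)


def carrier_trend(phenotypes: pd.DataFrame, copies) -> tuple[float, float]:
    """OLS regression of the carrier indicator on birth year.

    The outcome is individual-level 0/1 (at least one haplotype copy);
    returns (slope per year, two-sided p).  A constant birth year leaves
    the slope undefined and raises.
    """
    copies = np.asarray(copies)
    if "birth_year" not in phenotypes.columns:
        raise InputError("phenotype table lacks birth_year")
    years = phenotypes["birth_year"].to_numpy(dtype=float)
    if len(years) != len(copies):
        raise InputError("copies not aligned with phenotype table")
    if np.ptp(years) == 0:
        raise InputError("birth year is constant; trend slope undefined")
    carrier = (copies >= 1).astype(float)
    fit = stats.linregress(years, carrier)
    return float(fit.slope), float(fit.pvalue)


def carrier_trend_by_year(phenotypes: pd.DataFrame, copies) -> pd.DataFrame:
    """Carrier frequency aggregated per birth year (companion to the
    individual-level regression)."""
    copies = np.asarray(copies)
    table = pd.DataFrame(
        {"birth_year": phenotypes["birth_year"].to_numpy(), "carrier": copies >= 1}
    )
    out = table.groupby("birth_year", as_index=False).agg(
        n=("carrier", "size"), carrier_freq=("carrier", "mean")
    )
    return out


def haplotype_effect(trait, copies, grm, covariates=None) -> tuple[float, float]:
    """Mixed-model effect of haplotype dosage on a trait: (effect, p)."""
    from .gwas import haplotype_dosage_test

    res = haplotype_dosage_test(trait, copies, grm, covariates)
    return res["effect"], res["p"]


def cnv_window_logr(
    logr: np.ndarray, group_labels, window: int = 3
) -> pd.DataFrame:
    """Sliding-window group means of log R ratios over markers.

    ``logr`` is (individuals x markers); ``window`` must be odd so output
    aligns to the centre marker.  Returns a tidy table (group,
    center_marker, mean_logr) — a drop in log R in one group only flags a
    deletion segregating with that group.
    """
    logr = np.asarray(logr, dtype=float)
    labels = np.asarray(group_labels)
    if window < 1 or window % 2 == 0:
        raise InputError(f"window must be odd and >= 1, got {window}")
    n, m = logr.shape
    if window > m:
        raise InputError(f"window {window} exceeds {m} markers")
    if len(labels) != n:
        raise InputError("group labels not aligned with log R matrix")
    half = window // 2
    kernel = np.ones(window) / window
    rows = []
    for group in pd.unique(labels):
        mean_profile = logr[labels == group].mean(axis=0)
        sliding = np.convolve(mean_profile, kernel, mode="valid")
        for k, value in enumerate(sliding):
            rows.append(
                {"group": group, "center_marker": k + half, "mean_logr": float(value)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive fertility summaries
# ---------------------------------------------------------------------------


def percent_successful(successes: int, total: int) -> float:
    """Share of successful inseminations in percent, 2 decimals."""
    if total <= 0:
        raise InputError("total inseminations must be positive")
    return round(100.0 * successes / total, 2)


def inseminations_per_bull(total: int, n_bulls: int) -> int:
    """Average inseminations per bull, nearest integer."""
    if n_bulls <= 0:
        raise InputError("n_bulls must be positive")
    return int(round(total / n_bulls))


def carrier_percent(counts: DiplotypeCounts) -> float:
    """Heterozygote share of the group in percent, 2 decimals."""
    return round(100.0 * counts.n1 / counts.n, 2)


def haplotype_frequency_percent(counts: DiplotypeCounts, decimals: int = 1) -> float:
    """Haplotype frequency (2 n2 + n1) / 2N in percent."""
    return round(100.0 * counts.haplotype_freq, decimals)


def fertility_summary(phenotypes: pd.DataFrame, copies) -> pd.DataFrame:
    """Per-diplotype-group fertility summary.

    One row per copy group (0/1/2): N, mean +- SD of the fertility score
    and NRR56, total and successful inseminations, percent successful
    (2 decimals) and mean inseminations per bull (nearest integer).  Empty
    groups appear with N = 0 and undefined means flagged as NaN.
    """
    copies = np.asarray(copies)
    if "inseminations" not in phenotypes.columns:
        raise InputError("phenotype table lacks insemination counts")
    if len(copies) != len(phenotypes):
        raise InputError("copies not aligned with phenotype table")
    rows = []
    for g in (0, 1, 2):
        sub = phenotypes[copies == g]
        n = len(sub)
        total = int(sub["inseminations"].sum()) if n else 0
        succ = int(sub["successes"].sum()) if n and "successes" in sub else 0
        rows.append(
            {
                "copies": g,
                "n": n,
                "mra_mean": float(sub["mra"].mean()) if n else np.nan,
                "mra_sd": float(sub["mra"].std(ddof=1)) if n > 1 else np.nan,
                "nrr56_mean": float(sub["nrr56"].mean()) if n and "nrr56" in sub else np.nan,
                "nrr56_sd": float(sub["nrr56"].std(ddof=1)) if n > 1 and "nrr56" in sub else np.nan,
                "inseminations": total,
                "successes": succ,
                "percent_successful": percent_successful(succ, total) if total else np.nan,
                "inseminations_per_bull": inseminations_per_bull(total, n) if n else 0,
            }
        )
    return pd.DataFrame(rows)
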