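"""Genotype quality control and relationship checks.

Filters are applied in a fixed, documented order — individuals by call
rate, then markers by call rate, minor allele frequency and Hardy-Weinberg
equilibrium — because marker statistics should be computed on the cleaned
sample set.  The order is part of the contract: reordering can change the
result.  MAF and HWE use non-missing calls only; the HWE test is a 1-df
chi-square goodness of fit without continuity correction.

The module also provides the pedigree-based additive (numerator)
relationship matrix via the tabular recursion, a genomic-vs-pedigree
concordance check used to detect sample swaps, and a per-marker
case/control differential-missingness test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AllFilteredError,
    ConfigurationError,
    InputError,
    PedigreeError,
)
from .genotypes import MISSING, GenotypeMatrix

EXCLUSION_REASONS = (
    "individual_call_rate",
    "marker_call_rate",
    "maf",
    "hwe",
)


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the quality-control filters."""

    min_call_rate_individual: float = 0.95
    min_call_rate_marker: float = 0.95
    min_maf: float = 0.005
    hwe_p_threshold: float = 1e-6
    missingness_test_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "min_call_rate_individual",
            "min_call_rate_marker",
            "min_maf",
            "hwe_p_threshold",
            "missingness_test_alpha",
        ):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ConfigurationError(f"{name} must be in (0, 1), got {value}")


@dataclass
class QCReport:
    """Exclusions with reasons plus summary counts."""

    excluded_individuals: list[tuple[str, str]] = field(default_factory=list)
    excluded_markers: list[tuple[str, str]] = field(default_factory=list)
    missingness_pvalues: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, reason in self.excluded_individuals + self.excluded_markers:
            if reason not in EXCLUSION_REASONS:
                raise InputError(f"unknown exclusion reason {reason!r}")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ind = pd.DataFrame(self.excluded_individuals, columns=["id", "reason"])
        mark = pd.DataFrame(self.excluded_markers, columns=["marker", "reason"])
        return ind, mark

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ind, mark = self.to_frames()
        ind.to_csv(directory / "excluded_individuals.tsv", sep="\t", index=False)
        mark.to_csv(directory / "excluded_markers.tsv", sep="\t", index=False)
        if self.missingness_pvalues is not None:
            self.missingness_pvalues.to_csv(
                directory / "differential_missingness.tsv", sep="\t", index=False
            )
        with open(directory / "qc_summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def hwe_test_counts(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg.

    ``n0/n1/n2`` are genotype counts for 0/1/2 copies of the allele whose
    frequency is estimated as ``q = (2 n2 + n1) / 2N``.  No continuity
    correction is applied.
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise InputError("zero genotyped individuals")
    q = (2 * n2 + n1) / (2.0 * n)
    if q in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: fits trivially
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def apply_qc(geno: GenotypeMatrix, config: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard filters and return the cleaned matrix + report.

    Order: individuals by call rate, markers by call rate, MAF, HWE.
    Raises :class:`AllFilteredError` if nothing survives.
    """
    config = config or QCConfig()
    if geno.n_individuals < 2 or geno.n_markers < 1:
        raise InputError("QC needs at least 2 individuals and 1 marker")
    report = QCReport()

    cr_ind = geno.call_rate_individuals()
    keep_ind = cr_ind >= config.min_call_rate_individual
    report.excluded_individuals = [
        (str(i), "individual_call_rate") for i in geno.ids[~keep_ind]
    ]
    stage = geno.subset(individuals=keep_ind)
    if stage.n_individuals == 0:
        raise AllFilteredError("all individuals removed by call-rate filter")

    cr_mark = stage.call_rate_markers()
    keep_cr = cr_mark >= config.min_call_rate_marker

    maf = stage.minor_allele_freq()
    keep_maf = keep_cr & ~(np.nan_to_num(maf, nan=0.0) < config.min_maf)

    counts = stage.genotype_counts()
    keep_hwe = keep_maf.copy()
    hwe_p = np.full(stage.n_markers, np.nan)
    for j in np.flatnonzero(keep_maf):
        _, p = hwe_test_counts(*counts[j])
        hwe_p[j] = p
        if p < config.hwe_p_threshold:
            keep_hwe[j] = False

    names = stage.markers["name"].to_numpy()
    for j in range(stage.n_markers):
        if not keep_cr[j]:
            report.excluded_markers.append((str(names[j]), "marker_call_rate"))
        elif not keep_maf[j]:
            report.excluded_markers.append((str(names[j]), "maf"))
        elif not keep_hwe[j]:
            report.excluded_markers.append((str(names[j]), "hwe"))

    cleaned = stage.subset(markers=keep_hwe)
    if cleaned.n_markers == 0:
        raise AllFilteredError("all markers removed by QC filters")
    report.summary = {
        "n_individuals_in": int(geno.n_individuals),
        "n_markers_in": int(geno.n_markers),
        "n_individuals_out": int(cleaned.n_individuals),
        "n_markers_out": int(cleaned.n_markers),
        "excluded_individuals": len(report.excluded_individuals),
        "excluded_markers": len(report.excluded_markers),
    }
    return cleaned, report


def differential_missingness(
    geno: GenotypeMatrix, case_ids, control_ids
) -> pd.DataFrame:
    """Per-marker 2x2 test of missingness against case/control status.

    Uses Fisher's exact test when any expected cell count is below 5,
    otherwise a chi-square test without continuity correction.  Returns a
    table with per-marker missing counts and the two-sided p-value.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise InputError("case and control groups must be non-empty")
    if set(case_ids) & set(control_ids):
        raise InputError("case and control groups overlap")
    cases = geno.individual_index(case_ids)
    controls = geno.individual_index(control_ids)

    miss = geno.calls == MISSING
    rows = []
    for j in range(geno.n_markers):
        a = int(miss[cases, j].sum())  # cases missing
        b = len(cases) - a
        c = int(miss[controls, j].sum())  # controls missing
        d = len(controls) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        if table.sum() == 0:
            p = 1.0
        else:
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if (expected < 5).any():
                _, p = stats.fisher_exact(table)
            elif a + c == 0 or b + d == 0:
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "marker": geno.markers["name"].iloc[j],
                "case_missing": a,
                "case_observed": b,
                "control_missing": c,
                "control_observed": d,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def pedigree_relationship(ped, ids=None) -> pd.DataFrame:
    """Additive (numerator) relationship matrix by the tabular method.

    ``a(i, j) = 0.5 * (a(sire_i, j) + a(dam_i, j))`` for j preceding i and
    ``a(i, i) = 1 + 0.5 * a(sire_i, dam_i)``; founders are unrelated and
    non-inbred.  Returns a DataFrame indexed by id (subset to ``ids`` when
    given, computed on the full pedigree).
    """
    table = ped.table
    order = table.sort_values(["birth_year", "id"], kind="stable")
    all_ids = list(order["id"])
    index = {ident: k for k, ident in enumerate(all_ids)}
    n = len(all_ids)
    A = np.zeros((n, n))
    sires = [None if s is None else index[s] for s in order["sire"]]
    dams = [None if d is None else index[d] for d in order["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        if s is not None and s >= i or d is not None and d >= i:
            raise PedigreeError("pedigree not sorted: parent after offspring")
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[s, j]
            if d is not None:
                a += 0.5 * A[d, j]
            A[i, j] = A[j, i] = a
        inb = 0.5 * A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + inb
    frame = pd.DataFrame(A, index=all_ids, columns=all_ids)
    if ids is not None:
        ids = list(ids)
        missing = [i for i in ids if i not in index]
        if missing:
            raise InputError(f"ids absent from pedigree: {missing[:5]}")
        frame = frame.loc[ids, ids]
    return frame


def relationship_concordance(
    grm: pd.DataFrame, A: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Pairs whose |genomic - pedigree| relationship exceeds ``threshold``.

    Large discrepancies indicate sample swaps or pedigree errors.  Both
    matrices must be DataFrames on identical id sets; returned pairs are
    sorted by descending discrepancy (off-diagonal pairs once each,
    diagonal entries included as self-pairs).
    """
    if list(grm.index) != list(A.index) or list(grm.columns) != list(A.columns):
        raise InputError("genomic and pedigree matrices must share id order")
    g = grm.to_numpy()
    a = A.to_numpy()
    diff = np.abs(g - a)
    ids = list(grm.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i, len(ids)):
            if diff[i, j] > threshold:
                rows.append(
                    {
                        "id1": ids[i],
                        "id2": ids[j],
                        "genomic": g[i, j],
                        "pedigree": a[i, j],
                        "discrepancy": diff[i, j],
                    }
                )
    frame = pd.DataFrame(rows, columns=["id1", "id2", "genomic", "pedigree", "discrepancy"])
    return frame.sort_values("discrepancy", ascending=False, kind="stable").reset_index(
        drop=True
    )
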