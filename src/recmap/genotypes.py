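"""In-memory genotype containers.

The central container is :class:`GenotypeMatrix`: an individuals x markers
matrix of diploid allele counts in {0, 1, 2} with -1 marking missing calls,
a marker map (chromosome, 1-based position, ref/alt alleles), and optional
phase as an (n, 2, m) haplotype array.  All downstream stages (QC, GWAS,
autozygosity mapping) operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DimensionError, SampleLookupError

MISSING = -1

#: required columns of the marker map
MARKER_COLUMNS = ("name", "chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n`` individuals at ``m`` biallelic markers.

    Parameters
    ----------
    ids
        Individual identifiers, length ``n``.
    calls
        ``(n, m)`` int8 array of alternate-allele counts; ``-1`` is missing.
    markers
        Marker map with columns ``name, chrom, pos, ref, alt`` (1-based
        positions).
    haplotypes
        Optional ``(n, 2, m)`` int8 array of phased alleles (0 = ref,
        1 = alt, -1 = missing).  Present iff the data are phased.
    meta
        Free-form per-dataset annotations (e.g. sex, birth year, simulation
        truth) keyed by name; array values are aligned with ``ids``.
    """

    ids: np.ndarray
    calls: np.ndarray
    markers: pd.DataFrame
    haplotypes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise DimensionError("calls must be a 2-d (individuals x markers) array")
        if self.calls.shape[0] != len(self.ids):
            raise DimensionError(
                f"{len(self.ids)} ids but calls has {self.calls.shape[0]} rows"
            )
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise DimensionError(f"marker map lacks columns {missing_cols}")
        if len(self.markers) != self.calls.shape[1]:
            raise DimensionError(
                f"marker map has {len(self.markers)} rows but calls has "
                f"{self.calls.shape[1]} columns"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.ids), 2, self.calls.shape[1]):
                raise DimensionError("haplotypes must have shape (n, 2, m)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def individual_index(self, ids) -> np.ndarray:
        """Positions of ``ids`` in the matrix; unknown ids raise."""
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise SampleLookupError(f"unknown individual id {exc.args[0]!r}") from None

    # -- summaries ------------------------------------------------------
    def call_rate_individuals(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def call_rate_markers(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """``(m, 3)`` counts of genotypes 0/1/2 per marker (missing excluded)."""
        out = np.empty((self.n_markers, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.calls == g).sum(axis=0)
        return out

    # -- subsetting -----------------------------------------------------
    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        """Return a copy restricted to boolean masks or integer indices."""
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        haps = None
        if self.haplotypes is not None:
            haps = self.haplotypes[rows][:, :, cols]
        meta = {}
        for key, val in self.meta.items():
            arr = np.asarray(val)
            if arr.ndim >= 1 and arr.shape[0] == self.n_individuals:
                meta[key] = arr[rows]
            else:
                meta[key] = val
        return GenotypeMatrix(
            ids=self.ids[rows],
            calls=self.calls[rows][:, cols],
            markers=self.markers.iloc[cols].reset_index(drop=True),
            haplotypes=haps,
            meta=meta,
        )

    def with_calls(self, calls: np.ndarray) -> "GenotypeMatrix":
        return replace(self, calls=np.asarray(calls, dtype=np.int8))

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Exact equality of ids, calls, map and phase (meta ignored)."""
        if not (
            np.array_equal(self.ids, other.ids)
            and np.array_equal(self.calls, other.calls)
            and self.markers[list(MARKER_COLUMNS)]
            .reset_index(drop=True)
            .equals(other.markers[list(MARKER_COLUMNS)].reset_index(drop=True))
        ):
            return False
        if (self.haplotypes is None) != (other.haplotypes is None):
            return False
        if self.haplotypes is not None and not np.array_equal(
            self.haplotypes, other.haplotypes
        ):
            return False
        return True
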