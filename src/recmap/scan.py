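"""Recessive-compatibility filtering of a resequencing panel.

A small panel of whole-genome re-sequenced animals is screened for variants
compatible with recessive inheritance of a mapped haplotype.  Each panel
sample carries a carrier flag (does it carry the defect haplotype on array
genotypes?) and a coverage class: HC (high coverage, reliable genotypes) or
LC (low coverage, heterozygotes may be under-called).

Two filter modes are provided:

``strict``
    A variant survives iff it is heterozygous in *every* carrier and
    homozygous reference in *every* non-carrier.  This is the idealised
    filter for error-free genotypes.

``conservative``
    Tolerates heterozygote miscalls in low-coverage carriers.  A variant
    survives iff (i) its non-reference allele frequency across the panel is
    below ``af_max``, (ii) it is heterozygous in the single high-coverage
    carrier and (iii) it is heterozygous in at least ``min_lc_het`` of the
    low-coverage carriers.  Non-carrier genotypes are unconstrained.

Missing genotypes fail any heterozygosity requirement and are excluded
from allele-frequency denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

MISSING = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "vtype")


def variant_type(ref: str, alt: str) -> str:
    """SNP for single-base substitutions, INDEL otherwise."""
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass
class SequencePanel:
    """Genotypes of a resequencing panel with carrier/coverage annotations.

    ``genotypes`` is ``(n_variants, n_samples)`` int8 with 0 = hom-ref,
    1 = het, 2 = hom-alt, -1 = missing.  ``coverage`` takes values
    ``HC``/``LC`` for carriers and ``none`` for non-carriers.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: np.ndarray
    carrier: np.ndarray
    coverage: np.ndarray
    causal_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.carrier = np.asarray(self.carrier, dtype=bool)
        self.coverage = np.asarray(self.coverage, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise InputError(f"variant table lacks columns {missing_cols}")
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise InputError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if len(self.carrier) != len(self.samples) or len(self.coverage) != len(self.samples):
            raise InputError("carrier/coverage annotations must align with samples")
        bad = (~self.carrier) & np.isin(self.coverage, ("HC", "LC"))
        if bad.any():
            raise InputError(
                f"coverage class HC/LC declared for non-carriers: {list(self.samples[bad])}"
            )
        pos = self.variants["pos"].to_numpy()
        if len(pos) > 1 and np.any(np.diff(pos) < 0):
            raise InputError("variant positions must be sorted")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def carrier_mask(self) -> np.ndarray:
        return self.carrier

    def allele_freq(self) -> np.ndarray:
        """Non-reference allele frequency per variant over non-missing calls."""
        obs = self.genotypes != MISSING
        n_obs = obs.sum(axis=1)
        alt = np.where(obs, self.genotypes, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def subset_variants(self, index) -> "SequencePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        causal = None
        if self.causal_index is not None:
            hits = np.flatnonzero(index == self.causal_index)
            causal = int(hits[0]) if hits.size else None
        return replace(
            self,
            variants=self.variants.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            causal_index=causal,
        )


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the recessive-compatibility filter."""

    af_max: float = 0.10
    min_lc_het: int = 3
    mode: str = "conservative"

    def __post_init__(self) -> None:
        if not 0 < self.af_max <= 1:
            raise ConfigurationError(f"af_max must be in (0, 1], got {self.af_max}")
        if self.min_lc_het < 0:
            raise ConfigurationError(f"min_lc_het must be >= 0, got {self.min_lc_het}")
        if self.mode not in ("strict", "conservative"):
            raise ConfigurationError(f"mode must be strict|conservative, got {self.mode!r}")


def restrict_to_region(panel: SequencePanel, segment) -> SequencePanel:
    """Variants with ``start_bp <= pos <= end_bp`` (inclusive bounds).

    ``segment`` is anything with ``chrom``, ``start_bp`` and ``end_bp``
    attributes (e.g. the shared homozygous segment).
    """
    pos = panel.variants["pos"].to_numpy()
    mask = (
        (panel.variants["chrom"].astype(str) == str(segment.chrom)).to_numpy()
        & (pos >= segment.start_bp)
        & (pos <= segment.end_bp)
    )
    return panel.subset_variants(mask)


def strict_filter(panel: SequencePanel) -> np.ndarray:
    """Indices of variants het in all carriers and hom-ref in all non-carriers."""
    carriers = panel.carrier
    if not carriers.any():
        raise ConfigurationError("strict filter requires at least one declared carrier")
    geno = panel.genotypes
    het_all_carriers = (geno[:, carriers] == 1).all(axis=1)
    homref_all_others = (geno[:, ~carriers] == 0).all(axis=1)
    return np.flatnonzero(het_all_carriers & homref_all_others)


def conservative_filter(panel: SequencePanel, config: FilterConfig | None = None) -> np.ndarray:
    """Indices of variants passing the three-condition carrier-tolerant filter.

    Conditions: panel non-reference allele frequency strictly below
    ``af_max``; heterozygous in the (single) high-coverage carrier;
    heterozygous in at least ``min_lc_het`` low-coverage carriers.
    """
    config = config or FilterConfig()
    hc = panel.carrier & (panel.coverage == "HC")
    lc = panel.carrier & (panel.coverage == "LC")
    if hc.sum() != 1:
        raise ConfigurationError(
            f"conservative filter expects exactly one HC carrier, found {int(hc.sum())}"
        )
    if lc.sum() < config.min_lc_het:
        raise ConfigurationError(
            f"min_lc_het={config.min_lc_het} exceeds the {int(lc.sum())} declared LC carriers"
        )
    geno = panel.genotypes
    af_ok = panel.allele_freq() < config.af_max
    hc_het = (geno[:, hc] == 1).all(axis=1)
    lc_het_count = (geno[:, lc] == 1).sum(axis=1)
    return np.flatnonzero(af_ok & hc_het & (lc_het_count >= config.min_lc_het))


def expected_carrier_af(n_carriers: int, n_samples: int) -> float:
    """Expected panel allele frequency of the causal allele: carriers/(2 x samples)."""
    if n_samples <= 0:
        raise InputError("n_samples must be positive")
    if n_carriers > 2 * n_samples:
        raise InputError("more carrier alleles than alleles in the panel")
    return n_carriers / (2.0 * n_samples)


def classify_retained(panel: SequencePanel, index, gene_models) -> dict:
    """Partition retained variants by CDS overlap with the gene models.

    Returns ``{"coding": indices, "noncoding": indices}``; the coding subset
    is what feeds consequence annotation.
    """
    from .annotate import GeneModel

    if isinstance(gene_models, GeneModel):
        gene_models = [gene_models]
    index = np.asarray(index, dtype=int)
    coding, noncoding = [], []
    for i in index:
        chrom = str(panel.variants["chrom"].iloc[i])
        pos = int(panel.variants["pos"].iloc[i])
        in_cds = any(gm.chrom == chrom and gm.contains(pos) for gm in gene_models)
        (coding if in_cds else noncoding).append(int(i))
    return {"coding": np.array(coding, dtype=int), "noncoding": np.array(noncoding, dtype=int)}


def genotype_class_report(panel: SequencePanel, index) -> pd.DataFrame:
    """Per-variant genotype class counts split by carrier status.

    One row per retained variant with hom-ref / het / hom-alt / missing
    counts among carriers and non-carriers — the layout of a candidate
    compatibility table.
    """
    index = np.asarray(index, dtype=int)
    carriers = panel.carrier
    rows = []
    for i in index:
        g = panel.genotypes[i]
        row = {
            "chrom": panel.variants["chrom"].iloc[i],
            "pos": panel.variants["pos"].iloc[i],
            "ref": panel.variants["ref"].iloc[i],
            "alt": panel.variants["alt"].iloc[i],
            "vtype": panel.variants["vtype"].iloc[i],
        }
        for label, mask in (("carrier", carriers), ("noncarrier", ~carriers)):
            sub = g[mask]
            row[f"{label}_homref"] = int((sub == 0).sum())
            row[f"{label}_het"] = int((sub == 1).sum())
            row[f"{label}_homalt"] = int((sub == 2).sum())
            row[f"{label}_missing"] = int((sub == MISSING).sum())
        rows.append(row)
    return pd.DataFrame(rows)
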