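"""Gene-drop population simulator for recessive-defect mapping.

Emulates the statistical structure of a livestock population segregating a
recessive fertility defect descending from a single founder sire:

* a multi-generation pedigree with heavy sire reuse, one founder flagged as
  the mutation founder;
* phased array genotypes produced by Mendelian gene drop with Poisson
  crossovers (no interference), the deleterious haplotype implanted on one
  founder chromosome and tracked exactly (per-haplotype descent interval);
* a quantitative fertility score (MRA, a percentage deviation from the
  population mean) with a polygenic component and a large negative shift in
  haplotype homozygotes only — heterozygotes are indistinguishable from
  non-carriers;
* a small resequencing panel containing the causal variant plus neutral
  decoys, with heterozygote under-calling in low-coverage carriers;
* a single-transcript gene model and reference sequence so that the causal
  variant has a defined coding consequence (a premature stop codon).

Every operation is deterministic given ``SimulationConfig.seed``; the seed
is combined with a per-stage stream index so stages can be re-run
independently without correlating their draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .exceptions import (
    ConfigurationError,
    DimensionError,
    InputError,
    PedigreeError,
    SampleLookupError,
)
from .genotypes import MISSING, GenotypeMatrix
from .scan import SequencePanel, variant_type

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the study-structured synthetic population.

    Trait defaults are the case/control group means and standard deviations
    of the modelled fertility score (controls -0.44 +- 3.16, haplotype
    homozygotes -27.69 +- 4.15), the target haplotype frequency is 7.2%,
    and insemination-count means follow the study cohort (1924 per normal
    bull, 892 per subfertile bull).
    """

    n_founders: int = 500
    n_generations: int = 8
    offspring_per_sire: int = 10
    n_markers: int = 600
    chrom_length_bp: int = 10_000_000
    recomb_rate: float = 1.0  # Morgans per chromosome
    target_hap_freq: float = 0.072
    mra_base_mean: float = -0.44
    mra_base_sd: float = 3.16
    mra_hom_mean: float = -27.69
    mra_hom_sd: float = 4.15
    polygenic_h2: float = 0.20
    missing_rate: float = 0.008
    seed: int = 0
    # auxiliary structure
    chrom: str = "19"
    causal_index: int | None = None  # defaults to the middle marker
    nrr_base_mean: float = 65.46
    nrr_base_sd: float = 5.35
    nrr_hom_mean: float = 29.16
    nrr_hom_sd: float = 5.27
    mra_nrr_corr: float = 0.59
    insem_mean: float = 1924.0
    insem_mean_hom: float = 892.0
    base_success_rate: float = 0.30
    success_per_mra: float = 0.0102
    founder_birth_year: int = 1966
    years_per_generation: int = 6

    def __post_init__(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_generations": self.n_generations,
            "offspring_per_sire": self.offspring_per_sire,
            "chrom_length_bp": self.chrom_length_bp,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_markers < 2:
            raise ConfigurationError(f"n_markers must be >= 2, got {self.n_markers}")
        fractions = {
            "target_hap_freq": self.target_hap_freq,
            "missing_rate": self.missing_rate,
        }
        for name, value in fractions.items():
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if not 0 < self.target_hap_freq < 1:
            raise ConfigurationError(
                f"target_hap_freq must be in (0, 1), got {self.target_hap_freq}"
            )
        if not 0 <= self.polygenic_h2 < 1:
            raise ConfigurationError(
                f"polygenic_h2 must be in [0, 1), got {self.polygenic_h2}"
            )
        if self.recomb_rate < 0:
            raise ConfigurationError(f"recomb_rate must be >= 0, got {self.recomb_rate}")
        if self.mra_hom_mean >= self.mra_base_mean:
            raise ConfigurationError(
                "mra_hom_mean must be below mra_base_mean (deleterious direction): "
                f"got {self.mra_hom_mean} >= {self.mra_base_mean}"
            )
        for name in ("mra_base_sd", "mra_hom_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.causal_index is not None and not 0 <= self.causal_index < self.n_markers:
            raise ConfigurationError(
                f"causal_index must be a marker index in [0, {self.n_markers}), "
                f"got {self.causal_index}"
            )

    @property
    def causal_marker(self) -> int:
        return self.n_markers // 2 if self.causal_index is None else self.causal_index

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SequencePanelConfig:
    """Parameters of the simulated resequencing panel.

    Defaults mirror the study design: 43 animals, six haplotype carriers of
    which one was sequenced at high coverage and five at low coverage; the
    heterozygote miscall rate of 0.4 matches the observed loss of the causal
    heterozygous call in two of five low-coverage carriers.
    """

    n_samples: int = 43
    n_hc_carriers: int = 1
    n_lc_carriers: int = 5
    het_miscall_rate: float = 0.4
    n_region_variants: int = 200
    causal_index: int | None = None
    indel_fraction: float = 0.114  # 678 of 5965 region variants
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc_carriers + self.n_lc_carriers > self.n_samples:
            raise ConfigurationError(
                "n_hc_carriers + n_lc_carriers exceeds n_samples "
                f"({self.n_hc_carriers}+{self.n_lc_carriers} > {self.n_samples})"
            )
        if not 0 <= self.het_miscall_rate < 1:
            raise ConfigurationError(
                f"het_miscall_rate must be in [0, 1), got {self.het_miscall_rate}"
            )
        if self.n_region_variants < 1:
            raise ConfigurationError("n_region_variants must be >= 1")
        if not 0 <= self.indel_fraction < 1:
            raise ConfigurationError("indel_fraction must be in [0, 1)")
        if self.causal_index is not None and not (
            0 <= self.causal_index < self.n_region_variants
        ):
            raise ConfigurationError(
                f"causal_index must be in [0, {self.n_region_variants}), "
                f"got {self.causal_index}"
            )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Pedigree records: id, sire, dam (None for founders), birth year, sex.

    ``founder_id`` flags the sire on which the deleterious haplotype is
    implanted during gene drop.
    """

    table: pd.DataFrame
    founder_id: str | None = None

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "birth_year", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {sorted(missing)}")
        self._row = {r.id: r for r in self.table.itertuples(index=False)}
        for rec in self.table.itertuples(index=False):
            for parent in (rec.sire, rec.dam):
                if parent is None:
                    continue
                if parent not in self._row:
                    raise PedigreeError(f"parent {parent!r} of {rec.id!r} has no record")
                if self._row[parent].birth_year >= rec.birth_year:
                    raise PedigreeError(
                        f"parent {parent!r} not born before offspring {rec.id!r}"
                    )

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.table)

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        rec = self._row[individual]
        return rec.sire, rec.dam

    def is_founder(self, individual: str) -> bool:
        sire, dam = self.parents(individual)
        return sire is None and dam is None

    def ancestors(self, individual: str) -> set[str]:
        """All ancestors of ``individual`` by graph traversal."""
        out: set[str] = set()
        stack = [p for p in self.parents(individual) if p is not None]
        while stack:
            a = stack.pop()
            if a in out:
                continue
            out.add(a)
            stack.extend(p for p in self.parents(a) if p is not None)
        return out


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a discrete-generation pedigree with heavy sire reuse.

    Generation sizes are constant at ``n_founders``.  The flagged founder
    sire fathers a fraction ``4 * target_hap_freq`` of the first offspring
    generation, so that the expected frequency of his implanted haplotype —
    half his expected genome share, which is preserved under the random
    parent sampling of later generations — settles at ``target_hap_freq``.
    Remaining matings draw ``ceil(size / offspring_per_sire)`` sires at
    random from the previous generation and dams uniformly at random.
    """
    rng = _rng(config.seed, 0)
    size = config.n_founders
    rows: list[dict] = []
    generation: list[str] = []
    sexes: dict[str, str] = {}

    def add(gen: int, i: int, sire: str | None, dam: str | None) -> str:
        ident = f"G{gen}_{i:05d}"
        sex = "M" if i % 2 == 0 else "F"  # alternate within generation
        rows.append(
            {
                "id": ident,
                "sire": sire,
                "dam": dam,
                "birth_year": config.founder_birth_year + gen * config.years_per_generation,
                "sex": sex,
                "generation": gen,
            }
        )
        sexes[ident] = sex
        return ident

    generation = [add(0, i, None, None) for i in range(size)]
    founder_id = next(i for i in generation if sexes[i] == "M")

    for gen in range(1, config.n_generations):
        males = [i for i in generation if sexes[i] == "M"]
        females = [i for i in generation if sexes[i] == "F"]
        if not males or not females:
            raise PedigreeError(
                f"generation {gen - 1} lacks {'males' if not males else 'females'}"
            )
        n_sires = max(1, math.ceil(size / config.offspring_per_sire))
        pool = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        sires = rng.choice(pool, size=size, replace=True)
        if gen == 1:
            n_founder_off = round(min(4 * config.target_hap_freq, 0.5) * size)
            sires[:n_founder_off] = founder_id
        dams = rng.choice(females, size=size, replace=True)
        generation = [add(gen, i, str(sires[i]), str(dams[i])) for i in range(size)]

    ped = Pedigree(pd.DataFrame(rows), founder_id=founder_id)
    return ped


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------


def _meiosis(
    haps: np.ndarray,
    origin: np.ndarray,
    positions: np.ndarray,
    chrom_length: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent: mosaic of the two parental haplotypes.

    Crossover count is Poisson(``recomb_rate``), positions uniform on the
    chromosome; segment sources alternate starting from a random haplotype.
    The per-marker founder-gamete label ``origin`` is transmitted with the
    alleles, so identity-by-descent of every chromosome chunk is tracked
    exactly.
    """
    n_cross = rng.poisson(recomb_rate)
    start = rng.integers(2)
    if n_cross == 0:
        return haps[start].copy(), origin[start].copy()
    cross = np.sort(rng.integers(1, chrom_length + 1, size=n_cross)).astype(float)
    # source haplotype for each marker: number of crossovers at or before pos
    source = (start + np.searchsorted(cross, positions, side="right")) % 2
    idx = np.arange(len(positions))
    return haps[source, idx], origin[source, idx]


def gene_drop(ped: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Drop alleles down the pedigree and return phased genotypes.

    Founder haplotype alleles are drawn per marker from allele frequencies
    uniform on (0.05, 0.95) so array markers are informative; the causal
    marker is monomorphic reference except for one implanted copy on the
    founder sire's first haplotype.  Missing calls are injected i.i.d. at
    ``missing_rate`` into the unphased calls only — the haplotypes are the
    simulation truth and stay complete.

    The returned matrix carries simulation truth in ``meta``: per-individual
    sex, birth year and generation, the per-haplotype mutant flag
    ``hap_mut`` (n, 2) and the exact per-marker founder-descent indicator
    ``hap_origin`` (n, 2, m) of the implanted founder chromosome.
    """
    rng = _rng(config.seed, 1)
    m = config.n_markers
    length = config.chrom_length_bp
    if m > length:
        raise ConfigurationError("n_markers exceeds chrom_length_bp")
    positions = np.sort(rng.choice(length, size=m, replace=False) + 1)
    causal = config.causal_marker
    causal_pos = int(positions[causal])

    ref = rng.choice(4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    markers = pd.DataFrame(
        {
            "name": [f"M{i:05d}" for i in range(m)],
            "chrom": config.chrom,
            "pos": positions,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
        }
    )

    freqs = rng.uniform(0.05, 0.95, size=m)
    freqs[causal] = 0.0

    order = ped.table.sort_values(["generation", "id"]) if "generation" in ped.table.columns else ped.table
    haps: dict[str, np.ndarray] = {}
    origin: dict[str, np.ndarray] = {}
    founder_count = 0
    founder_label = None
    for rec in order.itertuples(index=False):
        if rec.sire is None:
            h = (rng.uniform(size=(2, m)) < freqs).astype(np.int8)
            labels = np.array([2 * founder_count, 2 * founder_count + 1], dtype=np.int32)
            o = np.repeat(labels[:, None], m, axis=1)
            founder_count += 1
            if rec.id == ped.founder_id:
                h[0, causal] = 1
                founder_label = int(labels[0])  # the implanted chromosome
            haps[rec.id], origin[rec.id] = h, o
        else:
            h = np.empty((2, m), dtype=np.int8)
            o = np.empty((2, m), dtype=bool)
            for k, parent in enumerate((rec.sire, rec.dam)):
                h[k], o[k] = _meiosis(
                    haps[parent],
                    origin[parent],
                    positions,
                    length,
                    config.recomb_rate,
                    rng,
                )
            haps[rec.id], origin[rec.id] = h, o

    ids = ped.ids
    hap_arr = np.stack([haps[i] for i in ids])
    origin_arr = np.stack([origin[i] for i in ids])
    calls = hap_arr.sum(axis=1).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.uniform(size=calls.shape) < config.missing_rate
        calls[mask] = MISSING

    meta = {
        "sex": ped.table["sex"].to_numpy(dtype=object),
        "birth_year": ped.table["birth_year"].to_numpy(),
        "generation": ped.table.get("generation", pd.Series(np.zeros(len(ids)))).to_numpy(),
        "hap_mut": origin_arr[:, :, causal] == founder_label,
        "hap_origin": origin_arr,
        "founder_label": founder_label,
        "causal_index": causal,
        "causal_pos": causal_pos,
        "founder_id": ped.founder_id,
    }
    return GenotypeMatrix(ids=ids, calls=calls, markers=markers, haplotypes=hap_arr, meta=meta)


def true_hap_copies(geno: GenotypeMatrix) -> np.ndarray:
    """Per-individual copies (0/1/2) of the implanted haplotype (truth)."""
    if "hap_mut" not in geno.meta:
        raise InputError("genotype matrix carries no simulation truth (hap_mut)")
    return geno.meta["hap_mut"].sum(axis=1).astype(int)


def implanted_segment(geno: GenotypeMatrix, ids=None) -> tuple[int, int]:
    """Truth interval (bp) shared by all mutant haplotypes of ``ids``.

    Defaults to all haplotype homozygotes: the maximal marker run around
    the causal site over which every case chromosome is identical by
    descent (all carry the same founder-gamete label, whether that chunk
    comes from the mutation founder or from a shared recombinant
    ancestor) — the target of autozygosity mapping.
    """
    copies = true_hap_copies(geno)
    if ids is None:
        rows = np.flatnonzero(copies == 2)
    else:
        rows = geno.individual_index(ids)
    if len(rows) == 0:
        raise InputError("no haplotype homozygotes to intersect")
    origin = geno.meta["hap_origin"][rows]
    muts = geno.meta["hap_mut"][rows]
    labels = origin[muts]  # (n_case_haplotypes, m) founder-gamete labels
    shared = (labels == labels[0]).all(axis=0)
    causal = geno.meta["causal_index"]
    lo = causal
    while lo > 0 and shared[lo - 1]:
        lo -= 1
    hi = causal
    while hi + 1 < len(shared) and shared[hi + 1]:
        hi += 1
    pos = geno.markers["pos"].to_numpy()
    return int(pos[lo]), int(pos[hi])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    geno: GenotypeMatrix,
    hap_copies,
    config: SimulationConfig,
    grm=None,
    males_only: bool = True,
) -> pd.DataFrame:
    """Simulate the fertility score and auxiliary records per individual.

    MRA = base mean + polygenic value + residual; the polygenic variance is
    ``polygenic_h2`` of the total and is correlated through the realized
    relationship matrix when ``grm`` is given (otherwise i.i.d.).  Haplotype
    homozygotes are rescaled so their marginal distribution has the
    configured case mean and SD; 0- and 1-copy individuals are identically
    distributed (recessiveness).  NRR56 is generated with the configured
    within-group correlation to MRA, and insemination counts/successes
    follow Poisson/binomial models with a success rate linear in MRA.

    By default only males are phenotyped (fertility scores are sires');
    set ``males_only=False`` to phenotype everyone.
    """
    hap_copies = np.asarray(hap_copies)
    n = geno.n_individuals
    if len(hap_copies) != n:
        raise DimensionError(
            f"hap_copies has length {len(hap_copies)} but genotypes have {n} individuals"
        )
    rng = _rng(config.seed, 2)
    sd = config.mra_base_sd
    sig_g = math.sqrt(config.polygenic_h2) * sd
    sig_e = math.sqrt(1.0 - config.polygenic_h2) * sd

    if grm is not None and sig_g > 0:
        matrix = grm.matrix if hasattr(grm, "matrix") else np.asarray(grm)
        if matrix.shape != (n, n):
            raise DimensionError(
                f"grm shape {matrix.shape} does not match {n} individuals"
            )
        chol = np.linalg.cholesky(matrix + 1e-6 * np.eye(n))
        g = sig_g * (chol @ rng.standard_normal(n))
    else:
        g = sig_g * rng.standard_normal(n)
    e = sig_e * rng.standard_normal(n)
    mra = config.mra_base_mean + g + e

    hom = hap_copies == 2
    mra[hom] = config.mra_hom_mean + (mra[hom] - config.mra_base_mean) * (
        config.mra_hom_sd / config.mra_base_sd
    )

    # NRR56 with the configured within-group correlation to MRA
    r = config.mra_nrr_corr
    z = rng.standard_normal(n)
    nrr = np.empty(n)
    for mask, mu_m, sd_m, mu_n, sd_n in (
        (~hom, config.mra_base_mean, config.mra_base_sd, config.nrr_base_mean, config.nrr_base_sd),
        (hom, config.mra_hom_mean, config.mra_hom_sd, config.nrr_hom_mean, config.nrr_hom_sd),
    ):
        nrr[mask] = (
            mu_n
            + r * sd_n / sd_m * (mra[mask] - mu_m)
            + math.sqrt(1.0 - r * r) * sd_n * z[mask]
        )

    insem_mean = np.where(hom, config.insem_mean_hom, config.insem_mean)
    inseminations = rng.poisson(insem_mean)
    rate = np.clip(config.base_success_rate + config.success_per_mra * mra, 0.0, 1.0)
    successes = rng.binomial(inseminations, rate)

    table = pd.DataFrame(
        {
            "id": geno.ids,
            "mra": mra,
            "nrr56": nrr,
            "birth_year": geno.meta.get("birth_year", np.zeros(n, dtype=int)),
            "sex": geno.meta.get("sex", np.array(["M"] * n, dtype=object)),
            "hap_copies": hap_copies,
            "inseminations": inseminations,
            "successes": successes,
        }
    )
    table["case"] = table["mra"] < -20.0
    if males_only:
        table = table[table["sex"] == "M"].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# resequencing panel
# ---------------------------------------------------------------------------


def simulate_sequence_panel(
    geno: GenotypeMatrix,
    carriers,
    panel_config: SequencePanelConfig,
    region: tuple[int, int] | None = None,
    causal_variant: tuple[int, str, str] | None = None,
) -> SequencePanel:
    """Simulate sequence-derived genotypes for a carrier/non-carrier panel.

    ``carriers`` lists exactly the HC + LC carriers (first
    ``n_hc_carriers`` are high coverage).  The panel contains the causal
    variant — heterozygous in every carrier, homozygous reference elsewhere
    before errors — plus neutral decoys at Hardy-Weinberg genotypes.  Every
    heterozygous call of a low-coverage carrier is independently converted
    to homozygous reference with probability ``het_miscall_rate``;
    high-coverage calls are error-free.

    ``causal_variant`` optionally pins the causal record to a known
    ``(pos, ref, alt)`` (e.g. the stop-gain position of a fixture gene).
    """
    cfg = panel_config
    rng = _rng(cfg.seed, 3)
    carriers = list(carriers)
    if len(carriers) != cfg.n_hc_carriers + cfg.n_lc_carriers:
        raise ConfigurationError(
            f"expected {cfg.n_hc_carriers + cfg.n_lc_carriers} carriers "
            f"(HC + LC), got {len(carriers)}"
        )
    carrier_rows = geno.individual_index(carriers)  # raises SampleLookupError
    del carrier_rows

    copies = true_hap_copies(geno)
    noncarrier_pool = [
        str(i) for i, c in zip(geno.ids, copies) if c == 0 and str(i) not in set(carriers)
    ]
    n_extra = cfg.n_samples - len(carriers)
    if n_extra > len(noncarrier_pool):
        raise InputError("not enough non-carriers in the population for the panel")
    extras = list(rng.choice(noncarrier_pool, size=n_extra, replace=False))
    samples = np.array(carriers + extras, dtype=object)
    carrier_flag = np.array([True] * len(carriers) + [False] * n_extra)
    coverage = np.array(
        ["HC"] * cfg.n_hc_carriers + ["LC"] * cfg.n_lc_carriers + ["none"] * n_extra,
        dtype=object,
    )

    if region is None:
        region = (1, int(geno.markers["pos"].max()))
    lo, hi = int(region[0]), int(region[1])
    if hi - lo + 1 < cfg.n_region_variants:
        raise ConfigurationError("region too small for n_region_variants")

    n_var = cfg.n_region_variants
    positions = rng.choice(np.arange(lo, hi + 1), size=n_var, replace=False)
    positions = np.sort(positions)
    if causal_variant is not None:
        causal_pos, causal_ref, causal_alt = causal_variant
        if not lo <= causal_pos <= hi:
            raise ConfigurationError("causal variant position outside region")
        # replace the nearest generated position with the pinned one
        drop = int(np.argmin(np.abs(positions - causal_pos)))
        positions = np.sort(np.concatenate([np.delete(positions, drop), [causal_pos]]))
        causal_idx = int(np.searchsorted(positions, causal_pos))
    else:
        causal_idx = n_var // 2 if cfg.causal_index is None else cfg.causal_index
        causal_pos = int(positions[causal_idx])
        causal_ref, causal_alt = "C", "A"

    ref_i = rng.choice(4, size=n_var)
    alt_i = (ref_i + rng.integers(1, 4, size=n_var)) % 4
    refs = _BASES[ref_i].astype(object)
    alts = _BASES[alt_i].astype(object)
    is_indel = rng.uniform(size=n_var) < cfg.indel_fraction
    for i in np.flatnonzero(is_indel):
        extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 5))))
        if rng.uniform() < 0.5:
            alts[i] = str(refs[i]) + extra  # insertion
        else:
            refs[i] = str(refs[i]) + extra  # deletion
    refs[causal_idx] = causal_ref
    alts[causal_idx] = causal_alt

    # neutral genotypes at Hardy-Weinberg proportions, AF uniform(0.01, 0.5)
    afs = rng.uniform(0.01, 0.5, size=n_var)
    genotypes = rng.binomial(2, afs[:, None], size=(n_var, cfg.n_samples)).astype(np.int8)
    genotypes[causal_idx] = 0
    genotypes[causal_idx, carrier_flag] = 1

    lc_cols = np.flatnonzero(carrier_flag & (coverage == "LC"))
    for j in lc_cols:
        het = genotypes[:, j] == 1
        flip = rng.uniform(size=int(het.sum())) < cfg.het_miscall_rate
        rows = np.flatnonzero(het)[flip]
        genotypes[rows, j] = 0

    variants = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"].iloc[0] if len(geno.markers) else "19",
            "pos": positions,
            "ref": refs,
            "alt": alts,
        }
    )
    variants["vtype"] = [variant_type(r, a) for r, a in zip(variants["ref"], variants["alt"])]
    return SequencePanel(
        variants=variants,
        genotypes=genotypes,
        samples=samples,
        carrier=carrier_flag,
        coverage=coverage,
        causal_index=causal_idx,
        meta={"het_miscall_rate": cfg.het_miscall_rate},
    )


# ---------------------------------------------------------------------------
# gene fixture + reference
# ---------------------------------------------------------------------------


def simulate_gene_model(
    chrom: str,
    cds_start_bp: int,
    rng: np.random.Generator,
    gene: str = "TMEM95",
    n_codons: int = 183,
    special_codons: dict[int, str] | None = None,
    n_exons: int = 6,
    strand: str = "+",
) -> tuple[GeneModel, str, list[tuple[int, int, str]]]:
    """Build a synthetic single-transcript gene with pinned codons.

    The CDS is ATG + ``n_codons - 1`` random non-stop codons + TAA, with
    ``special_codons`` (1-based codon index -> trinucleotide) overriding the
    random fill.  The CDS is split into ``n_exons`` exons separated by
    random introns.  Returns the gene model, the spliced CDS, and reference
    patches ``(start_bp, end_bp, plus-strand sequence)`` to splice into a
    reference sequence.
    """
    special_codons = dict(special_codons or {})
    codons = ["ATG"]
    for idx in range(2, n_codons + 1):
        if idx in special_codons:
            codons.append(special_codons[idx].upper())
            continue
        while True:
            c = "".join(rng.choice(_BASES, size=3))
            if c not in _STOPS and c != "ATG":
                break
        codons.append(c)
    if 1 in special_codons and special_codons[1] != "ATG":
        raise ConfigurationError("codon 1 must be the start codon ATG")
    cds = "".join(codons) + "TAA"

    # split CDS length into n_exons positive chunks
    cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [len(cds)]])).astype(int)
    introns = rng.integers(200, 800, size=n_exons - 1)

    exons: list[tuple[int, int]] = []
    patches: list[tuple[int, int, str]] = []
    pos = cds_start_bp
    offset = 0
    for k, size in enumerate(sizes):
        start, end = pos, pos + int(size) - 1
        exons.append((start, end))
        chunk = cds[offset : offset + int(size)]
        if strand == "-":
            from .annotate import _revcomp

            patches.append((start, end, _revcomp(chunk)))
        else:
            patches.append((start, end, chunk))
        offset += int(size)
        if k < n_exons - 1:
            pos = end + 1 + int(introns[k])
        else:
            pos = end + 1
    if strand == "-":
        # transcription order is descending genomic coordinates: the exon
        # holding the CDS start must be the genomically last one
        span_lo = exons[0][0]
        span_hi = exons[-1][1]
        mirrored = [(span_lo + span_hi - e, span_lo + span_hi - s) for s, e in exons]
        patch_map = {}
        for (s, e), (_, _, seq) in zip(mirrored, patches):
            patch_map[(s, e)] = seq
        exons = mirrored
        patches = [(s, e, patch_map[(s, e)]) for s, e in exons]

    gm = GeneModel(gene=gene, chrom=chrom, strand=strand, exons=exons)
    return gm, cds, patches


def simulate_reference(
    chrom: str,
    length: int,
    rng: np.random.Generator,
    patches: list[tuple[int, int, str]] | None = None,
) -> str:
    """Random reference sequence with optional patched intervals (1-based)."""
    seq = rng.choice(_BASES, size=length)
    for start, end, sub in patches or []:
        if end > length:
            raise ConfigurationError("reference patch extends past contig end")
        seq[start - 1 : end] = list(sub)
    return "".join(seq)


# ---------------------------------------------------------------------------
# full study-structured scenario
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """Bundle of all artefacts of one simulated mapping study."""

    config: SimulationConfig
    panel_config: SequencePanelConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    panel: SequencePanel
    gene_model: GeneModel
    reference_seq: str
    causal_pos: int
    true_segment: tuple[int, int]


def simulate_study(
    config: SimulationConfig,
    panel_config: SequencePanelConfig | None = None,
    reference_window: int = 20_000,
) -> SimulatedStudy:
    """Run the full generator: pedigree, gene drop, phenotypes, gene, panel.

    The fixture gene is placed inside the implanted identical-by-descent
    segment with its stop-gain site (CDS position 483, C>A in a TGC codon)
    as the panel's causal variant, so the whole mapping pipeline — GWAS,
    autozygosity mapping, recessive scan, annotation — can be exercised
    against known truth.  ``reference_window`` caps the length of reference
    sequence kept in memory around the gene (the rest of the chromosome is
    random filler written on demand).
    """
    panel_config = panel_config or SequencePanelConfig(seed=config.seed)
    ped = simulate_pedigree(config)
    geno = gene_drop(ped, config)
    copies = true_hap_copies(geno)
    pheno = simulate_phenotypes(geno, copies, config, males_only=False)

    seg_lo, seg_hi = implanted_segment(geno)
    rng = _rng(config.seed, 4)
    gene_rng = _rng(config.seed, 5)
    causal_marker_pos = geno.meta["causal_pos"]
    gene_start = min(
        max(seg_lo, causal_marker_pos - 2000), config.chrom_length_bp - 10_000
    )
    gm, cds, patches = simulate_gene_model(
        chrom=config.chrom,
        cds_start_bp=int(gene_start),
        rng=gene_rng,
        special_codons={66: "CAG", 161: "TGC"},
    )
    causal_pos = gm.cds_to_genomic(483)

    window_lo = max(1, min(s for s, _ in gm.exons) - reference_window // 2)
    window_hi = min(
        config.chrom_length_bp, max(e for _, e in gm.exons) + reference_window // 2
    )
    ref_seq = simulate_reference(
        config.chrom,
        window_hi,
        rng,
        patches=patches,
    )
    del window_lo  # full prefix kept so genomic coordinates stay 1-based

    carrier_ids = [str(i) for i, c in zip(geno.ids, copies) if c == 1]
    if len(carrier_ids) < panel_config.n_hc_carriers + panel_config.n_lc_carriers:
        raise InputError("too few heterozygous carriers for the configured panel")
    pick = _rng(config.seed, 6).choice(
        carrier_ids,
        size=panel_config.n_hc_carriers + panel_config.n_lc_carriers,
        replace=False,
    )
    panel = simulate_sequence_panel(
        geno,
        list(pick),
        panel_config,
        region=(seg_lo, seg_hi),
        causal_variant=(int(causal_pos), "C", "A"),
    )
    return SimulatedStudy(
        config=config,
        panel_config=panel_config,
        pedigree=ped,
        genotypes=geno,
        phenotypes=pheno,
        panel=panel,
        gene_model=gm,
        reference_seq=ref_seq,
        causal_pos=int(causal_pos),
        true_segment=(seg_lo, seg_hi),
    )


def write_fixture_bundle(study: SimulatedStudy, directory) -> dict:
    """Write all study artefacts as plain-text files plus a manifest.

    Emits a phased VCF (the haplotype truth), array genotypes with
    missingness as a tab-separated 0/1/2/NA table, phenotype and pedigree
    tables, the panel VCF with its sample-annotation table, the gene model
    exon table and the reference FASTA.  Re-reading the bundle reproduces
    the in-memory objects exactly.
    """
    from . import io as rio

    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "genotypes_vcf": "genotypes.vcf",
        "genotypes_tsv": "genotypes.tsv",
        "phenotypes": "phenotypes.tsv",
        "pedigree": "pedigree.tsv",
        "panel_vcf": "panel.vcf",
        "panel_samples": "panel_samples.tsv",
        "gene_model": "gene_model.tsv",
        "reference": "reference.fa",
    }
    rio.write_vcf(study.genotypes, directory / files["genotypes_vcf"])
    rio.write_genotype_tsv(study.genotypes, directory / files["genotypes_tsv"])
    rio.write_table(study.phenotypes, directory / files["phenotypes"])
    rio.write_table(study.pedigree.table, directory / files["pedigree"])
    rio.write_panel_vcf(study.panel, directory / files["panel_vcf"])
    rio.write_panel_samples(study.panel, directory / files["panel_samples"])
    rio.write_table(study.gene_model.to_exon_table(), directory / files["gene_model"])
    rio.write_fasta({study.config.chrom: study.reference_seq}, directory / files["reference"])

    manifest = {
        "seed": study.config.seed,
        "config": study.config.to_dict(),
        "panel_config": {
            f.name: getattr(study.panel_config, f.name)
            for f in fields(study.panel_config)
        },
        "founder_id": study.pedigree.founder_id,
        "causal_pos": study.causal_pos,
        "true_segment": list(study.true_segment),
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
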