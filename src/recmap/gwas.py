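"""Mixed-model association scan with a genomic relationship matrix.

The model is ``y = X b + u + e`` with polygenic effects
``u ~ N(0, sigma_a^2 G)`` and residuals ``e ~ N(0, sigma_e^2 I)``, where G
is the realized genomic relationship matrix built from centred marker
genotypes.  Variance components are estimated once under the null by
restricted maximum likelihood, profiled over the single ratio
``delta = sigma_e^2 / sigma_a^2`` after one spectral decomposition of G.
Per-marker tests then keep the null covariance structure fixed (the
approximation popularised by EMMAX): the data are rotated and whitened by
the null decomposition, so each marker test is an ordinary regression on
the transformed scale with cost linear in n.  The per-marker Wald statistic
re-estimates the residual scale on the transformed data, so with G = I the
scan collapses exactly to ordinary least squares.

The fitting surface follows the model/results idiom: build a
:class:`MixedModelGWAS` from data, call :meth:`~MixedModelGWAS.fit`, and
read estimates, per-marker statistics and a summary table off the returned
:class:`GWASResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DimensionError, InputError, NumericalError
from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """Realized genomic relationship matrix and the frequencies behind it."""

    matrix: np.ndarray
    freqs: np.ndarray
    n_markers: int
    ids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = self.ids if self.ids is not None else np.arange(len(self.matrix))
        return pd.DataFrame(self.matrix, index=ids, columns=ids)

    def subset(self, rows) -> "GRM":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return GRM(
            matrix=self.matrix[np.ix_(rows, rows)],
            freqs=self.freqs,
            n_markers=self.n_markers,
            ids=None if self.ids is None else self.ids[rows],
        )


def _dosage_matrix(geno) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(geno, GenotypeMatrix):
        calls = geno.calls.astype(float)
        calls[geno.calls == MISSING] = np.nan
        return calls, geno.ids
    arr = np.asarray(geno, dtype=float)
    return arr, None


def build_grm(geno) -> GRM:
    """VanRaden-style GRM: ``G = W W' / (2 sum p_k (1 - p_k))``.

    W is the dosage matrix column-centred by twice the observed allele
    frequency; missing calls are imputed to the column mean before
    centring (so they contribute nothing).  Accepts a
    :class:`GenotypeMatrix` or a float dosage array with NaN for missing.
    """
    dosages, ids = _dosage_matrix(geno)
    n, m = dosages.shape
    if n < 2:
        raise InputError("GRM needs at least 2 individuals")
    all_missing = np.all(np.isnan(dosages), axis=0)
    if all_missing.any():
        bad = int(np.flatnonzero(all_missing)[0])
        raise InputError(
            f"marker column {bad} is entirely missing; run QC before building the GRM"
        )
    col_mean = np.nanmean(dosages, axis=0)
    filled = np.where(np.isnan(dosages), col_mean, dosages)
    p = col_mean / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise InputError("all markers monomorphic; GRM undefined")
    W = filled - 2.0 * p
    G = (W @ W.T) / denom
    return GRM(matrix=G, freqs=p, n_markers=m, ids=ids)


# ---------------------------------------------------------------------------
# variance components (REML, one spectral decomposition)
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Null-model REML estimates."""

    sigma2_a: float
    sigma2_e: float
    delta: float
    log_restricted_likelihood: float

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def _as_design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise DimensionError(f"covariates have {X.shape[0]} rows, expected {n}")
    if not np.any(np.isclose(X.var(axis=0), 0)):  # ensure an intercept column
        X = np.column_stack([np.ones(n), X])
    return X


class _Spectral:
    """Cached eigendecomposition of G with REML profile over delta."""

    def __init__(self, grm_matrix: np.ndarray, y: np.ndarray, X: np.ndarray):
        n = len(y)
        if grm_matrix.shape != (n, n):
            raise DimensionError(
                f"GRM shape {grm_matrix.shape} does not match n={n}"
            )
        vals, vecs = np.linalg.eigh(grm_matrix)
        if vals[0] < -1e-6 * max(1.0, vals[-1]):
            raise NumericalError(
                f"relationship matrix has eigenvalue {vals[0]:.3g} well below zero; "
                "add a small ridge (G + eps*I) or re-check the input"
            )
        self.values = np.clip(vals, 0.0, None)
        self.vectors = vecs
        self.y_rot = vecs.T @ y
        self.X_rot = vecs.T @ X
        self.n = n
        self.q = np.linalg.matrix_rank(X)
        _, logdet_xtx = np.linalg.slogdet(X.T @ X)
        self.logdet_xtx = logdet_xtx

    def reml(self, delta: float) -> tuple[float, float]:
        """(restricted log-likelihood, profiled sigma2_a) at ``delta``."""
        w = 1.0 / (self.values + delta)
        Xw = self.X_rot * w[:, None]
        xtx = self.X_rot.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ self.y_rot)
        resid = self.y_rot - self.X_rot @ beta
        rss = float(np.sum(w * resid**2))
        df = self.n - self.q
        sigma2_a = rss / df
        sign, logdet_xvx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return -np.inf, sigma2_a
        ll = -0.5 * (
            df * (np.log(2 * np.pi * sigma2_a) + 1.0)
            + float(np.sum(np.log(self.values + delta)))
            + logdet_xvx
            - self.logdet_xtx
        )
        return ll, sigma2_a


def estimate_variance_components(
    y,
    covariates,
    grm,
    grid_points: int = 100,
    delta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> VarianceComponents:
    """REML estimate of (sigma_a^2, sigma_e^2) under the null model.

    One spectral decomposition of G, then a log-spaced grid over
    ``delta = sigma_e^2 / sigma_a^2`` refined by bounded Brent search
    around the best grid point.  The returned restricted log-likelihood is
    the maximum found.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise InputError(f"variance-component estimation needs n >= 10, got {n}")
    matrix = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    X = _as_design(covariates, n)
    spec = _Spectral(matrix, y, X)

    log_lo, log_hi = np.log10(delta_bounds[0]), np.log10(delta_bounds[1])
    grid = np.logspace(log_lo, log_hi, grid_points)
    lls = np.array([spec.reml(d)[0] for d in grid])
    k = int(np.argmax(lls))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda t: -spec.reml(10.0**t)[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(lls[k], grid[k]), (-res.fun, 10.0**res.x)]
    ll, delta = max(candidates, key=lambda t: t[0])
    _, sigma2_a = spec.reml(delta)
    return VarianceComponents(
        sigma2_a=float(sigma2_a),
        sigma2_e=float(delta * sigma2_a),
        delta=float(delta),
        log_restricted_likelihood=float(ll),
    )


# ---------------------------------------------------------------------------
# per-marker scan
# ---------------------------------------------------------------------------


def _marker_dosages(geno) -> tuple[np.ndarray, pd.DataFrame]:
    if isinstance(geno, GenotypeMatrix):
        dos = geno.calls.astype(float)
        dos[geno.calls == MISSING] = np.nan
        return dos, geno.markers
    arr = np.asarray(geno, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    markers = pd.DataFrame(
        {
            "name": [f"X{j}" for j in range(arr.shape[1])],
            "chrom": "0",
            "pos": np.arange(1, arr.shape[1] + 1),
            "ref": "A",
            "alt": "B",
        }
    )
    return arr, markers


def emmax_scan(
    y,
    geno,
    grm,
    vc: VarianceComponents,
    covariates=None,
) -> pd.DataFrame:
    """Per-marker generalized-least-squares scan with the null covariance.

    ``V = sigma_a^2 G + sigma_e^2 I`` is held fixed at the null REML
    estimates; data are whitened through the spectral decomposition of G
    and each marker is tested by a Wald t-test (df = n - rank of the full
    design) with the residual scale re-estimated per marker.  Missing
    dosages are imputed to the marker mean; monomorphic markers are
    returned flagged with effect 0 and p = 1.

    Returns a table with marker, chrom, pos, allele frequency, n, effect
    (trait units per allele), SE, t statistic and p-value.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    matrix = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    if matrix.shape != (n, n):
        raise DimensionError(f"GRM shape {matrix.shape} does not match n={n}")
    dosages, markers = _marker_dosages(geno)
    if dosages.shape[0] != n:
        raise DimensionError(
            f"genotypes have {dosages.shape[0]} individuals, phenotype has {n}"
        )
    X = _as_design(covariates, n)

    vals, vecs = np.linalg.eigh(matrix)
    vals = np.clip(vals, 0.0, None)
    D = vc.sigma2_a * vals + vc.sigma2_e
    if np.any(D <= 0):
        raise NumericalError("null covariance is singular; check variance components")
    s = 1.0 / np.sqrt(D)

    y_t = s * (vecs.T @ y)
    X_t = s[:, None] * (vecs.T @ X)
    Q, _ = np.linalg.qr(X_t)
    y_r = y_t - Q @ (Q.T @ y_t)
    yry = float(y_r @ y_r)

    col_mean = np.nanmean(dosages, axis=0)
    filled = np.where(np.isnan(dosages), col_mean, dosages)
    mono = np.nanvar(filled, axis=0) <= 0

    G_t = s[:, None] * (vecs.T @ filled)
    G_r = G_t - Q @ (Q.T @ G_t)
    sxx = np.sum(G_r**2, axis=0)
    sxy = G_r.T @ y_r

    q = X.shape[1]
    df = n - q - 1
    if df <= 0:
        raise InputError("not enough observations for the per-marker test")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = yry - beta * sxy
        sigma2 = rss / df
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.nan))
        tstat = np.where(sxx > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    p = np.where(mono | (sxx <= 0), 1.0, p)
    beta = np.where(mono | (sxx <= 0), 0.0, beta)

    obs = ~np.isnan(dosages)
    freq = col_mean / 2.0
    table = pd.DataFrame(
        {
            "marker": markers["name"].to_numpy(),
            "chrom": markers["chrom"].to_numpy(),
            "pos": markers["pos"].to_numpy(),
            "freq": freq,
            "n": obs.sum(axis=0),
            "effect": beta,
            "se": se,
            "stat": tstat,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "monomorphic": mono | (sxx <= 0),
        }
    )
    return table


def case_control_scan(case_ids, control_ids, geno: GenotypeMatrix, grm) -> pd.DataFrame:
    """Linear mixed-model scan of a binary case/control phenotype.

    Cases are coded 1, controls 0; the same variance-component + fixed-V
    machinery as the quantitative scan is applied to the binary trait.
    Individuals outside both groups are dropped (GRM subset accordingly).
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if set(case_ids) & set(control_ids):
        raise InputError("case and control groups overlap")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise InputError("need at least 2 cases and 2 controls")
    rows = geno.individual_index(case_ids + control_ids)
    y = np.concatenate([np.ones(len(case_ids)), np.zeros(len(control_ids))])
    sub = geno.subset(individuals=rows)
    g = grm if isinstance(grm, GRM) else GRM(np.asarray(grm, float), np.array([]), 0)
    if g.matrix.shape[0] == geno.n_individuals:
        gsub = g.subset(rows)
    elif g.matrix.shape[0] == len(rows):
        gsub = g
    else:
        raise DimensionError(
            f"GRM of size {g.matrix.shape[0]} matches neither the full matrix "
            f"({geno.n_individuals}) nor the case/control subset ({len(rows)})"
        )
    vc = estimate_variance_components(y, None, gsub)
    return emmax_scan(y, sub, gsub, vc)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class MixedModelGWAS:
    """Genome scan model: quantitative trait, marker dosages, GRM.

    Parameters
    ----------
    y
        Phenotype vector (missing values dropped together with their rows).
    geno
        :class:`GenotypeMatrix` or dosage array aligned with ``y``.
    grm
        :class:`GRM` or matrix; built from ``geno`` when omitted.
    covariates
        Optional fixed covariates; an intercept is always included.
    """

    def __init__(self, y, geno, grm=None, covariates=None):
        y = np.asarray(y, dtype=float)
        keep = ~np.isnan(y)
        self.dropped = int((~keep).sum())
        if isinstance(geno, GenotypeMatrix):
            geno_kept = geno.subset(individuals=keep) if self.dropped else geno
        else:
            geno_kept = np.asarray(geno, float)[keep]
        if grm is None:
            grm = build_grm(geno_kept)
        elif self.dropped:
            grm = grm.subset(keep) if isinstance(grm, GRM) else GRM(
                np.asarray(grm, float)[np.ix_(keep, keep)], np.array([]), 0
            )
        self.y = y[keep]
        self.geno = geno_kept
        self.grm = grm
        self.covariates = None if covariates is None else np.asarray(covariates, float)[keep]

    @classmethod
    def from_tables(cls, phenotypes: pd.DataFrame, geno: GenotypeMatrix, trait: str = "mra"):
        """Align a phenotype table with a genotype matrix on ``id``."""
        pheno = phenotypes.set_index(phenotypes["id"].astype(str))
        ids = [str(i) for i in geno.ids if str(i) in pheno.index]
        if not ids:
            raise InputError("no phenotyped individuals found in the genotype matrix")
        rows = geno.individual_index(ids)
        sub = geno.subset(individuals=rows)
        y = pheno.loc[ids, trait].to_numpy(dtype=float)
        return cls(y, sub)

    def fit(self) -> "GWASResults":
        vc = estimate_variance_components(self.y, self.covariates, self.grm)
        table = emmax_scan(self.y, self.geno, self.grm, vc, self.covariates)
        return GWASResults(model=self, vc=vc, table=table)


@dataclass
class GWASResults:
    """Fitted scan: variance components plus the per-marker table."""

    model: MixedModelGWAS
    vc: VarianceComponents
    table: pd.DataFrame

    def top_hits(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")

    @property
    def min_p_marker(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]

    def manhattan_data(self) -> pd.DataFrame:
        out = self.table[["marker", "chrom", "pos", "p"]].copy()
        out["neglog10p"] = -np.log10(out["p"])
        return out

    def summary(self) -> str:
        top = self.top_hits(5)
        lines = [
            "Mixed-model association scan",
            "=" * 34,
            f"n individuals        {len(self.model.y)}",
            f"n markers            {len(self.table)}",
            f"sigma2_a             {self.vc.sigma2_a:.4f}",
            f"sigma2_e             {self.vc.sigma2_e:.4f}",
            f"delta (e/a)          {self.vc.delta:.4g}",
            f"h2                   {self.vc.heritability:.3f}",
            f"logL (restricted)    {self.vc.log_restricted_likelihood:.3f}",
            "",
            "Top markers:",
            top[["marker", "chrom", "pos", "effect", "se", "p"]].to_string(index=False),
        ]
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def haplotype_dosage_test(trait, copies, grm, covariates=None) -> dict:
    """Mixed-model effect of haplotype dosage (0/1/2) on a trait.

    Reuses the variance-component + fixed-covariance machinery with the
    copy count as the single tested regressor; returns effect, SE, t and p.
    """
    trait = np.asarray(trait, dtype=float)
    copies = np.asarray(copies, dtype=float)
    if trait.shape != copies.shape:
        raise DimensionError("trait and copies must be aligned")
    vc = estimate_variance_components(trait, covariates, grm)
    table = emmax_scan(trait, copies[:, None], grm, vc, covariates)
    row = table.iloc[0]
    return {
        "effect": float(row["effect"]),
        "se": float(row["se"]),
        "stat": float(row["stat"]),
        "p": float(row["p"]),
        "vc": vc,
    }
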