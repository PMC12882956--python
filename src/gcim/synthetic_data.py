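"""Synthetic genotype/phenotype generator for G×E direction studies.

The generator produces a pair of heritable traits (an outcome ``y`` and an
exposure ``c``) on top of independent biallelic SNP genotypes.  Per-SNP causal
effects for the outcome's additive component, the outcome's genotype-by-
environment (G×E) component, and the exposure's additive component are drawn
jointly multivariate-normal so that genetic correlation between the two traits
can be dialled in.  Residuals are drawn jointly as well, with an optional
residual-by-environment component that induces heteroscedasticity of the
outcome across exposure levels — the classic generator of spurious G×E
signals.

The generative equations, with ``G`` the column-standardized genotype matrix:

    c = G·β_add_c + ε_c
    y = G·β_add + β_c·c + (G ⊙ c)·β_g×e + ε_r×e ⊙ c + ε_y

where ``⊙`` scales each individual's row/value by that individual's exposure.
Summed causal-effect variances are configured directly, so the variance of
each trait is the sum of its configured components (1.0 under the default
settings).  Binary traits are produced by thresholding the continuous trait at
the top decile (cases = top 10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError, ContractError, DegenerateInputError

__all__ = [
    "GenotypeMatrix",
    "EffectCovConfig",
    "TrueEffects",
    "PhenotypePair",
    "Dataset",
    "simulate_genotypes",
    "draw_true_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "dichotomize",
    "split_indices",
    "split_discovery_target",
    "standardize_columns",
    "implied_cov",
]


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (n individuals × m SNPs) with SNP metadata.

    ``counts`` holds 0/1/2 copies of the effect allele (float so that readers
    of external data can carry NaN for missing genotypes; simulated data never
    contains missing values).
    """

    counts: np.ndarray
    snp_ids: np.ndarray
    allele_freqs: np.ndarray
    individual_ids: np.ndarray
    a1: Optional[np.ndarray] = None  # effect allele labels (external data)
    a2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.snp_ids = np.asarray(self.snp_ids)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids)
        n, m = self.counts.shape
        if len(self.snp_ids) != m:
            raise ContractError(f"snp_ids length {len(self.snp_ids)} != column count {m}")
        if len(self.individual_ids) != n:
            raise ContractError(f"individual_ids length {len(self.individual_ids)} != row count {n}")
        if len(self.allele_freqs) != m:
            raise ContractError("allele_freqs length mismatch")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.counts).any())

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            counts=self.counts[index],
            snp_ids=self.snp_ids,
            allele_freqs=self.allele_freqs,
            individual_ids=self.individual_ids[index],
            a1=self.a1,
            a2=self.a2,
        )


def _check_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T):
        raise ConfigurationError(f"{name} covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -1e-8:
        raise ConfigurationError(
            f"{name} covariance matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )


@dataclass
class EffectCovConfig:
    """Summed variance components of the two-trait generative model.

    Variances are *summed over causal SNPs* (per-SNP variance is
    ``var / n_causal``), so e.g. ``var_add=0.4`` puts heritability 0.4 on the
    outcome regardless of the causal-SNP count.  ``cov_add_addc`` controls the
    genetic covariance between outcome and exposure; with the default
    variances (0.4, 0.5) a covariance of 0.179 gives genetic correlation 0.4
    and 0.358 gives 0.8.  ``var_res_rxe`` > 0 switches on residual
    heteroscedasticity of the outcome across exposure levels.
    """

    var_add: float = 0.4
    var_gxe: float = 0.0
    var_add_c: float = 0.5
    cov_add_addc: float = 0.0
    var_res_y: float = 0.6
    var_res_rxe: float = 0.0
    var_res_c: float = 0.5
    cov_res: float = 0.0
    beta_c: float = 0.0
    n_causal: int = 200

    def __post_init__(self) -> None:
        for name in ("var_add", "var_gxe", "var_add_c", "var_res_y", "var_res_rxe", "var_res_c"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_causal < 1:
            raise ConfigurationError("n_causal must be >= 1")
        _check_psd(self.genetic_cov_matrix(), "genetic")
        _check_psd(self.residual_cov_matrix(), "residual")

    def genetic_cov_matrix(self) -> np.ndarray:
        """Summed covariance of (β_add, β_g×e, β_add_c); off-diagonals with the
        G×E component are zero by construction."""
        return np.array(
            [
                [self.var_add, 0.0, self.cov_add_addc],
                [0.0, self.var_gxe, 0.0],
                [self.cov_add_addc, 0.0, self.var_add_c],
            ]
        )

    def residual_cov_matrix(self) -> np.ndarray:
        """Covariance of (ε_y, ε_r×e, ε_c); ε_r×e is independent of the other
        two components."""
        return np.array(
            [
                [self.var_res_y, 0.0, self.cov_res],
                [0.0, self.var_res_rxe, 0.0],
                [self.cov_res, 0.0, self.var_res_c],
            ]
        )

    def genetic_correlation(self) -> float:
        denom = math.sqrt(self.var_add * self.var_add_c)
        return self.cov_add_addc / denom if denom > 0 else 0.0

    def residual_correlation(self) -> float:
        denom = math.sqrt(self.var_res_y * self.var_res_c)
        return self.cov_res / denom if denom > 0 else 0.0


def implied_cov(correlation: float, var1: float, var2: float, ndigits: int = 3) -> float:
    """Covariance implied by a target correlation, rounded to the precision
    conventionally quoted for these components (e.g. 0.4 with variances
    0.4/0.5 → 0.179)."""
    return round(correlation * math.sqrt(var1 * var2), ndigits)


@dataclass
class TrueEffects:
    """Per-SNP causal effects and per-individual residual draws — the
    simulation ground truth."""

    causal_index: np.ndarray
    beta_add: np.ndarray     # length n_causal
    beta_gxe: np.ndarray
    beta_add_c: np.ndarray
    eps_y: np.ndarray        # length n
    eps_c: np.ndarray
    eps_rxe: np.ndarray
    m: int

    def full_vector(self, which: str) -> np.ndarray:
        """Effects expanded to all m SNPs (zero at non-causal positions)."""
        out = np.zeros(self.m)
        out[self.causal_index] = getattr(self, which)
        return out


@dataclass
class PhenotypePair:
    """Outcome/exposure phenotype vectors with trait-type flags.

    For binary traits the pre-thresholding continuous values are retained in
    ``y_latent``/``c_latent`` (None for quantitative traits, where ``y``/``c``
    already are the continuous values)."""

    y: np.ndarray
    c: np.ndarray
    y_type: str = "quantitative"
    c_type: str = "quantitative"
    y_latent: Optional[np.ndarray] = None
    c_latent: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.y.shape != self.c.shape:
            raise ContractError("y and c must have the same length")
        for name, vec, kind in (("y", self.y, self.y_type), ("c", self.c, self.c_type)):
            if not np.isfinite(vec).all():
                raise ContractError(f"{name} contains non-finite values")
            if kind == "binary" and not np.isin(vec, (0.0, 1.0)).all():
                raise ContractError(f"binary trait {name} contains values outside {{0,1}}")


@dataclass
class Dataset:
    """A genotype matrix with its aligned phenotypes (one split)."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypePair
    covariates: Optional[np.ndarray] = None


def simulate_genotypes(
    n: int,
    m: int,
    maf_low: float = 0.01,
    maf_high: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Independent biallelic SNP genotypes, counts ~ Binomial(2, f) with the
    effect-allele frequency f of each SNP drawn uniform on [maf_low, maf_high].

    SNPs are simulated without linkage disequilibrium: each column is
    independent, which preserves the statistical claims under study (type-I
    error, power, direction asymmetry) without modelling real LD structure.
    """
    if n < 2 or m < 1:
        raise ContractError(f"need n >= 2 and m >= 1, got n={n}, m={m}")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ConfigurationError(
            f"invalid MAF bounds: require 0 < maf_low <= maf_high <= 0.5, got ({maf_low}, {maf_high})"
        )
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=m)
    counts = rng.binomial(2, freqs, size=(n, m)).astype(np.float64)
    snp_ids = np.array([f"snp{j + 1:06d}" for j in range(m)])
    ind_ids = np.array([f"id{i + 1:06d}" for i in range(n)])
    return GenotypeMatrix(counts=counts, snp_ids=snp_ids, allele_freqs=freqs, individual_ids=ind_ids)


def _sample_mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Multivariate-normal draws robust to singular covariance matrices.

    Coordinates with exactly zero variance are returned as exact zeros rather
    than being polluted by eigendecomposition round-off.
    """
    d = cov.shape[0]
    out = np.zeros((size, d))
    sd = np.sqrt(np.diag(cov))
    live = sd > 0
    if live.any():
        sub = cov[np.ix_(live, live)]
        w, v = np.linalg.eigh(sub)
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal((size, int(live.sum())))
        out[:, live] = z @ (v * np.sqrt(w)).T
    return out


def draw_true_effects(cfg: EffectCovConfig, m: int, n: int, seed: int = 0) -> TrueEffects:
    """Draw causal-SNP effect triplets and per-individual residuals.

    ``n_causal`` SNP indices are sampled without replacement; each causal
    SNP's (β_add, β_g×e, β_add_c) triplet is i.i.d. multivariate normal with
    covariance = summed matrix / n_causal.  Residual triplets
    (ε_y, ε_r×e, ε_c) are drawn per individual from the residual covariance
    matrix.
    """
    if cfg.n_causal > m:
        raise ConfigurationError(f"n_causal={cfg.n_causal} exceeds SNP count m={m}")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
    per_snp_cov = cfg.genetic_cov_matrix() / cfg.n_causal
    betas = _sample_mvn(rng, per_snp_cov, cfg.n_causal)
    eps = _sample_mvn(rng, cfg.residual_cov_matrix(), n)
    return TrueEffects(
        causal_index=causal,
        beta_add=betas[:, 0],
        beta_gxe=betas[:, 1],
        beta_add_c=betas[:, 2],
        eps_y=eps[:, 0],
        eps_rxe=eps[:, 1],
        eps_c=eps[:, 2],
        m=m,
    )


def standardize_columns(counts: np.ndarray) -> np.ndarray:
    """Column-standardize an allele-count matrix (mean 0, variance 1 per SNP).

    Monomorphic columns are mapped to all-zero so they contribute nothing to
    genetic values.
    """
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0)
    out = counts - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def dichotomize(values: np.ndarray, prevalence: float = 0.1) -> np.ndarray:
    """Threshold a continuous vector at the top quantile: the
    ceil(n·prevalence) largest values become cases (1), the rest controls (0).

    Ties are broken by original index order (earlier index wins a case slot);
    continuous simulated values make ties measure-zero.
    """
    values = np.asarray(values, dtype=float)
    if not (0 < prevalence < 1):
        raise ContractError(f"prevalence must be in (0,1), got {prevalence}")
    if not np.isfinite(values).all():
        raise ContractError("values must be finite")
    if np.ptp(values) == 0:
        raise DegenerateInputError("cannot dichotomize a constant vector")
    n = len(values)
    k = math.ceil(n * prevalence)
    order = np.argsort(-values, kind="stable")
    out = np.zeros(n)
    out[order[:k]] = 1.0
    return out


def simulate_phenotypes(
    G: GenotypeMatrix,
    eff: TrueEffects,
    cfg: EffectCovConfig,
    y_type: str = "quantitative",
    c_type: str = "quantitative",
    prevalence: float = 0.1,
) -> PhenotypePair:
    """Generate the exposure first, then the outcome conditional on it.

    Genetic values use the column-standardized genotype matrix so that summed
    per-SNP effect variances equal the configured trait variance components.
    Binary traits are produced by transforming the quantitative data after
    generation: the continuous pair is simulated first and each binary trait
    is then thresholded at the top decile, so the generative interaction
    always acts on the continuous exposure.
    """
    if eff.m != G.m:
        raise ContractError(f"effects were drawn for m={eff.m} SNPs but genotypes have m={G.m}")
    if len(eff.eps_y) != G.n:
        raise ContractError(f"residuals were drawn for n={len(eff.eps_y)} but genotypes have n={G.n}")
    if G.has_missing():
        raise ContractError("simulate_phenotypes requires complete genotypes")

    Gs = standardize_columns(G.counts[:, eff.causal_index])
    g_c = Gs @ eff.beta_add_c
    g_y = Gs @ eff.beta_add
    g_gxe = Gs @ eff.beta_gxe

    c_cont = g_c + eff.eps_c
    y_cont = g_y + cfg.beta_c * c_cont + c_cont * g_gxe + c_cont * eff.eps_rxe + eff.eps_y

    c = dichotomize(c_cont, prevalence) if c_type == "binary" else c_cont
    y = dichotomize(y_cont, prevalence) if y_type == "binary" else y_cont
    return PhenotypePair(
        y=y,
        c=c,
        y_type=y_type,
        c_type=c_type,
        y_latent=y_cont if y_type == "binary" else None,
        c_latent=c_cont if c_type == "binary" else None,
    )


def simulate_dataset(
    cfg: EffectCovConfig,
    n: int,
    m: int,
    maf: Tuple[float, float] = (0.01, 0.5),
    y_type: str = "quantitative",
    c_type: str = "quantitative",
    prevalence: float = 0.1,
    seed: int = 0,
) -> Tuple[GenotypeMatrix, PhenotypePair, TrueEffects]:
    """One-call convenience wrapper: genotypes, effects, phenotypes."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_eff = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    G = simulate_genotypes(n, m, maf[0], maf[1], seed=s_geno)
    eff = draw_true_effects(cfg, m, n, seed=s_eff)
    phen = simulate_phenotypes(G, eff, cfg, y_type=y_type, c_type=c_type, prevalence=prevalence)
    return G, phen, eff


def split_indices(n: int, discovery_fraction: float = 0.8, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive row partition into discovery/target index arrays."""
    if not (0 < discovery_fraction < 1):
        raise ContractError(f"discovery_fraction must be in (0,1), got {discovery_fraction}")
    if n < 10:
        raise ContractError(f"need n >= 10 for a non-trivial split, got {n}")
    n_d = round(n * discovery_fraction)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_d]), np.sort(perm[n_d:])


def split_discovery_target(
    G: GenotypeMatrix,
    phen: PhenotypePair,
    discovery_fraction: float = 0.8,
    seed: int = 0,
    covariates: Optional[np.ndarray] = None,
) -> Tuple[Dataset, Dataset]:
    """80/20-style split of an aligned genotype+phenotype set.

    Summary statistics are estimated in the discovery part; the PRS×E models
    are tested in the held-out target part.
    """
    if G.n != len(phen.y):
        raise ContractError("genotypes and phenotypes are not aligned")
    idx_d, idx_t = split_indices(G.n, discovery_fraction, seed)

    def subset(idx: np.ndarray) -> Dataset:
        return Dataset(
            genotypes=G.take_individuals(idx),
            phenotypes=PhenotypePair(
                y=phen.y[idx], c=phen.c[idx], y_type=phen.y_type, c_type=phen.c_type
            ),
            covariates=None if covariates is None else np.asarray(covariates)[idx],
        )

    return subset(idx_d), subset(idx_t)
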