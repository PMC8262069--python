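"""Synthetic genotype/phenotype generator with paternal half-sib structure.

Genotypes arise by Mendelian transmission from simulated sire haplotypes and
per-offspring dam haplotypes. Haplotype alleles follow a first-order latent
Gaussian chain along the genome so adjacent-SNP LD is tunable with a single
parameter. True genetic values are built from NOIA codings at the SNP (and
SNP-pair) level, each component rescaled exactly to a requested fraction of
the target phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from epiblup.genotypes import GenotypeMatrix, filter_maf, read_genotypes, write_genotypes
from epiblup.kernels import build_codings, build_kernel

__all__ = [
    "GenotypeMatrix",
    "TrueEffects",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "read_genotypes",
    "write_genotypes",
]


def _sample_haplotypes(
    n_hap: int, thresholds: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotypes from a stationary AR(1) latent Gaussian chain.

    ``thresholds[j]`` is the standard-normal quantile of the target allele
    frequency at SNP j; allele 1 is carried where the latent variable falls
    below it.
    """
    m = thresholds.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if ld_rho == 0.0:
        z[:, 1:] = rng.standard_normal((n_hap, m - 1))
    else:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + innov[:, j - 1]
    return (z < thresholds).astype(np.int8)


def _meiosis(
    hap1: np.ndarray, hap2: np.ndarray, rng: np.random.Generator, switch_prob: float
) -> np.ndarray:
    """Recombinant gamete: copy from one parental haplotype, switching with
    probability ``switch_prob`` between adjacent SNPs."""
    m = hap1.size
    switches = rng.random(m) < switch_prob
    switches[0] = rng.random() < 0.5
    use_second = np.cumsum(switches) % 2 == 1
    return np.where(use_second, hap2, hap1)


def simulate_genotypes(
    n_sires: int,
    offspring_per_sire: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
    maf_threshold: float = 0.05,
    full_sibs: bool = False,
    switch_prob: float = 0.01,
) -> GenotypeMatrix:
    """Simulate offspring genotypes for paternal half-sib families.

    Each sire carries two population haplotypes; every offspring receives a
    recombinant sire gamete plus a gamete from its own independently drawn
    dam (so maternal sibs do not occur unless ``full_sibs`` shares one dam
    per family). Monomorphic and sub-MAF SNPs are removed afterwards.
    """
    if n_sires < 1 or offspring_per_sire < 1:
        raise ValueError("n_sires and offspring_per_sire must be >= 1")
    low, high = maf_range
    if low >= high:
        raise ValueError(f"degenerate maf_range ({low}, {high}): low must be < high")
    if not (0 < low and high <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got ({low}, {high})")
    if not 0 <= ld_rho < 1:
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")

    rng = np.random.default_rng(seed)
    p = rng.uniform(low, high, size=n_snps)
    flip = rng.random(n_snps) < 0.5  # minor allele is randomly ref or alt
    p = np.where(flip, 1.0 - p, p)
    thresholds = norm.ppf(p)

    sire_haps = _sample_haplotypes(2 * n_sires, thresholds, ld_rho, rng)
    n_off = n_sires * offspring_per_sire
    dosages = np.empty((n_off, n_snps), dtype=np.int16)
    row = 0
    for s in range(n_sires):
        h1, h2 = sire_haps[2 * s], sire_haps[2 * s + 1]
        if full_sibs:
            dam_haps = _sample_haplotypes(2, thresholds, ld_rho, rng)
        for _ in range(offspring_per_sire):
            sire_gamete = _meiosis(h1, h2, rng, switch_prob)
            if full_sibs:
                dam_gamete = _meiosis(dam_haps[0], dam_haps[1], rng, switch_prob)
            else:
                dam_gamete = _sample_haplotypes(1, thresholds, ld_rho, rng)[0]
            dosages[row] = sire_gamete.astype(np.int16) + dam_gamete
            row += 1

    animal_ids = [
        f"S{s + 1:03d}_O{o + 1:03d}"
        for s in range(n_sires)
        for o in range(offspring_per_sire)
    ]
    positions = [("1", 10_000 * (j + 1)) for j in range(n_snps)]
    g = GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=[f"snp{j + 1:06d}" for j in range(n_snps)],
        dosages=dosages,
        positions=positions,
    )
    return filter_maf(g, maf_threshold)


def sire_of(animal_id: str) -> str:
    """Family (sire) label encoded in a simulated animal ID."""
    return animal_id.split("_")[0]


# ---------------------------------------------------------------------------
# True genetic effects
# ---------------------------------------------------------------------------


@dataclass
class TrueEffects:
    """Ground-truth SNP(-pair) effects and per-animal genetic values.

    ``u_A``, ``u_D`` and ``u_AA`` are exact linear combinations of the NOIA
    codings with the stored (already rescaled) effects; ``scale_factors``
    records the multiplier applied per component to hit the requested
    variance fraction exactly.
    """

    additive_snp_effects: np.ndarray
    dominance_snp_effects: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]]
    directional_dominance_shift: float
    u_A: np.ndarray
    u_D: np.ndarray
    u_AA: np.ndarray
    scale_factors: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.u_A + self.u_D + self.u_AA


def _rescale(u: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    if target_var == 0:
        return np.zeros_like(u), 0.0
    v = u.var()
    if v == 0:
        raise ValueError("cannot rescale a zero-variance component to a nonzero target")
    s = float(np.sqrt(target_var / v))
    return u * s, s


def _sample_pairs(
    n_snps: int, n_pairs: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    total = n_snps * (n_snps - 1) // 2
    if n_pairs > total:
        raise ValueError(
            f"n_epistatic_pairs={n_pairs} exceeds the {total} available "
            f"unordered pairs"
        )
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_pairs:
        draw = rng.integers(0, n_snps, size=(n_pairs - len(chosen) + 8, 2))
        for j, k in draw:
            if j == k:
                continue
            pair = (min(j, k), max(j, k))
            chosen.add((int(pair[0]), int(pair[1])))
            if len(chosen) == n_pairs:
                break
    return sorted(chosen)


def simulate_effects(
    g: GenotypeMatrix,
    variance_fractions: dict[str, float],
    n_epistatic_pairs: int = 0,
    directional_shift: float = 0.0,
    seed: int = 0,
    target_variance: float = 1.0,
    aa_mode: str = "snp_pairs",
) -> TrueEffects:
    """Draw SNP-level genetic effects and compute per-animal true values.

    Each component's per-animal values are rescaled so the empirical variance
    over animals equals its requested fraction of ``target_variance`` exactly.
    ``aa_mode='snp_pairs'`` gives the AA component an explicit SNP-pair
    architecture; ``aa_mode='mvn_kernel'`` draws it from MVN(0, AA kernel)
    instead.
    """
    fr = {c: float(variance_fractions.get(c, 0.0)) for c in ("A", "D", "AA")}
    if any(v < 0 for v in fr.values()):
        raise ValueError("variance fractions must be non-negative")
    if sum(fr.values()) >= 1.0 + 1e-12:
        raise ValueError("variance fractions must sum to < 1")
    if aa_mode not in ("snp_pairs", "mvn_kernel"):
        raise ValueError(f"unknown aa_mode {aa_mode!r}")

    rng = np.random.default_rng(seed)
    codings = build_codings(g)
    W_add, W_dom = codings.W_add, codings.W_dom
    n, m = W_add.shape

    a = rng.standard_normal(m)
    u_A, s_A = _rescale(W_add @ a, fr["A"] * target_variance)
    a *= s_A

    d = rng.standard_normal(W_dom.shape[1]) + directional_shift
    u_D, s_D = _rescale(W_dom @ d, fr["D"] * target_variance)
    d *= s_D

    pairs: list[tuple[int, int, float]] = []
    if fr["AA"] > 0 and aa_mode == "mvn_kernel":
        AA = build_kernel(W_add, "A", g.animal_ids).matrix
        AA = AA * AA  # covariance of the epistatic values, un-scaled is fine
        L = np.linalg.cholesky(AA + 1e-10 * np.eye(n))
        u_AA, _ = _rescale(L @ rng.standard_normal(n), fr["AA"] * target_variance)
    else:
        if n_epistatic_pairs > 0:
            idx_pairs = _sample_pairs(m, n_epistatic_pairs, rng)
            e = rng.standard_normal(len(idx_pairs))
            raw = np.zeros(n)
            for (j, k), ej in zip(idx_pairs, e):
                raw += ej * W_add[:, j] * W_add[:, k]
            u_AA, s_AA = _rescale(raw, fr["AA"] * target_variance)
            pairs = [
                (j, k, float(ej * s_AA)) for (j, k), ej in zip(idx_pairs, e)
            ]
        else:
            if fr["AA"] > 0:
                raise ValueError(
                    "AA fraction > 0 requires n_epistatic_pairs > 0 "
                    "(or aa_mode='mvn_kernel')"
                )
            u_AA = np.zeros(n)

    return TrueEffects(
        additive_snp_effects=a,
        dominance_snp_effects=d,
        epistatic_pairs=pairs,
        directional_dominance_shift=directional_shift,
        u_A=u_A,
        u_D=u_D,
        u_AA=u_AA,
        scale_factors={"A": s_A, "D": s_D},
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    g: GenotypeMatrix,
    effects: TrueEffects,
    factor_spec: dict[str, int] | None = None,
    covariate_spec: dict[str, float] | None = None,
    residual_fraction: float = 0.4,
    seed: int = 0,
    target_variance: float = 1.0,
    intercept: float = 0.0,
    factor_effect_sd: float = 0.5,
) -> pd.DataFrame:
    """Assemble a phenotype table: fixed effects + genetic values + residual.

    Factor levels are assigned round-robin after a seeded shuffle (balanced,
    every level gets >= 2 animals when feasible); level effects are drawn
    once per level. ``covariate_spec`` maps covariate name -> effect size on
    the standardized covariate; ``age_months`` is simulated, ``het_percent``
    always derives from the genotypes.
    """
    if factor_spec is None:
        factor_spec = {}
    if covariate_spec is None:
        covariate_spec = {}
    if not 0 <= residual_fraction <= 1:
        raise ValueError("residual_fraction must be in [0, 1]")
    n = g.n_animals
    for fac, levels in factor_spec.items():
        if levels > n:
            raise ValueError(
                f"factor {fac!r} has {levels} levels but only {n} animals"
            )
        if levels < 1:
            raise ValueError(f"factor {fac!r} needs >= 1 level")

    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"animal_id": g.animal_ids})
    y = np.full(n, intercept, dtype=float)

    for fac, levels in factor_spec.items():
        assign = np.arange(n) % levels
        rng.shuffle(assign)
        level_effects = rng.normal(0.0, factor_effect_sd, size=levels)
        df[fac] = [f"{fac}{a + 1}" for a in assign]
        y += level_effects[assign]

    df["age_months"] = rng.normal(29.0, 1.5, size=n)
    df["het_percent"] = g.het_percent()
    for cov, beta in covariate_spec.items():
        if cov not in df.columns:
            df[cov] = rng.standard_normal(n)
        x = df[cov].to_numpy(dtype=float)
        sd = x.std()
        y += beta * ((x - x.mean()) / sd if sd > 0 else 0.0)

    y += effects.u_A + effects.u_D + effects.u_AA
    if residual_fraction > 0:
        y += rng.normal(0.0, np.sqrt(residual_fraction * target_variance), size=n)
    df["trait_value"] = y
    df["phenotyped_flag"] = True
    return df
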