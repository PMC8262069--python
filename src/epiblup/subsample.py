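"""Subsampling stability analysis.

Refits an intercept-only model with additive and additive-by-additive
kernels on random subsamples of pre-adjusted phenotypes, then compares (a)
the variance-component estimates and (b) the per-animal effect estimates —
separately for sampled (phenotyped) and unsampled animals — against the
full-data fit. This exposes the contrast between stable epistatic variance
components and unstable extrapolated epistatic effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epiblup.genotypes import GenotypeMatrix
from epiblup.kernels import Kernel, KernelSet, build_kernel_set
from epiblup.reml import FitResult, MixedModelSpec, fit_reml

logger = logging.getLogger(__name__)


def effect_correlation(
    est_sub: np.ndarray, est_full: np.ndarray, id_subset: np.ndarray
) -> float:
    """Pearson correlation of two effect vectors restricted to a subset."""
    idx = np.asarray(id_subset)
    if idx.size < 3:
        warnings.warn("fewer than 3 animals in subset; correlation undefined",
                      stacklevel=2)
        return np.nan
    a, b = np.asarray(est_sub)[idx], np.asarray(est_full)[idx]
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance effect vector; correlation undefined",
                      stacklevel=2)
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SubsampleResult:
    full_fit: FitResult
    records: pd.DataFrame  # tidy: size, replicate, varcomps, correlations
    sampled_ids: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    seed: int = 0


def _subsample_kernels(
    full_kernels: KernelSet,
    genotypes: GenotypeMatrix | None,
    sample_idx: np.ndarray,
    mode: str,
) -> KernelSet:
    """Kernels used for a subsample fit, covering ALL animals.

    'recompute' rebuilds codings from the subsample's observed genotype
    frequencies (applied to every animal); 'slice' reuses the full-data
    kernels. Either way the matrices are rescaled so the trace over the
    sampled block equals the subsample size.
    """
    if mode == "recompute":
        if genotypes is None:
            raise ValueError("recompute mode requires the genotype matrix")
        freq_source = genotypes.subset_animals(sample_idx)
        ks = build_kernel_set(genotypes, which=("A", "AA"), freq_source=freq_source)
    elif mode == "slice":
        ks = full_kernels
    else:
        raise ValueError(f"unknown kernel mode {mode!r}")
    out = KernelSet()
    for name, k in ks.items():
        block_trace = float(np.trace(k.matrix[np.ix_(sample_idx, sample_idx)]))
        if block_trace <= 0:
            raise ValueError(f"kernel {name}: non-positive trace on the subsample")
        out[name] = Kernel(
            name, k.matrix * (sample_idx.size / block_trace), k.animal_ids
        )
    return out


def _intercept_fit(
    y: np.ndarray, kernels: KernelSet, obs_idx: np.ndarray, **engine_options
) -> FitResult:
    spec = MixedModelSpec(
        y=y,
        X=np.ones((y.size, 1)),
        kernels=kernels,
        obs_indices=obs_idx,
        x_names=["intercept"],
    )
    return fit_reml(spec, **engine_options)


def run_subsampling(
    pheno_adjusted: pd.DataFrame,
    kernels: KernelSet | None,
    sizes: list[int],
    n_replicates: int = 10,
    seed: int = 0,
    genotypes: GenotypeMatrix | None = None,
    kernel_mode: str = "recompute",
    nested: bool = False,
    **engine_options,
) -> SubsampleResult:
    """Stability experiment over random subsamples.

    ``pheno_adjusted`` has columns ``animal_id`` and ``y_adj`` (phenotypes
    already adjusted for fixed effects). For each size and replicate, animals
    are sampled without replacement, an intercept-only A + AA model is
    refitted, effects are predicted for every animal, and varcomps plus the
    four correlations (additive/AA x sampled/unsampled) against the full-data
    estimates are recorded. ``nested=True`` draws smaller samples as subsets
    of the largest one within each replicate.
    """
    if kernel_mode == "recompute" and genotypes is None:
        raise ValueError("recompute mode requires genotypes; pass kernel_mode='slice'")
    if kernels is None:
        if genotypes is None:
            raise ValueError("either kernels or genotypes must be provided")
        kernels = build_kernel_set(genotypes, which=("A", "AA"))
    animal_ids = kernels.animal_ids
    index = {a: i for i, a in enumerate(animal_ids)}
    obs_idx = np.asarray([index[a] for a in pheno_adjusted["animal_id"]])
    y = pheno_adjusted["y_adj"].to_numpy(dtype=float)
    n_obs = y.size
    n_par = len(kernels) + 1
    for size in sizes:
        if size > n_obs:
            raise ValueError(f"subsample size {size} exceeds {n_obs} phenotyped animals")
        if size < n_par + 2:
            raise ValueError(
                f"subsample size {size} too small to identify {n_par} variance "
                "components"
            )

    full_fit = _intercept_fit(y, kernels, obs_idx, **engine_options)
    full_effects = {nm: full_fit.blups[nm] for nm in ("A", "AA")}

    rng = np.random.default_rng(seed)
    rows = []
    sampled_ids: dict[tuple[int, int], np.ndarray] = {}
    all_idx = np.arange(len(animal_ids))
    for rep in range(n_replicates):
        base = rng.permutation(n_obs)
        for size in sorted(sizes, reverse=True):
            if nested:
                take = base[:size]
            else:
                take = rng.choice(n_obs, size=size, replace=False)
            sample_records = np.sort(take)
            sample_animals = np.sort(obs_idx[sample_records])
            sub_kernels = _subsample_kernels(
                kernels, genotypes, sample_animals, kernel_mode
            )
            fit = _intercept_fit(
                y[sample_records],
                sub_kernels,
                obs_idx[sample_records],
                **engine_options,
            )
            unsampled = np.setdiff1d(all_idx, sample_animals)
            row = {
                "size": size,
                "replicate": rep,
                "converged": fit.converged,
            }
            for nm in ("A", "AA", "residual"):
                row[f"var_{nm}"] = fit.varcomps[nm][0]
                row[f"se_{nm}"] = fit.varcomps[nm][1]
            for nm in ("A", "AA"):
                est = fit.blups[nm]
                row[f"r_{nm}_sampled"] = effect_correlation(
                    est, full_effects[nm], sample_animals
                )
                row[f"r_{nm}_unsampled"] = (
                    effect_correlation(est, full_effects[nm], unsampled)
                    if unsampled.size >= 3
                    else np.nan
                )
            rows.append(row)
            sampled_ids[(size, rep)] = sample_animals
    return SubsampleResult(
        full_fit=full_fit,
        records=pd.DataFrame(rows),
        sampled_ids=sampled_ids,
        seed=seed,
    )
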