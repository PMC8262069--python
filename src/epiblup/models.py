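"""Model variants, fixed-effect design construction and adjusted phenotypes.

The six model variants differ only in which genomic kernels they include:

    A    : A
    D    : A, D
    AA   : A, D, AA
    AA2  : A, AA          (dominance dropped)
    AD   : A, D, AA, AD
    Full : A, D, AA, AD, DD

The fixed-effect design one-hot encodes categorical factors (reference level
dropped, small levels merged into an "other" level) and standardizes
continuous covariates to mean 0, SD 1, recording the constants so
coefficients — in particular the heterozygosity slope used to measure
directional dominance — can be back-transformed to their raw per-unit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr

from epiblup.kernels import KernelSet
from epiblup.reml import FitResult, MixedModelSpec, fit_reml

MODEL_KERNELS: dict[str, list[str]] = {
    "A": ["A"],
    "D": ["A", "D"],
    "AA": ["A", "D", "AA"],
    "AA2": ["A", "AA"],
    "AD": ["A", "D", "AA", "AD"],
    "Full": ["A", "D", "AA", "AD", "DD"],
}

OTHER_LEVEL = "__other__"


@dataclass
class DesignInfo:
    columns: list[str]
    factors: list[str]
    covariates: list[str]
    cov_means: dict[str, float]
    cov_sds: dict[str, float]
    merged_levels: dict[str, list[str]] = field(default_factory=dict)
    reference_levels: dict[str, str] = field(default_factory=dict)


def build_design(
    pheno: pd.DataFrame,
    factors: list[str],
    covariates: list[str],
    min_level_size: int = 10,
) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + one-hot factors (reference dropped, rare levels merged)
    + standardized covariates."""
    for col in list(factors) + list(covariates):
        if col not in pheno.columns:
            raise KeyError(f"column {col!r} not found in the phenotype table")
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["intercept"]
    info = DesignInfo(
        columns=names,
        factors=list(factors),
        covariates=list(covariates),
        cov_means={},
        cov_sds={},
    )
    for fac in factors:
        values = pheno[fac].astype(str).copy()
        counts = values.value_counts()
        small = sorted(counts.index[counts < min_level_size])
        if small and len(counts) > len(small):
            values[values.isin(small)] = OTHER_LEVEL
            info.merged_levels[fac] = small
        levels = sorted(values.unique())
        ref = levels[0]
        info.reference_levels[fac] = ref
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(dtype=float))
            names.append(f"{fac}[{lev}]")
    for cov in covariates:
        x = pheno[cov].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError(f"covariate {cov!r} has zero variance")
        info.cov_means[cov] = mu
        info.cov_sds[cov] = sd
        cols.append((x - mu) / sd)
        names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {', '.join(bad)}"
        )
    info.columns = names
    return X, info


def build_model_spec(
    name: str,
    pheno: pd.DataFrame,
    kernels: KernelSet,
    factors: list[str],
    covariates: list[str],
    min_level_size: int = 10,
    trait: str = "trait_value",
) -> tuple[MixedModelSpec, DesignInfo]:
    if name not in MODEL_KERNELS:
        raise ValueError(f"unknown model {name!r}; choose from {list(MODEL_KERNELS)}")
    needed = MODEL_KERNELS[name]
    missing = [k for k in needed if k not in kernels]
    if missing:
        raise KeyError(f"model {name} requires kernel {missing[0]!r}, not provided")
    mask = pheno.get("phenotyped_flag", pd.Series(True, index=pheno.index))
    sub = pheno[mask.astype(bool) & pheno[trait].notna()].reset_index(drop=True)
    index = {a: i for i, a in enumerate(kernels.animal_ids)}
    unknown = [a for a in sub["animal_id"] if a not in index]
    if unknown:
        raise KeyError(f"phenotyped animal {unknown[0]!r} absent from the kernels")
    X, info = build_design(sub, factors, covariates, min_level_size)
    spec = MixedModelSpec(
        y=sub[trait].to_numpy(dtype=float),
        X=X,
        kernels=KernelSet({k: kernels[k] for k in needed}),
        obs_indices=np.asarray([index[a] for a in sub["animal_id"]]),
        x_names=info.columns,
    )
    return spec, info


def fit_model(
    name: str,
    pheno: pd.DataFrame,
    kernels: KernelSet,
    factors: list[str],
    covariates: list[str],
    min_level_size: int = 10,
    trait: str = "trait_value",
    **engine_options,
) -> FitResult:
    """Fit one of the named model variants by REML."""
    spec, info = build_model_spec(
        name, pheno, kernels, factors, covariates, min_level_size, trait
    )
    fit = fit_reml(spec, **engine_options)
    fit.design_meta = info
    return fit


def directional_dominance_slope(
    fit: FitResult, covariate: str = "het_percent"
) -> dict[str, tuple[float, float]]:
    """Heterozygosity slope on both the standardized and raw per-% scales.

    A positive per-% slope means more-heterozygous animals have higher
    phenotypes, the signature of directional dominance.
    """
    info: DesignInfo = fit.design_meta
    if info is None or covariate not in info.covariates:
        raise ValueError(f"covariate {covariate!r} is not part of the fitted design")
    j = info.columns.index(covariate)
    b_std, se_std = float(fit.beta[j]), float(fit.beta_se[j])
    sd = info.cov_sds[covariate]
    return {
        "standardized": (b_std, se_std),
        "per_unit": (b_std / sd, se_std / sd),
    }


def adjusted_phenotypes(
    pheno: pd.DataFrame, fit: FitResult, trait: str = "trait_value"
) -> pd.DataFrame:
    """y_adj = Y - X * beta_hat over phenotyped records (random effects kept).

    The design is rebuilt with the standardization and level-merging
    constants recorded at fit time, so the adjustment matches the fit's X.
    """
    info: DesignInfo = fit.design_meta
    spec = fit._spec
    if info is None or spec is None:
        raise ValueError("fit does not carry design metadata")
    mask = pheno.get("phenotyped_flag", pd.Series(True, index=pheno.index))
    sub = pheno[mask.astype(bool) & pheno[trait].notna()].reset_index(drop=True)
    if len(sub) != spec.n_obs:
        raise ValueError(
            f"phenotype table has {len(sub)} records but the fit used {spec.n_obs}"
        )
    X = _rebuild_design(sub, info)
    y = sub[trait].to_numpy(dtype=float)
    return pd.DataFrame(
        {"animal_id": sub["animal_id"], "y_adj": y - X @ fit.beta}
    )


def _rebuild_design(pheno: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    n = len(pheno)
    cols = {name: np.zeros(n) for name in info.columns}
    cols["intercept"] = np.ones(n)
    for fac in info.factors:
        values = pheno[fac].astype(str).copy()
        merged = info.merged_levels.get(fac, [])
        values[values.isin(merged)] = OTHER_LEVEL
        for lev in values.unique():
            name = f"{fac}[{lev}]"
            if name in cols:
                cols[name] = (values == lev).to_numpy(dtype=float)
            elif lev != info.reference_levels[fac]:
                raise ValueError(
                    f"level {lev!r} of factor {fac!r} was not present at fit time"
                )
    for cov in info.covariates:
        x = pheno[cov].to_numpy(dtype=float)
        cols[cov] = (x - info.cov_means[cov]) / info.cov_sds[cov]
    return np.column_stack([cols[name] for name in info.columns])
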