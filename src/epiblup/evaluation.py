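"""Stratified 10-fold cross-validation of predictive accuracy and bias, plus
a PCA check of population structure on the additive kernel.

Accuracy is the pooled Pearson correlation between adjusted phenotypes
(phenotype minus full-data fixed-effect estimates) and the total genotypic
value predicted for held-out animals; bias is the slope of predictions
regressed on adjusted phenotypes (1 = no dispersion bias). Folds are
constrained so every level of each stratification factor occurs in every
training split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from epiblup.kernels import Kernel, KernelSet
from epiblup.models import (
    adjusted_phenotypes,
    build_model_spec,
    fit_model,
    _rebuild_design,
)
from epiblup.reml import MixedModelSpec, fit_reml, predict_unphenotyped

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    model_name: str
    seed: int
    folds: pd.DataFrame  # animal_id, fold
    predictions: pd.DataFrame  # animal_id, fold, y_adj, pred_total, pred_additive
    pooled: dict[str, float]  # accuracy/bias for total and additive-only
    per_fold: pd.DataFrame
    n_failed_folds: int = 0


def _phenotyped(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    mask = pheno.get("phenotyped_flag", pd.Series(True, index=pheno.index))
    return pheno[mask.astype(bool) & pheno[trait].notna()].reset_index(drop=True)


def make_cv_folds(
    pheno: pd.DataFrame,
    n_folds: int = 10,
    strat_factors: tuple[str, ...] = (),
    seed: int = 0,
    trait: str = "trait_value",
) -> pd.DataFrame:
    """Random partition of phenotyped animals into folds such that every
    level of every stratification factor keeps at least one animal in each
    training split (i.e. no level is confined to a single fold)."""
    sub = _phenotyped(pheno, trait)
    n = len(sub)
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds={n_folds} infeasible for {n} animals")
    rng = np.random.default_rng(seed)
    fold = np.arange(n) % n_folds
    rng.shuffle(fold)
    level_members = {}
    for fac in strat_factors:
        for level, grp in sub.groupby(sub[fac].astype(str)).groups.items():
            idx = np.asarray(grp)
            if idx.size < 2:
                raise ValueError(
                    f"level {level!r} of factor {fac!r} has a single animal; "
                    "the training-split constraint is unsatisfiable (merge it "
                    "upstream)"
                )
            level_members[(fac, level)] = idx
    # repair passes: a level confined to one fold loses one animal to the
    # next fold; repeat since a move can (rarely) confine another level
    for _ in range(100):
        clean = True
        for (fac, level), idx in level_members.items():
            if np.unique(fold[idx]).size == 1:
                move = idx[rng.integers(idx.size)]
                fold[move] = (fold[move] + 1) % n_folds
                clean = False
        if clean:
            break
    else:
        raise RuntimeError("could not satisfy the stratification constraint")
    return pd.DataFrame({"animal_id": sub["animal_id"], "fold": fold})


def _acc_bias(y_adj: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    if y_adj.size < 3 or np.std(pred) == 0 or np.std(y_adj) == 0:
        warnings.warn(
            "degenerate predictions or targets; accuracy undefined", stacklevel=2
        )
        return np.nan, np.nan
    r = float(np.corrcoef(y_adj, pred)[0, 1])
    slope = float(np.cov(pred, y_adj, ddof=1)[0, 1] / np.var(y_adj, ddof=1))
    return r, slope


def run_cv(
    pheno: pd.DataFrame,
    kernels: KernelSet,
    model_name: str,
    factors: list[str],
    covariates: list[str],
    folds: pd.DataFrame | None = None,
    n_folds: int = 10,
    strat_factors: tuple[str, ...] | None = None,
    seed: int = 0,
    min_level_size: int = 10,
    trait: str = "trait_value",
    adjust: str = "full",
    **engine_options,
) -> CVResult:
    """Cross-validate one model: per fold, refit on the training animals only
    and predict the held-out animals' genetic values through the kernels.

    ``adjust='full'`` adjusts phenotypes with the full-data fixed effects
    (accepting the mild information leak); ``adjust='per_fold'`` uses each
    training fit's fixed effects instead.
    """
    if adjust not in ("full", "per_fold"):
        raise ValueError(f"unknown adjust mode {adjust!r}")
    if strat_factors is None:
        strat_factors = tuple(factors)
    sub = _phenotyped(pheno, trait)
    if folds is None:
        folds = make_cv_folds(pheno, n_folds, strat_factors, seed, trait)
    if list(folds["animal_id"]) != list(sub["animal_id"]):
        raise ValueError("fold assignment does not match the phenotyped animals")
    fold_ids = folds["fold"].to_numpy()

    full_fit = fit_model(
        model_name, pheno, kernels, factors, covariates, min_level_size, trait,
        **engine_options,
    )
    y_adj_full = adjusted_phenotypes(pheno, full_fit, trait)["y_adj"].to_numpy()
    info = full_fit.design_meta
    spec_full, _ = build_model_spec(
        model_name, pheno, kernels, factors, covariates, min_level_size, trait
    )

    records = []
    n_failed = 0
    for f in np.unique(fold_ids):
        train = np.flatnonzero(fold_ids != f)
        test = np.flatnonzero(fold_ids == f)
        train_df = sub.iloc[train]
        X_train = _rebuild_design(train_df, info)
        spec = MixedModelSpec(
            y=train_df[trait].to_numpy(dtype=float),
            X=X_train,
            kernels=spec_full.kernels,
            obs_indices=spec_full.obs_indices[train],
            x_names=info.columns,
        )
        fit = fit_reml(spec, **engine_options)
        if not fit.converged:
            logger.warning("fold %d fit did not converge; excluded from pooling", f)
            n_failed += 1
            continue
        fit.design_meta = info
        test_ids = list(sub["animal_id"].iloc[test])
        preds = predict_unphenotyped(fit, test_ids)
        if adjust == "full":
            y_adj_test = y_adj_full[test]
        else:
            X_test = _rebuild_design(sub.iloc[test], info)
            y_adj_test = (
                sub[trait].to_numpy(dtype=float)[test] - X_test @ fit.beta
            )
        for i, aid in enumerate(test_ids):
            records.append(
                {
                    "animal_id": aid,
                    "fold": int(f),
                    "y_adj": float(y_adj_test[i]),
                    "pred_total": float(preds["total"][i]),
                    "pred_additive": float(preds["A"][i]),
                }
            )
    pred_df = pd.DataFrame.from_records(records)

    pooled: dict[str, float] = {}
    per_fold_rows = []
    if len(pred_df):
        r, b = _acc_bias(pred_df["y_adj"].to_numpy(), pred_df["pred_total"].to_numpy())
        ra, ba = _acc_bias(
            pred_df["y_adj"].to_numpy(), pred_df["pred_additive"].to_numpy()
        )
        pooled = {
            "accuracy": r,
            "bias": b,
            "accuracy_additive": ra,
            "bias_additive": ba,
        }
        for f, grp in pred_df.groupby("fold"):
            rf, bf = _acc_bias(grp["y_adj"].to_numpy(), grp["pred_total"].to_numpy())
            per_fold_rows.append(
                {"fold": int(f), "accuracy": rf, "bias": bf, "n_test": len(grp)}
            )
    return CVResult(
        model_name=model_name,
        seed=seed,
        folds=folds,
        predictions=pred_df,
        pooled=pooled,
        per_fold=pd.DataFrame(per_fold_rows),
        n_failed_folds=n_failed,
    )


def pca_structure(kernel: Kernel, n_components: int = 10) -> dict:
    """Eigendecomposition of a relationship matrix for structure checks.

    Scores are eigenvectors scaled by sqrt(eigenvalue); cumulative variance
    proportions are taken over the positive part of the spectrum.
    """
    K = kernel.matrix
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel matrix is not symmetric")
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    cumprop = np.cumsum(pos) / pos.sum()
    k = min(n_components, vals.size)
    return {
        "eigenvalues": vals,
        "scores": vecs[:, :k] * np.sqrt(pos[:k]),
        "cumulative_proportion": cumprop,
        "animal_ids": kernel.animal_ids,
    }
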