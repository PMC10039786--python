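"""Out-of-sample evaluation: repeated random sub-sampling and k-fold CV.

Predictive ability is the Pearson correlation in the validation set between
GEBVs and the (pre-adjusted) phenotypes.  Every training computation — MAF
filtering, standardization statistics, shape grid search, weight estimation,
REML, BLUP — sees training individuals only; validation genotypes are
standardized with the training means and scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import weights as weights_mod
from .blup import SNPEffects, blup_snp_effects, fit_two_pass, predict_gebv, select_fixed_snps
from .plink import (
    GenotypeMatrix,
    StandardizedGenotypes,
    compute_maf,
    standardize,
    standardize_like,
)
from .reml import MixedModelData, VarianceComponents, reml_direct, reml_stochastic_lanczos


@dataclass
class PipelineConfig:
    """One genomic-prediction pipeline: weighting scheme and fitting options.

    scheme: "identity", "maf", "window" or "combined".  ``shape`` is the
    beta shape a = b for MAF weighting; setting ``grid`` instead selects it
    by REML-log-likelihood grid search on the training data.  ``S`` is the
    window half-width in SNPs, ``rounds`` the number of reweighting rounds.
    """

    scheme: str = "identity"
    shape: float = 1.5
    grid: tuple | None = None
    S: int = 20
    rounds: int = 1
    min_maf: float = 0.01
    scale_kind: str = "sample_sd"
    fixed_snp_policy: str = "none"
    algorithm: str = "direct"  # or "stochastic_lanczos"
    probes: int = 30
    seed: int = 1

    def reml(self):
        if self.algorithm == "direct":
            return reml_direct, {}
        if self.algorithm == "stochastic_lanczos":
            return reml_stochastic_lanczos, {"probes": self.probes, "seed": self.seed}
        raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class TrainedPipeline:
    """Everything needed to predict new individuals."""

    config: PipelineConfig
    sg: StandardizedGenotypes  # training standardization statistics
    weights: weights_mod.SNPWeightVector
    vc: VarianceComponents
    effects: SNPEffects
    shape: float | None = None
    grid_profile: pd.DataFrame | None = None
    rounds: list = field(default_factory=list)
    fixed_snps: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class ValidationResult:
    """Predictive ability of one replicate or fold."""

    replicate: int
    method_label: str
    r: float
    n_train: int
    n_valid: int
    seed: int


def fit_pipeline(
    config: PipelineConfig,
    data: MixedModelData,
    g: GenotypeMatrix,
    train_idx: np.ndarray,
) -> TrainedPipeline:
    """Fit the configured pipeline using only the individuals in ``train_idx``.

    ``data`` must be row-aligned with ``g.sample_ids``; ``train_idx`` are
    positional indices into those rows.
    """
    train_idx = np.asarray(train_idx)
    maf = compute_maf(g, train_idx)
    keep = np.nan_to_num(maf, nan=-1.0) >= config.min_maf
    g_kept = g.subset_snps(keep)
    sg = standardize(g_kept, train_idx, scale_kind=config.scale_kind)
    d_train = data.subset(train_idx)
    reml_fn, reml_kw = config.reml()

    fixed = np.array([], dtype=int)
    if config.fixed_snp_policy != "none":
        fixed = select_fixed_snps(d_train, sg.Z, config.fixed_snp_policy)
        if fixed.size:
            d_train = MixedModelData(
                y=d_train.y,
                X=np.column_stack([d_train.X, sg.Z[:, fixed]]),
                r=d_train.r,
                sample_ids=d_train.sample_ids,
            )

    shape = config.shape
    profile = None
    if config.scheme in ("maf", "combined") and config.grid is not None:
        shape, profile = weights_mod.grid_search_shape(
            d_train, sg, grid=config.grid, reml=reml_fn, **reml_kw
        )

    rounds: list = []
    if config.scheme == "identity":
        wv = weights_mod.identity_weights(sg.m)
        vc = reml_fn(d_train, sg.Z, wv.w, **reml_kw)
        eff = blup_snp_effects(vc, d_train, sg.Z, wv.w, force=True, fit_round=0)
    elif config.scheme == "maf":
        wv = weights_mod.maf_weights(sg.maf, shape, shape)
        vc = reml_fn(d_train, sg.Z, wv.w, **reml_kw)
        eff = blup_snp_effects(vc, d_train, sg.Z, wv.w, force=True, fit_round=0)
    else:
        rounds = fit_two_pass(
            d_train,
            sg.Z,
            chrom=sg.chrom,
            maf=sg.maf,
            scheme=config.scheme,
            shape=shape,
            S=config.S,
            rounds=config.rounds,
            reml=reml_fn,
            **reml_kw,
        )
        last = rounds[-1]
        wv, vc, eff = last.weights, last.vc, last.effects
    return TrainedPipeline(
        config=config,
        sg=sg,
        weights=wv,
        vc=vc,
        effects=eff,
        shape=shape,
        grid_profile=profile,
        rounds=rounds,
        fixed_snps=fixed,
    )


def predict_pipeline(trained: TrainedPipeline, g: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """GEBVs for the individuals in ``idx`` using training standardization."""
    g_sub = g.subset_samples(np.asarray(idx))
    Z_new = standardize_like(g_sub, trained.sg)
    return predict_gebv(trained.effects, Z_new).gebv


def _pearson(gebv: np.ndarray, y: np.ndarray) -> float:
    if gebv.size < 3 or np.std(gebv) == 0 or np.std(y) == 0:
        warnings.warn("predictive ability undefined (constant GEBV or phenotype); recorded as NaN")
        return float("nan")
    return float(stats.pearsonr(gebv, y)[0])


def _summarize(results: list[ValidationResult]) -> dict:
    rs = np.array([res.r for res in results], dtype=float)
    ok = ~np.isnan(rs)
    return {
        "mean_r": float(np.mean(rs[ok])) if ok.any() else float("nan"),
        "sd_r": float(np.std(rs[ok], ddof=1)) if ok.sum() > 1 else float("nan"),
        "n_replicates": len(results),
        "n_missing": int((~ok).sum()),
    }


def subsample_validation(
    config: PipelineConfig,
    data: MixedModelData,
    g: GenotypeMatrix,
    frac_train: float = 0.8,
    reps: int = 20,
    seed: int = 1,
    method_label: str | None = None,
) -> tuple[list[ValidationResult], dict]:
    """Repeated random sub-sampling validation (default 80/20, 20 replicates).

    Each replicate refits the full pipeline on its training split (no
    leakage) and reports the validation-set Pearson r; the summary carries
    the mean and the across-replicate SD.
    """
    n = data.n
    if n < 25:
        raise ValueError("need at least 25 individuals for sub-sampling validation")
    if g.n != n:
        raise ValueError("genotypes and phenotypes are not row-aligned")
    label = method_label or config.scheme
    n_train = int(round(frac_train * n))
    results = []
    for rep in range(reps):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(n)
        train_idx, valid_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        trained = fit_pipeline(config, data, g, train_idx)
        gebv = predict_pipeline(trained, g, valid_idx)
        r = _pearson(gebv, data.y[valid_idx])
        results.append(
            ValidationResult(rep, label, r, train_idx.size, valid_idx.size, rep_seed)
        )
    return results, _summarize(results)


def kfold_cv(
    config: PipelineConfig,
    data: MixedModelData,
    g: GenotypeMatrix,
    k: int = 5,
    seed: int = 1,
    method_label: str | None = None,
) -> tuple[list[ValidationResult], dict]:
    """k-fold cross-validation: random disjoint folds of near-equal size.

    Folds come from one random permutation chunked contiguously.  Per-fold
    Pearson r is reported along with the across-fold mean; the summary also
    carries the correlation of the pooled out-of-fold predictions, which is
    the defined quantity when folds are too small for a per-fold r (e.g.
    leave-one-out).
    """
    n = data.n
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    label = method_label or config.scheme
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]).generate_state(1)[0])
    folds = np.array_split(rng.permutation(n), k)
    results = []
    pooled_pred = np.full(n, np.nan)
    for i, fold in enumerate(folds):
        valid_idx = np.sort(fold)
        train_idx = np.sort(np.setdiff1d(np.arange(n), valid_idx))
        trained = fit_pipeline(config, data, g, train_idx)
        gebv = predict_pipeline(trained, g, valid_idx)
        pooled_pred[valid_idx] = gebv
        with warnings.catch_warnings():
            if valid_idx.size < 3:
                warnings.simplefilter("ignore")
            r = _pearson(gebv, data.y[valid_idx])
        results.append(ValidationResult(i, label, r, train_idx.size, valid_idx.size, seed))
    summary = _summarize(results)
    summary["pooled_r"] = _pearson(pooled_pred, data.y)
    return results, summary


def results_frame(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(res) for res in results])
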