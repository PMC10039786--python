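"""BLUP of SNP effects, GEBV prediction, fixed-SNP selection and two-pass fits.

Given REML variance components, SNP effects are the best linear unbiased
predictions

    beta_hat  = (X'V^{-1}X)^{-1} X'V^{-1} y
    alpha_hat = sigma2_alpha W Z' V^{-1} (y - X beta_hat)

with V = sigma2_alpha Z W Z' + sigma2_e R.  Systems in V are solved by
Cholesky below n = 5000 and by Jacobi-preconditioned conjugate gradients
above; a dense inverse is never formed.

``fit_two_pass`` runs the weighted protocol: fit once with identity weights,
recompute W from the fitted squared effects (window or combined scheme) and
refit.  One weighting round is the default; more rounds chain the same step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import LinearOperator, cg

from . import weights as weights_mod
from .reml import MixedModelData, VarianceComponents, _weights_vector, reml_direct

_DENSE_MAX_N = 5000
_CG_RTOL = 1e-8


@dataclass
class SNPEffects:
    """BLUP SNP effects on the standardized-genotype scale plus fixed-effect solutions."""

    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    fit_round: int = 1
    effect_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha_hat = np.asarray(self.alpha_hat, dtype=np.float64).ravel()
        self.beta_hat = np.asarray(self.beta_hat, dtype=np.float64).ravel()
        if not np.isfinite(self.alpha_hat).all() or not np.isfinite(self.beta_hat).all():
            raise ValueError("non-finite effect estimates")

    @property
    def m(self) -> int:
        return self.alpha_hat.size


@dataclass
class Predictions:
    """Per-individual genomic estimated breeding values."""

    gebv: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=np.float64).ravel()
        if not np.isfinite(self.gebv).all():
            raise ValueError("non-finite GEBVs")


def _solve_V(vc: VarianceComponents, data: MixedModelData, Zw: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve V x = b column-wise for V = Zw Zw' * s2a + s2e R without forming V^{-1}."""
    n = data.n
    s2a, s2e = vc.sigma2_alpha, vc.sigma2_e
    if n <= _DENSE_MAX_N:
        V = s2a * (Zw @ Zw.T) + np.diag(s2e * data.r)
        return cho_solve(cho_factor(V), B)
    diag = s2a * (Zw**2).sum(axis=1) + s2e * data.r
    op = LinearOperator((n, n), matvec=lambda v: s2a * (Zw @ (Zw.T @ v)) + s2e * data.r * v)
    pre = LinearOperator((n, n), matvec=lambda v: v / diag)
    B = np.atleast_2d(B.T).T
    out = np.empty_like(B)
    for j in range(B.shape[1]):
        x, info = cg(op, B[:, j], rtol=_CG_RTOL, atol=0.0, M=pre, maxiter=20 * n)
        if info != 0:
            warnings.warn(f"CG solve in V did not reach tolerance (info={info})")
        out[:, j] = x
    return out


def blup_snp_effects(
    vc: VarianceComponents,
    data: MixedModelData,
    Z: np.ndarray,
    w=None,
    fit_round: int = 1,
    force: bool = False,
    effect_allele: np.ndarray | None = None,
) -> SNPEffects:
    """BLUP of SNP effects and GLS fixed-effect solutions at the REML optimum."""
    if not vc.converged and not force:
        raise RuntimeError("variance components did not converge; pass force=True to override")
    Z = np.asarray(getattr(Z, "Z", Z), dtype=np.float64)
    wvec = _weights_vector(w, Z.shape[1])
    if vc.sigma2_alpha == 0.0:
        # no genetic variance: alpha_hat = 0 and beta_hat is the GLS solution under R
        Xw = data.X / data.r[:, None]
        A = data.X.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ data.y)
        return SNPEffects(np.zeros(Z.shape[1]), beta, fit_round, effect_allele)
    Zw = Z * np.sqrt(wvec)
    ViY = _solve_V(vc, data, Zw, np.column_stack([data.y, data.X]))
    Viy, ViX = ViY[:, 0], ViY[:, 1:]
    A = data.X.T @ ViX
    beta = np.linalg.solve(A, data.X.T @ Viy)
    resid = data.y - data.X @ beta
    Vir = _solve_V(vc, data, Zw, resid[:, None])[:, 0]
    alpha = vc.sigma2_alpha * wvec * (Z.T @ Vir)
    return SNPEffects(alpha, beta, fit_round, effect_allele)


def predict_gebv(
    effects: SNPEffects, Z_new: np.ndarray, sample_ids: np.ndarray | None = None
) -> Predictions:
    """GEBV = Z_new alpha_hat; Z_new must be standardized with TRAINING statistics."""
    Z_new = np.asarray(getattr(Z_new, "Z", Z_new), dtype=np.float64)
    if Z_new.shape[1] != effects.m:
        raise ValueError(
            f"SNP mismatch: effects for {effects.m} SNPs, genotypes have {Z_new.shape[1]}"
        )
    return Predictions(Z_new @ effects.alpha_hat, sample_ids)


def select_fixed_snps(
    data: MixedModelData,
    Z: np.ndarray,
    threshold_policy: str = "bonferroni",
    alpha: float = 0.05,
) -> np.ndarray:
    """Single-marker scan for SNPs to fit as fixed covariates.

    Regresses y on each standardized SNP column together with X and returns
    the indices passing the significance policy ("bonferroni" over m tests,
    or "none" for an empty selection).  Raises if the selection would use
    n/10 or more SNPs as fixed effects.
    """
    Z = np.asarray(getattr(Z, "Z", Z), dtype=np.float64)
    if threshold_policy == "none":
        return np.array([], dtype=int)
    if threshold_policy != "bonferroni":
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    n, m = Z.shape
    X = data.X
    # residualize y and Z on the fixed-effect design
    Q, _ = np.linalg.qr(X)
    y_r = data.y - Q @ (Q.T @ data.y)
    Z_r = Z - Q @ (Q.T @ Z)
    zz = (Z_r**2).sum(axis=0)
    ok = zz > 1e-12
    slope = np.zeros(m)
    slope[ok] = (Z_r[:, ok] * y_r[:, None]).sum(axis=0) / zz[ok]
    dof = n - X.shape[1] - 1
    rss = (y_r**2).sum() - slope**2 * zz
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope * np.sqrt(zz) / np.sqrt(rss / dof)
    pvals = np.ones(m)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    selected = np.flatnonzero(pvals < alpha / m)
    if selected.size >= n / 10:
        raise ValueError(
            f"{selected.size} SNPs selected as fixed (>= n/10 = {n / 10:.0f}); model overparameterized"
        )
    return selected


@dataclass
class FitRound:
    """One round of the two-pass protocol: its weights, variance components and effects."""

    round_index: int
    weights: weights_mod.SNPWeightVector
    vc: VarianceComponents
    effects: SNPEffects


def fit_two_pass(
    data: MixedModelData,
    Z: np.ndarray,
    chrom: np.ndarray | None = None,
    maf: np.ndarray | None = None,
    scheme: str = "window",
    shape: float = 1.5,
    S: int = 20,
    rounds: int = 1,
    reml=reml_direct,
    weight_floor: float = 0.0,
    **reml_kwargs,
) -> list[FitRound]:
    """Weighted SNP-BLUP protocol: identity fit, reweight from alpha_hat, refit.

    Round 0 always uses identity weights; each of the ``rounds`` subsequent
    rounds recomputes W from the previous round's squared effects with the
    window scheme (or the MAF-by-window combined scheme, which also needs
    ``maf`` and ``shape``) and refits REML and BLUP.  Returns every round's
    artifacts so round 0 doubles as the unweighted reference fit.  If a
    reweighting round degenerates the fit stops with a warning and the valid
    rounds are returned.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if scheme not in ("window", "combined"):
        raise ValueError(f"two-pass scheme must be 'window' or 'combined', got {scheme!r}")
    if scheme == "combined" and maf is None:
        maf = getattr(Z, "maf", None)
        if maf is None:
            raise ValueError("combined scheme needs the MAF vector")
    if chrom is None:
        chrom = getattr(Z, "chrom", None)
    Zmat = np.asarray(getattr(Z, "Z", Z), dtype=np.float64)
    m = Zmat.shape[1]
    out: list[FitRound] = []
    wv = weights_mod.identity_weights(m)
    for k in range(rounds + 1):
        vc = reml(data, Zmat, wv.w, **reml_kwargs)
        eff = blup_snp_effects(vc, data, Zmat, wv.w, fit_round=k, force=True)
        out.append(FitRound(k, wv, vc, eff))
        if k == rounds:
            break
        try:
            if scheme == "window":
                wv = weights_mod.window_weights(eff.alpha_hat, S, chrom)
            else:
                wv = weights_mod.combined_weights(maf, shape, shape, eff.alpha_hat, S, chrom)
            wv = weights_mod.apply_weight_floor(wv, weight_floor)
        except ValueError as exc:
            warnings.warn(f"stopping after round {k}: degenerate weights ({exc})")
            break
    return out


def allelic_effects(effects: SNPEffects, scales: np.ndarray) -> np.ndarray:
    """Per-allele effects: alpha_hat divided by the training column scales."""
    return effects.alpha_hat / np.asarray(scales, dtype=np.float64)
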