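"""REML variance-component estimation for the weighted SNP-effects model.

Model: y = X beta + Z alpha + e with alpha ~ N(0, W sigma2_alpha) and
e ~ N(0, R sigma2_e); W is the mean-one diagonal SNP weight matrix, R a
diagonal of per-individual residual-variance weights (identity unless the
phenotypes are deregressed EBVs of varying reliability).

Both fitting paths profile the restricted likelihood in the single ratio
lambda = sigma2_alpha / sigma2_e, maximizing over log10(lambda) in [-6, 6]
with a coarse grid followed by bounded Brent refinement:

* ``reml_direct`` eigendecomposes K = R^{-1/2} Z W Z' R^{-1/2} once, making
  each lambda evaluation O(n); it is the exact oracle (guarded to
  n <= 20,000).
* ``reml_stochastic_lanczos`` touches Z only through matrix-vector products:
  log-determinants come from Hutchinson probing with Lanczos quadrature
  (Rademacher probes shared across lambda so the profile stays smooth) and
  the linear solves from conjugate gradients.

The log-likelihood convention is the full restricted likelihood
-1/2 [ (n-c) log 2pi + log|V| + log|X'V^{-1}X| + y'Py ] with no |X'X| term,
so values are comparable across weight choices on the same data.

Heritability is reported as h2 = m sigma2_alpha / (m sigma2_alpha +
sigma2_e), which equals the share of phenotypic variance captured by the
SNPs when Z has unit-variance columns and W has mean one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh, eigh_tridiagonal
from scipy.sparse.linalg import LinearOperator, cg

LOG10_LAMBDA_BOUNDS = (-6.0, 6.0)
_DIRECT_MAX_N = 20_000


@dataclass
class MixedModelData:
    """Phenotypes, fixed-effect design and residual weights, row-aligned with Z."""

    y: np.ndarray
    X: np.ndarray
    r: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        self.r = np.asarray(self.r, dtype=np.float64).ravel()
        n = self.y.size
        if self.X.shape[0] != n or self.r.size != n:
            raise ValueError("y, X and r must have matching numbers of rows")
        if np.isnan(self.y).any():
            raise ValueError("phenotypes contain missing values after alignment")
        if (self.r <= 0).any():
            raise ValueError("residual-variance weights must be positive")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def c(self) -> int:
        return self.X.shape[1]

    def subset(self, index: np.ndarray) -> "MixedModelData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return MixedModelData(
            y=self.y[index],
            X=self.X[index],
            r=self.r[index],
            sample_ids=None if self.sample_ids is None else self.sample_ids[index],
        )


def residual_weight_from_reliability(reliability: np.ndarray) -> np.ndarray:
    """Common choice of diag(R) for deregressed EBVs: r_i = (1 - rel_i) / rel_i."""
    rel = np.asarray(reliability, dtype=np.float64)
    if (rel <= 0).any() or (rel > 1).any():
        raise ValueError("reliabilities must lie in (0, 1]")
    return (1.0 - rel) / rel


@dataclass
class VarianceComponents:
    """REML estimates: per-SNP effect variance, residual variance and derived h2."""

    sigma2_alpha: float
    sigma2_e: float
    h2: float
    logL: float
    converged: bool
    n_iter: int
    m: int
    boundary: bool = False
    logL_se: float | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_alpha": self.sigma2_alpha,
                "sigma2_e": self.sigma2_e,
                "h2": self.h2,
                "logL": self.logL,
                "converged": self.converged,
                "boundary": self.boundary,
            }
        )


def _weights_vector(w, m: int) -> np.ndarray:
    if w is None:
        return np.ones(m)
    w = getattr(w, "w", w)
    w = np.asarray(w, dtype=np.float64)
    if w.size != m:
        raise ValueError(f"weight vector length {w.size} != number of SNPs {m}")
    if (w < 0).any():
        raise ValueError("SNP weights must be non-negative")
    return w


def _transformed(data: MixedModelData, Z: np.ndarray, w) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """R^{-1/2}-scaled responses, design and weighted genotype factor."""
    Z = np.asarray(getattr(Z, "Z", Z), dtype=np.float64)
    if Z.shape[0] != data.n:
        raise ValueError("Z and phenotype rows are not aligned")
    wvec = _weights_vector(w, Z.shape[1])
    rs = np.sqrt(data.r)
    ry = data.y / rs
    RX = data.X / rs[:, None]
    Zw = (Z / rs[:, None]) * np.sqrt(wvec)
    return ry, RX, Zw, wvec


def reml_loglik(theta, data: MixedModelData, Z: np.ndarray, w=None) -> float:
    """Exact restricted log-likelihood at theta = (sigma2_alpha, sigma2_e).

    Dense reference evaluation of
    -1/2 [ (n-c) log 2pi + log|V| + log|X'V^{-1}X| + y'Py ]
    with V = sigma2_alpha Z W Z' + sigma2_e R.  Used as the objective oracle;
    the fitting paths must agree with it.
    """
    s2a, s2e = float(theta[0]), float(theta[1])
    if s2a < 0 or s2e <= 0:
        raise ValueError(f"invalid variance components ({s2a}, {s2e})")
    Z = np.asarray(getattr(Z, "Z", Z), dtype=np.float64)
    wvec = _weights_vector(w, Z.shape[1])
    n, c = data.n, data.c
    V = s2a * (Z * wvec) @ Z.T + s2e * np.diag(data.r)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValueError("V is numerically singular; consider jitter or stronger SNP filtering")
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - slogdet catches most
        raise ValueError("V is numerically singular; consider jitter or stronger SNP filtering") from exc
    Viy = cho_solve(cf, data.y)
    ViX = cho_solve(cf, data.X)
    A = data.X.T @ ViX
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        raise ValueError("X'V^{-1}X is singular")
    XtViy = data.X.T @ Viy
    quad = data.y @ Viy - XtViy @ np.linalg.solve(A, XtViy)
    return -0.5 * ((n - c) * np.log(2.0 * np.pi) + logdetV + logdetA + quad)


class _ProfileObjective:
    """Shared profile-REML machinery given a per-lambda log|H| and solve backend."""

    def __init__(self, data: MixedModelData, constant_terms: float):
        self.n, self.c = data.n, data.c
        self.sum_log_r = float(np.sum(np.log(data.r)))
        self.const = constant_terms
        self.evals = 0

    def assemble(self, logdetH: float, logdetA: float, quad: float) -> tuple[float, float]:
        """Return (negative profiled logL, profiled sigma2_e)."""
        nc = self.n - self.c
        s2e = quad / nc
        ll = -0.5 * (
            nc * (np.log(2.0 * np.pi) + 1.0)
            + nc * np.log(s2e)
            + logdetH
            + self.sum_log_r
            + logdetA
        )
        return -ll, s2e


def _profile_pieces_dense(ry, RX, d, yt, Xt, lam):
    """log|H|, log|X'H^{-1}X| and the REML quadratic for H = lam K + I via eigenvalues."""
    h = lam * d + 1.0
    logdetH = float(np.sum(np.log(h)))
    Xh = Xt / h[:, None]
    A = Xt.T @ Xh
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        raise ValueError("X'V^{-1}X is singular")
    yh = yt / h
    Xty = Xt.T @ yh
    quad = float(yt @ yh - Xty @ np.linalg.solve(A, Xty))
    return logdetH, logdetA, quad


def _optimize_profile(negll, bounds=LOG10_LAMBDA_BOUNDS, grid_points=25, xatol=1e-4):
    """Coarse grid then bounded Brent on log10(lambda); returns (t_hat, nll_hat, evals, grid_min)."""
    ts = np.linspace(bounds[0], bounds[1], grid_points)
    vals = np.array([negll(t) for t in ts])
    i = int(np.argmin(vals))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": xatol})
    t_hat, f_hat = float(res.x), float(res.fun)
    if vals[i] < f_hat:  # never return worse than the best grid point
        t_hat, f_hat = float(ts[i]), float(vals[i])
    return t_hat, f_hat, grid_points + int(res.nfev), float(vals.min())


def _finish(t_hat, negll_at, n_evals, m, bounds, grid_points_converged=True):
    lam = 10.0**t_hat
    nll, s2e = negll_at(t_hat)
    boundary = False
    if t_hat <= bounds[0] + 1e-3:
        # effectively zero genetic variance: pin sigma2_alpha to the boundary
        lam = 0.0
        nll, s2e = negll_at(None, lam_override=0.0)
        boundary = True
    elif t_hat >= bounds[1] - 1e-3:
        boundary = True
    s2a = lam * s2e
    h2 = m * s2a / (m * s2a + s2e) if (m * s2a + s2e) > 0 else 0.0
    return VarianceComponents(
        sigma2_alpha=s2a,
        sigma2_e=s2e,
        h2=h2,
        logL=-nll,
        converged=grid_points_converged,
        n_iter=n_evals,
        m=m,
        boundary=boundary,
    )


def reml_direct(
    data: MixedModelData,
    Z: np.ndarray,
    w=None,
    bounds: tuple[float, float] = LOG10_LAMBDA_BOUNDS,
    grid_points: int = 25,
    xatol: float = 1e-4,
) -> VarianceComponents:
    """Exact REML by a single dense eigendecomposition of K = R^{-1/2} Z W Z' R^{-1/2}.

    Guarded to n <= 20,000; beyond that use ``reml_stochastic_lanczos``.
    """
    if data.n > _DIRECT_MAX_N:
        raise ValueError(f"n={data.n} too large for the dense path (max {_DIRECT_MAX_N})")
    ry, RX, Zw, wvec = _transformed(data, Z, w)
    n, c = data.n, data.c
    m = Zw.shape[1]
    K = Zw @ Zw.T
    d, U = eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ ry
    Xt = U.T @ RX
    obj = _ProfileObjective(data, 0.0)

    def pieces(lam):
        return _profile_pieces_dense(ry, RX, d, yt, Xt, lam)

    def negll(t):
        obj.evals += 1
        return obj.assemble(*pieces(10.0**t))[0]

    t_hat, _, n_evals, _ = _optimize_profile(negll, bounds, grid_points, xatol)

    def negll_at(t, lam_override=None):
        lam = 10.0**t if lam_override is None else lam_override
        return obj.assemble(*pieces(lam))

    return _finish(t_hat, negll_at, n_evals, m, bounds)


def _batched_lanczos_quadrature(matmat, Q, max_iter, project=None, check_every=5, rtol=1e-9):
    """Per-probe Gauss quadrature rules for spectral sums of a PSD operator K.

    Runs one Lanczos recurrence per probe column of Q, batched across probes
    with full reorthogonalization, and returns for each probe the Ritz nodes
    ``theta`` and weights ``tau2`` (squared first eigenvector components)
    together with the probe's squared norm.  The rule estimates
    z' f(K) z ~ ||z||^2 sum_j tau2_j f(theta_j) for ANY f, so a single pass
    serves every lambda in the profile search for f = log(lambda x + 1).

    ``project`` (optional) re-projects every Krylov vector, keeping the
    recurrence inside a deflated subspace.  A near-zero recurrence norm means
    an exact invariant subspace was found (the quadrature is then exact for
    that probe).  Convergence is declared when the quadrature value of the
    stiffest profile point, f(x) = log(1e6 x + 1), stabilizes.
    """
    n, p = Q.shape
    norm2 = (Q**2).sum(axis=0)
    safe = np.sqrt(np.where(norm2 > 0, norm2, 1.0))
    V = Q / safe
    kmax = int(min(max_iter, n))
    basis = [V]
    alphas = []
    betas = []
    length = np.zeros(p, dtype=int)
    active = norm2 > 1e-20
    converged = False
    prev_check = None

    def rules():
        A = np.array(alphas)
        B = np.array(betas)
        out = []
        for i in range(p):
            k = length[i]
            if k == 0:
                out.append((np.zeros(1), np.ones(1)))
                continue
            theta, S = eigh_tridiagonal(A[:k, i], B[: k - 1, i] if k > 1 else np.empty(0))
            out.append((np.clip(theta, 0.0, None), S[0] ** 2))
        return out

    def check_value():
        return np.array(
            [norm2[i] * float(t2 @ np.log1p(1e6 * th)) for i, (th, t2) in enumerate(rules())]
        )

    for j in range(kmax):
        if not active.any():
            converged = True
            break
        Wv = matmat(basis[j])
        if project is not None:
            Wv = project(Wv)
        a = np.einsum("np,np->p", basis[j], Wv)
        alphas.append(np.where(active, a, 0.0))
        Wv = Wv - a * basis[j]
        if j > 0:
            Wv = Wv - betas[j - 1] * basis[j - 1]
        stacked = np.stack(basis)
        proj = np.einsum("knp,np->kp", stacked, Wv)
        Wv = Wv - np.einsum("knp,kp->np", stacked, proj)
        b = np.sqrt(np.einsum("np,np->p", Wv, Wv))
        length[active] = j + 1
        done = b < 1e-10
        betas.append(np.where(active & ~done, b, 0.0))
        active = active & ~done
        safe_b = np.where(b > 0, b, 1.0)
        basis.append(np.where(active, Wv / safe_b, 0.0))
        if (j + 1) % check_every == 0 or j == kmax - 1:
            val = check_value()
            if prev_check is not None and np.max(np.abs(val - prev_check)) < rtol * max(
                1.0, float(np.abs(val).max())
            ):
                converged = True
                break
            prev_check = val
    if not active.any():
        converged = True
    return rules(), norm2, converged


def reml_stochastic_lanczos(
    data: MixedModelData,
    Z: np.ndarray,
    w=None,
    probes: int = 30,
    lanczos_iters: int = 200,
    seed: int = 1,
    deflate_rank: int = 120,
    bounds: tuple[float, float] = LOG10_LAMBDA_BOUNDS,
    grid_points: int = 13,
    xatol: float = 1e-4,
    cg_rtol: float = 1e-10,
) -> VarianceComponents:
    """REML by stochastic Lanczos quadrature, touching Z only via mat-vec products.

    log|H(lambda)| with H = lambda K + I splits into an exact part over the
    top ``deflate_rank`` eigenpairs of K (computed once by matrix-free
    Lanczos) and a Hutchinson estimate of the spectral tail from Rademacher
    probes deflated against that subspace — the tail's log contributions are
    small, which collapses the Monte-Carlo variance.  Because the Lanczos
    recurrence for K does not depend on lambda, one quadrature pass serves
    every lambda visited by the profile optimizer, and the shared probes make
    the stochastic profile smooth with a well-defined optimum.  Conjugate
    gradients supply H^{-1}y and H^{-1}X.  The result carries the
    Monte-Carlo standard error of the log-likelihood and must agree with
    ``reml_direct``.
    """
    from scipy.sparse.linalg import eigsh

    ry, RX, Zw, wvec = _transformed(data, Z, w)
    n, c = data.n, data.c
    m = Zw.shape[1]
    rng = np.random.default_rng(seed)
    obj = _ProfileObjective(data, 0.0)
    all_converged = True

    def kmat(Vb):
        return Zw @ (Zw.T @ Vb)

    k_defl = int(min(deflate_rank, n - 2, m))
    if k_defl > 0:
        Kop = LinearOperator((n, n), matvec=kmat)
        d_top, Qd = eigsh(Kop, k=k_defl, which="LA", v0=rng.standard_normal(n))
        d_top = np.clip(d_top, 0.0, None)
    else:
        d_top, Qd = np.zeros(0), np.zeros((n, 0))

    def deflate(Vb):
        return Vb - Qd @ (Qd.T @ Vb) if k_defl > 0 else Vb

    probes_Z = rng.choice(np.array([-1.0, 1.0]), size=(n, probes))
    rules, norm2, lanczos_ok = _batched_lanczos_quadrature(
        lambda Vb: deflate(kmat(Vb)), deflate(probes_Z), lanczos_iters, project=deflate
    )
    all_converged &= lanczos_ok
    cache: dict[float, tuple] = {}

    def pieces(lam):
        nonlocal all_converged
        if lam in cache:
            return cache[lam]
        top = float(np.log1p(lam * d_top).sum())
        tail = np.array(
            [norm2[i] * float(t2 @ np.log1p(lam * th)) for i, (th, t2) in enumerate(rules)]
        )
        logdetH = top + float(tail.mean())
        se_logdet = float(tail.std(ddof=1) / np.sqrt(probes)) if probes > 1 else 0.0
        op = LinearOperator((n, n), matvec=lambda v: lam * kmat(v) + v)
        diag = lam * (Zw**2).sum(axis=1) + 1.0
        pre = LinearOperator((n, n), matvec=lambda v: v / diag)
        rhs = np.column_stack([ry, RX])
        sols = np.empty_like(rhs)
        for jcol in range(rhs.shape[1]):
            x, info = cg(op, rhs[:, jcol], rtol=cg_rtol, atol=0.0, M=pre, maxiter=20 * n)
            if info != 0:
                warnings.warn(f"CG did not fully converge (info={info}) at lambda={lam:g}")
                all_converged = False
            sols[:, jcol] = x
        Hy = sols[:, 0]
        HX = sols[:, 1:]
        A = RX.T @ HX
        signA, logdetA = np.linalg.slogdet(A)
        if signA <= 0:
            raise ValueError("X'V^{-1}X is singular")
        Xty = RX.T @ Hy
        quad = float(ry @ Hy - Xty @ np.linalg.solve(A, Xty))
        out = (logdetH, logdetA, quad, se_logdet)
        cache[lam] = out
        return out

    def negll(t):
        obj.evals += 1
        logdetH, logdetA, quad, _ = pieces(10.0**t)
        return obj.assemble(logdetH, logdetA, quad)[0]

    t_hat, _, n_evals, _ = _optimize_profile(negll, bounds, grid_points, xatol)

    def negll_at(t, lam_override=None):
        lam = 10.0**t if lam_override is None else lam_override
        logdetH, logdetA, quad, _ = pieces(lam)
        return obj.assemble(logdetH, logdetA, quad)

    vc = _finish(t_hat, negll_at, n_evals, m, bounds, grid_points_converged=all_converged)
    lam_final = 0.0 if (vc.boundary and vc.sigma2_alpha == 0.0) else 10.0**t_hat
    vc.logL_se = 0.5 * pieces(lam_final)[3]
    return vc


def make_mixed_model_data(
    sample_ids: np.ndarray,
    pheno: pd.DataFrame,
    trait: str,
    id_col: str | None = None,
    weight_col: str | None = None,
    covariates: list[str] | None = None,
) -> tuple[MixedModelData, np.ndarray]:
    """Align a phenotype table to genotype sample IDs.

    Returns the model data (intercept plus optional covariate columns) and
    the positional indices of the genotyped samples that have a non-missing
    phenotype, in genotype order.
    """
    id_col = id_col or pheno.columns[0]
    tab = pheno.set_index(pheno[id_col].astype(str))
    ids = [str(s) for s in sample_ids]
    present = [i for i, s in enumerate(ids) if s in tab.index and pd.notna(tab.loc[s, trait])]
    if not present:
        raise ValueError("no genotyped sample has a non-missing phenotype")
    rows = tab.loc[[ids[i] for i in present]]
    y = rows[trait].astype(float).to_numpy()
    n = len(present)
    cols = [np.ones(n)]
    if covariates:
        for cov in covariates:
            cols.append(rows[cov].astype(float).to_numpy())
    X = np.column_stack(cols)
    r = rows[weight_col].astype(float).to_numpy() if weight_col else np.ones(n)
    data = MixedModelData(y=y, X=X, r=r, sample_ids=np.array(ids, dtype=object)[present])
    return data, np.asarray(present)
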