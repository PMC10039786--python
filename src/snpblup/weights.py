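"""Per-SNP variance weights for the weighted SNP-BLUP model.

The diagonal of W gives each SNP's relative contribution to genetic
variance; every scheme rescales to an arithmetic mean of exactly one so a
weight is interpretable as a relative share.  Three schemes:

* MAF-based: w_j proportional to p_j^(a-1) (1-p_j)^(b-1), the beta density
  evaluated at the minor allele frequency.  a = b = 1 is the unweighted
  model; a = b = 2 matches the common 2p(1-p) heritability assumption;
  a < 1 <= b up-weights rare variants.
* Window-based: w_j proportional to the mean squared BLUP effect of the
  2S+1 SNPs centered on j (truncated at chromosome ends), exploiting the
  local similarity of fitted effects under LD.
* Combined: the product of the two, rescaled once.

The beta shape (constrained a = b) is chosen by grid search on the REML
log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_SHAPE_GRID = (0.5, 1.0, 1.5, 2.0, 2.5)
FINE_SHAPE_GRID = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass
class SNPWeightVector:
    """Diagonal of W with its scaling constant and scheme parameters."""

    w: np.ndarray
    scheme: str
    C: float
    a: float | None = None
    b: float | None = None
    S: int | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if abs(self.w.mean() - 1.0) > 1e-10:
            raise ValueError("weights must have mean one")
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return self.w.size


def identity_weights(m: int) -> SNPWeightVector:
    return SNPWeightVector(w=np.ones(m), scheme="identity", C=1.0)


def _normalize(raw: np.ndarray, scheme: str, **params) -> SNPWeightVector:
    total = raw.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"{scheme} weights degenerate: raw weights sum to {total}")
    C = raw.size / total
    return SNPWeightVector(w=raw * C, scheme=scheme, C=C, **params)


def _beta_raw(maf: np.ndarray, a: float, b: float) -> np.ndarray:
    maf = np.asarray(maf, dtype=np.float64)
    if a <= 0 or b <= 0:
        raise ValueError(f"beta shape parameters must be positive, got a={a}, b={b}")
    if (maf <= 0).any() or (maf > 0.5).any() or np.isnan(maf).any():
        raise ValueError("maf values must lie in (0, 0.5]; run the MAF filter first")
    return maf ** (a - 1.0) * (1.0 - maf) ** (b - 1.0)


def maf_weights(maf: np.ndarray, a: float, b: float) -> SNPWeightVector:
    """Beta-density MAF weights w_j = C p_j^(a-1) (1-p_j)^(b-1), mean one."""
    return _normalize(_beta_raw(maf, a, b), "maf", a=a, b=b)


def _window_raw(alpha_hat: np.ndarray, S: int, chrom: np.ndarray | None) -> np.ndarray:
    """Mean squared effect in the (2S+1)-SNP window around each SNP.

    Windows are truncated at chromosome boundaries and divided by the actual
    number of SNPs they contain, and never span chromosomes.
    """
    alpha_hat = np.asarray(alpha_hat, dtype=np.float64)
    if S < 0 or int(S) != S:
        raise ValueError(f"window half-width S must be a non-negative integer, got {S}")
    S = int(S)
    m = alpha_hat.size
    sq = alpha_hat**2
    if chrom is None:
        chrom = np.zeros(m, dtype=object)
    chrom = np.asarray(chrom, dtype=object)
    out = np.empty(m)
    start = 0
    while start < m:
        stop = start
        while stop < m and chrom[stop] == chrom[start]:
            stop += 1
        block = sq[start:stop]
        csum = np.concatenate(([0.0], np.cumsum(block)))
        L = stop - start
        j = np.arange(L)
        lo = np.maximum(j - S, 0)
        hi = np.minimum(j + S, L - 1)
        out[start:stop] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
        start = stop
    return out


def window_weights(
    alpha_hat: np.ndarray, S: int, chrom: np.ndarray | None = None
) -> SNPWeightVector:
    """Window weights from a prior identity-weight fit's SNP effects (mean one)."""
    raw = _window_raw(alpha_hat, S, chrom)
    if raw.max() <= 0:
        raise ValueError("all estimated effects are zero: window weights cannot be normalized")
    return _normalize(raw, "window", S=int(S))


def combined_weights(
    maf: np.ndarray,
    a: float,
    b: float,
    alpha_hat: np.ndarray,
    S: int,
    chrom: np.ndarray | None = None,
) -> SNPWeightVector:
    """Product of the MAF and window factors with a single mean-one rescale."""
    raw = _beta_raw(maf, a, b) * _window_raw(alpha_hat, S, chrom)
    if raw.max() <= 0:
        raise ValueError("all estimated effects are zero: combined weights cannot be normalized")
    return _normalize(raw, "combined", a=a, b=b, S=int(S))


def apply_weight_floor(wv: SNPWeightVector, floor: float) -> SNPWeightVector:
    """Raise weights below ``floor`` to the floor, then renormalize to mean one."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if floor == 0:
        return wv
    return _normalize(np.maximum(wv.w, floor), wv.scheme, a=wv.a, b=wv.b, S=wv.S)


def grid_search_shape(
    data,
    sg,
    grid=DEFAULT_SHAPE_GRID,
    reml=None,
    **reml_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Choose the beta shape a = b maximizing the REML log-likelihood.

    Fits variance components once per grid value with W = maf_weights(s, s)
    (no shortcut; identical convergence settings).  Returns the winning shape
    and the full (shape, logL) profile in input order.  Ties are broken by
    the shape closest to 1; a failed fit is recorded with NaN and skipped.
    """
    from . import reml as reml_mod

    grid = list(grid)
    if not grid:
        raise ValueError("shape grid must be non-empty")
    fit = reml if reml is not None else reml_mod.reml_direct
    rows = []
    for s in grid:
        try:
            wv = maf_weights(sg.maf, s, s)
            vc = fit(data, sg.Z, wv.w, **reml_kwargs)
            rows.append({"shape": s, "logL": vc.logL, "h2": vc.h2, "converged": vc.converged})
        except Exception as exc:  # noqa: BLE001 - a failed grid point must not stop the search
            rows.append({"shape": s, "logL": np.nan, "h2": np.nan, "converged": False,
                         "error": str(exc)})
    profile = pd.DataFrame(rows)
    ok = profile["logL"].notna()
    if not ok.any():
        raise RuntimeError("REML failed at every grid point")
    best_ll = profile.loc[ok, "logL"].max()
    # ties (within 1e-9) broken by |shape - 1|
    cand = profile.loc[ok & (profile["logL"] >= best_ll - 1e-9), "shape"]
    best = min(cand, key=lambda s: (abs(s - 1.0), s))
    return float(best), profile


def write_weight_file(path, snp_ids: np.ndarray, wv: SNPWeightVector) -> None:
    """Write a delimited weight file with columns SNP_ID, WEIGHT."""
    pd.DataFrame({"SNP_ID": snp_ids, "WEIGHT": wv.w}).to_csv(path, index=False)


def read_weight_file(path, snp_ids: np.ndarray) -> SNPWeightVector:
    """Read pre-specified per-SNP weights and align them to ``snp_ids``.

    Weights are renormalized to mean one (with the implied C recorded) so a
    file produced elsewhere can be used directly.
    """
    df = pd.read_csv(path)
    if not {"SNP_ID", "WEIGHT"}.issubset(df.columns):
        raise ValueError(f"{path}: weight file needs columns SNP_ID and WEIGHT")
    table = dict(zip(df["SNP_ID"].astype(str), df["WEIGHT"].astype(float)))
    missing = [s for s in snp_ids if str(s) not in table]
    if missing:
        raise ValueError(f"{len(missing)} SNP(s) absent from weight file: {missing[:5]}")
    raw = np.array([table[str(s)] for s in snp_ids])
    if (raw < 0).any():
        raise ValueError("weights must be non-negative")
    return _normalize(raw, "prespecified")
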