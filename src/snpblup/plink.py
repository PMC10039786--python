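"""PLINK binary genotype input/output and genotype standardization.

Genotypes are stored as counted-allele dosages in {0, 1, 2} with -1 for
missing, decoded from the PLINK 1.x variant-major .bed format (magic bytes
0x6C 0x1B, mode byte 0x01, two bits per genotype).  The counted allele is
PLINK's A1, so every downstream effect estimate has an explicit effect
allele.

Standardization centers each SNP column by its (training-set) mean after
mean-imputing missing calls and scales it either to unit sample variance
(default) or by sqrt(2p(1-p)); the stored means and scales are re-applied
to new individuals so that prediction never uses validation statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_BED_MAGIC = b"\x6c\x1b"


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam file violates the PLINK 1.x format."""


def _byte_tables() -> tuple[np.ndarray, np.ndarray]:
    # 2-bit codes, least-significant pair first:
    # 00 -> 2 copies of A1, 01 -> missing, 10 -> het, 11 -> 0 copies of A1
    code2dose = np.array([2, -1, 1, 0], dtype=np.int8)
    decode = np.empty((256, 4), dtype=np.int8)
    for byte in range(256):
        for k in range(4):
            decode[byte, k] = code2dose[(byte >> (2 * k)) & 0b11]
    return decode, code2dose


_DECODE_TABLE, _ = _byte_tables()


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with SNP and sample metadata.

    ``dosages`` is n x m, int8, counted-allele copies in {0, 1, 2} with
    -1 marking a missing call.  SNPs must be in genomic order
    (non-decreasing position within each contiguous chromosome block).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray  # counted allele
    a2: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        for name in ("snp_ids", "chrom", "a1", "a2", "sample_ids"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.dosages.shape
        # n = 1 is allowed so single individuals can be sliced out for prediction;
        # model fitting and standardization enforce n >= 2 themselves
        if n < 1 or m < 1:
            raise ValueError(f"need n >= 1 samples and m >= 1 SNPs, got n={n}, m={m}")
        valid = np.isin(self.dosages, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New GenotypeMatrix keeping the SNPs selected by ``index`` (mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            a1=self.a1[index],
            a2=self.a2[index],
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            a1=self.a1,
            a2=self.a2,
            sample_ids=self.sample_ids[index],
        )


@dataclass
class StandardizedGenotypes:
    """Centered and scaled genotypes plus the statistics needed to reproduce them.

    ``means`` and ``scales`` are the training-set column statistics; they are
    the only quantities ``standardize_like`` uses on new individuals.
    """

    Z: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    maf: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    sample_ids: np.ndarray
    scale_kind: str = "sample_sd"

    @property
    def m(self) -> int:
        return self.Z.shape[1]


def _check_genomic_order(chrom: np.ndarray, pos: np.ndarray) -> None:
    seen: set = set()
    prev = None
    prev_pos = None
    for c, p in zip(chrom, pos):
        if c != prev:
            if c in seen:
                raise PlinkFormatError(
                    f"SNPs of chromosome {c!r} are not contiguous; genomic order required"
                )
            seen.add(c)
            prev, prev_pos = c, p
        else:
            if p < prev_pos:
                raise PlinkFormatError(
                    f"positions not non-decreasing on chromosome {c!r} (at bp {p})"
                )
            prev_pos = p


def read_plink(prefix: str | Path, validate_order: bool = True) -> GenotypeMatrix:
    """Read a PLINK 1.x binary fileset ``prefix``.bed/.bim/.fam.

    The .bed file must be variant-major (mode byte 0x01).  A1 is recorded as
    the counted allele.  Raises FileNotFoundError for missing files and
    PlinkFormatError for bad magic bytes, sample-major mode or truncation.
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(f".{ext}") for ext in ("bed", "bim", "fam")}
    for ext, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing PLINK {ext} file: {path}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(paths["bim"], sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise PlinkFormatError(f"{paths['bim']} has {bim.shape[1]} columns, expected 6")
    n = len(fam)
    m = len(bim)

    raw = paths["bed"].read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{paths['bed']}: bad magic bytes, not a PLINK .bed file")
    if raw[2] != 0x01:
        raise PlinkFormatError(
            f"{paths['bed']}: mode byte 0x{raw[2]:02x}; only variant-major (0x01) is supported"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + m * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{paths['bed']}: expected {expected} bytes for {n} samples x {m} SNPs, got {len(raw)}"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    dosages = _DECODE_TABLE[body].reshape(m, bytes_per_snp * 4)[:, :n].T

    chrom = bim.iloc[:, 0].to_numpy(dtype=object)
    pos = bim.iloc[:, 3].astype(np.int64).to_numpy()
    if validate_order:
        _check_genomic_order(chrom, pos)
    return GenotypeMatrix(
        dosages=np.ascontiguousarray(dosages),
        snp_ids=bim.iloc[:, 1].to_numpy(dtype=object),
        chrom=chrom,
        pos=pos,
        a1=bim.iloc[:, 4].to_numpy(dtype=object),
        a2=bim.iloc[:, 5].to_numpy(dtype=object),
        sample_ids=fam.iloc[:, 1].to_numpy(dtype=object),
    )


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a PLINK 1.x variant-major .bed/.bim/.fam fileset (bit-exact dialect)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.dosages.shape
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    # inverse of the decode table: dose 0 -> code 3, 1 -> 2, 2 -> 0, missing -> 1
    lut = np.array([3, 2, 0], dtype=np.uint8)
    d = g.dosages.T
    enc = np.where(d < 0, np.uint8(1), lut[np.clip(d, 0, 2)])
    codes[:, :n] = enc
    codes[:, n:] = 0
    shifted = codes.reshape(m, bytes_per_snp, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = shifted[..., 0] | shifted[..., 1] | shifted[..., 2] | shifted[..., 3]
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.astype(np.uint8).tobytes())
    bim = pd.DataFrame(
        {
            0: g.chrom,
            1: g.snp_ids,
            2: 0,
            3: g.pos,
            4: g.a1,
            5: g.a2,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {0: g.sample_ids, 1: g.sample_ids, 2: 0, 3: 0, 4: 0, 5: -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def compute_maf(g: GenotypeMatrix, samples: np.ndarray | None = None) -> np.ndarray:
    """Minor allele frequencies per SNP over the given sample subset.

    Frequencies are computed over non-missing calls only and folded:
    maf = min(freq, 1 - freq) where freq is the counted-allele frequency.
    A SNP with zero non-missing calls gets NaN with a warning.
    """
    d = g.dosages if samples is None else g.dosages[np.asarray(samples)]
    if d.shape[0] == 0:
        raise ValueError("sample subset is empty")
    miss = d == MISSING
    n_obs = (~miss).sum(axis=0)
    total = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = total / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    if (n_obs == 0).any():
        bad = g.snp_ids[n_obs == 0]
        warnings.warn(f"{len(bad)} SNP(s) with no non-missing calls (e.g. {bad[0]}); maf set to NaN")
        maf = np.where(n_obs == 0, np.nan, maf)
    return maf


def filter_snps(
    g: GenotypeMatrix, samples: np.ndarray | None = None, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop SNPs with maf below ``min_maf`` (or undefined maf); returns (subset, kept mask)."""
    maf = compute_maf(g, samples)
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    if not keep.any():
        raise ValueError(f"no SNP passes the MAF filter (min_maf={min_maf})")
    return g.subset_snps(keep), keep


def standardize(
    g: GenotypeMatrix,
    samples: np.ndarray | None = None,
    scale_kind: str = "sample_sd",
) -> StandardizedGenotypes:
    """Center and scale the genotypes of the training subset ``samples``.

    Missing dosages are mean-imputed per SNP before centering.  ``scale_kind``
    is "sample_sd" (unit sample variance, the default) or "expected_hw"
    (sqrt(2p(1-p)) with p the counted-allele frequency).  Zero-variance
    columns raise, naming the SNP: they should have been MAF-filtered.
    """
    idx = np.arange(g.n) if samples is None else np.asarray(samples)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size < 2:
        raise ValueError("standardization needs at least 2 training individuals")
    d = g.dosages[idx].astype(np.float64)
    miss = d < 0
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = g.snp_ids[n_obs == 0][0]
        raise ValueError(f"SNP {bad} has no non-missing calls in the training subset")
    d[miss] = 0.0
    means = d.sum(axis=0) / n_obs
    d[miss] = np.broadcast_to(means, d.shape)[miss]
    centered = d - means
    if scale_kind == "sample_sd":
        scales = centered.std(axis=0, ddof=1)
    elif scale_kind == "expected_hw":
        freq = means / 2.0
        scales = np.sqrt(2.0 * freq * (1.0 - freq))
    else:
        raise ValueError(f"unknown scale_kind {scale_kind!r}")
    zero = scales <= 0
    if zero.any():
        raise ValueError(
            f"SNP {g.snp_ids[zero][0]} has zero variance after imputation; apply the MAF filter first"
        )
    freq = means / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return StandardizedGenotypes(
        Z=centered / scales,
        means=means,
        scales=scales,
        maf=maf,
        snp_ids=g.snp_ids,
        chrom=g.chrom,
        pos=g.pos,
        a1=g.a1,
        a2=g.a2,
        sample_ids=g.sample_ids[idx],
        scale_kind=scale_kind,
    )


def standardize_like(g_new: GenotypeMatrix, ref: StandardizedGenotypes) -> np.ndarray:
    """Standardize new individuals with the TRAINING means and scales of ``ref``.

    SNPs are matched by ID and counted allele; any missing SNP or flipped
    allele coding is an error (listing the offending SNPs).  Missing calls
    are imputed with the training means.
    """
    order = {sid: j for j, sid in enumerate(g_new.snp_ids)}
    missing = [sid for sid in ref.snp_ids if sid not in order]
    if missing:
        raise ValueError(f"{len(missing)} reference SNP(s) absent from new genotypes: {missing[:5]}")
    cols = np.array([order[sid] for sid in ref.snp_ids])
    flipped = g_new.a1[cols] != ref.a1
    if flipped.any():
        raise ValueError(
            "counted-allele mismatch for SNP(s): " + ", ".join(map(str, ref.snp_ids[flipped][:5]))
        )
    d = g_new.dosages[:, cols].astype(np.float64)
    miss = d < 0
    d[miss] = np.broadcast_to(ref.means, d.shape)[miss]
    return (d - ref.means) / ref.scales
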