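"""Fourth-order joint cumulant (cokurtosis) machinery.

This module is the mathematical heart of the detector: standardization,
the cokurtosis joint cumulant tensor, its HOSVD factorization, the
feature moment metric (FMM) that turns the spectrum into a discrete
distribution over features, and the Hellinger divergence used to compare
two such distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DataError,
    DegenerateFeatureError,
    DegenerateSpectrumError,
    DistributionError,
    WindowTooShortError,
)

__all__ = [
    "DataMatrix",
    "StandardizedMatrix",
    "CokurtosisTensor",
    "SpectralFactors",
    "FMMVector",
    "standardize",
    "cokurtosis_tensor",
    "hosvd_factors",
    "feature_moment_metric",
    "hellinger_distance",
    "derive_features",
    "fmm_of",
]


@dataclass
class DataMatrix:
    """An n-observations x m-features real matrix with feature labels."""

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise DataError("feature_names length does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored matrix with the original means/sds retained."""

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def inverse(self) -> np.ndarray:
        """Map the standardized values back to original units."""
        return self.values * self.sds + self.means


@dataclass
class CokurtosisTensor:
    """Fully symmetric fourth-order cumulant tensor (m x m x m x m)."""

    entries: np.ndarray

    @property
    def m(self) -> int:
        return self.entries.shape[0]


@dataclass
class SpectralFactors:
    """Singular value/vector pairs from the HOSVD of a cokurtosis tensor.

    ``singular_values`` is nonnegative and sorted descending;
    ``singular_vectors`` has orthonormal columns, one per singular value.
    """

    singular_values: np.ndarray
    singular_vectors: np.ndarray


@dataclass
class FMMVector:
    """Feature moment metric: each feature's fraction of total kurtosis.

    Nonnegative, sums to one — a discrete distribution over features.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def standardize(X: DataMatrix | np.ndarray) -> StandardizedMatrix:
    """Z-score each column using the population-sd convention (ddof=0).

    Raises
    ------
    DegenerateFeatureError
        If any column has zero sample standard deviation; the message
        names the offending column.
    """
    if isinstance(X, DataMatrix):
        values, names = X.values, X.feature_names
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
    if not np.all(np.isfinite(values)):
        raise DataError("input matrix contains non-finite values")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=0)
    bad = np.flatnonzero(sds <= 0.0)
    if bad.size:
        raise DegenerateFeatureError(
            f"zero-variance feature column(s): {[names[i] for i in bad]}"
        )
    return StandardizedMatrix(values=(values - means) / sds, means=means, sds=sds)


def cokurtosis_tensor(Z: StandardizedMatrix | np.ndarray) -> CokurtosisTensor:
    """Cokurtosis joint cumulant tensor of a standardized matrix.

    T[i,j,k,l] = E[x_i x_j x_k x_l] - E[x_i x_j] E[x_k x_l]
                 - E[x_i x_k] E[x_j x_l] - E[x_i x_l] E[x_j x_k]

    with E the sample expectation over rows.  The subtracted pair terms
    remove the Gaussian combinatorial contribution, so i.i.d. Gaussian
    data yields a tensor of zeros (up to sampling noise), and the
    diagonal T[i,i,i,i] is the sample excess kurtosis of feature i.
    """
    values = Z.values if isinstance(Z, StandardizedMatrix) else np.asarray(Z, float)
    if not np.all(np.isfinite(values)):
        raise DataError("standardized matrix contains non-finite values")
    n, m = values.shape
    # pairwise products row-by-row, then one BLAS matmul for the 4th moment
    B = (values[:, :, None] * values[:, None, :]).reshape(n, m * m)
    M4 = (B.T @ B / n).reshape(m, m, m, m)
    C = values.T @ values / n
    CC = np.multiply.outer(C, C)  # CC[i,j,k,l] = C[i,j] * C[k,l]
    T = M4 - CC - CC.transpose(0, 2, 1, 3) - CC.transpose(0, 2, 3, 1)
    return CokurtosisTensor(entries=T)


def hosvd_factors(T: CokurtosisTensor | np.ndarray) -> SpectralFactors:
    """HOSVD of a fully symmetric fourth-order tensor.

    Because the tensor is invariant under index permutation, all mode
    unfoldings coincide, so the SVD of the mode-1 unfolding (m x m^3)
    supplies the full set of singular value/vector pairs.  Singular
    vector signs are fixed so the largest-magnitude entry of each
    column is positive.
    """
    entries = T.entries if isinstance(T, CokurtosisTensor) else np.asarray(T, float)
    m = entries.shape[0]
    unfolding = entries.reshape(m, m**3)
    try:
        U, s, _ = np.linalg.svd(unfolding, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical edge
        raise DataError(
            f"SVD failed on unfolded tensor (norm={np.linalg.norm(unfolding):g})"
        ) from exc
    # deterministic sign: largest-|entry| of each singular vector positive
    for k in range(m):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return SpectralFactors(singular_values=s, singular_vectors=U)


def feature_moment_metric(S: SpectralFactors) -> FMMVector:
    """Feature moment metric from the HOSVD spectrum.

    F_i = sum_k lambda_k (e_i . v_k)^2 / sum_k lambda_k

    i.e. the kurtosis fraction attributable to each feature.  Entries
    lie in [0, 1] and sum to one because the singular vectors are
    orthonormal.
    """
    lam = np.asarray(S.singular_values, dtype=float)
    V = np.asarray(S.singular_vectors, dtype=float)
    total = lam.sum()
    if total <= 0.0:
        raise DegenerateSpectrumError("all singular values are zero; no kurtosis signal")
    F = (V**2) @ lam / total
    return FMMVector(values=F)


def hellinger_distance(
    p: FMMVector | np.ndarray, q: FMMVector | np.ndarray, form: str = "sqrt"
) -> float:
    """Hellinger distance between two discrete distributions.

    The default square-root form, H = (1/sqrt(2)) * ||sqrt(p) - sqrt(q)||_2,
    is symmetric, zero iff p == q, and bounded by 1.  ``form="l2"``
    selects the plain (1/sqrt(2)) * ||p - q||_2 variant instead.
    """
    pv = np.asarray(p.values if isinstance(p, FMMVector) else p, dtype=float)
    qv = np.asarray(q.values if isinstance(q, FMMVector) else q, dtype=float)
    if pv.shape != qv.shape:
        raise DistributionError(f"length mismatch: {pv.shape} vs {qv.shape}")
    if np.any(pv < 0) or np.any(qv < 0):
        raise DistributionError("distributions must be nonnegative")
    if form == "sqrt":
        return float(np.linalg.norm(np.sqrt(pv) - np.sqrt(qv)) / np.sqrt(2.0))
    if form == "l2":
        return float(np.linalg.norm(pv - qv) / np.sqrt(2.0))
    raise DistributionError(f"unknown Hellinger form {form!r}")


_STAT_FUNCS = {
    "mean": np.mean,
    "median": np.median,
    "min": np.min,
    "max": np.max,
    "std": np.std,
}


def derive_features(
    x: np.ndarray,
    block: int = 4,
    stats: tuple[str, ...] = ("mean", "median", "min", "max"),
) -> DataMatrix:
    """Expand a univariate sample into a multivariate descriptive matrix.

    The sample is split into consecutive sub-blocks of length ``block``
    (a trailing partial block is dropped) and each block is summarized
    by the requested descriptive statistics, producing one row per
    block.  This makes the cokurtosis method usable on single-vital
    streams.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < block:
        raise WindowTooShortError(
            f"sample of length {x.size} shorter than sub-block size {block}"
        )
    unknown = [s for s in stats if s not in _STAT_FUNCS]
    if unknown:
        raise DataError(f"unknown derived statistics: {unknown}")
    n_blocks = x.size // block
    blocks = x[: n_blocks * block].reshape(n_blocks, block)
    cols = [_STAT_FUNCS[s](blocks, axis=1) for s in stats]
    return DataMatrix(values=np.column_stack(cols), feature_names=list(stats))


def fmm_of(data: np.ndarray) -> FMMVector:
    """Convenience pipeline: standardize -> cokurtosis -> HOSVD -> FMM."""
    return feature_moment_metric(hosvd_factors(cokurtosis_tensor(standardize(data))))
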