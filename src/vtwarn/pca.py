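"""Tachogram PCA with Gavish-Donoho optimal hard thresholding.

Training windows (m intervals each) form the columns of an m x n matrix. The
mean column profile is subtracted from every column and each column is scaled
to unit variance; the reduced SVD R = U S V^T then yields principal
components (columns of U), and the retained rank k is the number of singular
values above the optimal hard threshold

    tau* = omega(beta) * median(singular values),   beta = n/m,

with the cubic approximation omega(beta) = 0.56 b^3 - 0.95 b^2 + 1.82 b + 1.43
appropriate when the noise level is unknown. New records are standardized
with the training mean profile and their own standard deviation, then
projected onto the retained components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import RRValidationError

__all__ = [
    "AssembledMatrix",
    "DecompositionResult",
    "GDThreshold",
    "assemble_matrix",
    "gavish_donoho_omega",
    "fit_decomposition",
    "fit_windows",
    "project_record",
    "save_decomposition",
    "load_decomposition",
]

_ORTHONORMAL_TOL = 1e-8


@dataclass
class AssembledMatrix:
    """Standardized m x n tachogram matrix plus the statistics that built it."""

    matrix: np.ndarray  # m x n, unit-variance columns
    mean_profile: np.ndarray  # length m
    column_scales: np.ndarray  # length n (per-column SD after centering)


@dataclass
class GDThreshold:
    beta: float
    omega: float
    median_sv: float

    @property
    def tau_star(self) -> float:
        return self.omega * self.median_sv


@dataclass
class DecompositionResult:
    """Fitted PCA state: mean profile, singular triplets and the retained rank."""

    m: int
    mean_profile: np.ndarray
    left_vectors: np.ndarray  # m x r
    singular_values: np.ndarray  # length r, non-increasing
    right_vectors: np.ndarray  # n x r
    k: int
    threshold: GDThreshold

    def __post_init__(self) -> None:
        r = self.singular_values.size
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise RRValidationError("singular values must be non-increasing")
        if not 1 <= self.k <= r:
            raise RRValidationError(f"retained rank k={self.k} outside [1, {r}]")

    @property
    def components(self) -> np.ndarray:
        """The k retained principal components (columns of U)."""
        return self.left_vectors[:, : self.k]


def assemble_matrix(windows: np.ndarray | list) -> AssembledMatrix:
    """Stack windows as columns, subtract the mean profile, scale columns to unit variance.

    *windows* is an iterable of n equal-length (m) interval sequences, or an
    (n, m) array with one window per row. The mean of all columns (the average
    tachogram across recordings) is subtracted from each column, and each
    column is then divided by its own population standard deviation.
    """
    W = np.asarray(windows, dtype=float)
    if W.ndim != 2 or W.shape[0] < 1:
        raise RRValidationError("assemble_matrix: need a non-empty set of equal-length windows")
    X = W.T  # m x n
    mean_profile = X.mean(axis=1)
    Xc = X - mean_profile[:, None]
    scales = Xc.std(axis=0)
    # relative floor: centering identical columns leaves O(eps) residue, not 0
    degenerate = np.flatnonzero(scales <= 1e-10 * (np.abs(X).max() + 1e-30))
    if degenerate.size:
        raise RRValidationError(
            f"assemble_matrix: zero-variance column(s) after centering at index {degenerate.tolist()}"
        )
    return AssembledMatrix(matrix=Xc / scales, mean_profile=mean_profile, column_scales=scales)


def gavish_donoho_omega(beta: float) -> float:
    """omega(beta) = 0.56 b^3 - 0.95 b^2 + 1.82 b + 1.43 for aspect ratio beta = n/m."""
    if not 0.0 < beta <= 1.0:
        raise RRValidationError(f"aspect ratio beta={beta} outside (0, 1]")
    return ((0.56 * beta - 0.95) * beta + 1.82) * beta + 1.43


def _orient_components(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the SVD sign ambiguity: each PC is oriented so that its projection
    onto an increasing beat-index ramp is positive (a positive first-PC
    coefficient then means the N-N interval lengthens over the window); a PC
    orthogonal to the ramp falls back to making its largest-|entry| positive."""
    m = U.shape[0]
    ramp = np.arange(m, dtype=float)
    ramp -= ramp.mean()
    ramp /= np.linalg.norm(ramp)
    dots = U.T @ ramp
    signs = np.sign(dots)
    weak = np.abs(dots) < 1e-6
    if np.any(weak):
        peak = U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])]
        signs[weak] = np.sign(peak[weak])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def fit_decomposition(
    matrix: AssembledMatrix | np.ndarray, mean_profile: np.ndarray | None = None
) -> DecompositionResult:
    """Reduced SVD of the standardized matrix plus Gavish-Donoho rank selection.

    k counts the singular values strictly above tau* = omega(n/m) * median(sv),
    floored at 1 so downstream feature rows are always well-formed.
    """
    if isinstance(matrix, AssembledMatrix):
        X = matrix.matrix
        mean_profile = matrix.mean_profile
    else:
        X = np.asarray(matrix, dtype=float)
        if mean_profile is None:
            mean_profile = np.zeros(X.shape[0])
    if X.ndim != 2 or X.shape[1] < 2:
        raise RRValidationError("fit_decomposition: need an m x n matrix with n >= 2")
    if not np.isfinite(X).all():
        raise RRValidationError("fit_decomposition: matrix contains non-finite entries")
    m, n = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)  # LinAlgError surfaces as-is
    U, V = _orient_components(U, Vt.T)
    beta = min(n, m) / max(n, m)
    thr = GDThreshold(
        beta=beta, omega=gavish_donoho_omega(beta), median_sv=float(np.median(s))
    )
    k = max(1, int(np.count_nonzero(s > thr.tau_star)))
    return DecompositionResult(
        m=m,
        mean_profile=np.asarray(mean_profile, dtype=float),
        left_vectors=U,
        singular_values=s,
        right_vectors=V,
        k=k,
        threshold=thr,
    )


def fit_windows(windows: np.ndarray | list) -> DecompositionResult:
    """Convenience: :func:`assemble_matrix` followed by :func:`fit_decomposition`."""
    return fit_decomposition(assemble_matrix(windows))


def project_record(decomp: DecompositionResult, window: np.ndarray) -> np.ndarray:
    """Coefficients of one window on the k retained PCs.

    The window is standardized exactly as a training column would be: the
    training mean profile is subtracted and the residual is divided by its own
    population standard deviation; the coefficients are U[:, :k]^T x.
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (decomp.m,):
        raise RRValidationError(
            f"project_record: window length {w.size} != decomposition m={decomp.m}"
        )
    x = w - decomp.mean_profile
    scale = x.std()
    if scale <= 0:
        raise RRValidationError("project_record: degenerate window (zero variance)")
    return decomp.components.T @ (x / scale)


_ARCHIVE_VERSION = 1


def save_decomposition(decomp: DecompositionResult, path: str | Path) -> None:
    """Persist mean profile, retained components, singular values, k and tau*."""
    np.savez(
        Path(path),
        version=_ARCHIVE_VERSION,
        m=decomp.m,
        mean_profile=decomp.mean_profile,
        left_vectors=decomp.left_vectors[:, : decomp.k],
        singular_values=decomp.singular_values,
        k=decomp.k,
        beta=decomp.threshold.beta,
        omega=decomp.threshold.omega,
        median_sv=decomp.threshold.median_sv,
    )


def load_decomposition(path: str | Path) -> DecompositionResult:
    with np.load(Path(path)) as z:
        if int(z["version"]) != _ARCHIVE_VERSION:
            raise RRValidationError(f"unsupported decomposition archive version {z['version']}")
        k = int(z["k"])
        U = z["left_vectors"]
        return DecompositionResult(
            m=int(z["m"]),
            mean_profile=z["mean_profile"],
            left_vectors=U,
            singular_values=z["singular_values"][: U.shape[1]],
            right_vectors=np.zeros((0, U.shape[1])),
            k=k,
            threshold=GDThreshold(
                beta=float(z["beta"]), omega=float(z["omega"]), median_sv=float(z["median_sv"])
            ),
        )
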