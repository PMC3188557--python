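"""Multivariate patterns of shape fluctuating asymmetry.

The FA pattern of a group is the covariance matrix of the individual-by-side
effect of the Procrustes sides model, corrected for measurement error — the
matrix analogue of FA10. With per-individual replicate-averaged side
differences d_i (right minus left, in shape-score space) and per-individual
error cross-products E_i:

    FA = Cov(d_i) / 2  -  (sum_i E_i / (2 n (M-1))) / M

Its first principal component is the dominant direction of shape FA; the
similarity of two groups' dominant directions is the angle between their
PC1s, tested against two nulls:

* random-vector null — angles between pairs of isotropic random vectors of
  the same dimension (small p: more similar than chance);
* bootstrap null — angles between FA PC1s recomputed from independent
  within-group resamples of individuals (sampling error only; large p: the
  two directions are as close as identical vectors would appear).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .asymmetry import InsufficientDataError, holm_adjust, procrustes_sides_table
from .procrustes import ProcrustesFit, ShapeSpace


@dataclass
class FAPatternMatrix:
    """Measurement-error-corrected covariance matrix of shape FA for one group."""

    matrix: np.ndarray  # (d, d) symmetric
    eigenvalues: np.ndarray  # descending, raw (may contain negatives)
    eigenvectors: np.ndarray  # (d, n_eig) columns, unit norm
    source: str = ""
    m_replicates: int = 1
    n_individuals: int = 0
    me_corrected: bool = True
    # per-individual ingredients, kept for bootstrap resampling
    side_differences: np.ndarray | None = None  # (n, d)
    error_sscp: np.ndarray | None = None  # (n, d, d) or None when M == 1

    @property
    def d(self) -> int:
        return self.matrix.shape[0]

    @property
    def pc1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))

    def clipped_eigenvalues(self) -> np.ndarray:
        """Spectrum with negative (ME-overcorrected) eigenvalues set to zero."""
        return np.clip(self.eigenvalues, 0.0, None)


def _eigh_desc(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):  # sign convention: largest |coef| positive
        col = vecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, j] = -col
    return vals, vecs


def _fa_matrix_from_components(
    diffs: np.ndarray, error_sscp: np.ndarray | None, m: int
) -> np.ndarray:
    n = diffs.shape[0]
    dev = diffs - diffs.mean(axis=0)
    cov = dev.T @ dev / (n - 1)
    fa = cov / 2.0
    if error_sscp is not None and m >= 2:
        mscp_err = error_sscp.sum(axis=0) / (2 * n * (m - 1))
        fa = fa - mscp_err / m
    return fa


def fa_matrix_from_differences(
    diffs: np.ndarray,
    error_sscp: np.ndarray | None = None,
    m: int = 1,
    source: str = "",
) -> FAPatternMatrix:
    """Build an FA pattern matrix directly from per-individual components.

    ``diffs`` are replicate-averaged R-L difference vectors (n, d) in any
    common shape space; ``error_sscp`` the per-individual error
    cross-products (n, d, d) when M >= 2. The entry point for data that is
    already superimposed or for score-space simulations.
    """
    diffs = np.asarray(diffs, float)
    if diffs.shape[0] < 3:
        raise InsufficientDataError("FA matrix needs at least 3 individuals")
    matrix = _fa_matrix_from_components(diffs, error_sscp, m)
    matrix = (matrix + matrix.T) / 2.0
    vals, vecs = _eigh_desc(matrix)
    return FAPatternMatrix(
        matrix=matrix,
        eigenvalues=vals,
        eigenvectors=vecs,
        source=source,
        m_replicates=m,
        n_individuals=diffs.shape[0],
        me_corrected=error_sscp is not None and m >= 2,
        side_differences=diffs,
        error_sscp=error_sscp,
    )


def fa_components(
    fit: ProcrustesFit, shape_space: ShapeSpace
) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Per-individual side differences and error cross-products in score space.

    Returns (diffs, error_sscp, M): replicate-averaged R-L difference vectors
    (n, d), per-individual error SSCP matrices (n, d, d) when M >= 2, and the
    replicate count.
    """
    arr, _, m = procrustes_sides_table(fit)  # (n, 2, M, 2k), sides (L, R)
    scores = np.einsum("nsmc,dc->nsmd", arr, shape_space.loadings)
    cell_means = scores.mean(axis=2)  # (n, 2, d)
    diffs = cell_means[:, 1] - cell_means[:, 0]  # R - L
    error_sscp = None
    if m >= 2:
        resid = scores - cell_means[:, :, None]  # (n, 2, M, d)
        error_sscp = np.einsum("nsmd,nsme->nde", resid, resid)
    return diffs, error_sscp, m


def fa_covariance_matrix(
    fit: ProcrustesFit, shape_space: ShapeSpace, source: str = ""
) -> FAPatternMatrix:
    """ME-corrected covariance matrix of the individual-by-side effect.

    The matrix analogue of FA10: interaction mean cross-products minus error
    mean cross-products, divided by M. With a single measurement session
    (M = 1) no ME correction is possible; the raw DA-centered difference
    covariance (halved) is returned and flagged ``me_corrected=False``.
    Its trace equals the shape dimension times the Procrustes-ANOVA FA10.
    """
    diffs, error_sscp, m = fa_components(fit, shape_space)
    if m == 1:
        warnings.warn(
            "M=1: FA matrix not corrected for measurement error", stacklevel=2
        )
    return fa_matrix_from_differences(diffs, error_sscp, m, source=source)


@dataclass
class FASpectrum:
    eigenvalues: np.ndarray  # raw, descending
    clipped: np.ndarray  # negatives set to 0
    variance_shares: np.ndarray  # from clipped spectrum
    pc1: np.ndarray  # (d,)
    pc1_displacement: np.ndarray | None  # (k, 2) landmark displacement field
    n_negative: int


def fa_pca(
    fam: FAPatternMatrix, shape_space: ShapeSpace | None = None
) -> FASpectrum:
    """Eigen-decomposition of an FA pattern matrix.

    The eigenvalue distribution shows whether shape FA concentrates along one
    direction or spreads over many; PC1 mapped through the shape-space
    loadings gives the landmark displacement field of the dominant FA
    pattern. Negative eigenvalues (ME over-correction) are clipped to zero
    for variance shares only; the raw spectrum is retained.
    """
    asym = np.abs(fam.matrix - fam.matrix.T).max()
    if asym > 1e-8 * max(1.0, np.abs(fam.matrix).max()):
        raise ValueError(f"matrix is not symmetric (max deviation {asym:.3e})")
    vals, vecs = _eigh_desc(fam.matrix)
    clipped = np.clip(vals, 0.0, None)
    total = clipped.sum()
    shares = clipped / total if total > 0 else np.zeros_like(clipped)
    disp = None
    if shape_space is not None:
        flatfield = vecs[:, 0] @ shape_space.loadings  # (2k,)
        k = flatfield.size // 2
        disp = np.column_stack([flatfield[:k], flatfield[k:]])
    return FASpectrum(
        eigenvalues=vals,
        clipped=clipped,
        variance_shares=shares,
        pc1=vecs[:, 0],
        pc1_displacement=disp,
        n_negative=int((vals < 0).sum()),
    )


def vector_angle(v1, v2) -> float:
    """Angle between two directions in degrees, in [0, 90].

    Uses the absolute cosine: principal-component signs are arbitrary, so v
    and -v are the same direction.
    """
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    c = abs(float(v1 @ v2)) / (n1 * n2)
    return float(np.degrees(np.arccos(min(1.0, c))))


@dataclass
class AngleTest:
    """Angle between two FA PC1s with its two null-hypothesis p-values."""

    angle: float  # degrees in [0, 90]
    p_random: float | None = None
    p_bootstrap: float | None = None
    n_draws: int = 0
    n_boot: int = 0
    seed: int | None = None
    null_random: np.ndarray | None = field(default=None, repr=False)
    null_bootstrap: np.ndarray | None = field(default=None, repr=False)


def random_angles(dim: int, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Angles (degrees) between pairs of independent isotropic random vectors."""
    a = rng.standard_normal((n_draws, dim))
    b = rng.standard_normal((n_draws, dim))
    cos = np.abs(np.einsum("ij,ij->i", a, b)) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))


def random_vector_null(
    observed_angle: float,
    dim: int,
    n_draws: int = 10_000,
    seed: int | None = None,
    literal_formula: bool = False,
) -> AngleTest:
    """Test an observed angle against pairs of random direction vectors.

    Small p: the two FA directions are more similar than unrelated random
    directions of the same dimensionality would be. p = (count of null
    angles <= observed) / n_draws. ``literal_formula`` switches to the
    as-published variant [1 - (count of null angles > observed)] / n_draws.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if seed is None:
        raise ValueError("seed is required for the resampling nulls")
    rng = np.random.default_rng(seed)
    null = random_angles(dim, n_draws, rng)
    if literal_formula:
        p = (1.0 - float(np.sum(null > observed_angle))) / n_draws
    else:
        p = float(np.sum(null <= observed_angle)) / n_draws
    return AngleTest(
        angle=float(observed_angle),
        p_random=p,
        n_draws=n_draws,
        seed=seed,
        null_random=null,
    )


def bootstrap_angles(
    fam: FAPatternMatrix,
    n_boot: int,
    rng: np.random.Generator,
    paired_resamples: bool = True,
) -> np.ndarray:
    """Null angles from within-group resampling of individuals.

    Each iteration draws individuals with replacement, recomputes the FA
    matrix and its PC1 in the fixed tangent space, and records the angle
    either between two independent resamples (default — both vectors carry
    sampling error, matching the 'identical vectors + sampling error' null)
    or between one resample and the original PC1.
    """
    diffs = fam.side_differences
    if diffs is None:
        raise ValueError("FA matrix carries no per-individual components")
    n = diffs.shape[0]
    if n < 10:
        raise InsufficientDataError("bootstrap needs >= 10 individuals")
    angles = np.empty(n_boot)
    skipped = 0
    for b in range(n_boot):
        vecs = []
        for _ in range(2 if paired_resamples else 1):
            idx = rng.integers(0, n, size=n)
            e = fam.error_sscp[idx] if fam.error_sscp is not None else None
            mat = _fa_matrix_from_components(diffs[idx], e, fam.m_replicates)
            if not np.all(np.isfinite(mat)):
                vecs = None
                break
            vals, v = _eigh_desc(mat)
            if vals[0] <= 0:
                vecs = None
                break
            vecs.append(v[:, 0])
        if vecs is None:
            skipped += 1
            angles[b] = np.nan
            continue
        other = vecs[1] if paired_resamples else fam.pc1
        angles[b] = vector_angle(vecs[0], other)
    if skipped:
        if skipped > 0.01 * n_boot:
            warnings.warn(
                f"{skipped}/{n_boot} bootstrap iterations degenerate", stacklevel=2
            )
        angles = angles[~np.isnan(angles)]
    return angles


def bootstrap_angle_null(
    fam_a: FAPatternMatrix,
    observed_angle: float | None = None,
    fam_b: FAPatternMatrix | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    paired_resamples: bool = True,
) -> AngleTest:
    """Test an observed angle against the within-group sampling-error null.

    The null sample pools bootstrap angles from each supplied group (one or
    two). p = (count of null angles >= observed) / total. A non-significant
    p means the two FA directions are as strongly correlated as estimates of
    one identical direction would be.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("seed is required for the resampling nulls")
    if observed_angle is None:
        if fam_b is None:
            raise ValueError("need an observed angle or a second FA matrix")
        observed_angle = vector_angle(fam_a.pc1, fam_b.pc1)
    rng = np.random.default_rng(seed)
    per = n_boot if fam_b is None else (n_boot + 1) // 2
    null = bootstrap_angles(fam_a, per, rng, paired_resamples)
    if fam_b is not None:
        null = np.concatenate(
            [null, bootstrap_angles(fam_b, per, rng, paired_resamples)]
        )
    p = float(np.sum(null >= observed_angle)) / len(null)
    return AngleTest(
        angle=float(observed_angle),
        p_bootstrap=p,
        n_boot=len(null),
        seed=seed,
        null_bootstrap=null,
    )


def compare_fa_patterns(
    matrices: list[FAPatternMatrix],
    n_draws: int = 10_000,
    n_boot: int = 10_000,
    seed: int | None = None,
    paired_resamples: bool = True,
) -> pd.DataFrame:
    """All pairwise PC1-angle comparisons among group FA matrices.

    One row per unordered pair with the angle, both null p-values and their
    Holm adjustments across the pairwise family.
    """
    if seed is None:
        raise ValueError("seed is required for the resampling nulls")
    dims = {fam.d for fam in matrices}
    if len(dims) > 1:
        raise ValueError(f"FA matrices have mixed dimensions: {sorted(dims)}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            a, b = matrices[i], matrices[j]
            angle = vector_angle(a.pc1, b.pc1)
            rand = random_vector_null(
                angle, a.d, n_draws=n_draws, seed=int(rng.integers(2**31))
            )
            boot = bootstrap_angle_null(
                a,
                observed_angle=angle,
                fam_b=b,
                n_boot=n_boot,
                seed=int(rng.integers(2**31)),
                paired_resamples=paired_resamples,
            )
            rows.append(
                {
                    "a": a.source or f"group{i}",
                    "b": b.source or f"group{j}",
                    "angle_deg": angle,
                    "p_random": rand.p_random,
                    "p_bootstrap": boot.p_bootstrap,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_random_holm"] = holm_adjust(table["p_random"].to_numpy())
        table["p_bootstrap_holm"] = holm_adjust(table["p_bootstrap"].to_numpy())
    return table
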