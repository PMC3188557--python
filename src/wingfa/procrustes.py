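"""Size and shape extraction from landmark configurations.

Implements centroid size, ordinary and generalized Procrustes superimposition
(GPA) with reflection of one body side so left and right configurations are
comparable, tangent-space principal components, multivariate allometry
correction, and canonical variate analysis (CVA) of group differences.

Conventions
-----------
* GPA scales every configuration to unit centroid size, aligns by
  least-squares rotation to an iteratively updated consensus (tolerance 1e-10
  on the consensus change, at most 100 iterations), and orthogonally projects
  the result onto the tangent space at the consensus.
* For k 2D landmarks the tangent space has dimension 2k - 4 (translation 2,
  rotation 1, scale 1 removed); with the 15 wing landmarks this is the
  26-dimensional shape space in which all downstream statistics run.
* Principal-component signs are oriented so each loading's largest-magnitude
  coefficient is positive, making outputs reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration, LandmarkDataset, SpecimenRecord

GPA_TOL = 1e-10
GPA_MAX_ITER = 1000  # diffuse shape scatter contracts slowly; iterations are cheap
EIG_ZERO_REL = 1e-10  # eigenvalues below max_eig * this are numerical zeros


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide; the configuration has no shape."""


class ConvergenceError(RuntimeError):
    pass


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    The standard geometric-morphometric size measure; its log is the size
    variable used in all downstream size analyses.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide (centroid size 0)")
    return cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal matrix R minimizing ||x @ R - target||_F (det +1 unless allowed)."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def align_pair(
    target: LandmarkConfiguration | np.ndarray,
    reference: LandmarkConfiguration | np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes fit of ``target`` onto ``reference``.

    Translates, scales and rotates (optionally reflects, when that lowers the
    residual — left and right wings are mirror images, so pairing sides needs
    it) the target to the best least-squares fit. Returns the fitted
    coordinates and the residual distance.
    """
    x = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target, float)
    y = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    if x.shape != y.shape:
        raise ValueError(f"landmark count mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if not (xc.any() and yc.any()):
        raise DegenerateConfigurationError("degenerate configuration")
    r = _optimal_rotation(xc, yc, allow_reflection=allow_reflection)
    xr = xc @ r
    beta = float((xr * yc).sum() / (xr * xr).sum())
    fitted = beta * xr + y.mean(axis=0)
    distance = float(np.linalg.norm(fitted - y))
    return fitted, distance


def reflect(coords: np.ndarray) -> np.ndarray:
    """Mirror a configuration about the vertical axis (x -> -x)."""
    out = np.array(coords, dtype=float, copy=True)
    out[..., 0] *= -1
    return out


def frame_rotation(consensus: np.ndarray, template: np.ndarray) -> np.ndarray:
    """2x2 rotation taking the GPA consensus frame into a template's frame.

    GPA fixes orientation only up to an arbitrary rotation; to compare a
    recovered shape direction with one defined on a template (e.g. a
    generator's ground-truth FA direction), rotate it by this matrix:
    ``field_in_template_frame = field @ frame_rotation(consensus, template)``.
    """
    c = np.asarray(consensus, float)
    t = np.asarray(template, float)
    c = c - c.mean(axis=0)
    t = t - t.mean(axis=0)
    return _optimal_rotation(c, t)


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition.

    ``aligned`` are unit-centroid-size, tangent-projected coordinates; the
    consensus has unit centroid size; ``centroid_sizes`` were recorded before
    scaling, on the original coordinate scale.
    """

    consensus: np.ndarray  # (k, 2)
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    records: list[SpecimenRecord]
    iterations: int
    convergence_delta: float
    reflected_side: str | None

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def flat(self) -> np.ndarray:
        """Aligned coordinates as an (n, 2k) matrix (x1..xk, y1..yk order)."""
        n, k, _ = self.aligned.shape
        return np.concatenate([self.aligned[:, :, 0], self.aligned[:, :, 1]], axis=1)

    def consensus_flat(self) -> np.ndarray:
        return np.concatenate([self.consensus[:, 0], self.consensus[:, 1]])

    def subset(self, **labels) -> "ProcrustesFit":
        """Records matching the given labels, in the same (common) alignment.

        Group-wise statistics (per-genotype ANOVAs, FA matrices) must share
        one superimposition so their shape spaces are directly comparable;
        subset the common fit rather than re-running GPA per group.
        """
        if not self.records:
            raise ValueError("fit carries no specimen records to subset by")
        idx = [
            i
            for i, r in enumerate(self.records)
            if all(getattr(r, k) == v for k, v in labels.items())
        ]
        return ProcrustesFit(
            consensus=self.consensus,
            aligned=self.aligned[idx],
            centroid_sizes=self.centroid_sizes[idx],
            records=[self.records[i] for i in idx],
            iterations=self.iterations,
            convergence_delta=self.convergence_delta,
            reflected_side=self.reflected_side,
        )


def gpa(
    dataset: LandmarkDataset | list[np.ndarray],
    reflect_side: str | None = "L",
) -> ProcrustesFit:
    """Generalized least-squares Procrustes superimposition.

    Configurations from ``reflect_side`` are mirrored first so both body
    sides live in one shape space; a perfectly symmetric individual then has
    exactly zero asymmetry downstream.
    """
    if isinstance(dataset, LandmarkDataset):
        records = [r for r in dataset.records if r.configuration is not None]
        raw = [r.configuration.coords for r in records]
        sides = [r.side for r in records]
    else:
        records = []
        raw = [np.asarray(c, float) for c in dataset]
        sides = [None] * len(raw)
    if len(raw) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = raw[0].shape[0]
    if any(c.shape != (k, 2) for c in raw):
        raise ValueError("all configurations must share the same landmark count")

    sizes = np.array([centroid_size(c) for c in raw])
    configs = np.empty((len(raw), k, 2))
    for i, c in enumerate(raw):
        c = reflect(c) if (reflect_side is not None and sides[i] == reflect_side.upper()) else np.array(c, float)
        c = c - c.mean(axis=0)
        configs[i] = c / np.linalg.norm(c)

    def rotate_all(configs: np.ndarray, consensus: np.ndarray) -> np.ndarray:
        # closed-form 2D least-squares rotations, batched over configurations
        h = np.einsum("nka,kb->nab", configs, consensus)
        tr = h[:, 0, 0] + h[:, 1, 1]
        od = h[:, 1, 0] - h[:, 0, 1]
        d = np.hypot(tr, od)
        d[d == 0] = 1.0
        c, s = tr / d, od / d
        rot = np.empty((len(configs), 2, 2))
        rot[:, 0, 0] = c
        rot[:, 0, 1] = -s
        rot[:, 1, 0] = s
        rot[:, 1, 1] = c
        return np.einsum("nka,nab->nkb", configs, rot)

    consensus = configs[0].copy()
    delta = np.inf
    for iteration in range(1, GPA_MAX_ITER + 1):
        configs = rotate_all(configs, consensus)
        new = configs.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.linalg.norm(new)
        # pin the (arbitrary) consensus orientation to the previous iterate;
        # otherwise a slow rotational drift mode dominates convergence
        new = new @ _optimal_rotation(new, consensus)
        delta = float(np.linalg.norm(new - consensus))
        consensus = new
        if delta < GPA_TOL:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {GPA_MAX_ITER} iterations (last delta {delta:.3e})"
        )
    # final pass against the converged consensus, then tangent projection
    configs = rotate_all(configs, consensus)
    mu = consensus.ravel()
    flat = configs.reshape(len(configs), -1)
    proj = flat + np.outer(1.0 - flat @ mu, mu)  # <aligned, mu> == 1 exactly
    aligned = proj.reshape(len(configs), k, 2)

    return ProcrustesFit(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        records=records,
        iterations=iteration,
        convergence_delta=delta,
        reflected_side=reflect_side.upper() if reflect_side else None,
    )


@dataclass
class ShapeSpace:
    """Tangent-space principal components of a Procrustes fit."""

    scores: np.ndarray  # (n, d)
    eigenvalues: np.ndarray  # (d,), descending
    loadings: np.ndarray  # (d, 2k) unit rows in coordinate space
    consensus_flat: np.ndarray  # (2k,)
    d: int

    def to_coordinates(self, scores: np.ndarray) -> np.ndarray:
        """Map score vectors back to flat tangent coordinates (adds consensus)."""
        return self.consensus_flat + np.atleast_2d(scores) @ self.loadings


def shape_pca(fit: ProcrustesFit) -> ShapeSpace:
    """PCA of the Procrustes-aligned coordinates.

    The count of non-zero components (eigenvalue above max_eig * 1e-10) is the
    shape dimension d; for 15 landmarks in 2D, d = 26. Non-zero PC scores are
    the shape variables for every downstream shape analysis.
    """
    if fit.n < 3:
        raise ValueError("shape PCA needs at least 3 configurations")
    flat = fit.flat()
    dev = flat - flat.mean(axis=0)
    u, s, vt = np.linalg.svd(dev, full_matrices=False)
    eig = s**2 / (fit.n - 1)
    if eig.size == 0 or eig[0] == 0:
        raise ValueError("no shape variation")
    d = int(np.sum(eig > eig[0] * EIG_ZERO_REL))
    d = min(d, 2 * fit.k - 4)
    loadings = vt[:d]
    # sign convention: largest-|coefficient| positive
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    scores = dev @ loadings.T
    return ShapeSpace(
        scores=scores,
        eigenvalues=eig[:d],
        loadings=loadings,
        consensus_flat=flat.mean(axis=0),
        d=d,
    )


@dataclass
class AllometryFit:
    slopes: np.ndarray  # (d,) per-dimension slope on log size
    intercepts: np.ndarray  # (d,)
    residuals: np.ndarray  # (n, d) allometry-free shape variables


def allometry_regression(scores: np.ndarray, log_sizes: np.ndarray) -> AllometryFit:
    """Multivariate regression of shape scores on log centroid size.

    Residuals are the allometry-free shape variables; they are exactly
    uncorrelated with log size.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    x = np.asarray(log_sizes, float)
    n, d = scores.shape
    if n <= d + 1:
        raise ValueError(f"need n > d+1 ({n} <= {d + 1})")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("size vector is constant (rank deficient)")
    design = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    residuals = scores - design @ coef
    return AllometryFit(slopes=coef[1], intercepts=coef[0], residuals=residuals)


@dataclass
class CVAResult:
    axes: np.ndarray  # (d, n_axes) canonical axes in score space
    canonical_scores: np.ndarray  # (n, n_axes), pooled within-group variance 1
    eigenvalues: np.ndarray  # descending, among/within ratios
    variance_shares: np.ndarray  # sums to 1
    shape_change: np.ndarray  # (n_axes, d) shape change per unit canonical score
    groups: list


def cva(scores: np.ndarray, groups, n_axes: int | None = None) -> CVAResult:
    """Canonical variate analysis: axes maximizing among- relative to
    within-group variation of the shape variables.

    Solves the generalized eigenproblem of the among-group versus pooled
    within-group covariance on the non-degenerate score subspace. Canonical
    scores are normalized to pooled within-group variance 1 per axis. The
    shape change along each axis is the regression of the shape variables on
    the canonical scores.
    """
    from scipy import linalg as sla

    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    labels = [g for g in dict.fromkeys(groups)]
    if len(labels) < 2:
        raise ValueError("CVA needs at least 2 groups")
    n, d = scores.shape
    grand = scores.mean(axis=0)
    w = np.zeros((d, d))
    b = np.zeros((d, d))
    for g in labels:
        sub = scores[groups == g]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        dev = sub - sub.mean(axis=0)
        w += dev.T @ dev
        md = sub.mean(axis=0) - grand
        b += len(sub) * np.outer(md, md)
    w /= n - len(labels)
    b /= len(labels) - 1
    try:
        eigvals, eigvecs = sla.eigh(b, w)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular within-group covariance: {exc}") from exc
    order = np.argsort(eigvals)[::-1]
    n_keep = min(len(labels) - 1, d) if n_axes is None else n_axes
    eigvals = np.clip(eigvals[order][:n_keep], 0, None)
    axes = eigvecs[:, order][:, :n_keep]  # a' W a = 1 per scipy normalization
    cscores = (scores - grand) @ axes
    total = eigvals.sum()
    shares = eigvals / total if total > 0 else np.zeros_like(eigvals)
    shape_change = np.empty((n_keep, d))
    for j in range(n_keep):
        v = cscores[:, j]
        vv = float(v @ v)
        shape_change[j] = (scores - grand).T @ v / vv if vv > 0 else 0.0
    return CVAResult(
        axes=axes,
        canonical_scores=cscores,
        eigenvalues=eigvals,
        variance_shares=shares,
        shape_change=shape_change,
        groups=labels,
    )
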