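"""Synthetic bilateral data with known ground truth.

Generates what the estimators are meant to recover, under the sides model
the analyses assume. For each individual i, side s in {L, R} (d_R = +1/2,
d_L = -1/2) and digitization replicate r:

* landmark shape:  latent = mu + a * d_s * u_DA + I_i + F_is, with
  individual deviations I_i ~ N(0, Sigma_I) and side-specific FA deviations
  F_is ~ N(0, Sigma_F), independent across sides. The observed configuration
  is the latent one scaled by the individual/side size, rotated and
  translated at random (so superimposition is genuinely exercised), mirrored
  for the left side, plus per-replicate digitization noise N(0, sigma2_ME).
* scalar trait:    y_isr = m + g_group + a * d_s + b_i + f_is + e_isr.

Sigma_F may be isotropic (sigma2_F * I) or rank-1 dominated
(lambda * u u' + floor * I), emulating FA concentrated along one shape
direction. Group structure mirrors a gain-of-function / loss-of-function /
control crossing design by genotype and sex, with per-group parameter
overrides. All outputs are bitwise reproducible for a given seed.

Default parameter values emulate the study conditions these analyses were
built for: 15 wing landmarks digitized twice, cells of a few dozen
individuals per genotype x sex, measurement error small relative to FA, and
FA variance inflated tens-fold in the perturbed genotypes for size and
several-fold for shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration, LandmarkDataset, SpecimenRecord
from .procrustes import reflect

# 15-landmark wing-like template: margin/vein intersection layout, unit scale.
WING_TEMPLATE = np.array(
    [
        [0.00, 0.10],  # 1 humeral region
        [0.35, 0.32],  # 2 anterior proximal margin
        [0.80, 0.46],  # 3 costa / L1 (wing-length proximal landmark)
        [1.40, 0.50],  # 4 anterior margin
        [2.05, 0.42],  # 5 L2 tip
        [2.55, 0.25],  # 6 L3 tip
        [2.75, 0.02],  # 7 wing tip (L4)
        [2.50, -0.22],  # 8 L5 tip
        [1.95, -0.38],  # 9 posterior margin
        [1.30, -0.42],  # 10 posterior margin proximal
        [0.60, -0.33],  # 11 alula notch
        [0.25, -0.18],  # 12 posterior proximal
        [1.05, 0.08],  # 13 anterior cross-vein (wing-length distal landmark)
        [1.55, -0.05],  # 14 posterior cross-vein anterior end
        [1.60, -0.22],  # 15 posterior cross-vein posterior end
    ]
)


class CapacityError(RuntimeError):
    """Requested hair count cannot be placed without overlap."""


@dataclass(frozen=True)
class GroupParams:
    """Per-genotype-x-sex simulation parameters (overrides of the defaults)."""

    genotype: str
    sex: str
    n_individuals: int = 40
    log_size_offset: float = 0.0
    # shape variances (per flattened coordinate, unit-size template scale)
    ind_sigma2: float = 1e-4
    fa_sigma2: float = 1e-5  # isotropic part of Sigma_F
    fa_lambda: float = 0.0  # rank-1 part along fa_direction
    fa_direction: np.ndarray | None = None  # (2k,) unit vector
    da_magnitude: float = 0.0
    da_direction: np.ndarray | None = None  # (2k,) unit vector
    # scalar size channel (log centroid size)
    size_ind_sigma2: float = 1e-3
    size_fa_sigma2: float = 1e-5
    size_da: float = 0.0


@dataclass(frozen=True)
class SimulationParams:
    """Full design: shared structure plus per-group overrides."""

    groups: tuple[GroupParams, ...]
    k: int = 15
    m_replicates: int = 2
    mean_shape: np.ndarray = field(default_factory=lambda: WING_TEMPLATE.copy())
    mean_log_size: float = 0.0
    me_sigma2: float = 1e-6  # digitization noise per coordinate per replicate
    seed: int = 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_shape, float)
        if mu.shape != (self.k, 2):
            raise ValueError(f"mean_shape must be ({self.k}, 2), got {mu.shape}")
        for g in self.groups:
            for v in (g.ind_sigma2, g.fa_sigma2, g.fa_lambda, g.size_ind_sigma2,
                      g.size_fa_sigma2, self.me_sigma2):
                if v < 0:
                    raise ValueError("variances must be non-negative")


def default_study_params(
    seed: int = 0,
    n_per_cell: int = 40,
    m_replicates: int = 2,
    genotypes: tuple[str, ...] = ("control", "GOF", "LOF"),
) -> SimulationParams:
    """The default gain/loss-of-function x sex design.

    Control FA levels are small relative to individual variation; the GOF
    genotype carries a ~37-fold size-FA inflation and ~8-fold shape-FA
    inflation, the LOF genotype intermediate inflations, matching the order
    of magnitude of the perturbations these analyses were designed to detect.
    """
    size_fold = {"control": 1.0, "GOF": 37.0, "LOF": 10.0}
    shape_fold = {"control": 1.0, "GOF": 8.0, "LOF": 4.0}
    size_off = {"control": 0.0, "GOF": -0.05, "LOF": 0.0}
    groups = tuple(
        GroupParams(
            genotype=g,
            sex=s,
            n_individuals=n_per_cell,
            fa_sigma2=1e-5 * shape_fold[g],
            size_fa_sigma2=1e-5 * size_fold[g],
            log_size_offset=size_off[g] + (0.04 if s == "F" else -0.04),
        )
        for g in genotypes
        for s in ("F", "M")
    )
    return SimulationParams(groups=groups, m_replicates=m_replicates, seed=seed)


def random_shape_direction(
    mean_shape: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random unit vector in the (2k-4)-dim shape subspace at ``mean_shape``.

    Projects out the translation, rotation and scale directions so the
    vector is a pure shape change, recoverable after superimposition.
    """
    mu = np.asarray(mean_shape, float)
    mu = mu - mu.mean(axis=0)
    k = mu.shape[0]
    mu_flat = np.concatenate([mu[:, 0], mu[:, 1]])
    mu_flat = mu_flat / np.linalg.norm(mu_flat)
    rot = np.concatenate([-mu[:, 1], mu[:, 0]])
    rot = rot / np.linalg.norm(rot)
    tx = np.concatenate([np.ones(k), np.zeros(k)]) / np.sqrt(k)
    ty = np.concatenate([np.zeros(k), np.ones(k)]) / np.sqrt(k)
    v = rng.standard_normal(2 * k)
    for b in (tx, ty, mu_flat, rot):
        v -= (v @ b) * b
    return v / np.linalg.norm(v)


@dataclass
class GroundTruth:
    """What the generator actually drew; the recovery-test reference."""

    params: SimulationParams
    latent_shapes: dict  # (individual, side) -> (k, 2) latent configuration
    fa_directions: dict  # genotype x sex label -> (2k,) unit vector or None
    fa_variances: dict  # label -> (isotropic sigma2, rank-1 lambda)
    log_sizes: dict  # (individual, side) -> float


def _flat_to_config(flat: np.ndarray, k: int) -> np.ndarray:
    return np.column_stack([flat[:k], flat[k:]])


def simulate_landmark_dataset(
    params: SimulationParams,
) -> tuple[LandmarkDataset, GroundTruth]:
    """Draw a labeled bilateral landmark dataset under the sides model."""
    rng = np.random.default_rng(params.seed)
    k = params.k
    mu = np.asarray(params.mean_shape, float)
    mu = mu - mu.mean(axis=0)
    mu_flat = np.concatenate([mu[:, 0], mu[:, 1]])
    records: list[SpecimenRecord] = []
    latent: dict = {}
    log_sizes: dict = {}
    fa_dirs: dict = {}
    fa_vars: dict = {}
    for grp in params.groups:
        label = f"{grp.genotype}:{grp.sex}"
        fa_dirs[label] = None if grp.fa_direction is None else np.asarray(grp.fa_direction, float)
        fa_vars[label] = (grp.fa_sigma2, grp.fa_lambda)
        for i in range(grp.n_individuals):
            ind = f"{grp.genotype}_{grp.sex}_{i:03d}"
            ind_dev = rng.standard_normal(2 * k) * np.sqrt(grp.ind_sigma2)
            b_size = rng.normal(0.0, np.sqrt(grp.size_ind_sigma2))
            for side, d_s in (("L", -0.5), ("R", 0.5)):
                fa_dev = rng.standard_normal(2 * k) * np.sqrt(grp.fa_sigma2)
                if grp.fa_lambda > 0:
                    if grp.fa_direction is None:
                        raise ValueError("fa_lambda > 0 requires fa_direction")
                    fa_dev = fa_dev + rng.normal(0.0, np.sqrt(grp.fa_lambda)) * np.asarray(
                        grp.fa_direction, float
                    )
                flat = mu_flat + ind_dev + fa_dev
                if grp.da_magnitude != 0:
                    if grp.da_direction is None:
                        raise ValueError("da_magnitude != 0 requires da_direction")
                    flat = flat + grp.da_magnitude * d_s * np.asarray(grp.da_direction, float)
                shape = _flat_to_config(flat, k)
                latent[(ind, side)] = shape
                log_size = (
                    params.mean_log_size
                    + grp.log_size_offset
                    + b_size
                    + grp.size_da * d_s
                    + rng.normal(0.0, np.sqrt(grp.size_fa_sigma2))
                )
                log_sizes[(ind, side)] = log_size
                # nuisance transforms: scale, rotation, translation, mirroring
                scale = np.exp(log_size)
                theta = rng.uniform(0.0, 2 * np.pi)
                rot = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                shift = rng.uniform(-5.0, 5.0, size=2)
                observed_base = scale * shape @ rot.T + shift
                if side == "L":
                    observed_base = reflect(observed_base)
                for rep in range(1, params.m_replicates + 1):
                    noise = rng.standard_normal((k, 2)) * np.sqrt(params.me_sigma2)
                    records.append(
                        SpecimenRecord(
                            individual_id=ind,
                            side=side,
                            replicate=rep,
                            genotype=grp.genotype,
                            sex=grp.sex,
                            configuration=LandmarkConfiguration(observed_base + noise),
                        )
                    )
    truth = GroundTruth(
        params=params,
        latent_shapes=latent,
        fa_directions=fa_dirs,
        fa_variances=fa_vars,
        log_sizes=log_sizes,
    )
    return LandmarkDataset(records), truth


# ---------------------------------------------------------------------------
# Scalar paired traits (wing length, femur length, log centroid size)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitParams:
    """Sides-model parameters for a scalar bilateral trait."""

    n_individuals: int = 40
    m_replicates: int = 1
    mean: float = 100.0
    group_offset: float = 0.0
    da: float = 0.0  # constant R-L side offset (R gets +da/2, L gets -da/2)
    ind_sigma2: float = 4.0
    fa_sigma2: float = 0.05  # per-side FA variance
    me_sigma2: float = 0.01
    genotype: str = "control"
    sex: str = "F"


def simulate_trait_values(
    params: TraitParams, rng: np.random.Generator
) -> np.ndarray:
    """Trait values as an (n, 2, M) array with side axis (L, R)."""
    n, m = params.n_individuals, params.m_replicates
    b = rng.normal(0.0, np.sqrt(params.ind_sigma2), size=n)
    f = rng.normal(0.0, np.sqrt(params.fa_sigma2), size=(n, 2))
    e = rng.normal(0.0, np.sqrt(params.me_sigma2), size=(n, 2, m))
    d_s = np.array([-0.5, 0.5])  # (L, R)
    cell = (
        params.mean
        + params.group_offset
        + b[:, None]
        + params.da * d_s[None, :]
        + f
    )
    return cell[:, :, None] + e


def simulate_trait_dataset(
    groups: list[TraitParams], seed: int = 0
) -> tuple[dict[str, np.ndarray], dict[str, TraitParams]]:
    """Per-group (n, 2, M) trait arrays keyed by 'genotype:sex'."""
    rng = np.random.default_rng(seed)
    out, truth = {}, {}
    for g in groups:
        label = f"{g.genotype}:{g.sex}"
        out[label] = simulate_trait_values(g, rng)
        truth[label] = g
    return out, truth


# ---------------------------------------------------------------------------
# Cellular data (paired cell size / cell number per individual)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellDataParams:
    """Per-group generator for paired cellular metrics.

    Wing size is cell number x mean cell area; ``compensation`` in [-1, 0]
    sets the correlation between log cell number and log cell size across
    individuals (-1: perfect size/number compensation, 0: none).
    """

    n_individuals: int = 40
    mean_count: float = 350.0  # hairs per 0.07 mm^2 window
    count_cv: float = 0.08  # among-individual variation of cell number
    size_cv: float = 0.08  # among-individual variation of cell size
    compensation: float = -0.8
    fa_size_sigma: float = 0.01  # per-side sd of log cell size
    fa_count_sigma: float = 0.01  # per-side sd of log cell number
    genotype: str = "control"
    sex: str = "F"


def simulate_cell_dataset(
    params: CellDataParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-individual R/L cellular metrics with wing size = number x size.

    Returns arrays (n,) for cell_size_r/l, cell_number_r/l, wing_size_r/l.
    Setting ``fa_count_sigma=0`` makes wing-size asymmetry derive purely
    from cell-size asymmetry (and vice versa).
    """
    n = params.n_individuals
    cov = np.array(
        [
            [params.count_cv**2, params.compensation * params.count_cv * params.size_cv],
            [params.compensation * params.count_cv * params.size_cv, params.size_cv**2],
        ]
    )
    base = rng.multivariate_normal(np.zeros(2), cov, size=n)
    log_n_i = np.log(params.mean_count) + base[:, 0]
    log_s_i = -np.log(params.mean_count) + base[:, 1]
    out = {}
    logs = {}
    for side in ("l", "r"):
        fa_n = rng.normal(0.0, params.fa_count_sigma, size=n)
        fa_s = rng.normal(0.0, params.fa_size_sigma, size=n)
        logs[f"n_{side}"] = log_n_i + fa_n
        logs[f"s_{side}"] = log_s_i + fa_s
        out[f"cell_number_{side}"] = np.exp(logs[f"n_{side}"])
        out[f"cell_size_{side}"] = np.exp(logs[f"s_{side}"])
        out[f"wing_size_{side}"] = np.exp(logs[f"n_{side}"] + logs[f"s_{side}"])
    return out


# ---------------------------------------------------------------------------
# Hair-dot wing images
# ---------------------------------------------------------------------------


def simulate_wing_image(
    n_hairs: int,
    image_size: tuple[int, int] = (256, 256),
    hair_radius: int = 2,
    foreground: int = 200,
    background: int = 20,
    vein_mask: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 200_000,
) -> tuple[np.ndarray, dict]:
    """Grayscale image of non-overlapping hair dots with exact ground truth.

    Dots are disks of ``hair_radius`` at uniform random positions, kept far
    enough apart to stay 8-disconnected after thresholding, so the true
    count is exact. With ``vein_mask``, two dark vein bands are carved out
    and contain no hairs (the margin/vein undercount stand-in); the mask is
    returned in the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = image_size
    img = np.full((h, w), background, dtype=np.uint8)
    mask = np.zeros((h, w), dtype=bool)
    if vein_mask:
        for frac in (0.33, 0.66):
            r = int(h * frac)
            mask[max(0, r - 4) : r + 4, :] = True
    margin = hair_radius + 1
    min_dist = 2 * hair_radius + 2.5
    centers: list[tuple[float, float]] = []
    pts = np.empty((0, 2))
    attempts = 0
    while len(centers) < n_hairs:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"placed {len(centers)}/{n_hairs} hairs in {max_attempts} attempts"
            )
        c = rng.uniform([margin, margin], [h - margin, w - margin])
        if vein_mask and mask[int(c[0]), int(c[1])]:
            continue
        if len(pts) and np.min(np.hypot(*(pts - c).T)) < min_dist:
            continue
        centers.append((c[0], c[1]))
        pts = np.array(centers)
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx in centers:
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= hair_radius**2
        img[disk] = foreground
    truth = {
        "n_hairs": n_hairs,
        "centers": np.array(centers).reshape(-1, 2),
        "vein_mask": mask if vein_mask else None,
    }
    return img, truth
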