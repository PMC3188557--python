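"""Wing cell number and cell size from trichome (hair-dot) images.

Each wing epidermal cell carries one hair, so counting hairs in a calibrated
window measures cell density. The protocol: threshold the image, count
8-connected hair blobs inside a 256x256-pixel window (0.07 mm^2), repeat in
two windows shifted along the proximo-distal axis, average the three counts.
Cell size is 1 / mean count (arbitrary units); the whole-image count gives a
(systematically under-estimated but genotype-stable) total cell number.

Downstream statistics quantify the cell size / cell number compensation that
keeps wing size constant: per-genotype Pearson correlations compared via
Fisher's r-to-z, and residual variances of the size-on-number regression
compared via Levene and pairwise F tests. Cellular FA is FA4 (variance of
R - L) of cell size and cell number, correlated with wing-size FA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from skimage.filters import threshold_otsu

from .asymmetry import FAEstimate, InsufficientDataError, fa4, holm_adjust

WINDOW_SIZE = 256  # pixels per side; corresponds to 0.07 mm^2
WINDOW_AREA_MM2 = 0.07


def threshold_image(image: np.ndarray, threshold="otsu") -> np.ndarray:
    """Binarize a grayscale image; keeps the bright hair marks.

    ``threshold`` is an intensity cutoff (foreground strictly above it) or
    "otsu" for automatic selection.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2D image, got shape {img.shape}")
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        threshold = threshold_otsu(img)
    return img > threshold


def count_objects(binary: np.ndarray, count_border: bool = True) -> int:
    """Number of 8-connected foreground blobs (one hair = one cell).

    8-connectivity keeps thin diagonal hair marks as single objects. Objects
    touching the window border are counted once by default; discarding them
    (``count_border=False``) would bias density low.
    """
    mask = np.asarray(binary).astype(bool)
    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    if not count_border and n:
        border = np.unique(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            )
        )
        n -= len(border[border > 0])
    return n


@dataclass
class CellStats:
    """Hair counts and derived cell metrics for one wing image."""

    region_counts: tuple[int, int, int]
    mean_count: float
    cell_size: float  # 1 / mean_count, arbitrary units
    total_count: int
    window_origin: tuple[int, int]
    window_size: int = WINDOW_SIZE
    homogeneity_p: float = float("nan")  # Poisson dispersion test across windows

    def __post_init__(self) -> None:
        assert abs(self.cell_size * self.mean_count - 1.0) < 1e-12

    @property
    def homogeneous(self) -> bool:
        return self.homogeneity_p > 0.05


def cell_metrics(
    image: np.ndarray,
    window_origin: tuple[int, int],
    shift_vector: tuple[int, int] = (0, WINDOW_SIZE),
    threshold="otsu",
    exclude_mask: np.ndarray | None = None,
) -> CellStats:
    """Count cells in three shifted windows and over the whole image.

    ``window_origin`` is the (row, col) of the first 256x256 window; the
    window is then shifted twice by ``shift_vector`` (default: one full
    window width along the image x-axis / columns, the proximo-distal
    stand-in). ``exclude_mask``
    (veins/margin) removes foreground from the whole-image total, emulating
    the deliberate undercount of vein cells.
    """
    binary = threshold_image(image, threshold)
    h, w = binary.shape
    counts = []
    r0, c0 = window_origin
    dr, dc = shift_vector
    for step in range(3):
        r, c = r0 + step * dr, c0 + step * dc
        if r < 0 or c < 0 or r + WINDOW_SIZE > h or c + WINDOW_SIZE > w:
            raise ValueError(
                f"window {step} at ({r}, {c}) falls outside the {h}x{w} image"
            )
        counts.append(count_objects(binary[r : r + WINDOW_SIZE, c : c + WINDOW_SIZE]))
    mean_count = float(np.mean(counts))
    if mean_count == 0:
        raise ZeroDivisionError("zero mean hair count; cell size undefined")
    total_mask = binary if exclude_mask is None else binary & ~np.asarray(exclude_mask, bool)
    total = count_objects(total_mask)
    # Poisson dispersion test: are the three window counts consistent with
    # one homogeneous density?
    chi2 = float(sum((c - mean_count) ** 2 for c in counts) / mean_count)
    return CellStats(
        region_counts=tuple(int(c) for c in counts),
        mean_count=mean_count,
        cell_size=1.0 / mean_count,
        total_count=total,
        window_origin=tuple(window_origin),
        homogeneity_p=float(stats.chi2.sf(chi2, 2)),
    )


# ---------------------------------------------------------------------------
# Compensation statistics
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise InsufficientDataError("correlation needs n >= 4")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's r-to-z transform.

    Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the z transform")
    if min(n1, n2) < 4:
        raise InsufficientDataError("need n >= 4 per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class CompensationReport:
    """Cell size vs cell number compensation, per group and between groups."""

    correlations: pd.DataFrame  # group, n, r, p
    z_comparisons: pd.DataFrame  # pairwise Fisher-z tests
    residual_variances: pd.DataFrame  # group, n, residual_variance
    levene_stat: float
    levene_p: float
    pairwise_f: pd.DataFrame  # pairwise variance-ratio F tests, Holm-adjusted


def _two_sided_f(f: float, df1: int, df2: int) -> float:
    dist = stats.f(df1, df2)
    return float(min(1.0, 2 * min(dist.cdf(f), dist.sf(f))))


def residual_variance_analysis(cell_size, cell_number, groups) -> CompensationReport:
    """Quantify the strength of the size/number compensation per group.

    Stronger compensation = tighter size-on-number regression = lower
    residual variance. Residual variances (df n-2) are compared across
    groups with a Levene test and pairwise two-sided F tests (Holm-adjusted).
    Per-group Pearson correlations are compared pairwise via Fisher's r-to-z.
    """
    cs = np.asarray(cell_size, float)
    cn = np.asarray(cell_number, float)
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g))
    corr_rows, var_rows, residuals = [], [], {}
    for label in labels:
        mask = g == label
        n = int(mask.sum())
        if n < 5:
            raise InsufficientDataError(f"group {label!r} has n={n} < 5")
        if np.ptp(cn[mask]) == 0:
            raise np.linalg.LinAlgError(f"cell number constant in group {label!r}")
        r, p = pearson_r(cn[mask], cs[mask])
        corr_rows.append({"group": label, "n": n, "r": r, "p": p})
        slope, intercept = np.polyfit(cn[mask], cs[mask], 1)
        resid = cs[mask] - (slope * cn[mask] + intercept)
        residuals[label] = resid
        var_rows.append(
            {
                "group": label,
                "n": n,
                "df": n - 2,
                "residual_variance": float(resid @ resid / (n - 2)),
            }
        )
    z_rows, f_rows = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = corr_rows[i], corr_rows[j]
            z, zp = fisher_z_compare(a["r"], a["n"], b["r"], b["n"])
            z_rows.append({"a": a["group"], "b": b["group"], "Z": z, "p": zp})
            va, vb = var_rows[i], var_rows[j]
            if vb["residual_variance"] == 0 and va["residual_variance"] == 0:
                f_rows.append(
                    {"a": va["group"], "b": vb["group"], "F": np.nan, "p": np.nan}
                )
                continue
            fstat = va["residual_variance"] / vb["residual_variance"]
            f_rows.append(
                {
                    "a": va["group"],
                    "b": vb["group"],
                    "F": fstat,
                    "p": _two_sided_f(fstat, va["df"], vb["df"]),
                }
            )
    fw = pd.DataFrame(f_rows)
    if len(fw) and fw["p"].notna().all():
        fw["p_holm"] = holm_adjust(fw["p"].to_numpy())
    scale = float(np.var(cs)) if np.var(cs) > 0 else 1.0
    all_zero = all(v["residual_variance"] <= 1e-20 * scale for v in var_rows)
    if all_zero:
        lev_stat, lev_p = 0.0, np.nan  # exact fits in every group; nothing to test
    else:
        lev_stat, lev_p = stats.levene(*residuals.values())
    return CompensationReport(
        correlations=pd.DataFrame(corr_rows),
        z_comparisons=pd.DataFrame(z_rows),
        residual_variances=pd.DataFrame(var_rows),
        levene_stat=float(lev_stat),
        levene_p=float(lev_p) if lev_p == lev_p else np.nan,
        pairwise_f=fw,
    )


# ---------------------------------------------------------------------------
# Cellular FA
# ---------------------------------------------------------------------------


@dataclass
class CellularFAReport:
    fa4_cell_size: FAEstimate
    fa4_cell_number: FAEstimate
    correlations: pd.DataFrame  # metric, pearson r/p, spearman rho/p
    n_pairs: int
    degenerate: bool = False


def cellular_fa(
    cell_size_r,
    cell_size_l,
    cell_number_r,
    cell_number_l,
    wing_size_r,
    wing_size_l,
    genotype: str = "",
    sex: str = "",
) -> CellularFAReport:
    """FA4 of cell size and cell number, and their link to wing-size FA.

    Per-individual unsigned asymmetries |R - L| of each cellular metric are
    correlated (Pearson and Spearman) with the unsigned wing-size asymmetry,
    asking which cellular process drives organ-size instability.
    """
    arrays = [
        np.asarray(a, float)
        for a in (cell_size_r, cell_size_l, cell_number_r, cell_number_l, wing_size_r, wing_size_l)
    ]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all inputs must be complete per-individual R/L pairs")
    if n < 5:
        raise InsufficientDataError("cellular FA needs >= 5 complete pairs")
    csr, csl, cnr, cnl, wsr, wsl = arrays
    fa_cs = fa4(csr, csl, trait="cell size", genotype=genotype, sex=sex)
    fa_cn = fa4(cnr, cnl, trait="cell number", genotype=genotype, sex=sex)
    asym = {
        "cell size": np.abs(csr - csl),
        "cell number": np.abs(cnr - cnl),
    }
    wing_asym = np.abs(wsr - wsl)
    rows = []
    degenerate = np.ptp(wing_asym) == 0
    for metric, a in asym.items():
        if degenerate or np.ptp(a) == 0:
            rows.append(
                {"metric": metric, "pearson_r": np.nan, "pearson_p": np.nan,
                 "spearman_rho": np.nan, "spearman_p": np.nan}
            )
            degenerate = True
            continue
        pr, pp = stats.pearsonr(a, wing_asym)
        sr, sp = stats.spearmanr(a, wing_asym)
        rows.append(
            {
                "metric": metric,
                "pearson_r": float(pr),
                "pearson_p": float(pp),
                "spearman_rho": float(sr),
                "spearman_p": float(sp),
            }
        )
    return CellularFAReport(
        fa4_cell_size=fa_cs,
        fa4_cell_number=fa_cn,
        correlations=pd.DataFrame(rows),
        n_pairs=n,
        degenerate=degenerate,
    )
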