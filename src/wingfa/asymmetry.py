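"""Sides-model ANOVA, FA indices and genotype comparisons.

The sides (mixed-model) ANOVA decomposes bilateral variation of a trait
measured on both sides of n individuals, M times each, into:

* Individual (random, df n-1) — among-individual variation,
* Side (fixed, df 1) — directional asymmetry (DA),
* Individual x Side (random, df n-1) — the fluctuating-asymmetry (FA) signal,
* Error (df 2n(M-1)) — digitization/measurement error (ME).

F-tests follow the mixed-model convention: Side and Individual over the
interaction, the interaction over Error. The Procrustes ANOVA applies the
same decomposition to Procrustes-superimposed coordinates, pooling sums of
squares over all 2k coordinates and multiplying every conventional df by the
shape dimension 2k - 4.

FA indices (Palmer-Strobeck terminology):

* FA10 = (MS_interaction - MS_error) / M — FA variance corrected for both ME
  and DA; requires replicated digitization (M >= 2).
* FA4 = var(R - L) — used when only a single measurement per side exists.

Genotype comparisons of FA are variance-ratio F-tests (two-sided); families
of p-values are adjusted with the Holm step-down procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .procrustes import ProcrustesFit


class BalanceError(ValueError):
    """Design is not balanced (missing sides/replicates)."""


class InsufficientDataError(ValueError):
    pass


@dataclass
class Effect:
    name: str
    df: int
    ss: float
    ms: float
    f: float | None = None
    p: float | None = None


@dataclass
class AsymmetryAnova:
    """Effect table of a sides-model ANOVA (univariate or Procrustes)."""

    effects: list[Effect]
    kind: str  # "univariate" | "procrustes"
    m_replicates: int
    n_individuals: int
    shape_dim: int | None = None  # 2k-4 for procrustes
    trait: str = ""

    def __getitem__(self, name: str) -> Effect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def has_error_stratum(self) -> bool:
        return self.m_replicates >= 2

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name,
                    "Df": e.df,
                    "SS": e.ss * scale,
                    "MS": e.ms * scale,
                    "F": e.f,
                    "p": e.p,
                }
                for e in self.effects
            ]
        )


def _two_sided_f(f: float, df1: int, df2: int) -> float:
    dist = stats.f(df1, df2)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def sides_table(
    values, individuals=None, sides=None, replicates=None
) -> np.ndarray:
    """Arrange per-(individual, side, replicate) values as an (n, 2, M) array.

    ``values`` may already be such an array, or a flat vector accompanied by
    individual/side/replicate label vectors. Side axis order is (L, R).
    Raises :class:`BalanceError` when the design is incomplete.
    """
    if individuals is None:
        arr = np.asarray(values, float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3 or arr.shape[1] != 2:
            raise BalanceError(f"expected (n, 2, M) array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise BalanceError("missing or non-finite values in sides table")
        return arr
    values = np.asarray(values, float)
    individuals = np.asarray(individuals)
    sides = np.asarray([str(s).upper() for s in sides])
    replicates = np.asarray(replicates, int)
    inds = list(dict.fromkeys(individuals))
    reps = sorted(set(replicates))
    m = len(reps)
    arr = np.full((len(inds), 2, m), np.nan)
    side_ix = {"L": 0, "R": 1}
    rep_ix = {r: j for j, r in enumerate(reps)}
    for v, i, s, r in zip(values, individuals, sides, replicates):
        if s not in side_ix:
            raise BalanceError(f"unknown side {s!r}")
        arr[inds.index(i), side_ix[s], rep_ix[r]] = v
    if np.isnan(arr).any():
        bad = [inds[i] for i in range(len(inds)) if np.isnan(arr[i]).any()]
        raise BalanceError(f"incomplete individuals (missing side/replicate): {bad}")
    return arr


def _sides_ss(arr: np.ndarray) -> dict[str, float]:
    """Sums of squares of the balanced two-way (individual x side) layout.

    ``arr`` has shape (n, 2, M, ...) — trailing axes (e.g. coordinates) are
    summed over, which is exactly how the Procrustes ANOVA pools coordinates.
    """
    n, two, m = arr.shape[:3]
    grand = arr.mean(axis=(0, 1, 2))
    ind_means = arr.mean(axis=(1, 2))  # (n, ...)
    side_means = arr.mean(axis=(0, 2))  # (2, ...)
    cell_means = arr.mean(axis=2)  # (n, 2, ...)
    ss_ind = 2 * m * ((ind_means - grand) ** 2).sum()
    ss_side = n * m * ((side_means - grand) ** 2).sum()
    inter = cell_means - ind_means[:, None] - side_means[None, :] + grand
    ss_int = m * (inter**2).sum()
    ss_err = ((arr - cell_means[:, :, None]) ** 2).sum()
    return {
        "Individual": float(ss_ind),
        "Side": float(ss_side),
        "Individual x Side": float(ss_int),
        "Error": float(ss_err),
    }


def _assemble_anova(
    ss: dict[str, float], n: int, m: int, mult: int, kind: str, trait: str
) -> AsymmetryAnova:
    dfs = {
        "Individual": (n - 1) * mult,
        "Side": 1 * mult,
        "Individual x Side": (n - 1) * mult,
        "Error": 2 * n * (m - 1) * mult,
    }
    effects = []
    for name in ("Individual", "Side", "Individual x Side", "Error"):
        df = dfs[name]
        if df == 0:
            continue
        effects.append(Effect(name=name, df=df, ss=ss[name], ms=ss[name] / df))
    anova = AsymmetryAnova(
        effects=effects,
        kind=kind,
        m_replicates=m,
        n_individuals=n,
        shape_dim=mult if kind == "procrustes" else None,
        trait=trait,
    )
    inter = anova["Individual x Side"]
    for name in ("Individual", "Side"):
        e = anova[name]
        if inter.ms > 0:
            e.f = e.ms / inter.ms
            e.p = float(stats.f.sf(e.f, e.df, inter.df))
    if m >= 2:
        err = anova["Error"]
        if err.ms > 0:
            inter.f = inter.ms / err.ms
            inter.p = float(stats.f.sf(inter.f, inter.df, err.df))
    return anova


def sides_anova_univariate(
    values, individuals=None, sides=None, replicates=None, trait: str = ""
) -> AsymmetryAnova:
    """Two-way mixed-model ANOVA on a size trait measured on both sides.

    The Side effect tests directional asymmetry; the Individual x Side mean
    square carries the FA signal; the Error mean square (available with
    replicated digitization, M >= 2) estimates measurement error.
    """
    arr = sides_table(values, individuals, sides, replicates)
    n, _, m = arr.shape
    if n < 2:
        raise InsufficientDataError("need at least 2 individuals")
    if m < 2:
        warnings.warn(
            "single measurement session (M=1): Error stratum absent, FA10 unavailable",
            stacklevel=2,
        )
    return _assemble_anova(_sides_ss(arr), n, m, 1, "univariate", trait)


def procrustes_sides_table(fit: ProcrustesFit) -> tuple[np.ndarray, list, int]:
    """Aligned coordinates arranged as (n, 2, M, 2k) plus individual ids.

    Requires the fit's records to carry individual/side/replicate labels and
    the design to be balanced.
    """
    if not fit.records:
        raise BalanceError("fit carries no specimen records")
    flat = fit.flat()
    inds = list(dict.fromkeys(r.individual_id for r in fit.records))
    reps = sorted({r.replicate for r in fit.records})
    m = len(reps)
    rep_ix = {r: j for j, r in enumerate(reps)}
    side_ix = {"L": 0, "R": 1}
    arr = np.full((len(inds), 2, m, flat.shape[1]), np.nan)
    for row, rec in zip(flat, fit.records):
        arr[inds.index(rec.individual_id), side_ix[rec.side], rep_ix[rec.replicate]] = row
    if np.isnan(arr).any():
        bad = [inds[i] for i in range(len(inds)) if np.isnan(arr[i]).any()]
        raise BalanceError(f"incomplete individuals: {bad}")
    return arr, inds, m


def procrustes_anova(fit: ProcrustesFit, trait: str = "shape") -> AsymmetryAnova:
    """Procrustes ANOVA: the sides model applied to superimposed coordinates.

    Sums of squares are pooled over all 2k aligned coordinates (numerically
    identical to summing 2k per-coordinate univariate sides ANOVAs) and each
    conventional df is multiplied by the shape dimension 2k - 4.
    """
    arr, inds, m = procrustes_sides_table(fit)
    n = len(inds)
    if n < 2:
        raise InsufficientDataError("need at least 2 individuals")
    k = fit.k
    return _assemble_anova(_sides_ss(arr), n, m, 2 * k - 4, "procrustes", trait)


@dataclass
class FAEstimate:
    """A fluctuating-asymmetry variance estimate for one group and trait."""

    index: str  # "FA10" | "FA4"
    value: float  # squared trait units
    trait: str = ""
    genotype: str = ""
    sex: str = ""
    n: int = 0
    m: int | None = None
    df: int = 0  # df of the underlying variance estimate
    ms_interaction: float | None = None
    ms_error: float | None = None
    negative: bool = False  # FA10 below zero (ME exceeds interaction MS)


def fa10(anova: AsymmetryAnova, genotype: str = "", sex: str = "") -> FAEstimate:
    """ME- and DA-corrected FA variance: (MS_interaction - MS_error) / M.

    Negative estimates (interaction MS below error MS) are returned as-is
    with ``negative=True`` — truncating to zero would bias fold-ratios.
    """
    if not anova.has_error_stratum:
        raise InsufficientDataError("FA10 requires M >= 2 replicate measurements")
    inter = anova["Individual x Side"]
    err = anova["Error"]
    value = (inter.ms - err.ms) / anova.m_replicates
    return FAEstimate(
        index="FA10",
        value=float(value),
        trait=anova.trait,
        genotype=genotype,
        sex=sex,
        n=anova.n_individuals,
        m=anova.m_replicates,
        df=inter.df,
        ms_interaction=inter.ms,
        ms_error=err.ms,
        negative=value < 0,
    )


def fa4(
    right, left=None, trait: str = "", genotype: str = "", sex: str = ""
) -> FAEstimate:
    """FA4: sample variance of (R - L), one value per individual.

    With replicated measurements, replicates are averaged per side before
    differencing. Pass either paired arrays (right, left) or a single array
    of per-individual differences.
    """
    if left is None:
        diffs = np.asarray(right, float)
    else:
        r = np.asarray(right, float)
        l = np.asarray(left, float)
        if r.ndim == 2:  # (n, M) replicates
            r = r.mean(axis=1)
        if l.ndim == 2:
            l = l.mean(axis=1)
        diffs = r - l
    n = len(diffs)
    if n < 2:
        raise InsufficientDataError("FA4 needs at least 2 complete pairs")
    return FAEstimate(
        index="FA4",
        value=float(np.var(diffs, ddof=1)),
        trait=trait,
        genotype=genotype,
        sex=sex,
        n=n,
        df=n - 1,
    )


@dataclass
class FAComparison:
    """F-test comparison of two FA estimates; ratio is a / b ("FA effect")."""

    fa_ratio: float
    f: float
    df: tuple[int, int]
    p_raw: float
    p_adjusted: float | None = None


def compare_fa(fa_a: FAEstimate, fa_b: FAEstimate) -> FAComparison:
    """Standard two-sided F-test of two FA estimates of the same index/trait.

    FA4: variance-ratio F with (n_a-1, n_b-1) df. FA10: ratio of the
    interaction mean squares with their interaction df.
    """
    if fa_a.index != fa_b.index:
        raise ValueError(f"index mismatch: {fa_a.index} vs {fa_b.index}")
    if fa_a.negative or fa_b.negative:
        warnings.warn(
            "negative FA10 estimate excluded from comparison", stacklevel=2
        )
        return FAComparison(fa_ratio=np.nan, f=np.nan, df=(fa_a.df, fa_b.df), p_raw=np.nan)
    if fa_b.value == 0:
        raise ZeroDivisionError("denominator FA estimate is zero; ratio undefined")
    ratio = fa_a.value / fa_b.value
    if fa_a.index == "FA10":
        f = fa_a.ms_interaction / fa_b.ms_interaction
    else:
        f = ratio
    df = (fa_a.df, fa_b.df)
    return FAComparison(fa_ratio=float(ratio), f=float(f), df=df, p_raw=_two_sided_f(f, *df))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down multiple-testing adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce monotone
    non-decreasing adjusted values, cap at 1; returned in the input order.
    """
    p = np.asarray(p_values, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, ix in enumerate(order):
        running = max(running, (m - rank) * p[ix])
        adj[ix] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# Antisymmetry screening
# ---------------------------------------------------------------------------

_DIP_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _convex_violation(x: np.ndarray, f: np.ndarray) -> float:
    """Max amount the piecewise points (x, f) lie above their lower convex hull."""
    n = len(x)
    if n < 3:
        return 0.0
    hull = [0]
    for i in range(1, n):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (f[b] - f[a]) * (x[i] - x[b]) >= (f[i] - f[b]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    worst = 0.0
    for a, b in zip(hull[:-1], hull[1:]):
        if x[b] == x[a]:
            continue
        seg = slice(a, b + 1)
        line = f[a] + (x[seg] - x[a]) * (f[b] - f[a]) / (x[b] - x[a])
        worst = max(worst, float(np.max(f[seg] - line)))
    return worst


def _unimodal_departure(x: np.ndarray) -> float:
    """Dip-style departure of the ECDF from the best convex/concave envelope.

    For a candidate mode m the ECDF should be convex left of m (rising
    density) and concave right of it (falling density); the statistic is the
    minimum over modes of the larger envelope violation. The left violation
    grows with m and the right one shrinks, so their max is V-shaped and the
    minimizing mode is found by bisection. Near zero for unimodal samples,
    large for well-separated bimodal ones. Calibrated by Monte Carlo against
    the uniform null (after the probability integral transform the statistic
    is distribution-free, as for Hartigan's dip).
    """
    x = np.sort(np.asarray(x, float))
    n = len(x)
    f = np.arange(1, n + 1) / n

    def left(m: int) -> float:
        return _convex_violation(x[: m + 1], f[: m + 1])

    def right(m: int) -> float:
        # concave-majorant violation of the tail == convex violation of the
        # point-reflected tail
        return _convex_violation(-x[m:][::-1], -f[m:][::-1])

    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if left(mid) < right(mid):
            lo = mid
        else:
            hi = mid
    return float(min(max(left(m), right(m)) for m in (lo, hi)))


def _dip_null_quantile(n: int, stat: float, n_mc: int, seed: int) -> float:
    key = (n, n_mc, seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(seed)
        _DIP_NULL_CACHE[key] = np.array(
            [_unimodal_departure(rng.uniform(size=n)) for _ in range(n_mc)]
        )
    null = _DIP_NULL_CACHE[key]
    return float((np.sum(null >= stat) + 1) / (len(null) + 1))


@dataclass
class AntisymmetryReport:
    excess_kurtosis: float
    dip_statistic: float
    dip_p: float
    normality_p: float
    flagged: bool
    degenerate: bool = False


def antisymmetry_check(
    diffs, alpha: float = 0.05, n_mc: int = 200, seed: int = 0
) -> AntisymmetryReport:
    """Screen right-minus-left differences for antisymmetry.

    Antisymmetry (bimodal R-L with random direction) invalidates FA as a
    developmental-instability readout. Flags when the sample is clearly
    platykurtic (excess kurtosis < -0.5) AND unimodality is rejected.
    """
    d = np.asarray(diffs, float)
    if len(d) < 8:
        raise InsufficientDataError("antisymmetry screen needs n >= 8")
    if np.ptp(d) == 0:
        return AntisymmetryReport(0.0, 0.0, 1.0, 1.0, flagged=False, degenerate=True)
    kurt = float(stats.kurtosis(d, fisher=True, bias=False))
    dip = _unimodal_departure(d)
    dip_p = _dip_null_quantile(len(d), dip, n_mc, seed)
    norm_p = float(stats.shapiro(d).pvalue) if len(d) <= 5000 else float(
        stats.normaltest(d).pvalue
    )
    flagged = (kurt < -0.5) and (dip_p < alpha)
    return AntisymmetryReport(kurt, dip, dip_p, norm_p, flagged=flagged)


# ---------------------------------------------------------------------------
# FA allometry screen
# ---------------------------------------------------------------------------


def fa_allometry_check(abs_asymmetry, mean_size, groups) -> pd.DataFrame:
    """Regression screen of |R - L| on individual size, within each group and
    across group means.

    A within-group size dependence of asymmetry would call for size
    standardization before FA comparisons; among-group dependence may simply
    reflect group mean-size differences.
    """
    a = np.asarray(abs_asymmetry, float)
    s = np.asarray(mean_size, float)
    g = np.asarray(groups)
    rows = []
    means = []
    for label in dict.fromkeys(g):
        mask = g == label
        if mask.sum() < 10:
            raise InsufficientDataError(
                f"group {label!r} has {int(mask.sum())} individuals (< 10)"
            )
        if np.ptp(s[mask]) == 0:
            raise np.linalg.LinAlgError(f"size constant within group {label!r}")
        res = stats.linregress(s[mask], a[mask])
        rows.append(
            {
                "group": label,
                "level": "within",
                "n": int(mask.sum()),
                "slope": res.slope,
                "r": res.rvalue,
                "p": res.pvalue,
            }
        )
        means.append((float(s[mask].mean()), float(a[mask].mean())))
    if len(means) >= 3:
        ms, ma = zip(*means)
        res = stats.linregress(ms, ma)
        rows.append(
            {
                "group": "(all)",
                "level": "among",
                "n": len(means),
                "slope": res.slope,
                "r": res.rvalue,
                "p": res.pvalue,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-effect tests (genotype x sex)
# ---------------------------------------------------------------------------


def group_tests(values, genotype, sex) -> pd.DataFrame:
    """Two-way fixed-effects test of genotype and sex on a trait.

    Univariate input: ordinary two-way ANOVA with interaction. Multivariate
    input (shape scores): MANOVA, reporting Pillai's trace with its
    approximate F.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    values = np.asarray(values, float)
    df = pd.DataFrame({"genotype": np.asarray(genotype), "sex": np.asarray(sex)})
    counts = df.value_counts(["genotype", "sex"])
    if (counts < 2).any():
        raise ValueError("each genotype x sex cell needs n >= 2")
    if values.ndim == 1:
        df["y"] = values
        model = ols("y ~ C(genotype) * C(sex)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table = table.rename(
            index={
                "C(genotype)": "genotype",
                "C(sex)": "sex",
                "C(genotype):C(sex)": "genotype x sex",
                "Residual": "residual",
            }
        )
        out = table.reset_index().rename(
            columns={"index": "effect", "sum_sq": "SS", "df": "Df", "F": "F", "PR(>F)": "p"}
        )
        out["kind"] = "anova"
        return out
    from statsmodels.multivariate.manova import MANOVA

    ycols = [f"v{i}" for i in range(values.shape[1])]
    for i, c in enumerate(ycols):
        df[c] = values[:, i]
    formula = " + ".join(ycols) + " ~ C(genotype) * C(sex)"
    mv = MANOVA.from_formula(formula, data=df)
    res = mv.mv_test()
    rows = []
    mapping = {
        "C(genotype)": "genotype",
        "C(sex)": "sex",
        "C(genotype):C(sex)": "genotype x sex",
    }
    for key, label in mapping.items():
        tab = res.results[key]["stat"]
        pillai = tab.loc["Pillai's trace"]
        rows.append(
            {
                "effect": label,
                "Pillai": float(pillai["Value"]),
                "F": float(pillai["F Value"]),
                "Df": (float(pillai["Num DF"]), float(pillai["Den DF"])),
                "p": float(pillai["Pr > F"]),
                "kind": "manova",
            }
        )
    return pd.DataFrame(rows)
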