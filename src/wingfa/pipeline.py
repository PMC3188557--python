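"""End-to-end analysis pipeline: data (read or simulated) -> report bundle.

Stages, in the order the method runs: Procrustes superimposition and shape
PCA; group-effect tests on size and shape; per-group sides ANOVAs with FA
indices and fold-ratio comparisons against the control genotype
(Holm-adjusted); FA-pattern matrices with pairwise PC1-angle tests per sex;
cellular compensation and cellular-FA analyses on simulated cell data.

Outputs one directory of CSV tables, SVG figures, a machine-readable
``results.json`` and a ``manifest.json``. Reruns with the same configuration
and seed reproduce ``results.json`` byte for byte. Reported MS/FA values
follow the conventional presentation scaling: size tables x 1e5, shape
tables x 1e7.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asymmetry, cells, patterns, procrustes, simulate
from .io import LandmarkDataset, read_landmark_table

log = logging.getLogger("wingfa")

SIZE_SCALE = 1e5
SHAPE_SCALE = 1e7


def significance_stars(p: float) -> str:
    if p != p:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    seed: int
    out_dir: str
    landmarks: str | None = None  # CSV path; mutually exclusive with simulate
    simulate: dict = field(default_factory=dict)  # default_study_params kwargs
    cell_data: bool = True  # also simulate/analyze cellular metrics
    reflect_side: str = "L"
    fa_index: str = "fa10"  # "fa10" | "fa4"
    allometry_correct: bool = False
    n_draws: int = 10_000
    n_boot: int = 1_000
    control_genotype: str = "control"
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ValueError(f"invalid YAML config: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or "out_dir" not in raw:
            raise ValueError("config requires 'seed' and 'out_dir'")
        return cls(**raw)


def _validate(config: PipelineConfig, dataset: LandmarkDataset) -> None:
    reps = {r.replicate for r in dataset.records}
    if config.fa_index == "fa10" and len(reps) < 2:
        raise ValueError(
            "fa_index=fa10 requires replicated digitization (M >= 2); "
            "use fa_index=fa4 for single-session data"
        )
    if config.fa_index not in ("fa10", "fa4"):
        raise ValueError(f"unknown fa_index {config.fa_index!r}")


def _group_cells(dataset: LandmarkDataset) -> list[tuple[str, str]]:
    seen = []
    for r in dataset.records:
        if (r.genotype, r.sex) not in seen:
            seen.append((r.genotype, r.sex))
    return seen


def _size_table(dataset: LandmarkDataset):
    """Per-record log centroid size plus lookup arrays."""
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "individual": r.individual_id,
                "side": r.side,
                "replicate": r.replicate,
                "genotype": r.genotype,
                "sex": r.sex,
                "log_cs": np.log(procrustes.centroid_size(r.configuration)),
            }
        )
    return pd.DataFrame(rows)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs and a manifest were kept."""


def run_fa_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the results dict also written to JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seed = {name: int(rng.integers(2**31)) for name in
                  ("patterns", "cells", "figures")}
    manifest: list[str] = []
    results: dict = {"seed": config.seed}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest.append(name)

    stage = "data"
    try:
        return _run(config, out, rng, stage_seed, manifest, results, emit)
    except Exception as exc:
        stage = results.get("_stage", "data")
        with open(out / "manifest.json", "w") as fh:
            json.dump({"outputs": sorted(manifest), "failed_stage": stage}, fh, indent=2)
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc


def _run(config, out, rng, stage_seed, manifest, results, emit) -> dict:
    # --- data ---------------------------------------------------------
    results["_stage"] = "data"
    if config.landmarks:
        dataset = read_landmark_table(config.landmarks)
        truth = None
    else:
        params = simulate.default_study_params(
            seed=config.seed, **config.simulate
        )
        dataset, truth = simulate.simulate_landmark_dataset(params)
    _validate(config, dataset)
    cells_per_group = _group_cells(dataset)
    log.info("dataset: %d records, %d groups", len(dataset.records), len(cells_per_group))
    emit(dataset.design_summary(), "design.csv")

    # --- superimposition & shape space (global, for group tests / CVA) -
    results["_stage"] = "superimposition"
    fit_all = procrustes.gpa(dataset, reflect_side=config.reflect_side)
    space_all = procrustes.shape_pca(fit_all)
    results["shape_dimension"] = int(space_all.d)
    sizes = _size_table(dataset)

    # individual-level shape scores (averaged over sides and replicates)
    by_ind: dict[str, list[int]] = {}
    for ix, rec in enumerate(fit_all.records):
        by_ind.setdefault(rec.individual_id, []).append(ix)
    ind_ids = list(by_ind)
    ind_scores = np.vstack(
        [space_all.scores[ixs].mean(axis=0) for ixs in by_ind.values()]
    )
    meta = {r.individual_id: (r.genotype, r.sex) for r in fit_all.records}
    genotypes = np.array([meta[i][0] for i in ind_ids])
    sexes = np.array([meta[i][1] for i in ind_ids])
    ind_log_cs = sizes.groupby("individual")["log_cs"].mean().reindex(ind_ids).to_numpy()

    shape_scores = ind_scores
    if config.allometry_correct:
        shape_scores = procrustes.allometry_regression(ind_scores, ind_log_cs).residuals
    # multivariate tests need an invertible within-group covariance: keep only
    # as many leading PCs as the individual-level sample can support
    max_dim = max(1, len(ind_ids) - len(cells_per_group) - 1)
    if shape_scores.shape[1] > max_dim:
        log.info("restricting multivariate analyses to %d leading PCs", max_dim)
        shape_scores = shape_scores[:, :max_dim]

    # --- group-effect tests (genotype x sex) ---------------------------
    results["_stage"] = "group_tests"
    emit(asymmetry.group_tests(ind_log_cs, genotypes, sexes), "group_tests_size.csv")
    emit(
        asymmetry.group_tests(shape_scores, genotypes, sexes),
        "group_tests_shape.csv",
    )

    # --- CVA ------------------------------------------------------------
    results["_stage"] = "cva"
    cva_res = procrustes.cva(shape_scores, genotypes)
    emit(
        pd.DataFrame(
            {
                "individual": ind_ids,
                "genotype": genotypes,
                "sex": sexes,
                **{
                    f"CV{j + 1}": cva_res.canonical_scores[:, j]
                    for j in range(cva_res.canonical_scores.shape[1])
                },
            }
        ),
        "cva_scores.csv",
    )

    # --- per-group sides ANOVAs, FA indices, fold comparisons -----------
    results["_stage"] = "fa_indices"
    fa_rows = []
    fa_by_cell: dict[tuple[str, str], dict] = {}
    fams_by_sex: dict[str, list[patterns.FAPatternMatrix]] = {}
    for genotype, sex in cells_per_group:
        label = f"{genotype}:{sex}"
        ssub = sizes[(sizes.genotype == genotype) & (sizes.sex == sex)]
        anova_size = asymmetry.sides_anova_univariate(
            ssub.log_cs.to_numpy(),
            ssub.individual.to_numpy(),
            ssub.side.to_numpy(),
            ssub.replicate.to_numpy(),
            trait="log centroid size",
        )
        emit(anova_size.to_frame(scale=SIZE_SCALE), f"anova_size_{genotype}_{sex}.csv")
        # group-wise shape statistics share the common superimposition so
        # FA matrices of different groups are directly comparable
        fit_g = fit_all.subset(genotype=genotype, sex=sex)
        space_g = space_all
        anova_shape = asymmetry.procrustes_anova(fit_g)
        emit(anova_shape.to_frame(scale=SHAPE_SCALE), f"anova_shape_{genotype}_{sex}.csv")
        if config.fa_index == "fa10":
            fa_size = asymmetry.fa10(anova_size, genotype=genotype, sex=sex)
            fa_shape = asymmetry.fa10(anova_shape, genotype=genotype, sex=sex)
        else:
            means = (
                ssub.groupby(["individual", "side"])["log_cs"].mean().unstack()
            )
            fa_size = asymmetry.fa4(
                means["R"].to_numpy(), means["L"].to_numpy(),
                trait="log centroid size", genotype=genotype, sex=sex,
            )
            diffs, _, _ = patterns.fa_components(fit_g, space_g)
            fa_shape = asymmetry.FAEstimate(
                index="FA4",
                value=float(np.trace(np.cov(diffs.T))),
                trait="shape", genotype=genotype, sex=sex,
                n=diffs.shape[0], df=diffs.shape[0] - 1,
            )
        fam = patterns.fa_covariance_matrix(fit_g, space_g, source=label)
        fams_by_sex.setdefault(sex, []).append(fam)
        fa_by_cell[(genotype, sex)] = {
            "size": fa_size,
            "shape": fa_shape,
            "anova_size": anova_size,
            "fam": fam,
            "space": space_g,
        }
        fa_rows.append(
            {
                "genotype": genotype,
                "sex": sex,
                "index": fa_size.index,
                "fa_size_x1e5": fa_size.value * SIZE_SCALE,
                "fa_shape_x1e7": fa_shape.value * SHAPE_SCALE,
                "side_p_size": anova_size["Side"].p,
                "n": fa_size.n,
            }
        )
    emit(pd.DataFrame(fa_rows), "fa_estimates.csv")

    comp_rows = []
    for genotype, sex in cells_per_group:
        if genotype == config.control_genotype:
            continue
        if (config.control_genotype, sex) not in fa_by_cell:
            continue
        for trait_name in ("size", "shape"):
            a = fa_by_cell[(genotype, sex)][trait_name]
            b = fa_by_cell[(config.control_genotype, sex)][trait_name]
            cmp_res = asymmetry.compare_fa(a, b)
            comp_rows.append(
                {
                    "genotype": genotype,
                    "sex": sex,
                    "trait": trait_name,
                    "fa_ratio": cmp_res.fa_ratio,
                    "F": cmp_res.f,
                    "p": cmp_res.p_raw,
                }
            )
    comp = pd.DataFrame(comp_rows)
    if len(comp):
        comp["p_holm"] = asymmetry.holm_adjust(comp["p"].fillna(1.0).to_numpy())
        comp["sig"] = [significance_stars(p) for p in comp["p_holm"]]
    emit(comp, "fa_comparisons.csv")
    results["fa_ratios"] = {
        f"{r.genotype}:{r.sex}:{r.trait}": float(r.fa_ratio)
        for r in comp.itertuples()
        if r.fa_ratio == r.fa_ratio
    }

    # --- FA-pattern angle tests per sex ---------------------------------
    results["_stage"] = "patterns"
    prng = np.random.default_rng(stage_seed["patterns"])
    for sex, fams in fams_by_sex.items():
        if len(fams) < 2:
            continue
        table = patterns.compare_fa_patterns(
            fams,
            n_draws=config.n_draws,
            n_boot=config.n_boot,
            seed=int(prng.integers(2**31)),
        )
        emit(table, f"fa_pattern_angles_{sex}.csv")
        results.setdefault("fa_pattern_angles", {})[sex] = {
            f"{r.a}|{r.b}": float(r.angle_deg) for r in table.itertuples()
        }

    # --- cellular analyses ----------------------------------------------
    results["_stage"] = "cells"
    if config.cell_data:
        crng = np.random.default_rng(stage_seed["cells"])
        genos = list(dict.fromkeys(g for g, _ in cells_per_group))
        cell_arrays = {}
        cs_list, cn_list, glabels = [], [], []
        for genotype in genos:
            pars = simulate.CellDataParams(
                genotype=genotype,
                compensation=-0.8 if genotype == config.control_genotype else -0.1,
                fa_size_sigma=0.01 if genotype == config.control_genotype else 0.05,
            )
            data = simulate.simulate_cell_dataset(pars, crng)
            cell_arrays[genotype] = data
            both = np.concatenate([data["cell_size_l"], data["cell_size_r"]])
            cs_list.append((data["cell_size_l"] + data["cell_size_r"]) / 2)
            cn_list.append((data["cell_number_l"] + data["cell_number_r"]) / 2)
            glabels.append(np.repeat(genotype, len(both) // 2))
        report = cells.residual_variance_analysis(
            np.concatenate(cs_list), np.concatenate(cn_list), np.concatenate(glabels)
        )
        emit(report.correlations, "cell_compensation_r.csv")
        emit(report.z_comparisons, "cell_compensation_z.csv")
        emit(report.residual_variances, "cell_residual_variance.csv")
        emit(report.pairwise_f, "cell_residual_variance_f.csv")
        results["cell_compensation_r"] = {
            r.group: float(r.r) for r in report.correlations.itertuples()
        }
        cfa_rows = []
        for genotype, data in cell_arrays.items():
            cfa = cells.cellular_fa(
                data["cell_size_r"], data["cell_size_l"],
                data["cell_number_r"], data["cell_number_l"],
                data["wing_size_r"], data["wing_size_l"],
                genotype=genotype,
            )
            cfa_rows.append(
                {
                    "genotype": genotype,
                    "fa4_cell_size": cfa.fa4_cell_size.value,
                    "fa4_cell_number": cfa.fa4_cell_number.value,
                    "r_cellsizeFA_wingsizeFA": cfa.correlations.iloc[0]["pearson_r"],
                    "r_cellnumberFA_wingsizeFA": cfa.correlations.iloc[1]["pearson_r"],
                }
            )
        emit(pd.DataFrame(cfa_rows), "cellular_fa.csv")

    # --- figures ---------------------------------------------------------
    results["_stage"] = "figures"
    if config.make_figures:
        _figures(out, manifest, cva_res, genotypes, fams_by_sex, fa_by_cell, fit_all)

    # --- results + manifest ----------------------------------------------
    results.pop("_stage", None)
    results_path = out / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    manifest.append("results.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"outputs": sorted(manifest)}, fh, indent=2)
    log.info("wrote %d outputs to %s", len(manifest) + 1, out)
    return results


def _figures(out, manifest, cva_res, genotypes, fams_by_sex, fa_by_cell, fit_all):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # CVA scatter
    fig, ax = plt.subplots(figsize=(5, 4))
    nax = cva_res.canonical_scores.shape[1]
    for g in cva_res.groups:
        mask = genotypes == g
        ax.scatter(
            cva_res.canonical_scores[mask, 0],
            cva_res.canonical_scores[mask, 1] if nax > 1 else np.zeros(mask.sum()),
            s=12, label=str(g), alpha=0.7,
        )
    ax.set_xlabel("CV1")
    ax.set_ylabel("CV2" if nax > 1 else "")
    ax.legend(fontsize=8)
    fig.savefig(out / "cva_scatter.svg", bbox_inches="tight")
    plt.close(fig)
    manifest.append("cva_scatter.svg")

    # FA eigenvalue histograms + PC1 deformation per group
    for (genotype, sex), entry in fa_by_cell.items():
        fam, space = entry["fam"], entry["space"]
        spec = patterns.fa_pca(fam, space)
        fig, (a1, a2) = plt.subplots(1, 2, figsize=(8, 3))
        a1.bar(np.arange(1, len(spec.clipped) + 1), spec.clipped, color="0.4")
        a1.set_xlabel("FA PC")
        a1.set_ylabel("eigenvalue")
        a1.set_title(f"{genotype} {sex}", fontsize=9)
        cons = fit_all.consensus
        disp = spec.pc1_displacement
        scale = 0.1 / max(np.abs(disp).max(), 1e-12)
        a2.plot(cons[:, 0], cons[:, 1], "o", ms=3, color="0.6")
        deformed = cons + scale * disp
        a2.plot(deformed[:, 0], deformed[:, 1], "o", ms=3, color="tab:red")
        for p, q in zip(cons, deformed):
            a2.plot([p[0], q[0]], [p[1], q[1]], "-", lw=0.8, color="tab:red")
        a2.set_aspect("equal")
        a2.set_title("FA PC1 shape change", fontsize=9)
        name = f"fa_spectrum_{genotype}_{sex}.svg"
        fig.savefig(out / name, bbox_inches="tight")
        plt.close(fig)
        manifest.append(name)
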