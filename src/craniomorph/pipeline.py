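"""End-to-end analysis pipeline: imputation -> GPA -> statistics -> trees.

One invocation processes one anatomical unit (crania and mandibles are
never merged).  Products mirror the study design of a diachronic
biodistance analysis: centroid-size ANOVA with Tukey HSD, total and
between-group PCA, MANOVA over several grouping schemes (cultural
horizons with and without the hunter-gatherer sample; dietary groups;
farmers merged), among-group Mahalanobis distances, and a bootstrapped
Neighbor-Joining tree, plus allometric regressions of PC scores on
centroid size.  A machine-readable run log records seed, versions and
per-stage checksums so reruns can be diffed cheaply.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gpa import ProcrustesResult, symmetric_gpa
from .group_stats import (
    GroupDistanceMatrix,
    ManovaResult,
    mahalanobis_matrix,
    manova,
    size_anova,
    tukey_hsd,
)
from .impute import impute_dataset
from .landmarks import (
    LandmarkSet,
    SymmetryScheme,
    filter_missingness,
    read_table,
    read_tps,
    stacked_coords,
    write_tps,
)
from .nj_trees import (
    NJTree,
    bootstrap_supports,
    stratified_score_resampler,
    to_newick,
)
from .ordination import (
    ShapeOrdination,
    allometry_regression,
    between_group_pca,
    retain_for_variance,
    total_pca,
)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (one anatomical unit)."""

    input_path: str | Path
    scheme_path: str | Path | None = None
    anatomical_unit: str = "cranium"
    input_format: str = "auto"  # "tps" | "csv" | "auto"
    variance_threshold: float = 0.95
    bootstrap_reps: int = 1000
    seed: int = 0
    output_dir: str | Path = "pipeline_out"
    max_missing_frac: float = 0.20
    exclude_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "exclude_groups" in data:
            data["exclude_groups"] = tuple(data["exclude_groups"])
        return cls(**data)


@dataclass
class PipelineReport:
    """All products of one run, as in-memory objects."""

    specimens: list[LandmarkSet]
    excluded: list[LandmarkSet]
    procrustes: ProcrustesResult
    groups: np.ndarray
    anova: tuple[float, float]
    tukey: pd.DataFrame
    total_ordination: ShapeOrdination
    retained_scores: np.ndarray
    bg_ordination: ShapeOrdination
    manova_table: pd.DataFrame
    mahalanobis: GroupDistanceMatrix
    tree: NJTree
    newick: str
    allometry: pd.DataFrame
    allometry_r2: float
    log: dict = field(default_factory=dict)


_MANOVA_ROWS = (
    ("Cultural groups", "All samples"),
    ("Cultural groups", "Without Mesolithic sample"),
    ("Dietary groups", "All groups (HG, EF, F)"),
    ("Dietary groups", "Farmers combined (HG, F)"),
    ("Dietary groups", "Without HG sample (EF, F)"),
)


def manova_grouping_table(
    scores: np.ndarray, groups: Sequence[str], diets: Sequence[str]
) -> pd.DataFrame:
    """MANOVA over the standard grouping schemes and sample subsets.

    Rows: cultural groups (all; without the hunter-gatherer horizon) and
    dietary groups (HG/EF/F; HG vs all farmers; EF vs F only).
    """
    groups = np.asarray(groups)
    diets = np.asarray(diets)
    rows = []
    for grouping, subset in _MANOVA_ROWS:
        if grouping == "Cultural groups":
            labels = groups
            keep = (
                np.ones(len(groups), bool)
                if subset == "All samples"
                else groups != "Mesolithic"
            )
        else:
            labels = diets.copy()
            keep = np.ones(len(groups), bool)
            if subset == "Farmers combined (HG, F)":
                labels = np.where(labels == "HG", "HG", "F")
            elif subset == "Without HG sample (EF, F)":
                keep = diets != "HG"
        if len(np.unique(labels[keep])) < 2:
            continue
        res: ManovaResult = manova(
            scores[keep], labels[keep], grouping=grouping, subset=subset
        )
        rows.append(
            {
                "grouping": grouping,
                "subset": subset,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
                "wilks_lambda": res.wilks_lambda,
                "q_used": res.q_used,
            }
        )
    return pd.DataFrame(rows)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run(config: PipelineConfig) -> PipelineReport:
    """Execute the full pipeline and write all artifacts to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "stages": {},
    }

    def stage(name):
        def fail(exc):
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return fail

    # --- load -------------------------------------------------------------
    path = Path(config.input_path)
    fmt = config.input_format
    if fmt == "auto":
        fmt = "tps" if path.suffix.lower() == ".tps" else "csv"
    try:
        sets = read_tps(path) if fmt == "tps" else read_table(path)
    except Exception as exc:  # noqa: BLE001
        stage("load")(exc)
    if config.exclude_groups:
        sets = [s for s in sets if s.group not in config.exclude_groups]
    scheme = (
        SymmetryScheme.from_yaml(config.scheme_path)
        if config.scheme_path
        else None
    )
    if scheme is None:
        from .synthetic import default_scheme

        scheme = default_scheme(config.anatomical_unit)

    # --- filter + impute --------------------------------------------------
    try:
        kept, excluded = filter_missingness(sets, config.max_missing_frac)
        complete = impute_dataset(kept, scheme)
    except Exception as exc:  # noqa: BLE001
        stage("imputation")(exc)
    log["stages"]["n_kept"] = len(kept)
    log["stages"]["n_excluded"] = len(excluded)

    # --- GPA + symmetric component ----------------------------------------
    try:
        configs = stacked_coords(complete)
        proc = symmetric_gpa(configs, scheme)
    except Exception as exc:  # noqa: BLE001
        stage("gpa")(exc)
    groups = np.array([s.group for s in complete])
    diets = np.array([s.diet for s in complete])
    log["stages"]["gpa_checksum"] = _checksum(proc.tangent_coords)

    # --- size statistics ---------------------------------------------------
    try:
        anova_res = size_anova(proc.centroid_sizes, groups)
        tukey_res = tukey_hsd(proc.centroid_sizes, groups)
    except Exception as exc:  # noqa: BLE001
        stage("size_stats")(exc)

    # --- ordination ---------------------------------------------------------
    try:
        tot = total_pca(proc.tangent_coords)
        scores = retain_for_variance(tot, config.variance_threshold)
        bg = between_group_pca(proc.tangent_coords, groups)
    except Exception as exc:  # noqa: BLE001
        stage("ordination")(exc)
    log["stages"]["pca_checksum"] = _checksum(scores)

    # --- group statistics ---------------------------------------------------
    try:
        manova_df = manova_grouping_table(scores, groups, diets)
        maha = mahalanobis_matrix(scores, groups)
    except Exception as exc:  # noqa: BLE001
        stage("group_stats")(exc)
    log["stages"]["mahalanobis_checksum"] = _checksum(maha.D)

    # --- trees ---------------------------------------------------------------
    try:
        resampler = stratified_score_resampler(
            proc.tangent_coords, groups, config.variance_threshold
        )
        tree = bootstrap_supports(
            maha, resampler, n_reps=config.bootstrap_reps, seed=config.seed
        )
        newick = to_newick(tree)
    except Exception as exc:  # noqa: BLE001
        stage("nj_tree")(exc)

    # --- allometry -----------------------------------------------------------
    try:
        allo_df, allo_r2 = allometry_regression(scores, proc.centroid_sizes)
    except Exception as exc:  # noqa: BLE001
        stage("allometry")(exc)

    report = PipelineReport(
        specimens=complete,
        excluded=excluded,
        procrustes=proc,
        groups=groups,
        anova=anova_res,
        tukey=tukey_res,
        total_ordination=tot,
        retained_scores=scores,
        bg_ordination=bg,
        manova_table=manova_df,
        mahalanobis=maha,
        tree=tree,
        newick=newick,
        allometry=allo_df,
        allometry_r2=allo_r2,
        log=log,
    )
    _write_artifacts(report, config, out, scheme)
    return report


def _write_artifacts(
    report: PipelineReport, config: PipelineConfig, out: Path, scheme: SymmetryScheme
) -> None:
    unit = config.anatomical_unit
    proc = report.procrustes

    sizes = pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in report.specimens],
            "group": report.groups,
            "centroid_size": proc.centroid_sizes,
        }
    )
    sizes.to_csv(out / f"{unit}_centroid_sizes.csv", index=False)

    f_stat, p = report.anova
    (out / f"{unit}_size_anova.tsv").write_text(f"F\tp\n{f_stat:.6g}\t{p:.6g}\n")
    report.tukey.to_csv(out / f"{unit}_size_tukey.tsv", sep="\t", index=False)

    aligned_flat = proc.aligned.reshape(proc.n, -1)
    cols = [f"{ax}{j + 1}" for j in range(proc.k) for ax in "xyz"]
    aligned_df = pd.DataFrame(aligned_flat, columns=cols)
    aligned_df.insert(0, "specimen_id", [s.specimen_id for s in report.specimens])
    aligned_df.to_csv(out / f"{unit}_aligned.csv", index=False)
    write_tps(
        [
            LandmarkSet(
                specimen_id=f"{unit}_mean_shape",
                coords=proc.mean_shape,
                missing=np.zeros(proc.k, bool),
            )
        ],
        out / f"{unit}_mean_shape.tps",
    )

    bg = report.bg_ordination
    scatter = pd.DataFrame(
        {
            "axis1": bg.scores[:, 0],
            "axis2": bg.scores[:, 1] if bg.p > 1 else 0.0,
            "group": report.groups,
        }
    )
    scatter.to_csv(out / f"{unit}_bgpca_scores.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "eigenvalue": bg.eigenvalues,
            "between_group_fraction": bg.variance_fraction,
            "total_variance_fraction": bg.eigenvalues / bg.total_variance,
        }
    ).to_csv(out / f"{unit}_bgpca_eigenvalues.tsv", sep="\t", index=False)

    report.manova_table.to_csv(out / f"{unit}_manova.tsv", sep="\t", index=False)
    report.mahalanobis.to_tsv(out / f"{unit}_mahalanobis.tsv")
    (out / f"{unit}_nj_tree.nwk").write_text(report.newick + "\n")
    supports = pd.DataFrame(
        [
            {"bipartition": "|".join(sorted(bp)), "support_pct": pct}
            for bp, pct in sorted(
                report.tree.supports.items(), key=lambda kv: -kv[1]
            )
        ]
    )
    supports.to_csv(out / f"{unit}_bootstrap_bipartitions.tsv", sep="\t", index=False)
    report.allometry.assign(multivariate_r2=report.allometry_r2).to_csv(
        out / f"{unit}_allometry.tsv", sep="\t", index=False
    )
    (out / f"{unit}_run_log.json").write_text(json.dumps(report.log, indent=2))


def compare_units(
    cranial: PipelineReport, mandibular: PipelineReport
) -> pd.DataFrame:
    """Side-by-side comparison of distance structure across anatomical units."""
    rows = []
    for rep, unit in ((cranial, "cranium"), (mandibular, "mandible")):
        frame = rep.mahalanobis.to_frame()
        for a in frame.index:
            for b in frame.columns:
                if a < b:
                    rows.append(
                        {"unit": unit, "group_a": a, "group_b": b,
                         "mahalanobis": frame.loc[a, b]}
                    )
    return pd.DataFrame(rows)
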