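"""End-to-end analysis pipeline: grids -> indices -> classes -> statistics
-> strategy clusters -> colonization maps.

``run_pipeline`` orchestrates every stage on either a grid-table CSV or a
named simulation preset and writes a reproducible report bundle: the
index table, a class summary with ANOVA/LSD letters, the five canonical
regressions, PCA and NMDS ordination scores, the cluster centroid table,
one representative map per cluster, and a run log recording the seed,
versions, and per-stage record counts. All outputs are deterministic for a
fixed seed (no timestamps), so two runs of the same config are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import grid_model, indices, strategy_stats, synthetic_data
from .grid_model import GRID_TABLE_COLUMNS, GRID_SIZE, ColonizationGrid, StructureCode

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one analysis run.

    Exactly one of ``input_path`` (grid-table CSV) or ``preset`` (simulation
    preset name) selects the data source.
    """

    out_dir: str | Path = "mycopattern_report"
    input_path: str | Path | None = None
    preset: str | None = "festuca_like"
    alpha: float = 0.05
    k_clusters: int = 9
    seed: int = 0
    histogram_solutions: tuple[str, ...] = ("best_fitted", "class_restricted")
    rounding: int = 2

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path or preset is required")


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(path: str | Path) -> ValidationReport:
    """Check a grid-table CSV: schema, code/index ranges, duplicate cells,
    and completeness of the sampling design.

    Range and duplicate violations are errors (with file line numbers);
    an incomplete design (e.g. a missing field within a segment) is only a
    warning — statistics pool whatever was observed.
    """
    report = ValidationReport()
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GRID_TABLE_COLUMNS if c not in df.columns]
    if missing:
        report.errors.append(f"missing columns: {missing}")
        return report
    lines = df.index + 2
    bad = ~df["code"].between(0, int(max(StructureCode)))
    for ln in lines[bad]:
        report.errors.append(f"line {ln}: code outside 0-6")
    for col in ("row", "col"):
        bad = ~df[col].between(1, GRID_SIZE)
        for ln in lines[bad]:
            report.errors.append(f"line {ln}: {col} outside 1-{GRID_SIZE}")
    key = ["replication", "segment", "field", "row", "col"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        report.errors.append(f"duplicate cell entries at lines {lines[dup].tolist()}")

    # design-completeness: each (replication, segment) should carry the same
    # number of fields, and each replication the same number of segments
    obs = df[["replication", "segment", "field"]].drop_duplicates()
    fields_per_seg = obs.groupby(["replication", "segment"])["field"].nunique()
    if fields_per_seg.nunique() > 1:
        mode = int(fields_per_seg.mode().iloc[0])
        for (rep, seg), nf in fields_per_seg.items():
            if nf != mode:
                report.warnings.append(
                    f"replication {rep} segment {seg}: {nf} fields (expected {mode}); "
                    "design incomplete"
                )
    segs_per_rep = obs.groupby("replication")["segment"].nunique()
    if segs_per_rep.nunique() > 1:
        mode = int(segs_per_rep.mode().iloc[0])
        for rep, ns in segs_per_rep.items():
            if ns != mode:
                report.warnings.append(
                    f"replication {rep}: {ns} segments (expected {mode}); design incomplete"
                )
    return report


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_grids(config: PipelineConfig) -> list[ColonizationGrid]:
    if config.input_path is not None:
        report = validate_inputs(config.input_path)
        if not report.ok:
            raise PipelineError(f"stage load: invalid input: {report.errors}")
        return grid_model.read_grid_table(config.input_path)
    sim = replace(synthetic_data.preset(config.preset), seed=config.seed)
    return synthetic_data.simulate_dataset(sim)


def _segment_means(df: pd.DataFrame) -> pd.DataFrame:
    seg = (
        df.groupby(["replication", "segment"], sort=True)[indices.INDEX_COLUMNS]
        .mean()
        .reset_index()
    )
    return seg


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every analysis stage and write the report bundle; returns the
    output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nd = config.rounding
    log_lines = [
        f"mycopattern pipeline, seed={config.seed}",
        f"source={'preset:' + config.preset if config.preset else config.input_path}",
        f"alpha={config.alpha} k_clusters={config.k_clusters} rounding={nd}",
    ]
    import sklearn, scipy, statsmodels
    from . import __version__
    log_lines.append(
        f"versions: mycopattern={__version__} numpy={np.__version__} "
        f"pandas={pd.__version__} scipy={scipy.__version__} "
        f"sklearn={sklearn.__version__} statsmodels={statsmodels.__version__}"
    )

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrap

    grids = stage("load")(_load_grids, config)
    log_lines.append(f"observations={len(grids)}")

    records = stage("indices")(lambda gs: [indices.compute_indices(g) for g in gs], grids)
    df = indices.records_to_frame(records)
    df.to_csv(out / "index_table.csv", index=False)  # full precision
    seg_df = _segment_means(df)
    log_lines.append(
        f"segments={len(seg_df)} replications={df['replication'].nunique()}"
    )

    # histograms
    hist_rows = []
    for param in indices.INDEX_COLUMNS:
        for sol in config.histogram_solutions:
            h = stage("histograms")(strategy_stats.histogram, df, param, sol)
            for lo, hi, cnt in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
                hist_rows.append((param, sol, round(lo, 6), round(hi, 6), int(cnt)))
    pd.DataFrame(
        hist_rows, columns=["parameter", "solution", "bin_lo", "bin_hi", "count"]
    ).to_csv(out / "histograms.csv", index=False)

    # class summary with ANOVA/LSD letters (Table-1 style)
    n_classes = df["freq_class"].nunique()
    summary_rows = []
    for param in indices.INDEX_COLUMNS:
        if n_classes >= 2:
            res = stage("anova")(strategy_stats.anova_lsd, df, param, config.alpha)
            for cls in sorted(res.means):
                summary_rows.append(
                    (cls, param, round(res.means[cls], nd), round(res.ses[cls], nd),
                     res.letters[cls], res.ns[cls])
                )
            summary_rows.append(
                ("F_test", param, round(res.f_statistic, nd),
                 round(res.p_value, 4), "", sum(res.ns.values()))
            )
        else:
            for agg in indices.aggregate(df, by="freq_class"):
                summary_rows.append(
                    (agg.key, param, round(agg.means[param], nd),
                     round(agg.ses[param], nd), "a", agg.n)
                )
    pd.DataFrame(
        summary_rows, columns=["class", "parameter", "mean", "se", "letter", "n"]
    ).to_csv(out / "class_summary.csv", index=False)

    # regressions (five canonical pairs); a zero-variance predictor (e.g.
    # every grid saturated) makes that pair inestimable and it is skipped
    reg_rows = []
    for x, y in strategy_stats.REGRESSION_PAIRS:
        if np.ptp(df[x].to_numpy()) == 0.0:
            logger.warning("regression %s->%s skipped: zero predictor variance", x, y)
            log_lines.append(f"regression {x}->{y}=skipped (zero predictor variance)")
            continue
        r = stage("regressions")(strategy_stats.fit_regression, df, x, y)
        reg_rows.append(
            (x, y, round(r.intercept, 4), round(r.slope, 4),
             round(r.r_squared, 4), round(r.resid_std, 4), r.n)
        )
    pd.DataFrame(
        reg_rows,
        columns=["predictor", "response", "intercept", "slope", "r_squared",
                 "resid_std", "n"],
    ).to_csv(out / "regressions.csv", index=False)

    # ordination: PCA per observation, NMDS on segment means. Degenerate
    # data (e.g. every grid saturated) make ordination meaningless; such a
    # stage is skipped with a note rather than aborting the run.
    try:
        p = stage("pca")(strategy_stats.pca, df)
        pca_scores = df[["replication", "segment", "field"]].copy()
        pca_scores["axis1"] = np.round(p.scores[:, 0], 6)
        pca_scores["axis2"] = np.round(p.scores[:, 1], 6)
        pca_scores.to_csv(out / "pca_scores.csv", index=False)
        with open(out / "pca_variance.csv", "w") as fh:
            fh.write("axis,variance_pct\n")
            for i, v in enumerate(p.variance_pct, start=1):
                fh.write(f"{i},{round(float(v), 4)}\n")
    except PipelineError as exc:
        if "degenerate" not in str(exc):
            raise
        logger.warning("PCA skipped: %s", exc)
        log_lines.append("pca=skipped (degenerate data)")
        (out / "pca_scores.csv").write_text("replication,segment,field,axis1,axis2\n")
        (out / "pca_variance.csv").write_text("axis,variance_pct\n")

    try:
        m = stage("nmds")(strategy_stats.nmds, seg_df, seed=config.seed)
        nmds_scores = seg_df[["replication", "segment"]].copy()
        nmds_scores["axis1"] = np.round(m.scores[:, 0], 6)
        nmds_scores["axis2"] = np.round(m.scores[:, 1], 6)
        nmds_scores.to_csv(out / "nmds_scores.csv", index=False)
        log_lines.append(f"nmds_stress={round(m.stress, 4)}")
    except PipelineError as exc:
        if "degenerate" not in str(exc):
            raise
        logger.warning("NMDS skipped: %s", exc)
        log_lines.append("nmds=skipped (degenerate data)")
        (out / "nmds_scores.csv").write_text("replication,segment,axis1,axis2\n")

    # strategy clustering on segment means (Table-2 style centroids)
    clusters = stage("clustering")(
        strategy_stats.cluster_strategies, seg_df, config.k_clusters
    )
    cent = strategy_stats.centroid_table(clusters).round(nd)
    cent.to_csv(out / "cluster_centroids.csv")
    log_lines.append(f"clusters={len(clusters)}")

    # representative map per cluster
    report = stage("maps")(strategy_stats.strategy_report, clusters, grids)
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for cid in sorted(report.maps, key=lambda s: int(s[1:])):
        cmap = report.maps[cid]
        if cmap is None:
            (maps_dir / f"{cid}.txt").write_text("no grid data for this cluster\n")
            continue
        grid_model.export_map_image(cmap, maps_dir / f"{cid}.png", "png")
        grid_model.export_map_image(cmap, maps_dir / f"{cid}.txt", "text")
    reps = pd.DataFrame(
        [
            (cid, *(report.representatives[cid] or ("", "", "")))
            for cid in sorted(report.representatives, key=lambda s: int(s[1:]))
        ],
        columns=["cluster", "replication", "segment", "field"],
    )
    reps.to_csv(out / "cluster_representatives.csv", index=False)

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
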