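"""End-to-end experiment orchestration: inputs -> linkage -> features ->
penalized regression -> metrics and TF report, with an optional null-model
arm that reruns the identical pipeline on distance-preserving loop shuffles.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import features as feat
from . import genome_model as gm
from . import linkage
from .learning import (
    CVResult,
    build_feature_matrix,
    default_alpha_grid,
    fit_elastic_net_cv,
    preprocess,
)
from .interpretation import mean_fold_coefficients, nonzero_features, rank_tfs
from .null_models import ShuffleSpec, shuffle_loops

__all__ = ["RunConfig", "ExperimentResult", "run_pipeline", "run_experiment", "compare_setups"]

KEPT_STATES_DEFAULT = frozenset({"TssA", "TssAFlnk", "EnhG", "Enh", "BivFlnk", "EnhBiv"})


@dataclass
class RunConfig:
    """Everything one experiment needs; serialized next to its outputs."""

    setup: str = "Promoter:Peaks"
    paradigm: str = "window"  # or "nearest"
    window_size: int = 3000
    loop_search_window: int = 5000
    d0: float = 5000.0
    tf_decay: bool = False  # decay TF promoter scores (50 kb-window variant)
    use_chromhmm: bool = False
    kept_states: frozenset = KEPT_STATES_DEFAULT
    resolution_filter: str = "All"
    pet_min: int = 0
    q_max: float = 1.0
    alpha_step: float = 0.01
    n_lambda: int = 100
    n_outer: int = 10
    n_inner: int = 6
    null_replicates: int = 0
    seed: int = 0
    # input paths (optional when running on in-memory objects)
    annotation: str | None = None
    peaks: str | None = None
    loops: str | None = None
    chromhmm: str | None = None
    psems: str | None = None
    genome: str | None = None
    affinity_table: str | None = None
    expression: str | None = None
    outdir: str | None = None

    def validate(self) -> None:
        from .learning import FEATURE_SETUPS

        if self.setup not in FEATURE_SETUPS:
            raise ValueError(f"unknown setup {self.setup!r}")
        if self.paradigm not in ("window", "nearest"):
            raise ValueError("paradigm must be 'window' or 'nearest'")
        if self.window_size <= 0 or self.loop_search_window <= 0 or self.d0 <= 0:
            raise ValueError("window sizes and d0 must be positive")
        needs_loops = self.setup in (
            "Promoter+Loops:Peaks",
            "Promoter+Loops:CPeaks",
            "ExtendedFeatureSpace",
        )
        if needs_loops and self.loops is None and self.annotation is not None:
            raise ValueError(f"setup {self.setup!r} requires a loop file")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["kept_states"] = sorted(self.kept_states)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "kept_states" in d:
            d["kept_states"] = frozenset(d["kept_states"])
        return cls(**d)


@dataclass
class ExperimentResult:
    config: RunConfig
    cv: CVResult
    metrics: pd.DataFrame  # one row per outer fold
    mean_coefficients: pd.Series
    feature_matrix_shape: tuple[int, int]
    null_metrics: pd.DataFrame | None = None
    null_comparison: dict | None = None

    @property
    def median_spearman(self) -> float:
        return float(np.nanmedian(self.cv.test_spearmans))


def _assignments(
    genes: Sequence[gm.Gene],
    peaks: Sequence[gm.Peak],
    loops: Sequence[gm.ChromatinLoop] | None,
    segments: Sequence[gm.ChromHMMSegment] | None,
    config: RunConfig,
):
    """Promoter and distal peak assignments under the configured paradigm."""
    if config.paradigm == "window":
        prom = linkage.window_linkage(genes, peaks, config.window_size)
        seg_assign = (
            linkage.assign_segments_window(genes, segments, config.window_size)
            if segments
            else None
        )
    else:
        prom, _ = linkage.nearest_gene_linkage(genes, peaks)
        seg_assign = (
            linkage.assign_segments_nearest(genes, segments) if segments else None
        )
    if config.use_chromhmm and seg_assign is not None:
        prom = linkage.chromhmm_filter(prom, seg_assign)

    distal: dict[str, list[linkage.AssignedPeak]] = {}
    if loops:
        windows = linkage.loop_linkage(genes, loops, config.loop_search_window)
        for g in genes:
            aps = linkage.distal_peak_assignment(
                g,
                windows.get(g.gene_id, ()),
                peaks,
                (ap.peak for ap in prom.get(g.gene_id, ())),
            )
            if config.use_chromhmm and segments:
                segs = linkage.distal_segment_assignment(
                    windows.get(g.gene_id, ()), segments
                )
                tmp = linkage.chromhmm_filter(
                    linkage.GenePeakAssignment({g.gene_id: aps}), {g.gene_id: segs}
                )
                aps = tmp.get(g.gene_id, [])
            if aps:
                distal[g.gene_id] = aps
    return prom, distal


def run_pipeline(
    genes: Sequence[gm.Gene],
    peaks: Sequence[gm.Peak],
    expression: Mapping[str, float],
    config: RunConfig,
    loops: Sequence[gm.ChromatinLoop] | None = None,
    segments: Sequence[gm.ChromHMMSegment] | None = None,
    psems: Sequence[gm.PSEM] | None = None,
    affinities: pd.DataFrame | None = None,
) -> ExperimentResult:
    """The full in-memory experiment: features -> matrix -> nested CV fit."""
    config.validate()
    gm.check_chrom_consistency(
        genes=(g.chrom for g in genes),
        peaks=(p.interval.chrom for p in peaks),
        loops=(l.chrom for l in (loops or ())),
    )
    universe = [
        g for g in genes if g.gene_type == "protein_coding" and g.gene_id in expression
    ]
    missing = sum(1 for g in genes if g.gene_type == "protein_coding") - len(universe)
    if missing:
        warnings.warn(f"{missing} protein-coding gene(s) lack expression values; excluded")
    if not universe:
        raise ValueError("no gene has both annotation and expression")

    prom, distal = _assignments(universe, peaks, loops, segments, config)
    pf = feat.peak_feature_table(universe, prom, distal, d0=config.d0)

    tf_prom = tf_loop = None
    needs_tfs = config.setup in ("Promoter:Peaks+TFs", "ExtendedFeatureSpace")
    if needs_tfs:
        if affinities is None or psems is None:
            raise ValueError("TF setups need PSEMs and a per-peak affinity table")
        tf_prom, tf_loop = feat.tf_score_table(
            universe,
            prom,
            affinities,
            psems,
            distal,
            use_decay=config.tf_decay,
            d0=config.d0,
        )

    X = build_feature_matrix(config.setup, pf, tf_prom, tf_loop)
    y = pd.Series({g.gene_id: expression[g.gene_id] for g in universe}).reindex(X.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xp, yp, _dropped = preprocess(X, y)
    cv = fit_elastic_net_cv(
        Xp,
        yp,
        seed=config.seed,
        n_outer=config.n_outer,
        n_inner=config.n_inner,
        alpha_grid=default_alpha_grid(config.alpha_step),
        n_lambda=config.n_lambda,
    )
    metrics = pd.DataFrame(
        {
            "fold": range(len(cv.folds)),
            "alpha": [f.alpha for f in cv.folds],
            "lambda": [f.lam for f in cv.folds],
            "spearman": [f.test_spearman for f in cv.folds],
            "mse": [f.test_mse for f in cv.folds],
            "n_nonzero": [(f.coef != 0).sum() for f in cv.folds],
        }
    )
    return ExperimentResult(
        config=config,
        cv=cv,
        metrics=metrics,
        mean_coefficients=mean_fold_coefficients(cv),
        feature_matrix_shape=Xp.shape,
    )


def run_null_arm(
    result: ExperimentResult,
    genes: Sequence[gm.Gene],
    peaks: Sequence[gm.Peak],
    expression: Mapping[str, float],
    loops: Sequence[gm.ChromatinLoop],
    genome_sizes: Mapping[str, int],
    segments=None,
    psems=None,
    affinities=None,
) -> ExperimentResult:
    """Re-run the identical pipeline on each shuffled-loop replicate and
    compare the real fold Spearman distribution against the pooled null."""
    config = result.config
    spec = ShuffleSpec(
        genome_sizes=dict(genome_sizes),
        n_replicates=config.null_replicates,
        seed=config.seed,
        same_chromosome=True,
    )
    null_rows = []
    for i, rep in enumerate(shuffle_loops(loops, spec)):
        r = run_pipeline(
            genes,
            peaks,
            expression,
            dataclasses.replace(config, null_replicates=0),
            loops=rep,
            segments=segments,
            psems=psems,
            affinities=affinities,
        )
        for f, sp in enumerate(r.cv.test_spearmans):
            null_rows.append({"replicate": i, "fold": f, "spearman": sp})
    null_metrics = pd.DataFrame(null_rows)
    # a constant prediction vector has no rank association; score it 0 so
    # real-vs-null comparisons stay defined when a null model keeps no feature
    real = np.nan_to_num(result.cv.test_spearmans, nan=0.0)
    pooled = np.nan_to_num(null_metrics["spearman"].to_numpy(), nan=0.0)
    test = scipy.stats.mannwhitneyu(real, pooled, alternative="greater")
    result.null_metrics = null_metrics
    result.null_comparison = {
        "real_median": float(np.median(real)),
        "null_median": float(np.median(pooled)),
        "null_replicate_medians": [
            float(np.median(np.nan_to_num(g["spearman"].to_numpy(), nan=0.0)))
            for _, g in null_metrics.groupby("replicate")
        ],
        "p_greater": float(test.pvalue),
    }
    return result


def run_experiment(config: RunConfig) -> ExperimentResult:
    """File-based entry point: read inputs per the config, run, write outputs."""
    config.validate()
    if config.annotation is None or config.peaks is None or config.expression is None:
        raise ValueError("run_experiment needs annotation, peaks and expression paths")
    genes = gm.read_gene_annotation(config.annotation, "protein_coding")
    peaks = gm.read_peaks(config.peaks)
    expression = gm.read_expression(config.expression)
    loops = (
        gm.read_loops(
            config.loops,
            resolution_filter=config.resolution_filter,
            pet_min=config.pet_min,
            q_max=config.q_max,
        )
        if config.loops
        else None
    )
    segments = (
        gm.read_chromhmm(config.chromhmm, set(config.kept_states))
        if config.chromhmm
        else None
    )
    psems = gm.read_psems(config.psems) if config.psems else None
    affinities = None
    if config.affinity_table:
        affinities = pd.read_csv(config.affinity_table, sep="\t", index_col=0)
    elif psems and config.genome:
        from pyfaidx import Fasta

        fasta = Fasta(str(config.genome))
        sequences = {
            feat.peak_key(p): str(
                fasta[p.interval.chrom][p.interval.start : p.interval.end]
            )
            for p in peaks
        }
        affinities = feat.peak_affinity_table(sequences, psems)

    result = run_pipeline(
        genes,
        peaks,
        expression,
        config,
        loops=loops,
        segments=segments,
        psems=psems,
        affinities=affinities,
    )
    if config.null_replicates > 0 and loops:
        sizes = _genome_sizes_from_inputs(config, genes, peaks, loops)
        result = run_null_arm(
            result, genes, peaks, expression, loops, sizes, segments, psems, affinities
        )
    if config.outdir:
        write_outputs(result, config.outdir)
    return result


def _genome_sizes_from_inputs(config, genes, peaks, loops) -> dict[str, int]:
    if config.genome:
        from pyfaidx import Fasta

        fasta = Fasta(str(config.genome))
        return {name: len(fasta[name]) for name in fasta.keys()}
    sizes: dict[str, int] = {}
    for iv in (
        [g.interval for g in genes]
        + [p.interval for p in peaks]
        + [l.anchor1 for l in loops]
        + [l.anchor2 for l in loops]
    ):
        sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end + 10_000)
    return sizes


def write_outputs(result: ExperimentResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    result.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    result.cv.coef_matrix().T.to_csv(outdir / "coefficients.tsv", sep="\t")
    result.mean_coefficients.rename("mean_coef").to_csv(
        outdir / "mean_coefficients.tsv", sep="\t"
    )
    top = rank_tfs(result.mean_coefficients, top_k=20)
    top.to_csv(outdir / "tf_report.tsv", sep="\t")
    if result.null_metrics is not None:
        result.null_metrics.to_csv(outdir / "null_metrics.tsv", sep="\t", index=False)
        (outdir / "null_comparison.json").write_text(
            json.dumps(result.null_comparison, indent=2)
        )


def compare_setups(
    results: Mapping[str, ExperimentResult], reference: str
) -> pd.DataFrame:
    """Per-setup fold Spearman distributions with a paired Wilcoxon test
    against the reference setup (folds are paired through the shared seed)."""
    if reference not in results:
        raise ValueError(f"reference {reference!r} not among results")
    universes = {
        name: r.feature_matrix_shape[0] for name, r in results.items()
    }
    if len(set(universes.values())) > 1:
        raise ValueError(f"gene universes differ across runs: {universes}")
    ref = results[reference].cv.test_spearmans
    rows = []
    for name, r in results.items():
        sp = r.cv.test_spearmans
        if name == reference or np.allclose(sp, ref):
            p = 1.0
        else:
            p = float(scipy.stats.wilcoxon(sp, ref).pvalue)
        rows.append(
            {
                "setup": name,
                "median_spearman": float(np.nanmedian(sp)),
                "mean_spearman": float(np.nanmean(sp)),
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows).set_index("setup")
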