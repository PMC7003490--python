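"""Coherent toy regulatory datasets with a planted expression model.

The generator emits every input the pipeline consumes — genome FASTA, gene
annotation (GTF), accessibility peaks (narrowPeak), chromatin loops (BEDPE
with PET count and q-value), a chromatin-state segmentation (BED4), PSEMs
and an expression table — at a scale where the full pipeline runs in
seconds and with ground truth known exactly.

Expression is generated *through the pipeline's own feature definitions*: a
sparse set of TF-gene scores (promoter scores and undecayed loop scores,
exactly as the feature layer computes them) is combined linearly on the
log1p/standardized scale, Gaussian noise is added, and the result is
inverse-transformed to non-negative expression values.  Because the learner
applies the same transform, the planted coefficients are recoverable
exactly in the noise-free limit.

TF-specific signal is created by embedding each TF's consensus sequence
into a random subset of peaks, so TF-gene scores decorrelate across TFs
instead of all tracking total peak mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import genome_model as gm
from . import linkage
from .learning import build_feature_matrix, preprocess

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture", "worked_example"]

_BASES = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    ``noise_sd`` is the standard deviation of the log-scale expression noise
    *relative to* the planted signal's standard deviation, i.e. the
    signal-to-noise ratio is ``1 / noise_sd`` (default 0.2 -> SNR 5).
    ``planted_tf_effects`` maps ``(tf_name, context)`` with context in
    {"promoter", "loop"} to a coefficient; ``None`` plants five effects
    (three promoter, two loop) with alternating signs.
    """

    n_chroms: int = 4
    chrom_length: int = 2_500_000
    n_genes: int = 2000
    n_peaks: int = 8000
    n_loops: int = 1000
    n_tfs: int = 50
    planted_tf_effects: Mapping[tuple[str, str], float] | None = None
    noise_sd: float = 0.2
    seed: int = 0
    promoter_window: int = 3000
    loop_search_window: int = 5000
    anchor_width: int = 5000
    motif_embed_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_peaks", "n_loops", "n_tfs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_genes * 4000 > self.n_chroms * self.chrom_length:
            raise ValueError("placement too dense: need >=4 kb of chromosome per gene")


@dataclass
class FixtureBundle:
    """In-memory fixture plus (when written) the paths of the emitted files."""

    spec: FixtureSpec
    genes: list[gm.Gene]
    peaks: list[gm.Peak]
    loops: list[gm.ChromatinLoop]
    segments: list[gm.ChromHMMSegment]
    psems: list[gm.PSEM]
    expression: dict[str, float]
    genome: dict[str, np.ndarray]  # chrom -> uint8 base codes (ASCII)
    planted_effects: dict[tuple[str, str], float]
    truth: pd.DataFrame  # per-gene log-scale signal/noise decomposition
    affinities: pd.DataFrame = field(default_factory=pd.DataFrame)  # peak x TF
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def genome_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.genome.items()}

    def peak_sequences(self) -> dict[str, str]:
        out = {}
        for p in self.peaks:
            iv = p.interval
            out[feat.peak_key(p)] = self.genome[iv.chrom][iv.start : iv.end].tobytes().decode()
        return out


def _random_psems(rng: np.random.Generator, n_tfs: int) -> list[gm.PSEM]:
    """PSEMs from random consensus sequences with controlled mismatch cost."""
    psems = []
    for t in range(n_tfs):
        L = int(rng.integers(7, 12))
        consensus = rng.integers(0, 4, size=L)
        rows = []
        for j in range(L):
            row = rng.uniform(1.2, 2.8, size=4)
            row[consensus[j]] = 0.0
            rows.append(tuple(float(v) for v in row))
        psems.append(gm.PSEM(f"TF{t:03d}", tuple(rows)))
    return psems


def _consensus_string(psem: gm.PSEM) -> np.ndarray:
    eps = psem.as_array()
    return _BASES[np.argmin(eps, axis=1)]


def generate_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate the dataset; write the file bundle when ``outdir`` is given.

    Deterministic in ``spec.seed``.  Layout per chromosome: genes on a
    jittered grid with generous margins; 1-3 accessibility peaks near each
    TSS; chromatin loops anchored at a subset of promoters whose distal
    anchors carry their own peaks; remaining peaks placed as background.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    margin = 20_000

    # --- genes ------------------------------------------------------------
    genes: list[gm.Gene] = []
    per_chrom = int(np.ceil(spec.n_genes / spec.n_chroms))
    gid = 0
    for chrom in chroms:
        usable = spec.chrom_length - 2 * margin
        pitch = usable // per_chrom
        for k in range(per_chrom):
            if gid >= spec.n_genes:
                break
            tss = margin + k * pitch + int(rng.integers(0, max(1, pitch // 4)))
            strand = "+" if rng.random() < 0.5 else "-"
            body = int(rng.integers(2000, 8000))
            if strand == "+":
                start, end = tss, min(tss + body, spec.chrom_length - 1)
                tss_list = [tss]
                if rng.random() < 0.3:
                    tss_list.append(tss + int(rng.integers(100, 600)))
            else:
                start, end = max(0, tss - body), tss
                tss_list = [tss]
                if rng.random() < 0.3:
                    tss_list.append(tss - int(rng.integers(100, 600)))
            genes.append(
                gm.Gene(
                    gene_id=f"G{gid:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    gene_type="protein_coding",
                    transcript_starts=tuple(tss_list),
                )
            )
            gid += 1

    # --- loops ------------------------------------------------------------
    loops: list[gm.ChromatinLoop] = []
    loop_genes = rng.choice(len(genes), size=min(spec.n_loops, len(genes)), replace=False)
    half_a = spec.anchor_width // 2
    for gi in loop_genes:
        g = genes[gi]
        tss = g.tss
        a1 = gm.GenomicInterval(
            g.chrom, max(0, tss - half_a), min(spec.chrom_length, tss + half_a)
        )
        dist = int(rng.integers(50_000, 400_000))
        sign = 1 if rng.random() < 0.5 else -1
        c2 = tss + sign * dist
        c2 = min(max(c2, half_a), spec.chrom_length - half_a)
        a2 = gm.GenomicInterval(g.chrom, c2 - half_a, c2 + half_a)
        loops.append(
            gm.ChromatinLoop(
                a1,
                a2,
                resolution="5kb",
                pet_count=1 + int(rng.poisson(3)),
                q_value=float(rng.uniform(0, 0.05)),
            )
        )

    # --- peaks ------------------------------------------------------------
    peaks: list[gm.Peak] = []

    def _make_peak(chrom: str, center: int) -> gm.Peak | None:
        length = int(np.clip(rng.lognormal(5.6, 0.35), 120, 900))
        start = max(0, center - length // 2)
        end = min(spec.chrom_length, start + length)
        if end - start < 120:
            return None
        signal = float(rng.lognormal(1.0, 0.6))
        return gm.Peak(gm.GenomicInterval(chrom, start, end), signal=signal)

    promoter_peaks: list[gm.Peak] = []
    for g in genes:
        for _ in range(1 + int(rng.poisson(1.2))):
            p = _make_peak(g.chrom, g.tss + int(rng.integers(-1200, 1200)))
            if p:
                promoter_peaks.append(p)
    distal_peaks: list[gm.Peak] = []
    for loop in loops:
        a2 = loop.anchor2
        for _ in range(1 + int(rng.poisson(0.8))):
            p = _make_peak(a2.chrom, int(rng.integers(a2.start + 200, a2.end - 200)))
            if p:
                distal_peaks.append(p)
    n_background = max(0, spec.n_peaks - len(promoter_peaks) - len(distal_peaks))
    background_peaks: list[gm.Peak] = []
    for _ in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        p = _make_peak(chrom, int(rng.integers(1000, spec.chrom_length - 1000)))
        if p:
            background_peaks.append(p)
    peaks = promoter_peaks + distal_peaks + background_peaks

    # --- chromatin states ---------------------------------------------------
    segments = gm.merge_adjacent_segments(
        [gm.ChromHMMSegment(p.interval, "TssA") for p in promoter_peaks]
        + [gm.ChromHMMSegment(p.interval, "Enh") for p in distal_peaks]
        + [gm.ChromHMMSegment(p.interval, "Quies") for p in background_peaks]
    )

    # --- genome sequence + motif embedding --------------------------------
    psems = _random_psems(rng, spec.n_tfs)
    genome = {
        chrom: _BASES[rng.integers(0, 4, size=spec.chrom_length)] for chrom in chroms
    }
    for psem in psems:
        cons = _consensus_string(psem)
        chosen = rng.random(len(peaks)) < spec.motif_embed_fraction
        for pi in np.nonzero(chosen)[0]:
            p = peaks[pi]
            room = p.length - len(cons)
            if room <= 0:
                continue
            for _ in range(1 + int(rng.integers(0, 2))):
                off = int(rng.integers(0, room + 1))
                s = p.interval.start + off
                genome[p.interval.chrom][s : s + len(cons)] = cons

    # --- pipeline features (the same code path the learner uses) ----------
    bundle = FixtureBundle(
        spec=spec,
        genes=genes,
        peaks=peaks,
        loops=loops,
        segments=segments,
        psems=psems,
        expression={},
        genome=genome,
        planted_effects={},
        truth=pd.DataFrame(),
    )
    sequences = bundle.peak_sequences()
    affinities = feat.peak_affinity_table(sequences, psems)
    prom_assign = linkage.window_linkage(genes, peaks, spec.promoter_window)
    loop_windows = linkage.loop_linkage(genes, loops, spec.loop_search_window)
    distal_assign = {
        g.gene_id: linkage.distal_peak_assignment(
            g,
            loop_windows.get(g.gene_id, ()),
            peaks,
            (ap.peak for ap in prom_assign.get(g.gene_id, ())),
        )
        for g in genes
    }
    pf = feat.peak_feature_table(genes, prom_assign, distal_assign)
    tf_prom, tf_loop = feat.tf_score_table(
        genes, prom_assign, affinities, psems, distal_assign, use_decay=False
    )
    X = build_feature_matrix("ExtendedFeatureSpace", pf, tf_prom, tf_loop)

    # --- planted linear model on the learner's scale -----------------------
    effects = dict(spec.planted_tf_effects) if spec.planted_tf_effects else None
    if effects is None:
        tf_names = [m.tf_name for m in psems]
        effects = {
            (tf_names[0], "promoter"): 1.0,
            (tf_names[1], "promoter"): -0.8,
            (tf_names[2], "promoter"): 0.9,
            (tf_names[3], "loop"): 1.0,
            (tf_names[4], "loop"): -0.9,
        }
    cols = [f"{tf}:{ctx}" for (tf, ctx) in effects]
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"planted effects reference unknown features: {missing}")
    # standardize the planted columns the way the learner will see them
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xp, _, _ = preprocess(X, pd.Series(1.0, index=X.index) + np.arange(len(X)))
    beta = np.array(list(effects.values()))
    if any(c not in Xp.columns for c in cols):
        raise ValueError("a planted feature has zero variance in this fixture")
    signal = Xp[cols].to_numpy() @ beta
    s_sd = float(np.std(signal))
    if s_sd == 0:
        raise ValueError("planted signal has zero variance")
    signal = signal / s_sd
    noise = rng.normal(0.0, spec.noise_sd, size=len(signal))
    log_expr = np.clip(4.0 + signal + noise, 0.0, None)
    expression = {g.gene_id: float(np.expm1(v)) for g, v in zip(genes, log_expr)}

    bundle.expression = expression
    bundle.planted_effects = effects
    bundle.affinities = affinities
    bundle.truth = pd.DataFrame(
        {"signal": signal, "noise": noise, "log_expression": log_expr},
        index=[g.gene_id for g in genes],
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "genes.gtf",
            "peaks": outdir / "peaks.narrowPeak",
            "loops": outdir / "loops.bedpe",
            "chromhmm": outdir / "chromhmm.bed",
            "psems": outdir / "psems.txt",
            "expression": outdir / "expression.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in chroms:
                fh.write(f">{chrom}\n")
                seq = genome[chrom].tobytes().decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gm.write_gene_annotation(genes, paths["annotation"])
        gm.write_peaks(peaks, paths["peaks"])
        gm.write_loops(loops, paths["loops"])
        gm.write_chromhmm(segments, paths["chromhmm"])
        gm.write_psems(psems, paths["psems"])
        gm.write_expression(expression, paths["expression"])
        bundle.paths = paths
    return bundle


def worked_example() -> dict:
    """A hand-checkable two-gene dataset covering the three linkage scenarios.

    * a peak shared by both genes' promoter windows (window linkage assigns
      it twice, nearest-gene linkage gives it to exactly one gene);
    * a promoter-exclusive peak for each gene;
    * a distal peak reachable only through a chromatin loop anchored at
      gene A's promoter (it enters the undecayed loop features only).
    """
    chrom = "chr1"
    gene_a = gm.Gene("GENE_A", chrom, "+", 10_000, 15_000, transcript_starts=(10_000,))
    gene_b = gm.Gene("GENE_B", chrom, "+", 12_000, 18_000, transcript_starts=(12_000,))
    shared = gm.Peak(gm.GenomicInterval(chrom, 10_900, 11_100), signal=4.0, name="shared")
    prom_a = gm.Peak(gm.GenomicInterval(chrom, 9_750, 10_250), signal=2.0, name="prom_a")
    prom_b = gm.Peak(gm.GenomicInterval(chrom, 12_400, 12_600), signal=3.0, name="prom_b")
    distal = gm.Peak(gm.GenomicInterval(chrom, 60_050, 60_250), signal=5.0, name="distal")
    loop = gm.ChromatinLoop(
        gm.GenomicInterval(chrom, 9_000, 11_000),
        gm.GenomicInterval(chrom, 59_000, 61_000),
        pet_count=4,
        q_value=0.01,
    )
    segments = [
        gm.ChromHMMSegment(gm.GenomicInterval(chrom, 9_500, 12_700), "TssA"),
        gm.ChromHMMSegment(gm.GenomicInterval(chrom, 59_500, 60_500), "Enh"),
    ]
    return {
        "genes": [gene_a, gene_b],
        "peaks": [shared, prom_a, prom_b, distal],
        "loops": [loop],
        "segments": segments,
    }
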