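"""Per-gene regulatory features from accessibility peaks and TF affinities.

Two feature families are computed for every gene:

* **peak features** — total peak length, peak count and aggregated peak
  signal over the peaks linked to the gene.  Promoter-linked peaks are
  weighted by an exponential distance decay ``exp(-dist/d0)`` (Ouyang-style,
  ``d0`` = 5000 bp by default); peaks linked through chromatin loops enter
  undecayed, because the loop itself is evidence of spatial proximity.

* **TF-gene scores** — biophysical TF binding affinities per peak (TRAP
  occupancy model driven by a position-specific energy matrix), normalized
  by the number of possible binding positions ``|p| - |m_t| + 1`` and summed
  over the gene's peaks; optionally decay-weighted for wide promoter
  windows, never decayed for loop-linked peaks.

The affinity engine can be bypassed entirely by supplying a precomputed
peak x TF affinity table, so the learning layers do not depend on it.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import PSEM, Gene, Peak
from .linkage import AssignedPeak

__all__ = [
    "decay_weight",
    "promoter_peak_features",
    "loop_peak_features",
    "trap_affinity",
    "peak_affinity_table",
    "tf_gene_scores",
    "tf_gene_loop_scores",
    "peak_feature_table",
    "tf_score_table",
    "peak_key",
]

PEAK_FEATURES = ("pl", "pc", "ps")
LOOP_PEAK_FEATURES = ("pl_star", "pc_star", "ps_star")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


def decay_weight(dist: float, d0: float) -> float:
    """Exponential distance decay ``exp(-dist/d0)``; 1 at the TSS."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    return math.exp(-dist / d0)


def promoter_peak_features(
    assigned_peaks: Sequence[AssignedPeak], d0: float = 5000.0
) -> tuple[float, float, float]:
    """Decay-weighted (pl, pc, ps) over a gene's promoter-linked peaks.

    pl = sum l(d) * exp(-dist/d0);  pc = sum exp(-dist/d0);
    ps = sum s(d) * exp(-dist/d0).  Empty input gives (0, 0, 0).
    """
    pl = pc = ps = 0.0
    for ap in assigned_peaks:
        w = decay_weight(ap.dist, d0)
        pl += ap.peak.length * w
        pc += w
        ps += ap.peak.signal * w
    return pl, pc, ps


def loop_peak_features(
    distal_peaks: Sequence[AssignedPeak],
) -> tuple[float, int, float]:
    """Undecayed (pl*, pc*, ps*) over loop-linked distal peaks."""
    pl = sum(ap.peak.length for ap in distal_peaks)
    pc = len(distal_peaks)
    ps = sum(ap.peak.signal for ap in distal_peaks)
    return float(pl), pc, float(ps)


# ---------------------------------------------------------------------------
# TRAP occupancy model
# ---------------------------------------------------------------------------


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; any other symbol (N, gap) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _default_r0(length: int, lam: float = 0.7, ln_r0_slope: float = 0.584, ln_r0_icept: float = -5.66) -> float:
    # Roider-style fit of the ratio R0 = [TF]/K_consensus as a function of
    # motif length; lam is absorbed into the stored energies.
    del lam
    return math.exp(ln_r0_slope * length + ln_r0_icept)


def _window_energies(codes: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Sum of per-position mismatch energies for every offset of a motif.

    ``codes``: int array with -1 for unknown bases (contribute zero energy);
    ``eps``: (L, 4) energy matrix.  Returns array of length len(codes)-L+1.
    """
    L = eps.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    energies = np.zeros(n)
    for j in range(L):
        window = codes[j : j + n]
        contrib = np.where(window >= 0, eps[j][np.clip(window, 0, 3)], 0.0)
        energies += contrib
    return energies


def trap_affinity(seq: str | np.ndarray, psem: PSEM, r0: float | None = None) -> float:
    """TRAP affinity of a sequence for one TF: summed occupancy over both
    strands and all offsets.

    Each candidate site contributes ``z / (1 + z)`` with
    ``z = R0 * exp(-E)``, where ``E`` is the summed mismatch energy of the
    site under the PSEM and ``R0`` a motif-length-dependent constant.
    Positions holding N contribute zero energy.  Deterministic; always >= 0.
    """
    codes = encode_sequence(seq) if isinstance(seq, str) else seq
    eps = psem.as_array()
    L = eps.shape[0]
    if codes.size < L:
        raise ValueError(
            f"sequence length {codes.size} shorter than motif {psem.tf_name} ({L})"
        )
    if r0 is None:
        r0 = _default_r0(L)
    total = 0.0
    for strand_eps in (eps, eps[::-1][:, ::-1]):  # forward; reverse complement
        z = r0 * np.exp(-_window_energies(codes, strand_eps))
        total += float(np.sum(z / (1.0 + z)))
    return total


def peak_affinity_table(
    sequences: Mapping[str, str], psems: Sequence[PSEM], r0: float | None = None
) -> pd.DataFrame:
    """Affinity of every peak sequence for every TF (peaks x TFs DataFrame).

    Sequences are concatenated with separator sentinels so each motif is
    scanned in a single vectorized pass; windows that straddle a sequence
    boundary or fall inside a too-short sequence are discarded.
    """
    names = list(sequences)
    if not names:
        return pd.DataFrame(columns=[m.tf_name for m in psems])
    coded = [encode_sequence(sequences[n]) for n in names]
    lengths = np.array([c.size for c in coded])
    max_len = max(int(m.length) for m in psems)
    sep = np.full(max_len, -2, dtype=np.int64)  # sentinel: kills any window
    big = np.concatenate([np.concatenate([c, sep]) for c in coded])
    starts = np.concatenate([[0], np.cumsum(lengths + max_len)])[:-1]

    out = np.zeros((len(names), len(psems)))
    for t, psem in enumerate(psems):
        eps = psem.as_array()
        L = eps.shape[0]
        if L > big.size:
            continue
        r0_t = _default_r0(L) if r0 is None else r0
        n_off = big.size - L + 1
        occ = np.zeros(n_off)
        valid = np.ones(n_off, dtype=bool)
        for strand_eps in (eps, eps[::-1][:, ::-1]):
            energies = np.zeros(n_off)
            for j in range(L):
                window = big[j : j + n_off]
                if strand_eps is eps:  # compute validity once
                    valid &= window != -2
                energies += np.where(window >= 0, strand_eps[j][np.clip(window, 0, 3)], 0.0)
            z = r0_t * np.exp(-energies)
            occ += z / (1.0 + z)
        occ[~valid] = 0.0
        # per-sequence sums; sequences shorter than the motif get zero sites
        sums = np.add.reduceat(occ, np.minimum(starts, n_off - 1))
        # correct sums for sequences whose block lies fully past n_off
        for i, (s, ln) in enumerate(zip(starts, lengths)):
            if ln < L:
                sums[i] = np.nan  # no valid site: flagged, warned below
        out[:, t] = sums
    df = pd.DataFrame(out, index=names, columns=[m.tf_name for m in psems])
    if df.isna().any().any():
        warnings.warn("some peaks are shorter than a motif; affinities set to NaN there")
    return df


def peak_key(peak: Peak) -> str:
    i = peak.interval
    return f"{i.chrom}:{i.start}-{i.end}"


# ---------------------------------------------------------------------------
# TF-gene score aggregation
# ---------------------------------------------------------------------------


def tf_gene_scores(
    assigned_peaks: Sequence[AssignedPeak],
    affinities: pd.DataFrame,
    psem_lengths: Mapping[str, int],
    use_decay: bool = False,
    d0: float = 5000.0,
) -> pd.Series:
    """Aggregate per-peak affinities into TF-gene scores.

    score_t = sum over peaks p of a_{p,t} / (|p| - |m_t| + 1), multiplied by
    ``exp(-dist(p, g)/d0)`` when ``use_decay``.  Peaks shorter than a motif
    are skipped for that TF (the site count would be non-positive).
    """
    tfs = list(affinities.columns)
    scores = pd.Series(0.0, index=tfs)
    skipped = 0
    for ap in assigned_peaks:
        key = peak_key(ap.peak)
        if key not in affinities.index:
            raise KeyError(f"no affinities for peak {key}")
        row = affinities.loc[key]
        w = decay_weight(ap.dist, d0) if use_decay else 1.0
        for tf in tfs:
            denom = ap.peak.length - psem_lengths[tf] + 1
            if denom <= 0 or np.isnan(row[tf]):
                skipped += 1
                continue
            scores[tf] += row[tf] / denom * w
    if skipped:
        warnings.warn(f"{skipped} peak/TF pairs skipped (peak shorter than motif)")
    return scores


def tf_gene_loop_scores(
    distal_peaks: Sequence[AssignedPeak],
    affinities: pd.DataFrame,
    psem_lengths: Mapping[str, int],
) -> pd.Series:
    """Loop TF-gene scores: same normalization, never decayed."""
    return tf_gene_scores(distal_peaks, affinities, psem_lengths, use_decay=False)


# ---------------------------------------------------------------------------
# gene-level tables
# ---------------------------------------------------------------------------


def peak_feature_table(
    genes: Sequence[Gene],
    promoter_assignment: Mapping[str, Sequence[AssignedPeak]],
    distal_assignment: Mapping[str, Sequence[AssignedPeak]] | None = None,
    d0: float = 5000.0,
) -> pd.DataFrame:
    """Per-gene (pl, pc, ps, pl*, pc*, ps*) table over a gene universe.

    Genes without linked peaks get zero rows; loop columns are zero when no
    distal assignment is supplied.
    """
    rows = []
    for g in genes:
        pl, pc, ps = promoter_peak_features(promoter_assignment.get(g.gene_id, ()), d0)
        dl = distal_assignment.get(g.gene_id, ()) if distal_assignment else ()
        pl_s, pc_s, ps_s = loop_peak_features(dl)
        rows.append((g.gene_id, pl, pc, ps, pl_s, pc_s, ps_s))
    return pd.DataFrame(
        rows, columns=["gene_id", *PEAK_FEATURES, *LOOP_PEAK_FEATURES]
    ).set_index("gene_id")


def tf_score_table(
    genes: Sequence[Gene],
    promoter_assignment: Mapping[str, Sequence[AssignedPeak]],
    affinities: pd.DataFrame,
    psems: Sequence[PSEM],
    distal_assignment: Mapping[str, Sequence[AssignedPeak]] | None = None,
    use_decay: bool = False,
    d0: float = 5000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter and loop TF-gene score tables (genes x TFs).

    Vectorized: the per-peak normalized affinities (optionally decayed by
    the peak's promoter distance) are accumulated per gene in one pass.
    """
    lengths = {m.tf_name: m.length for m in psems}
    tfs = [m.tf_name for m in psems]
    aff = affinities[tfs]
    motif_len = np.array([lengths[t] for t in tfs], dtype=float)

    def _accumulate(assignment, decay: bool) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=[g.gene_id for g in genes], columns=tfs)
        values = mat.to_numpy()
        gene_pos = {g.gene_id: i for i, g in enumerate(genes)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for gid, aps in assignment.items():
                if gid not in gene_pos:
                    continue
                acc = np.zeros(len(tfs))
                for ap in aps:
                    row = aff.loc[peak_key(ap.peak)].to_numpy(dtype=float)
                    denom = ap.peak.length - motif_len + 1
                    contrib = np.where(
                        (denom > 0) & ~np.isnan(row), row / np.maximum(denom, 1e-300), 0.0
                    )
                    if decay:
                        contrib = contrib * decay_weight(ap.dist, d0)
                    acc += contrib
                values[gene_pos[gid]] = acc
        return pd.DataFrame(values, index=mat.index, columns=tfs)

    promoter = _accumulate(promoter_assignment, use_decay)
    distal = _accumulate(distal_assignment or {}, False)
    return promoter, distal
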