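import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromgex import features as feat
from chromgex import genome_model as gm
from chromgex.linkage import AssignedPeak


def _peak(start, end, signal=1.0, chrom="chr1"):
    return gm.Peak(gm.GenomicInterval(chrom, start, end), signal=signal)


def _ap(peak, dist, context="promoter"):
    return AssignedPeak(peak, context, dist)


# ------------------------------- decay weight --------------------------------


@pytest.mark.parametrize(
    "dist,d0,expected",
    [(0, 5000, 1.0), (5000, 5000, math.exp(-1)), (2500, 5000, math.exp(-0.5))],
)
def test_decay_closed_forms(dist, d0, expected):
    assert feat.decay_weight(dist, d0) == pytest.approx(expected, abs=1e-12)


def test_decay_rejects_negative_distance():
    with pytest.raises(ValueError):
        feat.decay_weight(-1, 5000)


# ------------------------------ peak features --------------------------------


def test_promoter_features_at_tss():
    pl, pc, ps = feat.promoter_peak_features([_ap(_peak(0, 500, signal=3.5), 0)])
    assert (pl, pc, ps) == (500.0, 1.0, 3.5)


def test_promoter_features_decayed_at_d0():
    aps = [_ap(_peak(0, 100), 5000), _ap(_peak(200, 300), 5000)]
    pl, pc, ps = feat.promoter_peak_features(aps, d0=5000)
    assert pl == pytest.approx(200 * math.exp(-1), rel=1e-9)
    assert pc == pytest.approx(2 * math.exp(-1), rel=1e-9)


def test_empty_assignment_gives_zeros():
    assert feat.promoter_peak_features([]) == (0.0, 0.0, 0.0)
    assert feat.loop_peak_features([]) == (0.0, 0, 0.0)


def test_loop_features_plain_sums():
    aps = [_ap(_peak(0, 100, 1.5), 0, "loop"), _ap(_peak(0, 200, 2.5), 0, "loop")]
    pl, pc, ps = feat.loop_peak_features(aps)
    assert (pl, pc, ps) == (300.0, 2, 4.0)


def test_doubling_lengths_doubles_pl_not_pc():
    peaks = [_ap(_peak(0, 100), 700), _ap(_peak(500, 800), 1200)]
    doubled = [_ap(_peak(0, 200), 700), _ap(_peak(500, 1100), 1200)]
    pl1, pc1, _ = feat.promoter_peak_features(peaks)
    pl2, pc2, _ = feat.promoter_peak_features(doubled)
    assert pl2 == pytest.approx(2 * pl1) and pc2 == pc1


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(50, 900),
                          st.floats(0, 100), st.floats(0, 100_000)),
                min_size=1, max_size=20),
       st.floats(100, 100_000))
def test_peak_feature_invariants(specs, d0):
    """pc is bounded by the peak count, all features are non-negative, and
    scaling every signal by c scales ps by exactly c."""
    aps = [_ap(_peak(s, s + ln, sig), d) for s, ln, sig, d in specs]
    pl, pc, ps = feat.promoter_peak_features(aps, d0)
    assert 0 <= pc <= len(aps)
    assert pl >= 0 and ps >= 0
    tripled = [_ap(_peak(s, s + ln, 3 * sig), d) for s, ln, sig, d in specs]
    _, pc3, ps3 = feat.promoter_peak_features(tripled, d0)
    assert pc3 == pytest.approx(pc) and ps3 == pytest.approx(3 * ps, rel=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.floats(0, 1e6), st.floats(1e-3, 1e6))
def test_decay_weight_in_unit_interval(dist, d0):
    w = feat.decay_weight(dist, d0)
    # mathematically in (0, 1]; extreme dist/d0 ratios underflow to 0.0
    assert 0 <= w <= 1.0
    if dist == 0:
        assert w == 1.0


def test_features_permutation_invariant():
    aps = [_ap(_peak(0, 100, 2.0), 10), _ap(_peak(300, 450, 1.0), 900),
           _ap(_peak(800, 900, 5.0), 4000)]
    fwd = feat.promoter_peak_features(aps)
    rev = feat.promoter_peak_features(aps[::-1])
    assert fwd == pytest.approx(rev)


# ------------------------------- TRAP affinity --------------------------------


@pytest.fixture(scope="module")
def fixture_psem():
    # consensus ACGTACGT, strong mismatch penalties
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    rows = []
    for base in "ACGTACGT":
        row = [2.5, 2.5, 2.5, 2.5]
        row[idx[base]] = 0.0
        rows.append(tuple(row))
    return gm.PSEM("FIX", tuple(rows))


def naive_trap(seq, psem):
    """Per-offset reference loop, forward and reverse-complement strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    eps = psem.as_array()
    L = psem.length
    r0 = math.exp(0.584 * L - 5.66)
    total = 0.0
    for s in (seq.upper(), "".join(comp[b] for b in reversed(seq.upper()))):
        for off in range(len(s) - L + 1):
            e = sum(eps[j][idx[s[off + j]]] for j in range(L) if s[off + j] in idx)
            z = r0 * math.exp(-e)
            total += z / (1 + z)
    return total


@pytest.mark.parametrize("seed", range(5))
def test_trap_agrees_with_naive_oracle(seed, fixture_psem):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), size=50, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    assert feat.trap_affinity(seq, fixture_psem) == pytest.approx(
        naive_trap(seq, fixture_psem), rel=1e-10)


def test_trap_nonnegative_and_concat_dominates_parts(fixture_psem):
    rng = np.random.default_rng(0)
    a = "".join(rng.choice(list("ACGT"), size=30))
    b = "".join(rng.choice(list("ACGT"), size=30))
    fa, fb = feat.trap_affinity(a, fixture_psem), feat.trap_affinity(b, fixture_psem)
    assert fa >= 0 and fb >= 0
    assert feat.trap_affinity(a + b, fixture_psem) >= max(fa, fb)


def test_consensus_beats_shuffled_composition(fixture_psem):
    rng = np.random.default_rng(42)
    flank = "".join(rng.choice(list("ACGT"), size=20))
    seq = flank + "ACGTACGT" + flank
    planted = feat.trap_affinity(seq, fixture_psem)
    for shuffle_seed in range(20):
        srng = np.random.default_rng(shuffle_seed)
        shuffled = "".join(srng.permutation(list(seq)))
        assert planted > feat.trap_affinity(shuffled, fixture_psem)


def test_trap_rejects_too_short_sequence(fixture_psem):
    with pytest.raises(ValueError, match="shorter than motif"):
        feat.trap_affinity("ACG", fixture_psem)


def test_batch_affinities_match_single_calls(fixture_psem):
    rng = np.random.default_rng(1)
    seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), size=int(n)))
            for i, n in enumerate(rng.integers(20, 80, size=6))}
    table = feat.peak_affinity_table(seqs, [fixture_psem])
    for name, s in seqs.items():
        assert table.loc[name, "FIX"] == pytest.approx(
            feat.trap_affinity(s, fixture_psem), rel=1e-9)


# ------------------------------ TF-gene scores --------------------------------


def _aff_table(peak, value, tf="T1"):
    return pd.DataFrame({tf: [value]}, index=[feat.peak_key(peak)])


def test_tf_gene_score_normalization():
    p = _peak(0, 30)
    scores = feat.tf_gene_scores([_ap(p, 0)], _aff_table(p, 4.0), {"T1": 11})
    assert scores["T1"] == pytest.approx(4.0 / 20)


def test_tf_gene_score_with_decay():
    p = _peak(0, 30)
    scores = feat.tf_gene_scores([_ap(p, 5000)], _aff_table(p, 4.0), {"T1": 11},
                                 use_decay=True, d0=5000)
    assert scores["T1"] == pytest.approx(0.2 * math.exp(-1), rel=1e-9)


def test_empty_peak_set_scores_zero():
    scores = feat.tf_gene_scores([], pd.DataFrame(columns=["T1"]), {"T1": 11})
    assert scores["T1"] == 0.0


def test_peak_shorter_than_motif_skipped_with_warning():
    p = _peak(0, 8)
    with pytest.warns(UserWarning, match="skipped"):
        scores = feat.tf_gene_scores([_ap(p, 0)], _aff_table(p, 4.0), {"T1": 11})
    assert scores["T1"] == 0.0


def test_loop_scores_equal_undecayed_scores():
    p = _peak(0, 30)
    aps = [_ap(p, 12_345, "loop")]
    a = feat.tf_gene_scores(aps, _aff_table(p, 4.0), {"T1": 11}, use_decay=False)
    b = feat.tf_gene_loop_scores(aps, _aff_table(p, 4.0), {"T1": 11})
    assert a["T1"] == b["T1"]


def test_decay_converges_to_plain_sum_at_huge_d0():
    peaks = [(_peak(0, 30), 100.0), (_peak(100, 160), 7000.0)]
    aps = [_ap(p, d) for p, d in peaks]
    aff = pd.concat([_aff_table(p, 2.0) for p, _ in peaks])
    plain = feat.tf_gene_scores(aps, aff, {"T1": 11}, use_decay=False)
    huge = feat.tf_gene_scores(aps, aff, {"T1": 11}, use_decay=True, d0=1e12)
    assert huge["T1"] == pytest.approx(plain["T1"], abs=1e-9)


def test_gene_table_matches_per_gene_functions(small_bundle):
    from chromgex import linkage as lk

    b = small_bundle
    prom = lk.window_linkage(b.genes, b.peaks, 3000)
    pf = feat.peak_feature_table(b.genes, prom)
    g = next(g for g in b.genes if g.gene_id in prom)
    pl, pc, ps = feat.promoter_peak_features(prom[g.gene_id])
    row = pf.loc[g.gene_id]
    assert (row["pl"], row["pc"], row["ps"]) == pytest.approx((pl, pc, ps))
    assert (pf[["pl", "pc", "ps", "pl_star", "pc_star", "ps_star"]] >= 0).all().all()
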