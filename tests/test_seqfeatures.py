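"""Sequence features: windows, scan grids, k-mers, motifs, pairing score."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utr3end import io, seqfeatures, simulate
from utr3end.seqfeatures import (
    DEFAULT_MOTIFS,
    MotifPattern,
    feature_expression_scan,
    global_utr_features,
    grouped_gc_profile,
    kmer_expression_association,
    motif_scan,
    pairing_score,
    window_at_content,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# Window content
# ---------------------------------------------------------------------------


def test_window_fraction_examples():
    assert window_at_content("ATATGC", 3, 6, 0).fraction == pytest.approx(4 / 6)
    assert window_at_content("GGGG", 2, 4, 0).fraction == 0.0


def test_window_outside_sequence_is_nan_not_zero():
    wc = window_at_content("ACGT", -50, 10, 0)
    assert np.isnan(wc.fraction) and wc.truncated


def test_truncated_window_is_flagged():
    wc = window_at_content("ATATATAT", -2, 8, 0)
    assert wc.truncated
    assert wc.fraction == pytest.approx(1.0)


def test_window_content_matches_brute_force_on_random_sequence():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    for _ in range(100):
        size = int(rng.integers(1, 200))
        center = int(rng.integers(-300, 10_300))
        anchor = int(rng.integers(0, 10_000))
        wc = window_at_content(seq, center, size, anchor)
        start = anchor + center - size // 2
        window = seq[max(0, start): max(0, start + size)]
        if not window:
            assert np.isnan(wc.fraction)
        else:
            expect = (window.count("A") + window.count("T")) / len(window)
            assert wc.fraction == pytest.approx(expect)
            # A/T + G/C partition the window
            gc = window_at_content(seq, center, size, anchor, "gc_content")
            assert wc.fraction + gc.fraction == pytest.approx(1.0)


@given(dna)
@settings(max_examples=100, deadline=None)
def test_at_content_is_strand_symmetric(seq):
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    a = window_at_content(seq, len(seq) // 2, len(seq), 0)
    b = window_at_content(rc, len(rc) // 2, len(rc), 0)
    assert a.fraction == pytest.approx(b.fraction)


# ---------------------------------------------------------------------------
# Scan grid
# ---------------------------------------------------------------------------


def _constructed_library():
    """40 constructs whose expression IS the A/T content of a known window."""
    rng = np.random.default_rng(17)
    cons = []
    for i in range(40):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        c = io.Construct(f"g{i}", seq, cleavage_site=200)
        c.expression = window_at_content(seq, -2, 4, 200).fraction
        cons.append(c)
    return cons


def test_scan_cell_matching_definition_has_unit_correlation():
    grid = feature_expression_scan(
        _constructed_library(), sizes=[4, 8], offsets=[-6, -2, 0]
    )
    i = list(grid.window_sizes).index(4)
    j = list(grid.center_offsets).index(-2)
    assert grid.r[i, j] == pytest.approx(1.0)


def test_scan_invariant_under_affine_expression_transforms():
    cons = _constructed_library()
    grid1 = feature_expression_scan(cons, sizes=[10, 20], offsets=[-20, 0])
    for c in cons:
        c.expression = 5.0 + 3.0 * c.expression
    grid2 = feature_expression_scan(cons, sizes=[10, 20], offsets=[-20, 0])
    np.testing.assert_allclose(grid1.r, grid2.r, rtol=1e-9)


def test_scan_recovers_planted_window(small_library):
    constructs, truth = small_library
    grid = feature_expression_scan(constructs)
    size, offset, r = grid.peak()
    assert abs(size - truth.effect_width) <= 10
    assert abs(offset - truth.effect_center) <= 5
    assert r > 0.8


def test_null_library_peak_inside_permutation_band():
    cons, _ = simulate.generate_construct_library(
        120, beta0=1.0, beta1=0.0, seed=71
    )
    grid = feature_expression_scan(cons)
    null = seqfeatures.scan_permutation_null(cons, n_perm=300, seed=72)
    assert grid.max_abs_r() <= np.quantile(null, 0.95)


def test_identical_expressions_yield_undefined_grid():
    cons = _constructed_library()
    for c in cons:
        c.expression = 2.0
    grid = feature_expression_scan(cons, sizes=[10], offsets=[0])
    assert np.isnan(grid.r).all()


# ---------------------------------------------------------------------------
# Grouped G/C profiles
# ---------------------------------------------------------------------------


def test_grouped_profiles_separate_planted_compositions():
    rng = np.random.default_rng(23)
    cons = []
    for i in range(30):
        gc = 0.3 if i < 15 else 0.7
        n_gc = int(300 * gc)
        bases = ["G", "C"] * (n_gc // 2) + ["A", "T"] * ((300 - n_gc) // 2)
        rng.shuffle(bases)
        c = io.Construct(f"g{i}", "".join(bases), cleavage_site=250)
        c.expression = 1.0 if i < 15 else 10.0  # low GC group expresses high? no:
        cons.append(c)
    profiles = grouped_gc_profile(cons, span=range(-100, 0, 10))
    low = profiles["low"]["mean_gc"].mean()
    high = profiles["high"]["mean_gc"].mean()
    assert low == pytest.approx(0.3, abs=0.05)
    assert high == pytest.approx(0.7, abs=0.05)


def test_identical_sequences_give_identical_group_profiles():
    seq = ("ACGT" * 100)
    cons = [
        io.Construct(f"g{i}", seq, cleavage_site=300, expression=float(i))
        for i in range(25)
    ]
    profiles = grouped_gc_profile(cons, span=range(-50, 0, 5))
    np.testing.assert_allclose(
        profiles["low"]["mean_gc"], profiles["high"]["mean_gc"]
    )


def test_empty_extreme_group_is_an_error():
    cons = [
        io.Construct(f"g{i}", "ACGT" * 50, cleavage_site=100, expression=float(i))
        for i in range(6)
    ]
    with pytest.raises(io.ValidationError, match="0.0"):
        grouped_gc_profile(cons, low_q=0.0, high_q=0.2, span=[0])


# ---------------------------------------------------------------------------
# k-mers
# ---------------------------------------------------------------------------


def test_kmer_defined_by_expression_ranks_first():
    rng = np.random.default_rng(29)
    cons = []
    for i in range(30):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        c = io.Construct(f"g{i}", seq, cleavage_site=399)
        c.expression = float(len(re.findall("(?=TATA)", seq))) + 1e-6 * i
        cons.append(c)
    table = kmer_expression_association(cons, k=4, n_perm=200, seed=30)
    assert table.iloc[0]["kmer"] == "TATA"
    assert table.iloc[0]["rho"] > 0.97


def test_single_kmer_count_on_exact_sequence():
    cons = [
        io.Construct("a", "ACGT", cleavage_site=3, expression=1.0),
        io.Construct("b", "ACGT", cleavage_site=3, expression=2.0),
        io.Construct("c", "TTTT", cleavage_site=3, expression=3.0),
    ]
    table = kmer_expression_association(cons, k=4, n_perm=50, seed=0)
    counts = dict(zip(table["kmer"], table["total_count"]))
    assert counts["ACGT"] == 2
    assert counts["TTTT"] == 1


def test_null_expression_calibrates_permutation_p():
    rng = np.random.default_rng(31)
    cons = []
    for i in range(40):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        cons.append(
            io.Construct(f"g{i}", seq, cleavage_site=299,
                         expression=float(rng.normal()) + 10.0)
        )
    table = kmer_expression_association(cons, k=3, n_perm=400, seed=32)
    frac = float((table["pvalue"] < 0.05).mean())
    assert frac <= 0.12  # ~5% expected under the null


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------


def test_efficiency_element_degenerate_match():
    matches = motif_scan("GGTATATAGG", [MotifPattern("efficiency_element", "TAYRTA")])
    assert (("efficiency_element", 2)) in [tuple(m) for m in matches]


def test_no_match_in_c_run():
    assert motif_scan("CCCCCC", [MotifPattern("positioning_element", "AAWAAA")]) == []


def test_invalid_iupac_code_is_reported():
    with pytest.raises(io.ValidationError, match="'E'"):
        MotifPattern("bad", "AAEAA")


@given(st.text(alphabet="ACGT", min_size=6, max_size=80))
@settings(max_examples=150, deadline=None)
def test_motif_scan_matches_regex_oracle(seq):
    iupac_re = {"A": "A", "C": "C", "G": "G", "T": "T",
                "Y": "[CT]", "R": "[AG]", "W": "[AT]"}
    for pat in DEFAULT_MOTIFS:
        rx = "".join(iupac_re[ch] for ch in pat.pattern)
        expect = [m.start() for m in re.finditer(f"(?=({rx}))", seq)]
        got = [m.start for m in motif_scan(seq, [pat]) if m.name == pat.name]
        assert got == expect


# ---------------------------------------------------------------------------
# Whole-UTR features and pairing score
# ---------------------------------------------------------------------------


def test_pairing_score_examples():
    assert pairing_score("GGGAAACCC") == 3
    assert pairing_score("AAAAAA") == 0


def _brute_force_max_pairs(seq, min_loop=3):
    """Exhaustively enumerate all nested pairings (oracle for short strings)."""
    ok = {frozenset("AT"), frozenset("GC"), frozenset("GT")}

    def pairs(i, j):
        return frozenset((seq[i], seq[j])) in ok and j - i > min_loop

    def best(i, j):
        # Plain exhaustive recursion over all nested pairings (no memo, no
        # tabulation): position j is unpaired, or pairs with some k.
        if j - i <= min_loop:
            return 0
        score = best(i, j - 1)
        for k in range(i, j - min_loop):
            if pairs(k, j):
                left = best(i, k - 1) if k > i else 0
                score = max(score, left + 1 + best(k + 1, j - 1))
        return score

    return best(0, len(seq) - 1)


@given(st.text(alphabet="ACGT", min_size=2, max_size=12))
@settings(max_examples=120, deadline=None)
def test_pairing_score_matches_enumeration_oracle(seq):
    assert pairing_score(seq) == _brute_force_max_pairs(seq)


def test_global_features_composition_and_provenance():
    c = io.Construct("g", "ATGCATGCAA", cleavage_site=7)
    feats = global_utr_features(c)
    assert feats.utr_length == 8
    assert feats.gc_fraction + feats.at_fraction == pytest.approx(1.0)
    assert not feats.whole_construct
    unknown = io.Construct("g2", "ATGCATGCAA")
    feats2 = global_utr_features(unknown)
    assert feats2.whole_construct and feats2.utr_length == 10


def test_external_energy_hook():
    c = io.Construct("g", "ATGCATGCAA", cleavage_site=7)
    feats = global_utr_features(c, external_energy={"g": -12.5})
    assert feats.folding_energy == -12.5
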