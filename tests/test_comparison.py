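import numpy as np
import pytest

from paleophony.comparison import (
    GroupSpectra,
    comparison_table,
    group_range,
    group_spectra,
    overlap,
    overlap_table,
    per_harmonic_test,
    range_table,
)
from paleophony.errors import AcousticsError, InsufficientSampleError
from paleophony.resonance import FrequencyRange, invert_length

from .test_resonance import open_spectrum
from .oracles import pooled_t_statistic, permutation_p_value


def group_from_f1(label, f1_values, **meta):
    spectra = tuple(
        open_spectrum(invert_length(f, "open"), specimen_id=f"{label}{i}",
                      **meta)
        for i, f in enumerate(f1_values)
    )
    return GroupSpectra(label, spectra)


def test_group_range_min_max():
    g = group_from_f1("g", [400.0, 900.0, 550.0])
    r = group_range(g, 1)
    assert (r.lo, r.hi) == pytest.approx((400.0, 900.0), rel=1e-9)
    singleton = group_from_f1("s", [500.0])
    r1 = group_range(singleton, 1)
    assert r1.lo == r1.hi


def test_identical_groups_null_result():
    a = group_from_f1("a", [400.0, 500.0, 600.0])
    b = group_from_f1("b", [400.0, 500.0, 600.0])
    c = per_harmonic_test(a, b, 1)
    assert c.t == pytest.approx(0.0, abs=1e-12)
    assert c.p == pytest.approx(1.0)


def test_pooled_t_textbook_example():
    """A = {1,2,3}, B = {2,3,4}: t = −1.2247, df = 4, p = 0.2879 by the
    pooled-variance formula."""
    a = group_from_f1("a", [1.0, 2.0, 3.0])
    b = group_from_f1("b", [2.0, 3.0, 4.0])
    c = per_harmonic_test(a, b, 1, variant="pooled")
    assert c.t == pytest.approx(-1.224745, rel=1e-5)
    assert c.df == pytest.approx(4.0)
    assert c.p == pytest.approx(0.287864, rel=1e-4)
    assert c.t == pytest.approx(pooled_t_statistic([1, 2, 3], [2, 3, 4]),
                                rel=1e-9)


def test_welch_variant_differs_under_unequal_variance():
    a = group_from_f1("a", [100.0, 101.0, 99.0])
    b = group_from_f1("b", [150.0, 400.0, 900.0, 120.0])
    pooled = per_harmonic_test(a, b, 1, "pooled")
    welch = per_harmonic_test(a, b, 1, "welch")
    assert welch.df < pooled.df


def test_small_group_rejected():
    a = group_from_f1("a", [400.0])
    b = group_from_f1("b", [500.0, 600.0])
    with pytest.raises(InsufficientSampleError):
        per_harmonic_test(a, b, 1)


@pytest.mark.parametrize("seedval", [0, 1, 2, 3])
def test_pooled_p_tracks_exact_permutation(seedval):
    """On small near-normal samples the Student p-value agrees with the
    full-enumeration permutation p-value to within its coarse grid."""
    rng = np.random.default_rng(seedval)
    xa = 500 + 40 * rng.standard_normal(6)
    xb = 560 + 40 * rng.standard_normal(6)
    a = group_from_f1("a", xa)
    b = group_from_f1("b", xb)
    p_t = per_harmonic_test(a, b, 1, "pooled").p
    p_perm = permutation_p_value(xa, xb)
    assert p_t == pytest.approx(p_perm, abs=0.1)


def test_comparison_table_shape_and_order():
    groups = {
        "a": group_from_f1("a", [400.0, 500.0]),
        "b": group_from_f1("b", [420.0, 510.0]),
        "c": group_from_f1("c", [800.0, 900.0]),
    }
    table = comparison_table(groups, K=2)
    assert len(table) == 6  # 3 pairs × 2 ranks
    assert list(table.columns) == ["group_a", "group_b", "k", "t", "df", "p"]
    pairs = list(zip(table.group_a, table.group_b))
    assert pairs == sorted(pairs)
    for _, sub in table.groupby(["group_a", "group_b"]):
        assert list(sub.k) == [1, 2]


def test_comparison_table_row_order_invariance():
    f_a, f_b = [400.0, 500.0, 650.0], [420.0, 510.0, 700.0]
    g1 = {"a": group_from_f1("a", f_a), "b": group_from_f1("b", f_b)}
    g2 = {"b": group_from_f1("b", f_b[::-1]), "a": group_from_f1("a", f_a[::-1])}
    t1 = comparison_table(g1, K=3)
    t2 = comparison_table(g2, K=3)
    assert np.allclose(t1.p.values, t2.p.values)
    assert np.allclose(np.abs(t1.t.values), np.abs(t2.t.values))


def test_comparison_table_corrections():
    groups = {
        "a": group_from_f1("a", [400.0, 410.0, 390.0]),
        "b": group_from_f1("b", [800.0, 820.0, 780.0]),
    }
    holm = comparison_table(groups, K=3, correction="holm")
    bonf = comparison_table(groups, K=3, correction="bonferroni")
    assert (holm.p_adj >= holm.p - 1e-15).all()
    assert (bonf.p_adj <= 1.0 + 1e-15).all()
    with pytest.raises(InsufficientSampleError):
        comparison_table({"a": groups["a"]})


@pytest.mark.parametrize("a,b,exp_len,exp_frac", [
    ((0.5, 10.0), (20.0, 30.0), 0.0, 0.0),
    ((0.5, 10.0), (5.0, 15.0), 5.0, 5.0 / 9.5),
    ((5.0, 8.0), (0.5, 10.0), 3.0, 1.0),
])
def test_overlap_interval_arithmetic(a, b, exp_len, exp_frac):
    rep = overlap(FrequencyRange(1, *a), FrequencyRange(1, *b))
    assert rep.overlap_hz == pytest.approx(exp_len)
    assert rep.fraction == pytest.approx(exp_frac)


def test_overlap_degenerate_range():
    point_in = overlap(FrequencyRange(1, 5.0, 5.0), FrequencyRange(1, 1.0, 9.0))
    point_out = overlap(FrequencyRange(1, 50.0, 50.0), FrequencyRange(1, 1.0, 9.0))
    assert point_in.fraction == 1.0
    assert point_out.fraction == 0.0


def test_overlap_symmetry_and_bound():
    a, b = FrequencyRange(1, 10.0, 30.0), FrequencyRange(1, 25.0, 100.0)
    ab, ba = overlap(a, b), overlap(b, a)
    assert ab.overlap_hz == pytest.approx(ba.overlap_hz)
    assert ab.overlap_hz <= min(a.width, b.width) + 1e-12


def test_stage_filtering(default_cohort):
    from paleophony.resonance import spectra_for_pathways
    spectra = spectra_for_pathways(default_cohort)
    adults = group_spectra(spectra, adults_only=True)
    everyone = group_spectra(spectra, adults_only=False)
    assert len(adults["lambeosaurine"].spectra) < \
        len(everyone["lambeosaurine"].spectra)
    # immature individuals extend the envelope upward (shorter airways)
    assert group_range(everyone["lambeosaurine"], 1).hi > \
        group_range(adults["lambeosaurine"], 1).hi


def test_range_and_overlap_tables(default_cohort):
    from paleophony.resonance import spectra_for_pathways
    groups = group_spectra(spectra_for_pathways(default_cohort))
    rt = range_table(groups)
    assert set(rt.columns) == {"group", "k", "lo_hz", "hi_hz"}
    assert len(rt) == 3 * 5
    ot = overlap_table(groups)
    assert ((ot.fraction_of_a >= 0) & (ot.fraction_of_a <= 1)).all()


def test_group_spectra_rejects_empty():
    with pytest.raises(AcousticsError):
        GroupSpectra("empty", ())
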