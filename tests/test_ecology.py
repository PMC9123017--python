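"""Detection, RPKM, Bray-Curtis, ANOSIM, rank-sum and size-fraction logic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from jumbophage import ecology
from jumbophage.ecology import (
    anosim,
    anosim_exhaustive,
    bray_curtis,
    build_abundance_matrix,
    co_collected_subset,
    detect_presence,
    fraction_class,
    fraction_exclusivity,
    rank_sum_test,
    richness,
    rpkm,
)


@pytest.mark.parametrize("cf, present", [(0.20, True), (0.19, False), (1.0, True), (0.0, False)])
def test_detection_threshold_inclusive(cf, present):
    assert detect_presence(cf) is present


def test_rpkm_worked_value_and_linearity():
    assert rpkm(500, 250_000, 20_000_000) == pytest.approx(0.1)
    assert rpkm(0, 250_000, 20_000_000) == 0.0
    assert rpkm(1000, 250_000, 20_000_000) == pytest.approx(0.2)


def test_rpkm_rejects_zero_denominators():
    with pytest.raises(ValueError):
        rpkm(10, 0, 1000)
    with pytest.raises(ValueError):
        rpkm(10, 1000, 0)


def test_richness_column_sums():
    presence = pd.DataFrame(np.eye(3, dtype=bool), columns=list("abc"))
    assert richness(presence).tolist() == [1, 1, 1]
    presence.loc[:, "a"] = False
    assert richness(presence)["a"] == 0


def test_abundance_matrix_assembly():
    mapping = pd.DataFrame(
        {
            "population_id": ["p1", "p1", "p2"],
            "sample_id": ["s1", "s2", "s1"],
            "covered_fraction": [0.5, 0.1, 0.25],
            "read_count": [500, 50, 100],
        }
    )
    am = build_abundance_matrix(mapping, {"p1": 250_000, "p2": 500_000}, 20_000_000)
    assert am.rpkm.loc["p1", "s1"] == pytest.approx(0.1)
    assert bool(am.presence.loc["p1", "s2"]) is False
    assert bool(am.presence.loc["p2", "s1"]) is True
    # rpkm is zero wherever read_count is zero (p2 absent from s2)
    assert am.rpkm.loc["p2", "s2"] == 0.0


# ---------------------------------------------------------------- Bray-Curtis


def test_bray_curtis_hand_values():
    mat = pd.DataFrame({"x": [1, 1, 0], "y": [0, 1, 1], "z": [1, 1, 0]})
    d = bray_curtis(mat)
    assert d.loc["x", "y"] == pytest.approx(0.5)
    assert d.loc["x", "z"] == 0.0
    disjoint = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
    assert bray_curtis(disjoint).loc["a", "b"] == 1.0


def test_bray_curtis_zero_sum_pair_is_zero(caplog):
    mat = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 1]})
    with caplog.at_level("WARNING"):
        d = bray_curtis(mat)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "c"] == 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        dtype=float,
        shape=st.tuples(st.integers(2, 8), st.integers(2, 6)),
        elements=st.floats(0, 100, allow_nan=False),
    )
)
def test_bray_curtis_metric_properties(x):
    d = bray_curtis(pd.DataFrame(x)).to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert (d >= 0).all() and (d <= 1.0 + 1e-12).all()


def test_bray_curtis_matches_scipy_on_positive_data(rng):
    from scipy.spatial.distance import braycurtis as scipy_bc

    mat = pd.DataFrame(rng.uniform(0.1, 5.0, size=(10, 6)))
    d = bray_curtis(mat)
    for j in range(6):
        for k in range(6):
            expected = scipy_bc(mat.iloc[:, j], mat.iloc[:, k])
            assert d.iloc[j, k] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- ANOSIM


def _distances(rng, n):
    x = rng.normal(size=(n, 4))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids)


def test_anosim_perfect_separation_r_is_one():
    ids = ["a1", "a2", "b1", "b2"]
    d = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in ids:
        for j in ids:
            if i != j:
                d.loc[i, j] = 1.0 if i[0] != j[0] else 0.1
    res = anosim(d, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                 n_permutations=99, seed=1)
    assert res.statistic == pytest.approx(1.0)


def test_anosim_small_fixture_matches_exhaustive_enumeration(rng):
    d = _distances(rng, 6)
    groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    exact = anosim_exhaustive(d, groups)
    approx = anosim(d, groups, n_permutations=9999, seed=0)
    assert approx.statistic == pytest.approx(exact.statistic)
    assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)


def test_anosim_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import anosim as skbio_anosim

    d = _distances(rng, 12)
    labels = ["A"] * 6 + ["B"] * 6
    ours = anosim(d, dict(zip(d.index, labels)), n_permutations=999, seed=3)
    dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
    theirs = skbio_anosim(dm, grouping=labels, permutations=999)
    assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-12)
    assert ours.p_value == pytest.approx(theirs["p-value"], abs=0.05)


def test_anosim_rank_based_monotone_invariance(rng):
    d = _distances(rng, 8)
    groups = {f"s{i}": ("A" if i % 2 else "B") for i in range(8)}
    r1 = anosim(d, groups, n_permutations=199, seed=5)
    r2 = anosim(d**2, groups, n_permutations=199, seed=5)  # monotone transform
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p_value == r2.p_value


def test_anosim_degenerate_grouping_rejected(rng):
    d = _distances(rng, 4)
    with pytest.raises(ValueError):
        anosim(d, {f"s{i}": "A" for i in range(4)})
    with pytest.raises(ValueError):
        anosim(d, {"s0": "A", "s1": "B", "s2": "B", "s3": "B"})


# ---------------------------------------------------------------- rank-sum


def test_ranksum_identical_groups_p_one():
    res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.method == "ranksum_exact"
    assert res.p_value == 1.0


def test_ranksum_extreme_split_smallest_exact_p():
    res = rank_sum_test([1, 2, 3], [10, 11, 12])
    assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 splits


def test_ranksum_exact_matches_scipy_without_ties(rng):
    for _ in range(10):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        ours = rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_ranksum_large_samples_use_normal_approximation(rng):
    a = rng.normal(size=20)
    b = rng.normal(loc=1.0, size=20)
    res = rank_sum_test(a, b)
    assert res.method == "ranksum_normal"
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue)


def test_ranksum_power_on_planted_depth_effect():
    """A 10x surface enrichment over 20 stations is reliably detected."""
    from jumbophage import synthetic

    pops = pd.DataFrame(
        {"population_id": [f"p{i}" for i in range(6)],
         "genome_length": [300_000] * 6,
         "cluster": ["c0"] * 3 + ["c1"] * 3}
    )
    mapping, meta = synthetic.simulate_mapping_and_metadata(
        pops, n_stations=20, depth_effects={"c0": {"SRF": 10.0, "MES": 0.2}}, seed=42
    )
    am = build_abundance_matrix(mapping, dict(zip(pops["population_id"], pops["genome_length"])),
                                20_000_000)
    sub = am.presence.loc[["p0", "p1", "p2"]]
    rich = richness(sub)
    meta_ix = meta.set_index("sample_id")
    srf = rich[meta_ix.loc[rich.index, "depth"] == "SRF"]
    mes = rich[meta_ix.loc[rich.index, "depth"] == "MES"]
    assert rank_sum_test(srf, mes).p_value < 0.05


# ---------------------------------------------------------------- size fractions


@pytest.mark.parametrize(
    "label, cls",
    [
        ("0.1-0.22", "below_022"),
        ("<-0.22", "below_022"),
        ("0.22-3", "above_022"),
        ("0.22-1.6", "above_022"),
        ("0.45-0.8", "above_022"),
        ("0.1-1.6", "mixed"),
    ],
)
def test_fraction_class_boundaries(label, cls):
    assert fraction_class(label) == cls


def _meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "station": ["st1", "st1", "st2", "st2"],
            "depth": ["SRF", "SRF", "SRF", "DCM"],
            "size_fraction": ["0.1-0.22", "0.22-3", "0.22-3", "0.1-0.22"],
        }
    )


def test_exclusivity_classes_and_denominator():
    presence = pd.DataFrame(
        {"s1": [False, True, False], "s2": [True, True, False],
         "s3": [True, False, False], "s4": [False, False, False]},
        index=["only_above", "both", "undetected"],
    )
    out = fraction_exclusivity(presence, _meta()).set_index("population_id")
    assert out.loc["only_above", "exclusivity"] == "only_above_022"
    assert out.loc["both", "exclusivity"] == "both"
    assert "undetected" not in out.index  # excluded from denominators
    summary = ecology.exclusivity_summary(out.reset_index())
    assert summary["fraction_of_detected"].sum() == pytest.approx(1.0)


def test_co_collected_pairing():
    sub = co_collected_subset(_meta())
    # only station st1 SRF has both fraction classes
    assert set(sub["sample_id"]) == {"s1", "s2"}
    empty = co_collected_subset(_meta().iloc[0:0])
    assert len(empty) == 0


def test_presence_monotone_in_threshold(rng):
    cf = rng.uniform(0, 1, size=(5, 8))
    p_low = detect_presence(cf, threshold=0.1)
    p_high = detect_presence(cf, threshold=0.4)
    assert (p_high <= p_low).all()
    assert (p_high.sum(axis=0) <= p_low.sum(axis=0)).all()
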