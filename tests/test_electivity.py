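"""Relativized electivity, sample filters, size bins and Simpson diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frogdiet import (
    apply_sample_filter,
    availability_proportions,
    electivity,
    simpson_diversity,
)
from frogdiet.electivity import SizeBins, electivity_by_trait
from frogdiet.errors import ConfigError, DomainError, UndefinedElectivityError
from frogdiet.types import AvailabilitySample, PreyItem
from tests.conftest import make_record


def _series(values, labels=None):
    labels = labels or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=labels, dtype=float)


def test_neutral_selection_gives_zero_everywhere():
    r = _series([0.5, 0.3, 0.2])
    out = electivity(r, r.copy())
    assert np.allclose(out["E_star"], 0.0)


@pytest.mark.parametrize("r,p,w_exp,e_exp", [
    ([1.0, 0.0], [0.5, 0.5], [1.0, 0.0], [1.0 / 3.0, -1.0]),
    ([0.8, 0.2], [0.5, 0.5], [0.8, 0.2], [0.23076923, -0.42857143]),
])
def test_two_group_closed_forms(r, p, w_exp, e_exp):
    out = electivity(_series(r), _series(p))
    assert np.allclose(out["W"], w_exp)
    assert np.allclose(out["E_star"], e_exp)


def test_consumed_but_unavailable_group_is_an_error():
    with pytest.raises(UndefinedElectivityError, match="g1"):
        electivity(_series([0.5, 0.5]), _series([1.0, 0.0]))


@given(
    r=st.lists(st.floats(0.0, 10.0), min_size=2, max_size=10),
    p=st.lists(st.floats(0.1, 10.0), min_size=2, max_size=10),
)
@settings(max_examples=200, derandomize=True)
def test_selectivity_invariants(r, p):
    """W sums to one; E* lies in [-1, 1]; E* = -1 iff unconsumed; both are
    invariant to common rescaling of either raw vector."""
    m = min(len(r), len(p))
    r, p = np.array(r[:m]), np.array(p[:m])
    if r.sum() <= 1e-9:
        return
    out = electivity(_series(r), _series(p))
    assert out["W"].sum() == pytest.approx(1.0, abs=1e-9)
    assert out["E_star"].between(-1.0, 1.0).all()
    for g in out.index:
        rg = out.loc[g, "r"]
        if rg == 0.0 or rg > 1e-12:  # skip denormal r where E* saturates
            assert (out.loc[g, "E_star"] == -1.0) == (rg == 0.0)
    scaled = electivity(_series(3.7 * r), _series(0.25 * p))
    assert np.allclose(scaled["E_star"], out["E_star"], atol=1e-9)


def test_exclusive_selection_is_the_only_route_to_plus_one():
    out = electivity(_series([1.0, 0.0, 0.0]), _series([0.2, 0.4, 0.4]))
    assert out.loc["g0", "E_star"] < 1.0 or out.loc["g0", "W"] == 1.0
    assert out.loc["g0", "E_star"] == pytest.approx(
        (1.0 - 1 / 3) / (1.0 + 1 / 3)
    )


def test_availability_proportions_normalize():
    samples = [
        AvailabilitySample("Webi", "agriculture", "dry", "T1", 1,
                           items=[PreyItem(taxon="A")] * 6 + [PreyItem(taxon="B")] * 4)
    ]
    p = availability_proportions(samples)
    assert p.to_dict() == {"A": 0.6, "B": 0.4}
    with pytest.raises(UndefinedElectivityError):
        availability_proportions(samples, season="wet")


@pytest.mark.parametrize("threshold,expected", [
    (10, {"A"}),
    (1, {"A", "B"}),
])
def test_sample_filter_thresholds(threshold, expected):
    records = [
        make_record("a", prey=[("A", 1.0)] * 12 + [("B", 1.0)] * 9),
    ]
    assert apply_sample_filter(records, "H_tigerinus", threshold) == expected


def test_sample_filter_empty_diet():
    assert apply_sample_filter([make_record("a")], "H_tigerinus", 1) == set()


def test_default_thresholds_differ_by_predator():
    prey = [("A", 1.0)] * 7
    rec_ht = make_record("a", prey=prey)
    rec_fej = make_record("b", taxon="Fejervarya", svl=30.0, prey=prey)
    assert apply_sample_filter([rec_ht], "H_tigerinus") == set()
    assert apply_sample_filter([rec_fej], "Fejervarya") == {"A"}


def test_trait_electivity_sign_follows_overrepresentation(trait_table):
    """A diet over-representing evasive prey 3:1 against a uniform trap
    community must elect evasive positively and sedentary negatively."""
    evasive = PreyItem(taxon="Coleoptera", volume_mm3=5.0)
    sedentary = PreyItem(taxon="Oligochaeta", volume_mm3=5.0)
    rec = make_record("a")
    rec.stomach = [trait_table.apply(evasive)] * 30 + [trait_table.apply(sedentary)] * 10
    trap_items = (
        [trait_table.apply(PreyItem(taxon="Coleoptera"))] * 20
        + [trait_table.apply(PreyItem(taxon="Oligochaeta"))] * 20
        + [trait_table.apply(PreyItem(taxon="Acari"))] * 20
    )
    samples = [AvailabilitySample("Webi", "agriculture", "dry", "T1", 1,
                                  items=trap_items)]
    out = electivity_by_trait([rec], samples, "motility", season="dry")
    assert out.loc["evasive", "E_star"] > 0 > out.loc["sedentary", "E_star"]


def test_identical_trait_distributions_are_neutral(trait_table):
    items = [trait_table.apply(PreyItem(taxon=t, volume_mm3=1.0))
             for t in ("Coleoptera", "Oligochaeta", "Acari")]
    rec = make_record("a")
    rec.stomach = list(items)
    samples = [AvailabilitySample("Webi", "agriculture", "dry", "T1", 1,
                                  items=list(items))]
    out = electivity_by_trait([rec], samples, "motility", season="dry")
    assert np.allclose(out["E_star"], 0.0, atol=1e-12)


def test_size_bins_assignment_and_validation():
    bins = SizeBins()
    assert bins.assign(5.0) == bins.labels[0]
    assert bins.assign(10.0) == bins.labels[0]   # right-closed
    assert bins.assign(10.1) == bins.labels[1]
    assert bins.assign(1e6) == bins.labels[-1]
    with pytest.raises(ConfigError):
        SizeBins(edges=(100.0, 10.0))
    with pytest.raises(DomainError):
        bins.assign(0.0)


@pytest.mark.parametrize("counts,variant,expected", [
    ([7], "complement", 0.0),
    ([1, 1, 1, 1], "complement", 0.75),
    ([5, 3, 2], "complement", 0.62),
    ([2, 2], "finite_sample", 1.0 - 2.0 / 6.0),
])
def test_simpson_diversity_values(counts, variant, expected):
    assert simpson_diversity(counts, variant) == pytest.approx(expected)


def test_simpson_diversity_guards():
    with pytest.raises(DomainError):
        simpson_diversity([0, 0])
    with pytest.raises(DomainError):
        simpson_diversity([1], "finite_sample")
    with pytest.raises(ConfigError):
        simpson_diversity([1, 2], "inverse")
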