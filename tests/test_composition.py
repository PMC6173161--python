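"""Utilization matrices, composition tables, IRI, vacuity, aggregation and
the predator-size/prey-volume regression."""

import numpy as np
import pytest

from frogdiet import (
    aggregate_by_class,
    build_diet_matrix,
    composition_table,
    count_nonzero_categories,
    iri,
    reconstruct_counts,
    size_prey_regression,
    vacuity_index,
)
from frogdiet.composition import apportion_counts
from frogdiet.errors import (
    DomainError,
    UndefinedCompositionError,
    VocabularyError,
)
from tests.conftest import make_record


def test_count_and_frequency_bases_tally_differently():
    records = [
        make_record("a", prey=[("A", 1.0), ("A", 1.0), ("B", 1.0)]),
        make_record("b", prey=[("A", 1.0)]),
    ]
    counts = build_diet_matrix(records, basis="count")
    assert counts.data.loc["H_tigerinus"].to_dict() == {"A": 3.0, "B": 1.0}
    freq = build_diet_matrix(records, basis="frequency")
    assert freq.data.loc["H_tigerinus"].to_dict() == {"A": 2.0, "B": 1.0}
    vol = build_diet_matrix(records, basis="volume")
    assert vol.data.loc["H_tigerinus", "A"] == pytest.approx(3.0)


def test_all_empty_stomachs_give_zero_row():
    records = [make_record("a"), make_record("b")]
    m = build_diet_matrix(records, basis="count", categories=["A", "B"])
    assert (m.data.to_numpy() == 0).all()


def test_unknown_basis_rejected():
    with pytest.raises(VocabularyError):
        build_diet_matrix([make_record("a", prey=[("A", 1.0)])], basis="biomass")


def test_unidentified_column_dropped_on_request():
    records = [make_record("a", prey=[("A", 1.0), ("Unidentified", 1.0)])]
    m = build_diet_matrix(records, include_unidentified=False)
    assert list(m.data.columns) == ["A"]


def test_single_category_normalizes_to_100():
    table = composition_table([make_record("a", prey=[("A", 2.0), ("A", 3.0)])])
    assert table.data.loc["A", "N_pct"] == pytest.approx(100.0)
    assert table.data.loc["A", "V_pct"] == pytest.approx(100.0)


def test_f_pct_denominator_conventions():
    records = [make_record("a"), make_record("b", prey=[("A", 1.0)])]
    all_ind = composition_table(records)
    assert all_ind.data.loc["A", "F_pct"] == pytest.approx(50.0)
    non_empty = composition_table(records, f_denominator="non_empty")
    assert non_empty.data.loc["A", "F_pct"] == pytest.approx(100.0)


def test_composition_percentages_sum_to_100(assemblage):
    records, _, _ = assemblage
    from frogdiet import impute_record_volumes
    imputed, _ = impute_record_volumes(records)
    for sp in ("H_tigerinus", "Limnonectes", "Fejervarya"):
        table = composition_table([r for r in imputed if r.taxon == sp])
        assert table.data["N_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table.data["V_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table.data["F_pct"].between(0, 100).all()
        assert (table.data["IRI"] >= 0).all()


def test_composition_undefined_without_prey():
    with pytest.raises(UndefinedCompositionError):
        composition_table([make_record("a")])


@pytest.mark.parametrize("n,v,f,expected", [
    (29.73, 12.14, 24.57, 1028.7459),
    (38.72, 5.80, 23.72, 1056.0144),
    (0.0, 0.0, 0.0, 0.0),
])
def test_iri_pinkas_form(n, v, f, expected):
    assert iri(n, v, f) == pytest.approx(expected, rel=1e-9)
    assert iri(v, n, f) == pytest.approx(iri(n, v, f))  # symmetric in N%, V%


def test_iri_rejects_out_of_range():
    with pytest.raises(DomainError):
        iri(101.0, 0.0, 0.0)


def test_vacuity_fractions():
    records = [make_record(f"e{i}") for i in range(2)] + [
        make_record(f"f{i}", prey=[("A", 1.0)]) for i in range(8)
    ]
    assert vacuity_index(records) == pytest.approx(0.2)
    assert vacuity_index(records[2:]) == 0.0
    with pytest.raises(UndefinedCompositionError):
        vacuity_index(records, season="wet")


@pytest.mark.parametrize("pct,total,expected", [
    (0.43, 687, 3),
    (29.73, 687, 204),
    (0.0, 687, 0),
    (0.5, 100, 1),  # tie rounds half-up
])
def test_reconstruct_counts_half_up(pct, total, expected):
    assert reconstruct_counts(pct, total) == expected


def test_apportioned_fixture_rows_sum_to_published_totals(fixture_matrix):
    sums = fixture_matrix.data.sum(axis=1)
    assert sums["H_tigerinus"] == 687
    assert sums["Limnonectes"] == 618
    assert sums["Fejervarya"] == 173


def test_apportionment_matches_half_up_when_consistent():
    pcts = np.array([50.0, 30.0, 20.0])
    assert list(apportion_counts(pcts, 10)) == [5, 3, 2]


VERTEBRATES = {"Amphibia", "Reptilia", "Mammalia"}


def test_vertebrate_aggregation_matches_published_sums(fixture_tables, trait_table):
    ht = fixture_tables["H_tigerinus"]
    n_sum, v_sum = aggregate_by_class(ht, VERTEBRATES, trait_table,
                                      reconstruct_n_from_counts=True)
    assert v_sum == pytest.approx(58.03, abs=1e-9)
    assert round(n_sum, 2) == 2.62
    lim = fixture_tables["Limnonectes"]
    n_sum, v_sum = aggregate_by_class(lim, VERTEBRATES, trait_table)
    assert n_sum == pytest.approx(0.48, abs=1e-9)
    assert v_sum == pytest.approx(5.16, abs=1e-9)
    assert aggregate_by_class(lim, set(), trait_table) == (0.0, 0.0)


def test_category_counts_with_exclusion_convention(fixture_tables):
    expected = {"H_tigerinus": 29, "Limnonectes": 25, "Fejervarya": 14}
    for sp, want in expected.items():
        assert count_nonzero_categories(
            fixture_tables[sp], exclude={"Unidentified"}) == want
    assert count_nonzero_categories(fixture_tables["H_tigerinus"]) == 30


def test_regression_recovers_exact_line():
    rng = np.random.default_rng(0)
    records = []
    for i in range(10):
        svl = float(rng.uniform(50, 150))
        y = 2.0 * np.log(svl) + 1.0
        records.append(make_record(f"r{i}", svl=svl, prey=[("A", float(y ** 3))]))
    fit = size_prey_regression(records)["H_tigerinus"]
    assert fit.slope == pytest.approx(2.0, abs=1e-8)
    assert fit.intercept == pytest.approx(1.0, abs=1e-7)
    assert fit.se < 1e-8
    assert fit.n == 10


def test_regression_singular_without_size_variation():
    records = [make_record(f"s{i}", svl=100.0, prey=[("A", 5.0)]) for i in range(5)]
    with pytest.raises(DomainError):
        size_prey_regression(records)
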