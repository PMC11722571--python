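import numpy as np
import pytest

from cooccur.datamodel import (
    EpiphyteRecord,
    ForestDataset,
    LianaRecord,
    TreeRecord,
    basal_area,
)
from cooccur.networks import (
    epiphyte_liana_matrix,
    epiphyte_tree_matrix,
    liana_tree_matrix,
    network_report,
)
from cooccur.synthetic import StandParams, generate_stand

META = {"A": {"forest_type": "mature"}}


def _ds(trees, lianas=(), epis=()):
    ds = ForestDataset(list(trees), list(lianas), list(epis), dict(META))
    ds.validate()
    return ds


class TestLianaTree:
    def test_single_record_cell(self):
        ds = _ds(
            [TreeRecord("T1", "A", "p01", "Ocotea porphyria", 30.0)],
            [LianaRecord("T1", "Cissus striata", 2.0, "specialized", "trunk")],
        )
        m = liana_tree_matrix(ds)
        assert m.weights.loc["Cissus striata", "Ocotea porphyria"] == pytest.approx(
            3.1416e-4, rel=1e-4
        )

    def test_multiple_stems_additive(self):
        ds = _ds(
            [TreeRecord("T1", "A", "p01", "Ocotea porphyria", 30.0)],
            [
                LianaRecord("T1", "Cissus striata", 1.0, "specialized", "trunk"),
                LianaRecord("T1", "Cissus striata", 2.0, "specialized", "crown"),
            ],
        )
        m = liana_tree_matrix(ds)
        assert m.weights.iloc[0, 0] == pytest.approx(basal_area(1.0) + basal_area(2.0))

    def test_conservation_of_total_basal_area(self, small_stand):
        m = liana_tree_matrix(small_stand)
        assert m.total == pytest.approx(
            sum(basal_area(l.diameter) for l in small_stand.lianas), rel=1e-12
        )


class TestEpiphyteTree:
    def test_two_zone_record_weighs_two(self):
        ds = _ds(
            [TreeRecord("T1", "A", "p01", "Ocotea porphyria", 30.0)],
            epis=[
                EpiphyteRecord(
                    "T1", "Pleopeltis tweediana", 2, frozenset({"trunk", "crown"})
                )
            ],
        )
        assert epiphyte_tree_matrix(ds).weights.iloc[0, 0] == 2

    def test_zone_counts_additive_across_trees(self):
        trees = [
            TreeRecord(f"T{i}", "A", "p01", "Ocotea porphyria", 30.0) for i in range(3)
        ]
        epis = [
            EpiphyteRecord(f"T{i}", "Pleopeltis tweediana", 1, frozenset({"crown"}))
            for i in range(3)
        ]
        assert epiphyte_tree_matrix(_ds(trees, epis=epis)).weights.iloc[0, 0] == 3

    def test_conservation_of_zone_total(self, small_stand):
        m = epiphyte_tree_matrix(small_stand)
        assert m.total == sum(len(e.zones) for e in small_stand.epiphytes)


class TestEpiphyteLiana:
    def test_no_shared_trees_empty(self):
        ds = _ds(
            [
                TreeRecord("T1", "A", "p01", "s", 20.0),
                TreeRecord("T2", "A", "p01", "s", 20.0),
            ],
            [LianaRecord("T1", "L", 2.0, "leaning", "trunk")],
            [EpiphyteRecord("T2", "E", 1, frozenset({"crown"}))],
        )
        assert epiphyte_liana_matrix(ds).is_empty()

    def test_one_shared_tree_two_epiphytes(self):
        ds = _ds(
            [TreeRecord("T1", "A", "p01", "s", 20.0)],
            [LianaRecord("T1", "L", 2.0, "leaning", "trunk")],
            [
                EpiphyteRecord("T1", "E1", 1, frozenset({"crown"})),
                EpiphyteRecord("T1", "E2", 1, frozenset({"trunk"})),
            ],
        )
        m = epiphyte_liana_matrix(ds)
        assert m.weights.loc["E1", "L"] == 1
        assert m.weights.loc["E2", "L"] == 1

    def test_cells_bounded_by_host_sets(self, small_stand):
        m = epiphyte_liana_matrix(small_stand)
        epi_hosts, liana_hosts = {}, {}
        for e in small_stand.epiphytes:
            epi_hosts.setdefault(e.species, set()).add(e.tree_id)
        for l in small_stand.lianas:
            liana_hosts.setdefault(l.species, set()).add(l.tree_id)
        for esp in m.row_species:
            for lsp in m.col_species:
                assert m.weights.loc[esp, lsp] <= min(
                    len(epi_hosts[esp]), len(liana_hosts[lsp])
                )

    def test_matches_brute_force_tree_scan(self, small_stand):
        m = epiphyte_liana_matrix(small_stand)
        for esp in m.row_species:
            for lsp in m.col_species:
                count = 0
                for t in small_stand.trees:
                    has_e = any(
                        e.tree_id == t.tree_id and e.species == esp
                        for e in small_stand.epiphytes
                    )
                    has_l = any(
                        l.tree_id == t.tree_id and l.species == lsp
                        for l in small_stand.lianas
                    )
                    count += has_e and has_l
                assert m.weights.loc[esp, lsp] == count


class TestReport:
    def test_dominant_species_ranked_first(self, small_stand):
        m = epiphyte_tree_matrix(small_stand)
        rep = network_report(m)
        totals = m.weights.sum(axis=1)
        assert rep["top_rows"][0] == totals.sort_values(ascending=False).index[0]

    def test_ties_break_alphabetically(self):
        ds = _ds(
            [TreeRecord("T1", "A", "p01", "s", 20.0)],
            epis=[
                EpiphyteRecord("T1", "Zed", 1, frozenset({"crown"})),
                EpiphyteRecord("T1", "Abe", 1, frozenset({"crown"})),
            ],
        )
        rep = network_report(epiphyte_tree_matrix(ds))
        assert rep["top_rows"] == ["Abe", "Zed"]

    def test_empty_matrix_empty_report(self):
        ds = _ds([TreeRecord("T1", "A", "p01", "s", 20.0)])
        rep = network_report(epiphyte_liana_matrix(ds))
        assert rep["top_rows"] == [] and rep["row_totals"] == {}


def test_canopy_dominant_attracts_most_epiphytes():
    """The generator's canopy-dominant species should lead the epiphyte
    marginals in mature stands."""
    params = StandParams(
        n_patches=2,
        plots_per_patch=10,
        patch_types={"M1": "mature", "M2": "mature"},
        mapped_patch="none",
    )
    totals = None
    for seed in range(3):
        m = epiphyte_tree_matrix(generate_stand(params, seed=seed))
        t = m.weights.sum(axis=0)
        totals = t if totals is None else totals.add(t, fill_value=0.0)
    assert totals.idxmax() == "Ocotea porphyria"
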