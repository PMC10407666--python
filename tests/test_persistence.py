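import numpy as np
import pytest

from ecostab.persistence import (
    NODATA,
    compute_persistence,
    refine_with_vegetation,
    select_ecological_classes,
)

from conftest import make_stack

F, G = 1, 2  # forest, grassland codes


def series_from_histories(histories):
    """Build a 1-row LULC stack where each column is one pixel's history."""
    arr = np.asarray(histories, dtype=np.int16).T  # (dates, pixels)
    return make_stack([a.reshape(1, -1) for a in arr], [str(2000 + 5 * i) for i in range(len(arr))])


class TestComputePersistence:
    @pytest.mark.parametrize(
        "history,expected",
        [
            ([F, F, F, F], 1),  # no change observed -> steady
            ([F, F, G, G], 0),  # change occurred -> unsteady
            ([G, G, G, G], NODATA),  # never the class -> outside
            ([G, F, F, F], NODATA),  # enters the class later -> excluded
            ([F, G, F, F], 0),  # transient change still counts as change
        ],
    )
    def test_label_definition(self, history, expected):
        stack = series_from_histories([history])
        mask = compute_persistence(stack, class_code=F)
        assert mask.values.values[0, 0] == expected

    def test_partition_property(self):
        """Pixels holding the class at date 1 are exactly the {0,1} pixels."""
        rng = np.random.default_rng(3)
        cube = rng.integers(1, 4, size=(4, 20, 20)).astype(np.int16)
        stack = make_stack(list(cube), ["a", "b", "c", "d"])
        mask = compute_persistence(stack, class_code=1)
        first = cube[0] == 1
        labelled = mask.values.values != NODATA
        np.testing.assert_array_equal(labelled, first)
        steady = mask.values.values == 1
        np.testing.assert_array_equal(steady, (cube == 1).all(axis=0))

    def test_adding_a_date_never_converts_0_to_1(self):
        rng = np.random.default_rng(4)
        cube = rng.integers(1, 3, size=(5, 15, 15)).astype(np.int16)
        short = make_stack(list(cube[:4]), ["a", "b", "c", "d"])
        full = make_stack(list(cube), ["a", "b", "c", "d", "e"])
        m4 = compute_persistence(short, 1).values.values
        m5 = compute_persistence(full, 1).values.values
        assert not ((m4 == 0) & (m5 == 1)).any()

    def test_nodata_at_any_date_excludes(self):
        cube = np.full((2, 2, 2), F, dtype=np.int16)
        cube[1, 0, 0] = -1
        stack = make_stack(list(cube), ["a", "b"], nodata=-1)
        mask = compute_persistence(stack, F)
        assert mask.values.values[0, 0] == NODATA
        assert mask.values.values[1, 1] == 1

    def test_errors(self):
        one_date = make_stack([np.full((2, 2), F, dtype=np.int16)], ["a"])
        with pytest.raises(ValueError, match="two dates"):
            compute_persistence(one_date, F)
        stack = series_from_histories([[F, F]])
        with pytest.raises(ValueError, match="absent"):
            compute_persistence(stack, 99, legend={F: "forest", G: "grassland"})


class TestRefinement:
    def _mask(self, label):
        stack = series_from_histories([[F, F, F, F] if label == 1 else [F, G, G, G]])
        return compute_persistence(stack, F)

    def _veg(self, values):
        return make_stack([np.full((1, 1), v) for v in values], [str(i) for i in range(len(values))])

    def test_constant_vegetation_keeps_steady(self):
        mask = self._mask(1)
        out = refine_with_vegetation(mask, self._veg([0.5] * 4), self._veg([900.0] * 4), cv_max=0.2)
        assert out.values.values[0, 0] == 1

    def test_erratic_ndvi_demotes_to_nodata(self):
        # hand CV of {0.1, 0.5, 0.1, 0.5}: sd(ddof=1) = 0.23094, mean = 0.3,
        # CV = 0.7698 > 0.2 -> classification error, not ecological change
        mask = self._mask(1)
        ndvi = self._veg([0.1, 0.5, 0.1, 0.5])
        out = refine_with_vegetation(mask, ndvi, self._veg([900.0] * 4), cv_max=0.2)
        assert out.values.values[0, 0] == NODATA
        sd = np.std([0.1, 0.5, 0.1, 0.5], ddof=1)
        assert sd / 0.3 == pytest.approx(0.76980, abs=1e-4)

    def test_unsteady_pixels_untouched_by_cv(self):
        mask = self._mask(0)
        ndvi = self._veg([0.1, 0.5, 0.1, 0.5])
        out = refine_with_vegetation(mask, ndvi, ndvi, cv_max=0.01)
        assert out.values.values[0, 0] == 0

    def test_lowering_cv_max_never_adds_steady_pixels(self):
        rng = np.random.default_rng(5)
        cube = np.full((4, 10, 10), F, dtype=np.int16)
        stack = make_stack(list(cube), list("abcd"))
        mask = compute_persistence(stack, F)
        ndvi = make_stack(list(rng.uniform(0.1, 0.9, size=(4, 10, 10))), list("abcd"))
        gpp = make_stack(list(rng.uniform(100, 1500, size=(4, 10, 10))), list("abcd"))
        counts = [
            (refine_with_vegetation(mask, ndvi, gpp, cv).values.values == 1).sum()
            for cv in (1.0, 0.5, 0.25, 0.1)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_nodata_vegetation_errors(self):
        mask = self._mask(1)
        nan = self._veg([np.nan] * 4)
        with pytest.raises(ValueError, match="all-nodata"):
            refine_with_vegetation(mask, nan, nan, cv_max=0.2)


class TestClassSelection:
    def test_ecological_surrogates_selected(self):
        legend = {
            1: "forest",
            2: "grassland_high",
            3: "grassland_sparse",
            4: "wetland",
            5: "desert",
            6: "urban",
        }
        assert select_ecological_classes(legend) == [1, 2, 3, 4]

    def test_only_excluded_classes_gives_empty(self):
        assert select_ecological_classes({5: "desert", 6: "urban"}) == []

    def test_untagged_legend_errors(self):
        with pytest.raises(ValueError, match="tag"):
            select_ecological_classes({1: "lorem"})
        with pytest.raises(ValueError, match="empty"):
            select_ecological_classes({})
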