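import numpy as np
import pytest

from rnacat.quantify import (
    FluorescenceSeries,
    GelBand,
    GelLaneTable,
    ReactionConditions,
    amount_from_concentration,
    extent_of_cleavage,
    pathway_curve,
    product_concentration,
    quantify_gel,
    turnover_per_conjugate,
)

T = np.array([0.0, 24.0, 48.0, 72.0, 96.0])


def _series(raw, background=100.0, ref=1100.0):
    return FluorescenceSeries(T, np.asarray(raw, float),
                              np.full(T.size, background), ref)


class TestExtent:
    def test_background_reads_zero(self):
        ext = extent_of_cleavage(_series([100.0] * 5))
        assert np.allclose(ext.percent, 0.0) and not ext.clipped

    def test_reference_reads_hundred(self):
        ext = extent_of_cleavage(_series([1100.0] * 5))
        assert np.allclose(ext.percent, 100.0)

    def test_midpoint_reads_fifty(self):
        ext = extent_of_cleavage(_series([600.0] * 5))
        assert np.allclose(ext.percent, 50.0)

    def test_affine_rescaling_invariance(self):
        """Changing the fluorescence unit jointly on raw, background and
        reference leaves the extent unchanged."""
        raw = np.array([100.0, 300.0, 600.0, 900.0, 1050.0])
        a = extent_of_cleavage(_series(raw)).percent
        b = extent_of_cleavage(FluorescenceSeries(
            T, 3.5 * raw + 40.0, np.full(5, 3.5 * 100.0 + 40.0),
            3.5 * 1100.0 + 40.0,
        )).percent
        assert np.allclose(a, b, atol=1e-9)

    def test_clipping_is_flagged(self):
        ext = extent_of_cleavage(_series([90.0, 300.0, 600.0, 900.0, 1200.0]))
        assert ext.clipped
        assert ext.percent[0] == 0.0 and ext.percent[-1] == 100.0

    def test_bad_reference_is_an_error(self):
        with pytest.raises(ValueError):
            _series([100.0] * 5, background=100.0, ref=90.0)


def test_product_concentration_is_proportional():
    assert product_concentration(100.0, 10.0) == 10.0
    assert product_concentration(0.0, 123.0) == 0.0
    assert product_concentration(66.0, 10.0) == pytest.approx(6.6)


@pytest.mark.parametrize("conc,vol,nmol", [
    (5.0, 100.0, 0.5),   # the study's conjugate amount
    (10.0, 100.0, 1.0),
    (0.0, 100.0, 0.0),
])
def test_amount_from_concentration(conc, vol, nmol):
    assert amount_from_concentration(conc, vol) == pytest.approx(nmol)


@pytest.mark.parametrize("cleaved,conj,expected", [
    (3.3, 0.5, 6.6),   # headline turnover, bis conjugate at 50 uM
    (3.2, 0.5, 6.4),
    (0.0, 0.5, 0.0),
])
def test_turnover_per_conjugate(cleaved, conj, expected):
    t = turnover_per_conjugate(cleaved, conj)
    assert t.rounded == expected
    assert t.value == pytest.approx(cleaved / conj)


def test_turnover_of_full_cleavage_equals_excess_ratio():
    cond = ReactionConditions(150.0, 5.0, 100.0)
    t = turnover_per_conjugate(cond.substrate_nmol, cond.conjugate_nmol)
    assert t.value == pytest.approx(cond.excess_ratio, rel=1e-12)


def _gel(intact, bands):
    table = {"intact": np.asarray(intact, float)}
    bmap = {"intact": GelBand("intact")}
    for bid, (kind, site, vals) in bands.items():
        table[bid] = np.asarray(vals, float)
        bmap[bid] = GelBand(kind, site)
    n = len(intact)
    return GelLaneTable(T[:n], table, bmap)


class TestGel:
    def test_intact_only_lane_is_zero_cleavage(self):
        prof = quantify_gel(_gel([100.0] * 5, {}))
        assert np.allclose(prof.total_pct, 0.0)
        assert np.allclose(prof.bulge_pct, 0.0)

    def test_fully_cleaved_single_bulge_band(self):
        prof = quantify_gel(_gel(
            [0.0] * 5, {"b1": ("bulge", "G65-A66", [500.0] * 5)}
        ))
        assert np.allclose(prof.total_pct, 100.0)
        assert np.allclose(prof.bulge_pct, 100.0)

    def test_mixed_lane_fractions(self):
        prof = quantify_gel(_gel(
            [50.0] * 5,
            {"b1": ("bulge", "C63-A64", [30.0] * 5),
             "e1": ("exbulge", "U8-A9", [20.0] * 5)},
        ))
        assert np.allclose(prof.total_pct, 50.0)
        assert np.allclose(prof.bulge_pct, 30.0)
        assert np.allclose(prof.exbulge_pct, 20.0)

    def test_site_fractions_sum_to_total(self):
        rng = np.random.default_rng(3)
        bands = {
            f"b{i}": ("bulge" if i % 2 else "exbulge", f"s{i}",
                      rng.uniform(0, 50, 5))
            for i in range(5)
        }
        prof = quantify_gel(_gel(rng.uniform(10, 100, 5), bands))
        assert np.allclose(prof.bulge_pct + prof.exbulge_pct,
                           prof.total_pct, atol=0.5)

    def test_all_zero_lane_is_an_error(self):
        with pytest.raises(ValueError):
            quantify_gel(_gel([0.0] * 5, {}))

    def test_exactly_one_intact_band_required(self):
        with pytest.raises(ValueError):
            GelLaneTable(T, {"x": np.ones(5)}, {"x": GelBand("bulge", "s")})


class TestPathway:
    def test_no_bulge_cleavage_means_no_takeover(self):
        prof = quantify_gel(_gel(
            [100, 80, 60, 50, 40],
            {"e1": ("exbulge", "U8-A9", [0, 20, 40, 50, 60])},
        ))
        res = pathway_curve(prof)
        assert not res.occurred and np.isnan(res.takeover_exbulge_pct)

    def test_takeover_at_exbulge_saturation(self):
        """Ex-bulge saturates at 35% before bulge cleavage rises."""
        prof = quantify_gel(_gel(
            [100, 65, 64, 34, 4],
            {"e1": ("exbulge", "U8-A9", [0, 35, 35, 35, 35]),
             "b1": ("bulge", "C63-A64", [0, 0, 1, 31, 61])},
        ))
        res = pathway_curve(prof)
        assert res.occurred
        assert res.takeover_exbulge_pct == pytest.approx(35.0, abs=1.0)

    def test_equal_rates_tie_at_first_point(self):
        prof = quantify_gel(_gel(
            [100, 80, 60, 40, 20],
            {"e1": ("exbulge", "U8-A9", [0, 10, 20, 30, 40]),
             "b1": ("bulge", "C63-A64", [0, 10, 20, 30, 40])},
        ))
        res = pathway_curve(prof)
        assert res.occurred
        assert res.takeover_exbulge_pct == pytest.approx(0.0)
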