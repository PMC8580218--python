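import numpy as np
import pytest
from shapely.geometry import Point, box

from wastewater.habitat import (
    HabitatRaster,
    HotspotRule,
    flag_hotspots,
    habitat_summary,
    nearest_rank_threshold,
    overlay_exposure,
    rasterize_habitat,
)
from wastewater.plume import PlumeField


def _field(shape, sewered=0.0, septic=0.0, direct=0.0):
    mk = lambda v: np.full(shape, float(v))
    return PlumeField(n_sewered=mk(sewered), n_septic=mk(septic), n_direct=mk(direct))


def test_rasterize_full_cell_polygon():
    # polygon covering an entire coarse cell -> that cell is habitat
    hab = rasterize_habitat([box(2.0, 2.0, 3.0, 3.0)], (5, 5), cell_km=1.0)
    assert hab.presence[2, 2]  # row 2 spans y in (2, 3)
    assert hab.presence.sum() == 1


def test_rasterize_single_fine_center():
    # small square around one fine-cell centre (0.25, 0.25) only
    hab = rasterize_habitat([box(0.15, 0.15, 0.35, 0.35)], (4, 4), cell_km=1.0, fine_factor=2)
    assert hab.presence[3, 0]
    assert hab.presence.sum() == 1


def test_rasterize_sliver_misses_all_centers():
    # sliver strictly between fine-cell centres -> empty raster
    hab = rasterize_habitat([box(0.3, 0.3, 0.45, 0.45)], (4, 4), cell_km=1.0, fine_factor=2)
    assert not hab.presence.any()


def test_rasterize_point_feature_and_empty_set():
    hab = rasterize_habitat([Point(1.5, 2.5)], (4, 4), cell_km=1.0)
    assert hab.presence[1, 1]  # y=2.5 -> row 1 of 4
    assert rasterize_habitat([], (4, 4)).presence.sum() == 0


def test_rasterize_fine_factor_one_equals_direct_center_rule():
    poly = Point(2.6, 2.6).buffer(0.8, quad_segs=16)
    fine1 = rasterize_habitat([poly], (6, 6), fine_factor=1).presence
    centers = [(r, c) for r in range(6) for c in range(6)
               if poly.contains(Point(c + 0.5, 6 - r - 0.5))]
    expected = np.zeros((6, 6), dtype=bool)
    for r, c in centers:
        expected[r, c] = True
    np.testing.assert_array_equal(fine1, expected)


def test_overlay_exposure_and_dominant_source():
    presence = np.zeros((3, 3), dtype=bool)
    presence[0, 0] = presence[1, 1] = presence[2, 2] = True
    hab = HabitatRaster(presence=presence)
    field = _field((3, 3), sewered=2.0, septic=1.0, direct=2.0)
    field.n_sewered[2, 2] = 0.0
    field.n_septic[2, 2] = 0.0
    field.n_direct[2, 2] = 0.0
    out = overlay_exposure(hab, field)
    assert out.dominant[0, 0] == "direct_or_septic"  # 3 > 2
    assert out.dominant[2, 2] == "none"
    assert out.exposure["n_total"][1, 1] == pytest.approx(5.0)
    # exposure defined only on habitat cells
    assert out.exposure["n_total"][0, 1] == 0.0


def test_dominant_tie_classified_sewered():
    presence = np.ones((1, 1), dtype=bool)
    out = overlay_exposure(HabitatRaster(presence=presence), _field((1, 1), sewered=2.0, septic=1.0, direct=1.0))
    assert out.dominant[0, 0] == "sewered"


def test_overlay_shape_mismatch():
    with pytest.raises(ValueError):
        overlay_exposure(HabitatRaster(presence=np.ones((2, 2), bool)), _field((3, 3)))


def test_hotspot_nearest_rank_on_1000_distinct_values():
    """Exactly the top 2.5% of 1000 distinct exposures are flagged."""
    presence = np.ones((20, 50), dtype=bool)
    exposure = np.arange(1, 1001, dtype=float).reshape(20, 50)
    hab = HabitatRaster(presence=presence, exposure={
        "n_total": exposure, "n_sewered": exposure, "n_septic": np.zeros((20, 50)),
        "n_direct": np.zeros((20, 50)),
    })
    out = flag_hotspots(hab, HotspotRule(quantile=0.975))
    assert out.hotspot.sum() == 25
    assert exposure[out.hotspot].min() == 976.0
    assert out.hotspot_threshold == 976.0


def test_hotspot_degenerate_distributions():
    presence = np.ones((2, 5), dtype=bool)
    const = {
        "n_total": np.full((2, 5), 7.0), "n_sewered": np.zeros((2, 5)),
        "n_septic": np.zeros((2, 5)), "n_direct": np.zeros((2, 5)),
    }
    out = flag_hotspots(HabitatRaster(presence=presence, exposure=const))
    assert out.hotspot.sum() == 10  # all equal -> all flagged
    zeros = {k: np.zeros((2, 5)) for k in const}
    out0 = flag_hotspots(HabitatRaster(presence=presence, exposure=zeros))
    assert out0.hotspot_threshold == 0.0
    assert out0.hotspot.sum() == 10


def test_hotspot_requires_habitat_cells():
    with pytest.raises(ValueError):
        flag_hotspots(HabitatRaster(presence=np.zeros((2, 2), bool),
                                    exposure={"n_total": np.zeros((2, 2))}))


def test_nearest_rank_threshold_small_samples():
    assert nearest_rank_threshold([5.0], 0.975) == 5.0
    assert nearest_rank_threshold(np.arange(1, 41), 0.975) == 40


def test_habitat_summary_fractions():
    presence = np.zeros((2, 5), dtype=bool)
    presence[0, :] = True
    presence[1, :] = True
    exposure = np.zeros((2, 5))
    exposure[0, :3] = 4.0
    exposure[0, 3:] = 1.0
    exposure[1, 0] = 2.0  # 6 of 10 exposed
    direct = np.where(exposure > 0, exposure, 0.0)
    hab = HabitatRaster(presence=presence, exposure={
        "n_total": exposure, "n_direct": direct,
        "n_septic": np.zeros((2, 5)), "n_sewered": np.zeros((2, 5)),
    })
    hab = overlay_exposure_like(hab)
    s = habitat_summary(hab)
    assert s["exposed_fraction"] == pytest.approx(0.6)
    assert s["share_direct_or_septic"] == 1.0
    assert s["total_n_total"] == pytest.approx(exposure.sum())


def overlay_exposure_like(hab):
    """Rebuild dominant codes from stored exposures (helper)."""
    field = PlumeField(
        n_sewered=hab.exposure["n_sewered"],
        n_septic=hab.exposure["n_septic"],
        n_direct=hab.exposure["n_direct"],
    )
    return overlay_exposure(HabitatRaster(presence=hab.presence), field)


def test_summary_no_plume():
    presence = np.ones((2, 2), dtype=bool)
    out = overlay_exposure(HabitatRaster(presence=presence), _field((2, 2)))
    s = habitat_summary(out)
    assert s["exposed_fraction"] == 0.0
    assert s["share_direct_or_septic"] == 0.0
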