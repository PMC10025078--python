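"""Pseudo-areas, integrated densities, site pooling and offsets."""

import math

import numpy as np
import pandas as pd
import pytest

from antscape.survey import (
    RecordingGroup,
    SeifertPlot,
    SpeciesCatalog,
    SurveyError,
    integrated_density,
    pool_site_matrix,
    pseudo_area,
    read_plots,
    site_offset,
)


@pytest.mark.parametrize(
    "weights, expected",
    [
        ((1.0, 1.0, 1.0), 13.64),  # full detection: total searched area / 100
        ((1.0, 0.0, 0.0), 0.64),  # only the scrutiny area counts
        ((1.0, 1.0, 0.0), 4.64),  # (64 + 400) / 100
    ],
)
def test_pseudo_area_weighted_sum(weights, expected):
    plot = SeifertPlot("p", "s", 64, 400, 900)
    group = RecordingGroup("g", *weights)
    assert pseudo_area(plot, group) == pytest.approx(expected, abs=1e-12)


def test_all_zero_weights_rejected():
    with pytest.raises(SurveyError, match="zero"):
        RecordingGroup("bad", 0.0, 0.0, 0.0)


def test_weights_outside_unit_interval_rejected():
    with pytest.raises(SurveyError):
        RecordingGroup("bad", 1.2, 0.0, 0.0)


def test_integrated_density_quotient():
    # 5 nests over a (1,1,0) pseudo-area of 4.64
    g = RecordingGroup("g", 1.0, 1.0, 0.0)
    cat = SpeciesCatalog({"g": g}, {"a": "g"})
    plot = SeifertPlot("p", "s", 64, 400, 900, counts={"a": (2, 3, 0)})
    assert integrated_density([plot], "a", cat) == pytest.approx(5 / 4.64, rel=1e-12)


def test_integrated_density_zero_counts(default_catalog):
    plot = SeifertPlot("p", "s", counts={"a": (0, 0, 0)})
    assert integrated_density([plot], "a", default_catalog) == 0.0


def test_missing_group_raises(default_catalog):
    plot = SeifertPlot("p", "s", counts={"unknown": (1, 0, 0)})
    with pytest.raises(SurveyError, match="unknown"):
        integrated_density([plot], "unknown", default_catalog)


def test_site_offset_single_group_single_plot():
    g = RecordingGroup("g", 1.0, 1.0, 0.0)
    cat = SpeciesCatalog({"g": g}, {"a": "g"})
    plot = SeifertPlot("p", "s", 64, 400, 900)
    assert site_offset([plot], cat) == pytest.approx(math.log(4.64), rel=1e-12)


def test_site_offset_mean_over_groups():
    # plot areas chosen so the two groups' pseudo-areas are 2 and 8
    g1 = RecordingGroup("g1", 1.0, 1.0, 0.0)  # (50 + 150) / 100 = 2
    g2 = RecordingGroup("g2", 1.0, 1.0, 1.0)  # (50 + 150 + 600) / 100 = 8
    cat = SpeciesCatalog({"g1": g1, "g2": g2}, {"a": "g1", "b": "g2"})
    plot = SeifertPlot("p", "s", 50, 150, 600)
    assert site_offset([plot], cat) == pytest.approx(math.log(5.0), rel=1e-12)


def test_site_offset_unit_pseudo_area_is_zero():
    g = RecordingGroup("g", 1.0, 0.0, 0.0)
    cat = SpeciesCatalog({"g": g}, {"a": "g"})
    plot = SeifertPlot("p", "s", 100, 400, 900)
    assert site_offset([plot], cat) == pytest.approx(0.0, abs=1e-12)


def test_offset_by_species_weights_groups_by_membership():
    g1 = RecordingGroup("g1", 1.0, 1.0, 0.0)
    g2 = RecordingGroup("g2", 1.0, 1.0, 1.0)
    cat = SpeciesCatalog({"g1": g1, "g2": g2}, {"a": "g1", "b": "g2", "c": "g2"})
    plot = SeifertPlot("p", "s", 50, 150, 600)
    # by_species: mean(2, 8, 8) = 6
    assert site_offset([plot], cat, mode="by_species") == pytest.approx(math.log(6.0))


def test_pool_block_structure(default_catalog):
    p1 = SeifertPlot("p1", "s1", counts={"a": (1, 1, 0)})
    p2 = SeifertPlot("p2", "s2", counts={"b": (0, 2, 0)})
    m = pool_site_matrix([p1, p2], default_catalog)
    assert m.density.shape == (2, 2)
    assert m.density.loc["s1", "b"] == 0.0
    assert m.density.loc["s2", "a"] == 0.0
    assert m.density.loc["s1", "a"] > 0
    assert (m.density.to_numpy() == 0) [0, 1]


def test_empty_site_retained_and_flagged(default_catalog):
    p1 = SeifertPlot("p1", "s1", counts={"a": (1, 0, 0)})
    p2 = SeifertPlot("p2", "s2", counts={})
    m = pool_site_matrix([p1, p2], default_catalog)
    assert "s2" in m.sites
    assert m.empty_sites == ["s2"]
    assert (m.density.loc["s2"] == 0).all()
    assert np.isfinite(m.offset.loc["s2"])
    assert "s2" not in m.modeling_view().sites


def test_density_zero_iff_count_zero(synthetic_bundle):
    m = pool_site_matrix(synthetic_bundle["plots"], synthetic_bundle["catalog"])
    assert ((m.density.to_numpy() == 0) == (m.raw_counts.to_numpy() == 0)).all()
    assert np.isfinite(m.offset).all()
    assert (m.density.to_numpy() >= 0).all()


def test_duplicate_records_rejected(tmp_path):
    df = pd.DataFrame({
        "plot_id": ["p1", "p1"], "site_id": ["s1", "s1"],
        "area_S": [64, 64], "area_Q": [400, 400], "area_SI": [900, 900],
        "species": ["a", "a"], "level": ["S", "S"], "count": [1, 2],
    })
    path = tmp_path / "plots.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SurveyError, match="duplicated"):
        read_plots(path)


def test_homogeneity_scaling_counts(default_catalog, standard_plot):
    """Multiplying every count by k scales every density by exactly k."""
    base = pool_site_matrix([standard_plot], default_catalog)
    k = 3
    scaled_plot = SeifertPlot(
        "p1", "s1", 64, 400, 900,
        counts={sp: tuple(k * c for c in v) for sp, v in standard_plot.counts.items()},
    )
    scaled = pool_site_matrix([scaled_plot], default_catalog)
    assert np.allclose(scaled.density.to_numpy(), k * base.density.to_numpy())


def test_monotonicity_adding_a_nest(default_catalog, standard_plot):
    base = pool_site_matrix([standard_plot], default_catalog)
    bumped_counts = dict(standard_plot.counts)
    bumped_counts["a"] = (2, 2, 1)
    bumped = pool_site_matrix(
        [SeifertPlot("p1", "s1", 64, 400, 900, counts=bumped_counts)], default_catalog
    )
    assert (bumped.density.to_numpy() >= base.density.to_numpy() - 1e-15).all()


def test_full_detection_oracle(full_detection_catalog):
    """With weights (1,1,1) density is exactly nests * 100 / searched m2."""
    plot = SeifertPlot("p", "s", 64, 400, 900, counts={"a": (2, 3, 4)})
    d = integrated_density([plot], "a", full_detection_catalog)
    assert d == pytest.approx(9 * 100 / 1364.0, rel=1e-14)


def test_pooling_identical_plots_leaves_density_unchanged(default_catalog, standard_plot):
    one = pool_site_matrix([standard_plot], default_catalog)
    twin = SeifertPlot("p2", "s1", 64, 400, 900, counts=dict(standard_plot.counts))
    two = pool_site_matrix([standard_plot, twin], default_catalog)
    assert np.allclose(one.density.to_numpy(), two.density.to_numpy())


def test_csv_roundtrip(tmp_path, synthetic_bundle):
    from antscape.simulate import plots_to_frame

    frame = plots_to_frame(synthetic_bundle["plots"])
    path = tmp_path / "plots.csv"
    frame.to_csv(path, index=False)
    back = read_plots(path)
    m0 = pool_site_matrix(synthetic_bundle["plots"], synthetic_bundle["catalog"])
    m1 = pool_site_matrix(back, synthetic_bundle["catalog"])
    pd.testing.assert_frame_equal(m0.density, m1.density)
    pd.testing.assert_series_equal(m0.offset, m1.offset)
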