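import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coastspan import coast_range as cr
from coastspan.coast_range import (
    Coastline,
    archipelago_range,
    assign_points,
    clean_occurrences,
    locale_to_points,
    point_at_s,
    project_many,
    project_to_coast,
    segment_coast_positions,
    total_range,
)
from coastspan.geodesy import great_circle_km, to_unit_vectors, from_unit_vectors


# ---------------------------------------------------------------------------
# independent oracles


def slerp(a, b, t):
    omega = np.arccos(np.clip(np.dot(a, b), -1, 1))
    if omega < 1e-12:
        return a
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def brute_force_projection(lat, lon, coast, n_samples=4000):
    """Densely sample the polyline (spherical interpolation) and return the
    (s, distance) of the closest sample."""
    best = (None, np.inf)
    for i in range(len(coast) - 1):
        a, b = coast._uv[i], coast._uv[i + 1]
        for t in np.linspace(0.0, 1.0, n_samples // (len(coast) - 1)):
            q = slerp(a, b, t)
            qlat, qlon = from_unit_vectors(q)
            d = great_circle_km((lat, lon), (qlat, qlon))
            if d < best[1]:
                s = coast.cum_s[i] + t * (coast.cum_s[i + 1] - coast.cum_s[i])
                best = (s, d)
    return best


def brute_force_segments(s_values, gap_km=1500.0, isolated_km=50.0):
    """Group positions by pairwise connectivity (components of the graph
    linking neighbors <= gap apart) and measure each group."""
    s = sorted(s_values)
    n = len(s)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j and abs(s[i] - s[j]) <= gap_km:
                adj[i].add(j)
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k])
        groups.append(sorted(s[k] for k in comp))
    # every group is floored at the measurement resolution
    lengths = [max(g[-1] - g[0], isolated_km) for g in groups]
    return sorted(lengths)


# ---------------------------------------------------------------------------
# coastline container


def test_coastline_invariants(wiggly_coast):
    assert wiggly_coast.cum_s[0] == 0.0
    assert np.all(np.diff(wiggly_coast.cum_s) > 0)
    steps = great_circle_km(
        (wiggly_coast.lats[:-1], wiggly_coast.lons[:-1]),
        (wiggly_coast.lats[1:], wiggly_coast.lons[1:]),
    )
    assert wiggly_coast.length_km == pytest.approx(steps.sum(), rel=1e-12)


def test_coastline_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        Coastline(id="one", lats=np.array([0.0]), lons=np.array([0.0]))
    with pytest.raises(ValueError):
        Coastline(id="dup", lats=np.array([0.0, 0.0]), lons=np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        Coastline(id="oob", lats=np.array([0.0, 95.0]), lons=np.array([0.0, 1.0]))


def test_geojson_round_trip(tmp_path, wiggly_coast):
    path = tmp_path / "coasts.geojson"
    cr.write_coastlines_geojson([wiggly_coast], path)
    back = cr.read_coastlines_geojson(path)[0]
    np.testing.assert_allclose(back.lats, wiggly_coast.lats)
    np.testing.assert_allclose(back.lons, wiggly_coast.lons)
    assert back.id == wiggly_coast.id and back.is_continental


# ---------------------------------------------------------------------------
# projection


def test_projection_at_vertex_zero(meridian):
    a = project_to_coast((0.0, 0.0), meridian)
    assert a.s == pytest.approx(0.0, abs=1e-9)
    assert a.offshore_km == pytest.approx(0.0, abs=1e-9)


def test_projection_matches_brute_force(meridian):
    s, d = project_many([5.0], [0.5], meridian)
    s_ref, d_ref = brute_force_projection(5.0, 0.5, meridian)
    assert s[0] == pytest.approx(s_ref, abs=1.0)
    assert d[0] == pytest.approx(d_ref, abs=0.05)
    # the along-coast position of lat 5 on a meridian is ~5 * 111.19 km
    assert s[0] == pytest.approx(555.97, abs=1.0)


def test_projection_on_jittered_coast_matches_brute_force(wiggly_coast):
    rng = np.random.default_rng(3)
    for _ in range(10):
        lat = rng.uniform(-9, 29)
        lon = rng.uniform(3, 7)
        s, d = project_many([lat], [lon], wiggly_coast)
        s_ref, d_ref = brute_force_projection(lat, lon, wiggly_coast)
        assert d[0] == pytest.approx(d_ref, abs=0.1)
        assert s[0] == pytest.approx(s_ref, abs=2.0)


def test_projection_clamps_past_terminus(meridian):
    a = project_to_coast((12.0, 0.0), meridian)
    assert a.s == pytest.approx(meridian.length_km, abs=1e-9)
    assert a.offshore_km == pytest.approx(
        great_circle_km((12.0, 0.0), (10.0, 0.0)), rel=1e-9)


def test_point_at_s_reprojects_exactly(wiggly_coast):
    s_in = np.linspace(0.0, wiggly_coast.length_km, 37)
    lat, lon = point_at_s(wiggly_coast, s_in)
    s_out, d = project_many(lat, lon, wiggly_coast)
    np.testing.assert_allclose(s_out, s_in, atol=1e-6)
    # constructed points sit on the polyline to within a few meters
    assert np.all(d < 0.005)


# ---------------------------------------------------------------------------
# locale discretization


def test_locale_point_counts(meridian):
    df = locale_to_points(meridian, 0.0, 1000.0, step_km=200.0)
    assert len(df) == 6
    df = locale_to_points(meridian, 0.0, 500.0, step_km=200.0)
    s, _ = project_many(df["lat"], df["lon"], meridian)
    np.testing.assert_allclose(np.sort(s), [0, 200, 400, 500], atol=1e-6)
    assert len(locale_to_points(meridian, 0.0, 0.0)) == 1
    assert (df["source"] == "literature").all()
    with pytest.raises(ValueError):
        locale_to_points(meridian, 10.0, 5.0)


def test_discretize_then_measure_round_trip(wiggly_coast):
    a, b = 300.0, 3200.0
    df = locale_to_points(wiggly_coast, a, b, step_km=200.0)
    s, _ = project_many(df["lat"], df["lon"], wiggly_coast)
    segs = segment_coast_positions(np.sort(s))
    assert len(segs) == 1
    assert segs[0].length_km == pytest.approx(b - a, abs=1e-6)


# ---------------------------------------------------------------------------
# cleaning


def test_cleaning_reason_codes(meridian, occurrences_df):
    occ = occurrences_df([
        ("sp1", 0.0, 0.0, "gbif"),       # zero-zero artifact
        ("sp1", 5.0, 0.1, "gbif"),       # good coastal point
        ("sp1", 5.0, 0.1, "gbif"),       # duplicate of the above
        ("sp1", 5.0, 3.0, "gbif"),       # ~300 km offshore
        ("sp2", 95.0, 0.0, "gbif"),      # invalid latitude
    ])
    kept, log = clean_occurrences(occ, [meridian], offshore_tol_km=200.0)
    assert len(kept) == 1
    assert kept.iloc[0]["lat"] == 5.0
    reasons = dict(zip(log["lat"], log["reason"]))
    assert set(log["reason"]) == {"zero-zero", "duplicate", "off-coast",
                                  "bad-coords"}
    assert len(log) == 4  # every drop logged exactly once


def test_cleaning_keeps_valid_points_unchanged(meridian, occurrences_df):
    occ = occurrences_df([("sp1", 4.0, 0.2, "gbif"), ("sp1", 6.0, -0.3, "lit")])
    kept, log = clean_occurrences(occ, [meridian])
    assert log.empty
    pd.testing.assert_frame_equal(kept, occ)


# ---------------------------------------------------------------------------
# assignment and archipelagos


def test_assignment_coastal_vs_archipelago(meridian, occurrences_df):
    # ~1330 km east of the meridian at the equator
    occ = occurrences_df([
        ("sp1", 5.0, 0.1, "gbif"),
        ("sp1", 2.0, 12.0, "gbif"),
        ("sp1", 2.4, 12.1, "gbif"),
    ])
    adf = assign_points(occ, [meridian])
    assert not adf.iloc[0]["is_archipelago"]
    assert adf.iloc[0]["coastline_id"] == "meridian"
    assert adf.iloc[1]["is_archipelago"] and adf.iloc[2]["is_archipelago"]
    # the two island points are ~60 km apart -> one cluster
    assert adf.iloc[1]["archipelago_id"] == adf.iloc[2]["archipelago_id"]
    with pytest.raises(ValueError):
        assign_points(occ, [])


def test_archipelago_span_rules():
    assert archipelago_range([2.0], [12.0]).length_km == 50.0
    two = archipelago_range([0.0, 0.0], [10.0, 13.0])
    assert two.length_km == pytest.approx(
        great_circle_km((0, 10), (0, 13)), rel=1e-9)
    # near-collinear cluster: span between the two extremes
    three = archipelago_range([0.0, 0.1, 0.0], [10.0, 11.5, 13.0])
    assert three.length_km == pytest.approx(
        great_circle_km((0, 10), (0, 13)), rel=1e-6)
    with pytest.raises(ValueError):
        archipelago_range([], [])


# ---------------------------------------------------------------------------
# segmenting rules


@pytest.mark.parametrize(
    "positions,expected_lengths",
    [
        ([100.0], [50.0]),                       # single isolated point
        ([100.0, 300.0], [200.0]),               # simple span
        ([100.0, 1700.0], [50.0, 50.0]),         # gap 1600 > 1500 splits
        ([0.0, 700.0, 1400.0, 3200.0], [50.0, 1400.0]),
        ([], []),
    ],
)
def test_segmenting_examples(positions, expected_lengths):
    segs = segment_coast_positions(positions)
    assert sorted(s.length_km for s in segs) == sorted(expected_lengths)
    for s in segs:
        assert s.is_isolated == (s.n_points == 1)


def test_gap_rule_is_strict_inequality():
    exactly = segment_coast_positions([0.0, 1500.0])
    assert len(exactly) == 1 and exactly[0].length_km == 1500.0
    beyond = segment_coast_positions([0.0, 1500.0 + 1e-6])
    assert len(beyond) == 2


@given(
    st.lists(st.floats(min_value=0.0, max_value=20000.0), min_size=0,
             max_size=25)
)
def test_segmenting_matches_connectivity_oracle(positions):
    segs = segment_coast_positions(positions)
    got = sorted(s.length_km for s in segs)
    expected = brute_force_segments(positions)
    np.testing.assert_allclose(got, expected, atol=1e-9)


@given(
    st.lists(st.floats(min_value=0.0, max_value=20000.0), min_size=1,
             max_size=25)
)
def test_total_range_bounds_on_one_coast(positions):
    s = np.asarray(positions)
    total = sum(seg.length_km for seg in segment_coast_positions(s))
    assert total >= 50.0 - 1e-9
    assert total <= (s.max() - s.min()) + 50.0 + 1e-9


# ---------------------------------------------------------------------------
# totals


def _assignments(rows):
    return pd.DataFrame(
        rows,
        columns=["species_id", "lat", "lon", "coastline_id", "s",
                 "offshore_km", "is_archipelago", "archipelago_id"],
    )


def test_total_range_composes_rules():
    adf = _assignments([
        ("sp1", 5.0, 0.1, "A", 500.0, 10.0, False, None),
        ("sp1", 2.0, 12.0, None, np.nan, 1300.0, True, "sp1/arch-0"),
    ])
    res = total_range("sp1", adf)
    assert res.total_km == pytest.approx(100.0)  # 50 coastal + 50 island

    adf = _assignments([
        ("sp2", 1.0, 0.0, "A", 100.0, 0.0, False, None),
        ("sp2", 4.0, 0.0, "A", 500.0, 0.0, False, None),
        ("sp2", 10.0, 5.0, "B", 200.0, 0.0, False, None),
        ("sp2", 15.0, 5.0, "B", 800.0, 0.0, False, None),
    ])
    res = total_range("sp2", adf)
    assert res.total_km == pytest.approx(400.0 + 600.0)
    assert res.lat_band_per_coast == {"A": (1.0, 4.0), "B": (10.0, 15.0)}


def test_total_range_invariant_to_order_and_duplicates():
    rows = [
        ("sp1", 1.0, 0.0, "A", 100.0, 0.0, False, None),
        ("sp1", 4.0, 0.0, "A", 500.0, 0.0, False, None),
        ("sp1", 9.0, 0.0, "A", 2300.0, 0.0, False, None),
    ]
    base = total_range("sp1", _assignments(rows)).total_km
    shuffled = total_range("sp1", _assignments(rows[::-1])).total_km
    doubled = total_range("sp1", _assignments(rows + rows)).total_km
    assert base == shuffled == doubled


def test_species_without_points_has_explicit_no_range():
    res = total_range("ghost", _assignments([]))
    assert not res.has_range
    assert np.isnan(res.total_km)
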