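"""Region assignment, occupancy profiles, fidelity and role labelling."""

import numpy as np
import pandas as pd
import pytest

import antsigns as A
from antsigns.errors import ParameterError


def ray_cast(point, polygon):
    """Independent even-odd ray-casting point-in-polygon oracle."""
    x, y = point
    inside = False
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def make_tracks(points, ant_id="a", rate=8.0):
    frame = pd.DataFrame(
        {
            "time_s": np.arange(len(points)) / rate,
            "ant_id": ant_id,
            "x_cm": [p[0] for p in points],
            "y_cm": [p[1] for p in points],
        }
    )
    return A.TrackTable(frame=frame, sampling_rate=rate)


class TestAssignRegions:
    def test_centroids_map_to_their_chamber(self, square_geometry):
        polys = square_geometry.chamber_polygons()
        pts = [(polys[c].centroid.x, polys[c].centroid.y) for c in polys]
        labelled = A.assign_regions(make_tracks(pts), square_geometry)
        assert list(labelled["region"]) == list(polys)

    def test_shared_vertex_lexicographic_tie_break(self, square_geometry):
        # the nest centre lies on all four chamber boundaries
        labelled = A.assign_regions(make_tracks([(7.5, 7.5)]), square_geometry)
        assert labelled["region"].iloc[0] == sorted(square_geometry.chamber_ids)[0]

    def test_matches_ray_casting_oracle(self, square_geometry, rng):
        pts = rng.uniform(-12, 27, size=(300, 2))
        labelled = A.assign_regions(make_tracks([tuple(p) for p in pts]), square_geometry)
        polys = {cid: verts for cid, verts in square_geometry.chambers}
        for (x, y), got in zip(pts, labelled["region"]):
            oracle = "outside"
            for cid in sorted(polys):
                if ray_cast((x, y), polys[cid]):
                    oracle = cid
                    break
            else:
                if ray_cast((x, y), square_geometry.arena):
                    oracle = "arena"
            # boundary points are the tie-break's business; skip exact edges
            on_edge = any(
                np.isclose(x, v) or np.isclose(y, v) for v in (0.0, 7.5, 15.0, -10.0, 25.0)
            )
            if not on_edge:
                assert got == oracle, (x, y)

    def test_far_point_is_outside(self, square_geometry):
        labelled = A.assign_regions(make_tracks([(500.0, 500.0)]), square_geometry)
        assert labelled["region"].iloc[0] == "outside"


class TestOccupancyProfiles:
    def test_always_in_one_chamber(self, square_geometry):
        pts = [(3.0, 3.0)] * 10  # chamber "1" of the square nest
        labelled = A.assign_regions(make_tracks(pts), square_geometry)
        prof = A.occupancy_profiles(labelled, square_geometry)
        assert prof.fractions.loc["a", "1"] == 1.0
        assert prof.in_nest["a"] == 1.0
        assert prof.n_excursions["a"] == 0

    def test_half_arena_renormalized(self, square_geometry):
        pts = [(3.0, 3.0)] * 5 + [(-5.0, -5.0)] * 5  # chamber then arena
        labelled = A.assign_regions(make_tracks(pts), square_geometry)
        prof = A.occupancy_profiles(labelled, square_geometry, renormalize_in_nest=True)
        assert prof.fractions.loc["a", "1"] == 1.0
        assert prof.in_nest["a"] == 0.5
        raw = A.occupancy_profiles(labelled, square_geometry, renormalize_in_nest=False)
        assert raw.fractions.loc["a", "1"] == 0.5

    def test_affine_invariance(self, square_geometry, short_tracks):
        tracks, _ = short_tracks
        shift = (37.0, -11.0)
        moved_geom = A.NestGeometry(
            chambers=tuple(
                (cid, tuple((x + shift[0], y + shift[1]) for x, y in verts))
                for cid, verts in square_geometry.chambers
            ),
            entrance=tuple(np.add(square_geometry.entrance, shift)),
            arena=tuple(tuple(np.add(v, shift)) for v in square_geometry.arena),
            door=tuple(np.add(square_geometry.door, shift)),
        )
        moved_frame = tracks.frame.assign(
            x_cm=tracks.frame["x_cm"] + shift[0], y_cm=tracks.frame["y_cm"] + shift[1]
        )
        moved = A.TrackTable(frame=moved_frame, sampling_rate=tracks.sampling_rate)
        p0 = A.occupancy_profiles(A.assign_regions(tracks, square_geometry), square_geometry)
        p1 = A.occupancy_profiles(A.assign_regions(moved, moved_geom), moved_geom)
        assert np.allclose(p0.fractions.to_numpy(), p1.fractions.to_numpy())

    def test_generator_fidelity_recovered(self, square_geometry, short_tracks):
        tracks, homes = short_tracks
        labelled = A.assign_regions(tracks, square_geometry)
        prof = A.occupancy_profiles(labelled, square_geometry)
        # preferred chamber equals the generator's home for almost every ant
        preferred = prof.fractions.idxmax(axis=1)
        agree = np.mean([preferred[a] == homes[a] for a in preferred.index])
        assert agree >= 0.95
        assert prof.fractions.max(axis=1).mean() == pytest.approx(0.71, abs=0.06)


class TestFidelitySummary:
    def test_immobile_ants(self, square_geometry):
        frames = []
        for i, pt in enumerate([(3, 3), (11, 3), (11, 11)]):
            frames.append(make_tracks([pt] * 8, ant_id=f"a{i}").frame)
        tracks = A.TrackTable(frame=pd.concat(frames, ignore_index=True), sampling_rate=8.0)
        labelled = A.assign_regions(tracks, square_geometry)
        summary = A.fidelity_summary(A.occupancy_profiles(labelled, square_geometry))
        assert summary["mean_max_fraction"] == 1.0
        assert summary["median_excursions"] == 0.0
        assert summary["n_kept"] == 3

    def test_strict_threshold_empties_summary(self, square_geometry):
        pts = [(3.0, 3.0)] * 5 + [(-5.0, -5.0)] * 5
        labelled = A.assign_regions(make_tracks(pts), square_geometry)
        prof = A.occupancy_profiles(labelled, square_geometry)
        summary = A.fidelity_summary(prof, in_nest_threshold=1.0)
        assert summary["n_kept"] == 0

    def test_hand_computed_two_ants(self, square_geometry):
        # a0: 6 frames chamber "1", 2 frames chamber "2" -> max fraction .75
        # a1: all 8 frames chamber "3" -> max fraction 1.0
        a0 = make_tracks([(3, 3)] * 3 + [(11, 3), (11, 3)] + [(3, 3)] * 3, ant_id="a0")
        a1 = make_tracks([(11, 11)] * 8, ant_id="a1")
        tracks = A.TrackTable(
            frame=pd.concat([a0.frame, a1.frame], ignore_index=True), sampling_rate=8.0
        )
        labelled = A.assign_regions(tracks, square_geometry)
        prof = A.occupancy_profiles(labelled, square_geometry)
        summary = A.fidelity_summary(prof)
        assert summary["mean_max_fraction"] == pytest.approx((0.75 + 1.0) / 2)
        assert prof.n_excursions["a0"] == 1  # one bounded 2-frame excursion
        assert summary["median_excursions"] == pytest.approx(0.5)


class TestExitReturn:
    def test_pvalue_equals_binom_tail(self, square_geometry):
        # ant exits from chamber "1" and returns to it: one success in one trial
        pts = [(3, 3)] * 3 + [(-5, -5)] * 2 + [(3, 3)] * 3
        labelled = A.assign_regions(make_tracks(pts), square_geometry)
        res = A.exit_return_test(labelled, square_geometry)
        assert (res["k"], res["n"]) == (1, 1)
        assert res["p_value"] == pytest.approx(A.binom_tail(1, 1, 0.25))

    def test_failed_return_counted(self, square_geometry):
        pts = [(3, 3)] * 3 + [(-5, -5)] * 2 + [(11, 11)] * 3
        res = A.exit_return_test(
            A.assign_regions(make_tracks(pts), square_geometry), square_geometry
        )
        assert (res["k"], res["n"]) == (0, 1)
        assert res["p_value"] == 1.0

    def test_no_exits_flagged(self, square_geometry):
        labelled = A.assign_regions(make_tracks([(3, 3)] * 5), square_geometry)
        res = A.exit_return_test(labelled, square_geometry)
        assert res["status"] == "no exits"
        assert np.isnan(res["p_value"])


class TestChamberRoles:
    def _profiles(self, square_geometry, queen_pts):
        frames = [make_tracks(queen_pts, ant_id="queen").frame]
        tracks = A.TrackTable(frame=pd.concat(frames, ignore_index=True), sampling_rate=8.0)
        labelled = A.assign_regions(tracks, square_geometry)
        return A.occupancy_profiles(labelled, square_geometry)

    def test_queen_chamber_labelled(self, square_geometry):
        prof = self._profiles(square_geometry, [(3, 11)] * 9 + [(3, 3)])
        roles = A.label_chamber_roles(
            prof, "queen", {"1": 0.5, "2": 1.9, "3": 3.0}, square_geometry
        )
        # chamber "Q" (upper-left quadrant) holds the queen 90% of the time
        assert roles.mapping["Q"] == "queen"

    def test_brood_threshold(self, square_geometry):
        # entrance -> "1" (tie-break), queen -> "Q"; workers are "2" and "3"
        prof = self._profiles(square_geometry, [(3, 11)] * 10)
        roles = A.label_chamber_roles(
            prof, "queen", {"2": 0.5, "3": 1.9}, square_geometry
        )
        workers = {c: r for c, r in roles.mapping.items() if r.startswith("worker")}
        assert workers == {
            "2": "worker_nonbrood",  # mean brood 0.5 < 1
            "3": "worker_brood",
        }

    def test_entrance_tie_flagged(self, square_geometry):
        # the door at the centre is equidistant from all four quadrants
        prof = self._profiles(square_geometry, [(3, 11)] * 10)
        roles = A.label_chamber_roles(prof, "queen", {}, square_geometry)
        assert roles.mapping[sorted(square_geometry.chamber_ids)[0]] == "entrance"
        assert any("tie" in f for f in roles.flags)

    def test_wandering_queen_unassigned(self, square_geometry):
        pts = [(3, 3)] * 5 + [(11, 3)] * 5
        prof = self._profiles(square_geometry, pts)
        roles = A.label_chamber_roles(prof, "queen", {}, square_geometry)
        assert "queen" not in roles.mapping.values()
        assert any("unassigned" in f for f in roles.flags)

    def test_unknown_queen_rejected(self, square_geometry):
        prof = self._profiles(square_geometry, [(3, 11)] * 10)
        with pytest.raises(ParameterError):
            A.label_chamber_roles(prof, "nobody", {}, square_geometry)
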