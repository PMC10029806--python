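"""Vaporshed partition, geodesic distances, tortuosity and g_ias."""

import math

import networkx as nx
import numpy as np
import pytest

from leafvox import vaporshed as vs
from leafvox.stack_io import DEFAULT_LEGEND

from conftest import make_stack

L = DEFAULT_LEGEND


def channel_stack(length=100, width=3, voxel=1.0):
    """Straight air channel along axis 0 inside a cell matrix."""
    vol = np.full((length + 4, width + 4, width + 4), L.mesophyll_cell, np.uint8)
    vol[2 : length + 2, 2 : width + 2, 2 : width + 2] = L.airspace
    return make_stack(vol, voxel=voxel)


def nx_geodesic_oracle(stack, sources):
    """Independent Dijkstra on an explicitly constructed voxel graph."""
    mask = (stack.volume == L.airspace) | (stack.volume == L.stoma)
    g = nx.Graph()
    coords = list(map(tuple, np.argwhere(mask)))
    coord_set = set(coords)
    offs = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for p in coords:
        for o in offs:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if q in coord_set:
                w = stack.voxel_size_um * math.sqrt(sum(x * x for x in o))
                g.add_edge(p, q, weight=w)
    dist = nx.multi_source_dijkstra_path_length(g, [tuple(s) for s in sources])
    return dist


class TestStomatalSites:
    def test_pore_count(self, small_slab):
        stack, truth = small_slab
        sites = vs.stomatal_sites(stack)
        assert len(sites) == truth.stoma_count == 4

    def test_touching_pores_merge(self):
        vol = np.full((10, 10, 10), L.mesophyll_cell, np.uint8)
        vol[4, 4, 4] = L.stoma
        vol[4, 4, 5] = L.stoma  # face-adjacent: one region
        vol[4, 4, 2] = L.airspace
        sites = vs.stomatal_sites(make_stack(vol))
        assert len(sites) == 1
        assert len(sites[0].voxels) == 2

    def test_no_stomata_rejected(self):
        vol = np.full((5, 5, 5), L.mesophyll_cell, np.uint8)
        with pytest.raises(ValueError, match="stoma"):
            vs.stomatal_sites(make_stack(vol))


class TestGeodesicDistance:
    def test_straight_channel_end_to_end(self):
        stack = channel_stack(length=100)
        field = vs.geodesic_distance(stack, sources=np.array([[2, 3, 3]]))
        far = field.distance[101, 3, 3]
        assert abs(far - 99.0) <= 1.0

    def test_l_shaped_channel_against_nx_oracle(self):
        # two 50-voxel single-file arms: corner-to-end path close to 100,
        # short of it only by the diagonal shortcut at the bend
        vol = np.full((55, 9, 56), L.mesophyll_cell, np.uint8)
        vol[2:52, 4, 3] = L.airspace  # arm 1 along axis 0
        vol[51, 4, 3:53] = L.airspace  # arm 2 along axis 2
        stack = make_stack(vol)
        sources = np.array([[2, 4, 3]])
        field = vs.geodesic_distance(stack, sources=sources)
        oracle = nx_geodesic_oracle(stack, sources)
        probe = (51, 4, 52)  # end of the far arm
        assert field.distance[probe] == pytest.approx(oracle[probe], rel=1e-9)
        assert field.distance[probe] == pytest.approx(98.0, rel=0.02)

    def test_sealed_cavity_flagged_unreachable(self):
        vol = np.full((40, 9, 9), L.mesophyll_cell, np.uint8)
        vol[2:20, 3:6, 3:6] = L.airspace  # open channel
        vol[30:34, 3:6, 3:6] = L.airspace  # sealed cavity
        stack = make_stack(vol)
        field = vs.geodesic_distance(stack, sources=np.array([[2, 4, 4]]))
        assert np.isfinite(field.distance[10, 4, 4])
        assert not field.reachable[31, 4, 4]
        assert np.isinf(field.distance[31, 4, 4])


class TestAssignVaporsheds:
    def test_single_stoma_claims_all_reachable_air(self, small_slab):
        stack, _ = small_slab
        vol = stack.volume.copy()
        sites = vs.stomatal_sites(stack)
        for site in sites[1:]:  # remove all but the first stoma
            vol[tuple(site.voxels.T)] = L.epidermis_abaxial
        one = make_stack(vol)
        field, _, _ = vs.assign_vaporsheds(one)
        air = one.volume == L.airspace
        assert set(np.unique(field[air])) <= {1, vs.UNREACHABLE}
        assert (field[air] == 1).sum() > 0

    def test_mirror_symmetric_two_stoma_volumes(self, two_stoma_slab):
        stack, _ = two_stoma_slab
        field, sites, _ = vs.assign_vaporsheds(stack)
        assert len(sites) == 2
        v1 = int((field == 1).sum())
        v2 = int((field == 2).sum())
        # equal up to the voxel layer on the tie plane
        tie_layer = stack.shape[1] * stack.shape[2]
        assert abs(v1 - v2) <= tie_layer

    def test_matches_brute_force_argmin_oracle(self, small_slab):
        stack, _ = small_slab
        field, sites, _ = vs.assign_vaporsheds(stack)
        air_idx = np.argwhere(stack.volume == L.airspace)
        per_stoma = []
        for site in sites:
            dist = nx_geodesic_oracle(stack, site.voxels)
            per_stoma.append(
                np.array([dist.get(tuple(p), np.inf) for p in air_idx])
            )
        per_stoma = np.vstack(per_stoma)
        finite = np.isfinite(per_stoma.min(axis=0))
        expected = np.where(
            finite,
            np.argmax(per_stoma <= per_stoma.min(axis=0) + 1e-9, axis=0) + 1,
            vs.UNREACHABLE,
        )
        observed = field[tuple(air_idx.T)]
        np.testing.assert_array_equal(observed, expected)

    def test_partition_disjoint_and_exhaustive(self, small_slab):
        stack, _ = small_slab
        field, _, _ = vs.assign_vaporsheds(stack)
        air = stack.volume == L.airspace
        assert np.all(field[air] != 0)  # every air voxel assigned or flagged
        assert np.all(field[~air] == 0)  # nothing outside the airspace


class TestEnclosedFilter:
    def test_spanning_vaporshed_not_enclosed(self, small_slab):
        stack, _ = small_slab
        vol = stack.volume.copy()
        sites = vs.stomatal_sites(stack)
        for site in sites[1:]:
            vol[tuple(site.voxels.T)] = L.epidermis_abaxial
        # corridor from the first channel to the k=0 lateral face so the
        # vaporshed touches the boundary
        c = np.round(sites[0].centroid_vox).astype(int)
        vol[c[0], vol.shape[1] // 2, 0 : c[2] + 1] = L.airspace
        one = make_stack(vol)
        field, _, _ = vs.assign_vaporsheds(one)
        assert vs.enclosed_filter(field) == {1: False}

    def test_interior_vaporsheds_enclosed(self, small_slab):
        stack, _ = small_slab
        field, _, _ = vs.assign_vaporsheds(stack)
        flags = vs.enclosed_filter(field)
        # slab channels are interior columns: all four enclosed
        assert flags == {1: True, 2: True, 3: True, 4: True}

    def test_grid_center_only(self):
        # 3x3 channel grid reaching the lateral faces except the center
        vol = np.full((31, 12, 31), L.mesophyll_cell, np.uint8)
        vol[:, 9:11, :] = L.epidermis_abaxial
        centers = [5, 15, 25]
        for idx_i, ci in enumerate(centers):
            for idx_k, ck in enumerate(centers):
                vol[ci - 1 : ci + 2, 2:9, ck - 1 : ck + 2] = L.airspace
                vol[ci, 9:11, ck] = L.stoma
        # connect channels laterally so the outer sheds reach the boundary
        vol[:, 2:4, 14:17] = L.airspace
        vol[14:17, 2:4, :] = L.airspace
        stack = make_stack(vol)
        field, sites, _ = vs.assign_vaporsheds(stack)
        flags = vs.enclosed_filter(field)
        center_id = field[15, 5, 15]
        assert flags[center_id]
        assert sum(flags.values()) < len(flags)


class TestVaporshedTraits:
    def test_volume_conservation_exact(self, small_slab):
        stack, _ = small_slab
        field, _, _ = vs.assign_vaporsheds(stack)
        table = vs.vaporshed_traits(stack, field)
        total = sum(r.V_ias_vap_um3 for r in table.rows) + table.V_ias_unreachable_um3
        v_ias = float((stack.volume == L.airspace).sum()) * stack.voxel_volume_um3
        assert total == v_ias

    def test_symmetric_stomata_equal_surfaces(self, two_stoma_slab):
        stack, _ = two_stoma_slab
        field, _, _ = vs.assign_vaporsheds(stack)
        table = vs.vaporshed_traits(stack, field)
        s1, s2 = (r.S_m_vap_um2 for r in table.rows)
        assert s1 == pytest.approx(s2, rel=0.02)

    def test_aggregation_consistent_with_whole_scan(self, small_slab):
        from leafvox import tissue_traits as tt

        stack, _ = small_slab
        field, _, _ = vs.assign_vaporsheds(stack)
        table = vs.vaporshed_traits(stack, field)
        s_sum = sum(r.S_m_vap_um2 for r in table.rows)
        v_sum = sum(r.V_ias_vap_um3 for r in table.rows)
        whole = tt.compute_trait_table(stack)
        assert s_sum / v_sum == pytest.approx(whole.Sm_Vias, rel=0.03)


class TestTortuosityLambda:
    def test_straight_vertical_channels_give_unity(self, small_slab):
        stack, _ = small_slab
        tau, lam = vs.tortuosity_lambda(stack)
        assert tau == pytest.approx(1.0, rel=0.02)
        assert lam == pytest.approx(1.0, rel=0.02)

    def test_u_detour_doubles_tau_at_far_arm(self):
        # U with arms of 15 voxels joined by a 30-voxel bend: the geodesic
        # to the far-arm tip (down + across + down = 2x the straight-line
        # gap) is about twice the euclidean distance to the stoma
        vol = np.full((9, 26, 41), L.mesophyll_cell, np.uint8)
        vol[3:6, 4:20, 3:6] = L.airspace  # near arm above the stoma
        vol[3:6, 4:7, 3:37] = L.airspace  # bend at the top
        vol[3:6, 4:19, 34:37] = L.airspace  # far arm back down
        vol[3:6, 20:23, 3:6] = L.epidermis_abaxial
        vol[4, 20:23, 4] = L.stoma
        stack = make_stack(vol)
        dist = vs.geodesic_distance(stack)
        sites = vs.stomatal_sites(stack)
        centroid = np.array(sites[0].centroid_vox)
        probe = np.array([4, 17, 35])  # bottom of the far arm
        l_geo = dist.distance[tuple(probe)]
        l_euc = np.linalg.norm(probe - centroid) * stack.voxel_size_um
        assert l_geo / l_euc == pytest.approx(2.0, rel=0.15)

    def test_ratios_at_least_one_everywhere(self, small_leaf):
        stack, _ = small_leaf
        tau, lam = vs.tortuosity_lambda(stack)
        assert tau >= 1.0 and lam >= 1.0

    def test_obstacles_do_not_decrease_medians(self, small_slab):
        stack, _ = small_slab
        tau0, lam0 = vs.tortuosity_lambda(stack)
        vol = stack.volume.copy()
        air = np.argwhere(vol == L.airspace)
        # wall off the middle of each channel, forcing detours
        j_mid = int(np.median(air[:, 1]))
        blocked = vol.copy()
        sel = (air[:, 1] == j_mid) & (air[:, 0] % 2 == 0)
        blocked[tuple(air[sel].T)] = L.mesophyll_cell
        tau1, lam1 = vs.tortuosity_lambda(make_stack(blocked))
        assert tau1 >= tau0 - 1e-12
        assert lam1 >= lam0 - 1e-12


class TestGias:
    def test_linear_in_porosity(self):
        g1 = vs.estimate_g_ias(0.15, 1.2, 1.3, 200.0)
        g2 = vs.estimate_g_ias(0.30, 1.2, 1.3, 200.0)
        assert g2 == pytest.approx(2 * g1)

    def test_free_air_limit(self):
        # tau = lam = theta = 1: conductance of free air over half depth
        g = vs.estimate_g_ias(1.0, 1.0, 1.0, 200.0)
        molar = 101325.0 / (8.314462618 * 298.15)
        assert g == pytest.approx(1.54e-5 / 100e-6 * molar)

    def test_hand_unit_conversion(self):
        # independent hand conversion: D*theta/(tau*lam*dL) * P/(RT)
        expected = (1.54e-5 * 0.3) / (1.1 * 1.3 * 100e-6) * (
            101325.0 / (8.314462618 * 298.15)
        )
        g = vs.estimate_g_ias(0.3, 1.1, 1.3, 200.0, 1.54e-5, 298.15, 101325.0)
        assert g == pytest.approx(expected, rel=1e-12)
        assert g == pytest.approx(1.32, rel=0.01)  # mol m-2 s-1 magnitude

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            vs.estimate_g_ias(1.5, 1.1, 1.3, 200.0)
        with pytest.raises(ValueError):
            vs.estimate_g_ias(0.3, 0.9, 1.3, 200.0)
        with pytest.raises(ValueError):
            vs.estimate_g_ias(0.3, 1.1, 1.3, -5.0)
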