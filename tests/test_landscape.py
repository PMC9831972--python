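"""Cost surfaces, least-cost distances, permeability search, origin map."""

import numpy as np
import pytest

from reefpop.errors import ConfigError, DegenerateInputError
from reefpop.landscape import (
    LAND,
    REEF,
    SEA,
    SEAMOUNT,
    HabitatRaster,
    PermeabilityConfig,
    build_cost_surface,
    lc_distance,
    lc_distance_matrix,
    optimize_permeability,
    origin_map,
)


def sea_raster(nrows, ncols):
    return HabitatRaster(codes=np.full((nrows, ncols), SEA))


def edge_w(surf, a, b):
    """Undirected edge weight (stored in one orientation only)."""
    return max(surf.graph[a, b], surf.graph[b, a])


class TestCostSurface:
    def test_uniform_sea_horizontal_edge_is_cellsize(self):
        r = sea_raster(3, 3)
        surf = build_cost_surface(r, PermeabilityConfig(1, 1))
        assert edge_w(surf, 4, 5) == pytest.approx(1.0)
        assert edge_w(surf, 4, 1) == pytest.approx(1.0)

    def test_sea_reef_edge_mixes_resistances(self):
        codes = np.full((1, 2), SEA)
        codes[0, 1] = REEF
        r = HabitatRaster(codes=codes)
        surf = build_cost_surface(r, PermeabilityConfig(p_reef=100, p_seamount=1))
        assert edge_w(surf, 0, 1) == pytest.approx((1 + 1 / 100) / 2)

    def test_doubling_permeability_halves_weights(self):
        codes = np.array([[SEA, REEF, SEAMOUNT], [REEF, SEA, SEA]])
        r = HabitatRaster(codes=codes)
        s1 = build_cost_surface(r, PermeabilityConfig(10, 5), conductance_mean=True)
        s2 = build_cost_surface(r, PermeabilityConfig(20, 10), conductance_mean=True)
        # under the conductance-mean convention sea stays at 1 so only scale
        # the reef/seamount pair; compare the reef-seamount edge
        assert edge_w(s1, 1, 2) == pytest.approx(2 * edge_w(s2, 1, 2))

    def test_land_cells_are_disconnected(self):
        codes = np.full((1, 3), SEA)
        codes[0, 1] = LAND
        surf = build_cost_surface(HabitatRaster(codes=codes), PermeabilityConfig(1, 1))
        d = lc_distance(surf, (0, 0))
        assert np.isinf(d[0, 2]) and np.isinf(d[0, 1])

    def test_all_land_raster_rejected(self):
        with pytest.raises(DegenerateInputError):
            HabitatRaster(codes=np.full((3, 3), LAND))

    def test_permeability_ordering_enforced(self):
        with pytest.raises(ConfigError):
            PermeabilityConfig(p_reef=5, p_seamount=10)
        with pytest.raises(ConfigError):
            PermeabilityConfig(p_reef=200, p_seamount=1)


class TestLCDistance:
    def test_straight_corridor(self):
        r = sea_raster(1, 5)
        surf = build_cost_surface(r, PermeabilityConfig(1, 1))
        assert lc_distance(surf, (0, 0), [(0, 4)])[0] == pytest.approx(4.0)

    def test_source_on_land_rejected(self):
        codes = np.full((2, 2), SEA)
        codes[0, 0] = LAND
        surf = build_cost_surface(HabitatRaster(codes=codes), PermeabilityConfig(1, 1))
        with pytest.raises(ConfigError):
            lc_distance(surf, (0, 0))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        codes = rng.choice([SEA, REEF, SEAMOUNT, LAND], size=(8, 8), p=[0.5, 0.2, 0.1, 0.2])
        codes[0, 0] = SEA
        codes[7, 7] = SEA
        r = HabitatRaster(codes=codes)
        surf = build_cost_surface(r, PermeabilityConfig(10, 3))
        d_ab = lc_distance(surf, (0, 0), [(7, 7)])[0]
        d_ba = lc_distance(surf, (7, 7), [(0, 0)])[0]
        assert d_ab == pytest.approx(d_ba, rel=1e-12)

    def test_wall_with_gap_matches_exhaustive_paths(self):
        """5x5 sea with a land wall pierced by one gap: compare against a
        brute-force enumeration over simple paths."""
        codes = np.full((5, 5), SEA)
        codes[:, 2] = LAND
        codes[3, 2] = SEA  # the gap
        r = HabitatRaster(codes=codes)
        surf = build_cost_surface(r, PermeabilityConfig(1, 1))
        got = lc_distance(surf, (0, 0), [(0, 4)])[0]
        assert got == pytest.approx(_exhaustive_shortest(r, (0, 0), (0, 4)), rel=1e-12)


def _exhaustive_shortest(raster, src, dst, perm=None):
    """Depth-first enumeration of simple paths (independent of Dijkstra)."""
    perm = perm or PermeabilityConfig(1, 1)
    p = perm.permeability()
    marine = raster.marine_mask()
    nrows, ncols = raster.shape
    best = [np.inf]

    def resist(cell):
        return 1.0 / p[raster.codes[cell]]

    def rec(cell, seen, acc):
        if acc >= best[0]:
            return
        if cell == dst:
            best[0] = acc
            return
        r, c = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and marine[rr, cc] and (rr, cc) not in seen:
                    step = np.sqrt(2) if dr and dc else 1.0
                    w = step * raster.cellsize * (resist((r, c)) + resist((rr, cc))) / 2
                    rec((rr, cc), seen | {(rr, cc)}, acc + w)

    rec(src, {src}, 0.0)
    return best[0]


class TestOptimizePermeability:
    def test_uniform_habitat_profile_is_flat_and_tie_broken_low(self, archipelago):
        codes = np.full((20, 30), SEA)
        r = HabitatRaster(codes=codes)
        import pandas as pd

        cells = [(2, 2), (5, 25), (15, 4), (18, 28)]
        sites = pd.DataFrame({"id": list("abcd"), "row": [c[0] for c in cells],
                              "col": [c[1] for c in cells]})
        surf = build_cost_surface(r, PermeabilityConfig(1, 1))
        D = lc_distance_matrix(surf, cells)
        x = np.clip(2e-3 * D, 0, None)
        F = x / (1 + x)
        np.fill_diagonal(F, 0)
        best, profile = optimize_permeability(r, sites, F, coarse=(1.0, 5.0, 20.0, 100.0),
                                              refine_step=1.0)
        rs = [p[2] for p in profile]
        assert np.var(rs) < 1e-20
        assert (best.p_reef, best.p_seamount) == (1.0, 1.0)

    def test_constraint_respected_over_profile(self, archipelago, archipelago_lc):
        raster, cells = archipelago
        import pandas as pd

        sites = pd.DataFrame({"id": [f"s{i}" for i in range(len(cells))],
                              "row": [c[0] for c in cells], "col": [c[1] for c in cells]})
        x = 2e-3 * archipelago_lc
        F = x / (1 + x)
        np.fill_diagonal(F, 0)
        _, profile = optimize_permeability(raster, sites, F,
                                           coarse=(1.0, 10.0, 100.0), refine_step=1.0)
        assert all(ps <= pr for pr, ps, _ in profile)

    def test_constant_genetic_distance_rejected(self, archipelago):
        raster, cells = archipelago
        import pandas as pd

        sites = pd.DataFrame({"id": [f"s{i}" for i in range(len(cells))],
                              "row": [c[0] for c in cells], "col": [c[1] for c in cells]})
        F = np.full((len(cells), len(cells)), 0.2)
        np.fill_diagonal(F, 0)
        with pytest.raises(DegenerateInputError):
            optimize_permeability(raster, sites, F, coarse=(1.0, 10.0), refine_step=1.0)


class TestOriginMap:
    def test_affine_rescaling_of_diversity_leaves_map_unchanged(self, archipelago):
        import pandas as pd

        raster, cells = archipelago
        rng = np.random.default_rng(5)
        theta = rng.uniform(1e-3, 3e-3, size=len(cells))
        sites = pd.DataFrame({"id": [f"s{i}" for i in range(len(cells))],
                              "row": [c[0] for c in cells], "col": [c[1] for c in cells],
                              "theta_pi": theta})
        m1 = origin_map(raster, sites, PermeabilityConfig(1, 1))
        sites2 = sites.assign(theta_pi=3.0 * theta + 1.0)
        m2 = origin_map(raster, sites2, PermeabilityConfig(1, 1))
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-10, equal_nan=True)
        assert m1.argmin == m2.argmin

    def test_two_sites_rejected(self, archipelago):
        import pandas as pd

        raster, cells = archipelago
        sites = pd.DataFrame({"id": ["a", "b"], "row": [cells[0][0], cells[1][0]],
                              "col": [cells[0][1], cells[1][1]], "theta_pi": [1e-3, 2e-3]})
        with pytest.raises(ConfigError):
            origin_map(raster, sites, PermeabilityConfig(1, 1))

    def test_constant_diversity_rejected(self, archipelago):
        import pandas as pd

        raster, cells = archipelago
        sites = pd.DataFrame({"id": [f"s{i}" for i in range(len(cells))],
                              "row": [c[0] for c in cells], "col": [c[1] for c in cells],
                              "theta_pi": 1e-3})
        with pytest.raises(DegenerateInputError):
            origin_map(raster, sites, PermeabilityConfig(1, 1))

    def test_values_are_valid_correlations(self, archipelago):
        import pandas as pd

        raster, cells = archipelago
        rng = np.random.default_rng(6)
        sites = pd.DataFrame({"id": [f"s{i}" for i in range(len(cells))],
                              "row": [c[0] for c in cells], "col": [c[1] for c in cells],
                              "theta_pi": rng.uniform(1e-3, 3e-3, len(cells))})
        om = origin_map(raster, sites, PermeabilityConfig(1, 1))
        v = om.values[~np.isnan(om.values)]
        assert v.size and (v >= -1 - 1e-12).all() and (v <= 1 + 1e-12).all()
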