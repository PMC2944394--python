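import numpy as np
import pytest
from scipy import stats

import stentsim as ss
from stentsim import dynamics
from stentsim.lattice import (
    OCC_CSMC,
    OCC_EC,
    OCC_NONE,
    OCC_SSMC,
    OUTSIDE,
)

P = ss.Params()
CENTER = (4, 4, 4)


class TestPhenotype:
    def test_intact_matrix_low_crowding_is_contractile(self, block_lattice):
        block_lattice.occupant[CENTER] = OCC_SSMC
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_CSMC

    def test_degraded_own_site_is_synthetic(self, block_lattice):
        block_lattice.ecm[CENTER] = 0.6
        block_lattice.occupant[CENTER] = OCC_CSMC
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_SSMC

    def test_degraded_neighbour_recruits(self, block_lattice):
        """A cSMC next to partially degraded matrix modulates to the
        synthetic phenotype even though its own site is intact."""
        block_lattice.ecm[4, 4, 5] = 0.95
        block_lattice.occupant[CENTER] = OCC_CSMC
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_SSMC

    def test_matrix_free_neighbour_does_not_recruit(self, block_lattice):
        """Absent matrix (ECM = 0, e.g. the lumen) is not degraded tissue:
        quiescence at the lumen surface is preserved."""
        block_lattice.ecm[4, 4, 5] = 0.0
        block_lattice.occupant[CENTER] = OCC_CSMC
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_CSMC

    def test_crowding_forces_synthetic(self, block_lattice):
        block_lattice.occupant[3:6, 3:6, 3:6] = OCC_SSMC
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_SSMC

    def test_switch_is_reversible(self, block_lattice):
        block_lattice.occupant[CENTER] = OCC_SSMC
        block_lattice.ecm[CENTER] = 0.8
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_SSMC
        block_lattice.ecm[CENTER] = 1.0
        assert dynamics.update_phenotype(block_lattice, CENTER, P) == OCC_CSMC

    def test_non_smc_rejected(self, block_lattice):
        block_lattice.occupant[CENTER] = OCC_EC
        with pytest.raises(ValueError):
            dynamics.update_phenotype(block_lattice, CENTER, P)


class TestMigration:
    def test_ec_blocks_all_moves(self, block_lattice, rng):
        """An EC on the only open neighbour is an impenetrable barrier."""
        lat = ss.Lattice.empty((3, 1, 1), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[:] = 1.0
        lat.occupant[0, 0, 0] = OCC_SSMC
        lat.occupant[1, 0, 0] = OCC_EC
        lat.occupant[2, 0, 0] = OCC_EC
        for _ in range(50):
            assert dynamics.attempt_migration(lat, (0, 0, 0), P, rng) is None
        assert lat.occupant[0, 0, 0] == OCC_SSMC

    def test_fully_crowded_never_moves(self, block_lattice, rng):
        block_lattice.occupant[:] = OCC_SSMC
        before = block_lattice.occupant.copy()
        for _ in range(20):
            assert dynamics.attempt_migration(block_lattice, CENTER, P, rng) is None
        np.testing.assert_array_equal(block_lattice.occupant, before)

    def test_outside_and_no_matrix_rejected(self, rng):
        lat = ss.Lattice.empty((3, 3, 3), np.zeros(3), 0.01)
        lat.domain[:] = OUTSIDE
        lat.domain[1, 1, 1] = ss.WALL
        lat.ecm[1, 1, 1] = 1.0
        lat.occupant[1, 1, 1] = OCC_SSMC
        for _ in range(50):
            assert dynamics.attempt_migration(lat, (1, 1, 1), P, rng) is None

    def test_destination_uniform_over_stencil(self, rng):
        """In uniform ECM the accepted destination is uniform over the
        neighbourhood (chi-squared at n = 1e4)."""
        counts = {}
        n = 10_000
        lat0 = ss.Lattice.empty((9, 9, 9), np.zeros(3), 0.01)
        lat0.domain[:] = ss.WALL
        lat0.ecm[:] = 1.0
        for _ in range(n):
            lat = lat0.copy()
            lat.occupant[CENTER] = OCC_SSMC
            dest = dynamics.attempt_migration(lat, CENTER, P, rng)
            assert dest is not None  # all destinations valid here
            counts[dest] = counts.get(dest, 0) + 1
        assert len(counts) == P.stencil
        chi2 = sum((c - n / P.stencil) ** 2 / (n / P.stencil)
                   for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, df=P.stencil - 1)

    def test_can_walk_adjacent_to_matrix(self, rng):
        """Matrix-free sites adjacent to matrix are walkable."""
        lat = ss.Lattice.empty((3, 3, 3), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[:, :, 0] = 1.0   # matrix only in the k=0 plane
        lat.occupant[1, 1, 1] = OCC_SSMC
        lat.ecm[1, 1, 1] = 0.0
        moved = 0
        for _ in range(200):
            site = tuple(np.argwhere(lat.occupant == OCC_SSMC)[0])
            if dynamics.attempt_migration(lat, site, P, rng) is not None:
                moved += 1
        assert moved > 0


class TestProliferationSMC:
    def test_successful_division_consumes_g(self, block_lattice, rng):
        """G = 3, G_crit = 1: a division leaves G = 2 and one daughter."""
        block_lattice.occupant[CENTER] = OCC_SSMC
        block_lattice.g[CENTER] = 3.0
        daughters = 0
        for _ in range(200):
            d = dynamics.attempt_proliferation_smc(block_lattice, CENTER, P, rng)
            if d is not None:
                daughters = 1
                break
        assert daughters == 1
        assert block_lattice.g[CENTER] == pytest.approx(2.0)
        assert (block_lattice.occupant == OCC_SSMC).sum() == 2

    def test_no_division_at_or_below_threshold(self, block_lattice, rng):
        block_lattice.occupant[CENTER] = OCC_SSMC
        block_lattice.g[CENTER] = 1.0   # equal to G_crit: strict inequality
        for _ in range(100):
            assert dynamics.attempt_proliferation_smc(
                block_lattice, CENTER, P, rng) is None
        assert block_lattice.g[CENTER] == 1.0

    def test_crowded_parent_keeps_g(self, block_lattice, rng):
        """Failure to site the daughter leaves G unchanged (consumption
        only on successful division)."""
        block_lattice.occupant[:] = OCC_SSMC
        block_lattice.g[CENTER] = 3.0
        for _ in range(100):
            assert dynamics.attempt_proliferation_smc(
                block_lattice, CENTER, P, rng) is None
        assert block_lattice.g[CENTER] == 3.0


class TestProliferationEC:
    def _surface_lattice(self):
        """k=0 plane carries matrix; k=1 plane is the matrix-free surface."""
        lat = ss.Lattice.empty((9, 9, 3), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[:, :, 0] = 1.0
        return lat

    def test_daughter_on_surface_only(self, rng):
        lat = self._surface_lattice()
        lat.occupant[4, 4, 1] = OCC_EC
        placed = set()
        for _ in range(500):
            d = dynamics.attempt_proliferation_ec(lat, (4, 4, 1), P, rng)
            if d is not None:
                placed.add(d)
                lat.occupant[d] = OCC_NONE  # reset for the next attempt
        assert placed
        for s in placed:
            assert lat.ecm[s] == 0.0
            assert any(lat.ecm[nb] > 0 for nb in ss.neighbors(lat, s, P.stencil))

    def test_candidate_with_ecm_rejected(self, rng):
        lat = self._surface_lattice()
        lat.ecm[:] = 1.0   # no matrix-free site anywhere
        lat.ecm[4, 4, 1] = 0.0
        lat.occupant[4, 4, 1] = OCC_EC
        for _ in range(100):
            assert dynamics.attempt_proliferation_ec(lat, (4, 4, 1), P, rng) is None

    def test_surrounded_ec_cannot_divide(self, rng):
        lat = self._surface_lattice()
        lat.occupant[:, :, 1] = OCC_EC
        for _ in range(50):
            assert dynamics.attempt_proliferation_ec(lat, (4, 4, 1), P, rng) is None

    def test_healing_strip_advances_monotonically(self, rng):
        """1D wound-healing: on a single-row surface the healed length is
        non-decreasing and eventually complete."""
        # two-row lattice: row 0 carries the supporting matrix, row 1 is
        # the matrix-free surface strip the front advances along
        lat = ss.Lattice.empty((2, 1, 40), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[0, :, :] = 1.0
        lat.occupant[1, 0, 0] = OCC_EC
        healed = 1
        for _ in range(2000):
            ecs = np.argwhere(lat.occupant == OCC_EC)
            for site in ecs:
                dynamics.attempt_proliferation_ec(lat, tuple(site), P, rng)
            new_healed = int((lat.occupant[1, 0, :] == OCC_EC).sum())
            assert new_healed >= healed
            healed = new_healed
            if healed == 40:
                break
        assert healed == 40


class TestMatrixFields:
    def test_production_steps_and_clamp(self, block_lattice):
        block_lattice.occupant[CENTER] = OCC_SSMC
        block_lattice.ecm[CENTER] = 0.4
        dynamics.produce_ecm(block_lattice, CENTER, P)
        assert block_lattice.ecm[CENTER] == pytest.approx(0.6)
        block_lattice.ecm[CENTER] = 0.95
        dynamics.produce_ecm(block_lattice, CENTER, P)
        assert block_lattice.ecm[CENTER] == 1.0

    def test_empty_site_full_after_five_days(self, block_lattice):
        """At c_ecm = 0.20 an sSMC rebuilds bare matrix in ceil(1/0.2) = 5
        daily applications."""
        block_lattice.occupant[CENTER] = OCC_SSMC
        block_lattice.ecm[CENTER] = 0.0
        for day in range(5):
            assert block_lattice.ecm[CENTER] < 1.0
            dynamics.produce_ecm(block_lattice, CENTER, P)
        assert block_lattice.ecm[CENTER] == 1.0

    def test_degradation_requires_both_components(self, block_lattice):
        lat = block_lattice
        lat.ecm[0, 0, 0] = 1.0
        lat.mdf[0, 0, 0] = 1.0
        lat.ecm[1, 1, 1] = 0.8   # ECM alone: untouched
        lat.mdf[2, 2, 2] = 0.0
        dynamics.degrade_matrix(lat, P)
        assert lat.ecm[0, 0, 0] == pytest.approx(0.95)
        assert lat.mdf[0, 0, 0] == pytest.approx(0.95)
        assert lat.ecm[1, 1, 1] == pytest.approx(0.8)

    def test_independent_floors(self):
        lat = ss.Lattice.empty((1, 1, 1), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[0, 0, 0] = 0.03
        lat.mdf[0, 0, 0] = 0.10
        dynamics.degrade_matrix(lat, P)
        assert lat.ecm[0, 0, 0] == 0.0
        assert lat.mdf[0, 0, 0] == pytest.approx(0.05)

    def test_full_resorption_in_twenty_days(self):
        """ECM = MDF = 1 at c_deg = 0.05: damaged tissue fully resorbed in
        exactly 20 daily increments."""
        lat = ss.Lattice.empty((1, 1, 1), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[0, 0, 0] = 1.0
        lat.mdf[0, 0, 0] = 1.0
        days = 0
        while lat.ecm[0, 0, 0] > 0.0:
            dynamics.degrade_matrix(lat, P)
            days += 1
            assert days < 100
        assert days == 20


class TestInvariants:
    def test_fields_stay_in_range_under_fuzzing(self, rng):
        """ECM in [0,1], MDF, G >= 0 after arbitrary operation sequences."""
        lat = ss.Lattice.empty((6, 6, 6), np.zeros(3), 0.01)
        lat.domain[:] = ss.WALL
        lat.ecm[:] = rng.random(lat.dims)
        lat.mdf[:] = rng.random(lat.dims)
        lat.g[:] = rng.random(lat.dims) * 3
        sites = [tuple(s) for s in rng.integers(0, 6, size=(30, 3))]
        for s in sites:
            lat.occupant[s] = OCC_SSMC
        for _ in range(300):
            op = rng.integers(4)
            occ = np.argwhere(lat.occupant == OCC_SSMC)
            if len(occ) == 0:
                break
            s = tuple(occ[rng.integers(len(occ))])
            if op == 0:
                dynamics.degrade_matrix(lat, P)
            elif op == 1:
                dynamics.produce_ecm(lat, s, P)
            elif op == 2:
                dynamics.attempt_migration(lat, s, P, rng)
            else:
                dynamics.attempt_proliferation_smc(lat, s, P, rng)
            assert lat.ecm.min() >= 0 and lat.ecm.max() <= 1
            assert lat.mdf.min() >= 0
            assert lat.g.min() >= 0

    def test_g_total_never_increases(self, block_lattice, rng):
        block_lattice.g[:] = 2.0
        block_lattice.occupant[CENTER] = OCC_SSMC
        total = block_lattice.g.sum()
        for _ in range(100):
            occ = np.argwhere(block_lattice.occupant == OCC_SSMC)
            s = tuple(occ[rng.integers(len(occ))])
            dynamics.attempt_proliferation_smc(block_lattice, s, P, rng)
            new_total = block_lattice.g.sum()
            assert new_total <= total + 1e-9
            total = new_total
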