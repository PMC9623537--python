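"""Collision and SNARE-encounter kinetics, including the Monte-Carlo
diffusion oracle for the Smoluchowski coagulation kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snarefusion import (
    EncounterParams,
    InvalidParameterError,
    Medium,
    VesicleGeometry,
    VesiclePopulation,
    collision_rate_per_vesicle,
    collisions_before_event,
    contact_dwell_time,
    encounter_probability_per_collision,
    explored_area,
    total_collision_rate,
)
from snarefusion.units import BOLTZMANN_J_PER_K


class TestCollisionRate:
    def test_standard_assay_rate_is_about_300_per_s(self, standard_populations, medium):
        # a vSUV in the 1 mM 9:1 mix collides with tSUVs ~300 times a second
        vpop, tpop = standard_populations
        rate = collision_rate_per_vesicle(tpop, medium, 25.0)
        assert rate == pytest.approx(300.0, rel=0.05)

    def test_zero_density_gives_zero(self, suv_geometry, medium):
        empty = VesiclePopulation(geometry=suv_geometry, number_density=0.0)
        assert collision_rate_per_vesicle(empty, medium, 25.0) == 0.0

    def test_equal_radii_rate_is_radius_independent(self, medium):
        # for equal radii the kernel reduces to 8kBT·ρ/(3η)
        rho = 2.7e19
        rates = []
        for r in (25.0, 50.0):
            pop = VesiclePopulation(
                geometry=VesicleGeometry(outer_radius=r), number_density=rho
            )
            rates.append(collision_rate_per_vesicle(pop, medium, r))
        assert rates[0] == pytest.approx(rates[1], rel=1e-12)
        kernel = rates[0] / rho
        assert kernel == pytest.approx(
            8 * medium.thermal_energy_j / (3 * medium.viscosity), rel=1e-12
        )

    def test_symmetric_under_radius_exchange(self, medium):
        pop_a = VesiclePopulation(
            geometry=VesicleGeometry(outer_radius=20.0), number_density=1e19
        )
        pop_b = VesiclePopulation(
            geometry=VesicleGeometry(outer_radius=60.0), number_density=1e19
        )
        r_ab = collision_rate_per_vesicle(pop_a, medium, 60.0)
        r_ba = collision_rate_per_vesicle(pop_b, medium, 20.0)
        assert r_ab == pytest.approx(r_ba, rel=1e-12)

    def test_kernel_equals_stokes_einstein_form(self, medium):
        # 2(R1+R2)²kBT/(3ηR1R2) is algebraically 4π(D1+D2)(R1+R2)
        r1, r2 = 20.0, 45.0
        pop = VesiclePopulation(
            geometry=VesicleGeometry(outer_radius=r1), number_density=1e19
        )
        kernel = collision_rate_per_vesicle(pop, medium, r2) / 1e19
        kbt = medium.thermal_energy_j
        d1 = kbt / (6 * math.pi * medium.viscosity * r1 * 1e-9)
        d2 = kbt / (6 * math.pi * medium.viscosity * r2 * 1e-9)
        assert kernel == pytest.approx(4 * math.pi * (d1 + d2) * (r1 + r2) * 1e-9, rel=1e-12)

    def test_zero_radius_rejected(self, suv_geometry, medium):
        pop = VesiclePopulation(geometry=suv_geometry, number_density=1e19)
        with pytest.raises(InvalidParameterError):
            collision_rate_per_vesicle(pop, medium, 0.0)


class TestSmoluchowskiMonteCarloOracle:
    def test_diffusive_capture_rate_matches_kernel(self):
        """Brute-force Brownian dynamics of a diffusing pair in a periodic box.

        In reduced units (relative diffusion D = 1, contact distance a = 1,
        box side L) the Smoluchowski pair-capture rate is k = 4πDa,
        finite-size-corrected by the cubic-lattice factor
        1/(1 − 2.837297·a/L). The mean first-contact time from a uniform
        start is then L³/k. The same 4π(D1+D2)(R1+R2) kernel is what
        collision_rate_per_vesicle evaluates (checked algebraically above),
        so this validates the physical rate law end to end.
        """
        rng = np.random.default_rng(20240917)
        d_rel, a, box = 1.0, 1.0, 15.0
        dt = 5e-3
        sigma = math.sqrt(2 * d_rel * dt)
        n_walkers = 400
        max_steps = 200_000
        pos = rng.uniform(0, box, size=(n_walkers, 3))
        # exclude starts already inside the contact sphere around the origin
        for _ in range(10):
            mic = np.abs((pos + box / 2) % box - box / 2)
            inside = np.einsum("ij,ij->i", mic, mic) < a * a
            pos[inside] = rng.uniform(0, box, size=(int(inside.sum()), 3))
        alive = np.ones(n_walkers, bool)
        t_hit = np.full(n_walkers, np.nan)
        for step in range(1, max_steps + 1):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            pos[idx] = (pos[idx] + rng.normal(0, sigma, size=(idx.size, 3))) % box
            mic = np.abs((pos[idx] + box / 2) % box - box / 2)
            hit = np.einsum("ij,ij->i", mic, mic) < a * a
            hit_idx = idx[hit]
            t_hit[hit_idx] = step * dt
            alive[hit_idx] = False
        captured = ~np.isnan(t_hit)
        assert captured.mean() > 0.97
        mean_fpt = np.nanmean(t_hit)
        k_smoluchowski = 4 * math.pi * d_rel * a / (1 - 2.837297 * a / box)
        expected_fpt = box**3 / k_smoluchowski
        assert mean_fpt == pytest.approx(expected_fpt, rel=0.15)


class TestTotalCollisionRate:
    def test_order_of_magnitude_in_100_ul(self, standard_populations, medium):
        # ~1e14 vSUV–tSUV collisions per second in 100 μL (the printed
        # 2e14 is an order-of-magnitude companion figure)
        vpop, tpop = standard_populations
        total = total_collision_rate(tpop, vpop, medium, 1e-4)
        assert 2e13 < total < 2e15

    def test_factorizes_as_per_vesicle_rate_times_count(self, standard_populations, medium):
        vpop, tpop = standard_populations
        volume_l = 1e-4
        per = collision_rate_per_vesicle(tpop, medium, vpop.geometry.outer_radius)
        n_v = vpop.number_density * volume_l * 1e-3
        assert total_collision_rate(tpop, vpop, medium, volume_l) == pytest.approx(
            per * n_v, rel=1e-12
        )

    def test_linear_in_volume_and_zero_density(self, standard_populations, suv_geometry, medium):
        vpop, tpop = standard_populations
        t1 = total_collision_rate(tpop, vpop, medium, 1e-4)
        t2 = total_collision_rate(tpop, vpop, medium, 2e-4)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)
        empty = VesiclePopulation(geometry=suv_geometry, number_density=0.0)
        assert total_collision_rate(empty, vpop, medium, 1e-4) == 0.0

    def test_negative_volume_rejected(self, standard_populations, medium):
        vpop, tpop = standard_populations
        with pytest.raises(InvalidParameterError):
            total_collision_rate(tpop, vpop, medium, -1.0)


class TestCollisionsBeforeEvent:
    @pytest.mark.parametrize(
        "rate,time,expected",
        [(300.0, 3600.0, 1.08e6), (300.0, 36000.0, 1.08e7), (0.0, 3600.0, 0.0)],
    )
    def test_collision_counts(self, rate, time, expected):
        # 300 s⁻¹ for 60 min ≈ 1e6 collisions; 10 h reaches the 1e7 end
        assert collisions_before_event(rate, time) == pytest.approx(expected)


class TestContactWindow:
    def test_dwell_time_is_microseconds(self, encounter_params):
        # d²/6D with d = 15 nm, D = 20 μm²/s
        assert contact_dwell_time(encounter_params) == pytest.approx(1.875e-6, rel=1e-9)
        assert contact_dwell_time(EncounterParams(interaction_distance=0.0)) == 0.0

    def test_dwell_quadratic_in_distance(self):
        t1 = contact_dwell_time(EncounterParams(interaction_distance=8.0))
        t2 = contact_dwell_time(EncounterParams(interaction_distance=16.0))
        assert t2 == pytest.approx(4 * t1, rel=1e-12)

    def test_explored_area_both_closed_forms(self, encounter_params):
        # 4·D_protein·τ and (2Dp/3Dsuv)·d² agree; 37.5 nm² at the defaults
        a = explored_area(5.0, encounter_params)
        assert a == pytest.approx(37.5, rel=1e-9)
        alt = 4 * 5.0 * contact_dwell_time(encounter_params) * 1e6  # μm² → nm²
        assert a == pytest.approx(alt, rel=1e-9)
        assert explored_area(0.0, encounter_params) == 0.0

    def test_explored_area_covers_about_100_lipids(self, encounter_params):
        # 37.5 nm² ÷ 0.65 nm² × 2 leaflets ≈ 115 ≈ the ~100-lipid threshold
        lipids = explored_area(5.0, encounter_params) / 0.65 * 2
        assert lipids == pytest.approx(115.0, abs=1.0)


class TestEncounterProbability:
    def _pop(self, geometry, copies):
        return VesiclePopulation(
            geometry=geometry, number_density=1e19, snare_copies_per_vesicle=copies
        )

    def test_saturates_at_physiological_density(self, suv_geometry, encounter_params):
        # one SNARE per 100 lipids on both vesicles: encounter is certain
        from snarefusion import lipids_per_vesicle

        copies = lipids_per_vesicle(suv_geometry) / 100
        vpop = self._pop(suv_geometry, copies)
        tpop = self._pop(suv_geometry, copies)
        assert encounter_probability_per_collision(vpop, tpop, encounter_params) == 1.0

    def test_zero_copies_gives_zero(self, suv_geometry, encounter_params):
        vpop = self._pop(suv_geometry, 0.0)
        tpop = self._pop(suv_geometry, 50.0)
        assert encounter_probability_per_collision(vpop, tpop, encounter_params) == 0.0

    def test_linear_below_threshold(self, suv_geometry, encounter_params):
        # halving the v-SNARE copy number halves p while unsaturated
        tpop = self._pop(suv_geometry, 40.0)
        p_full = encounter_probability_per_collision(
            self._pop(suv_geometry, 20.0), tpop, encounter_params
        )
        p_half = encounter_probability_per_collision(
            self._pop(suv_geometry, 10.0), tpop, encounter_params
        )
        assert p_half == pytest.approx(p_full / 2, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(nv=st.floats(0, 500), nt=st.floats(0, 500), dn=st.floats(0, 100))
    def test_bounded_and_monotone(self, nv, nt, dn):
        geometry = VesicleGeometry()
        encounter_params = EncounterParams()
        p = encounter_probability_per_collision(
            self._pop(geometry, nv), self._pop(geometry, nt), encounter_params
        )
        p_more = encounter_probability_per_collision(
            self._pop(geometry, nv + dn), self._pop(geometry, nt), encounter_params
        )
        assert 0.0 <= p <= 1.0
        assert p_more >= p - 1e-15
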