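"""Gamete classes, mating pathways, pollen choice, seed formation, inheritance."""

import math

import numpy as np
import pytest

from polyestab.demography import Plant
from polyestab.environment import generate_synthetic_environment
from polyestab.reproduction import (
    ANEUPLOID,
    GameteSpec,
    MatingConfig,
    MatingConfigError,
    assign_shifted_optimum,
    choose_optimum_patches,
    choose_pathway,
    classify_polyploidization,
    form_seed,
    gamete_class_distribution,
    inherit_adaptivity,
    is_new_event,
    pollen_kernel_matrix,
    sample_gametes_vector,
    select_pollen_donor,
)


def _plant(pid=0, ploidy=2, x=0, y=0, ia=None, event_id=-1):
    return Plant(
        id=pid, ploidy=ploidy, age=1, ia=np.zeros(5) if ia is None else np.asarray(ia, float),
        x=x, y=y, event_id=event_id,
    )


class TestGameteDistributions:
    def test_legal_gamete_classes_only(self):
        with pytest.raises(MatingConfigError):
            GameteSpec(3, "unreduced", 2)
        with pytest.raises(MatingConfigError):
            GameteSpec(1, "reduced", 4)
        assert GameteSpec(2, "unreduced", 2).unreduced
        assert not GameteSpec(2, "reduced", 3).unreduced

    def test_diploid_unreduced_fraction(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=0.2, onset_generation=0)
        _, unred = sample_gametes_vector(np.full(10_000, 2), cfg, rng, generation=500)
        assert unred.mean() == pytest.approx(0.2, abs=0.012)

    def test_no_unreduced_before_onset(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=0.2, onset_generation=200)
        dosage, unred = sample_gametes_vector(np.full(5000, 2), cfg, rng, generation=150)
        assert not unred.any()
        assert np.all(dosage == 1)
        dist = gamete_class_distribution(2, cfg, generation=150)
        assert dist[GameteSpec(2, "unreduced", 2)] == 0.0

    def test_tetraploid_all_reduced_when_rate_zero(self, rng):
        cfg = MatingConfig(unreduced_rate_4x=0.0)
        dosage, unred = sample_gametes_vector(np.full(2000, 4), cfg, rng, generation=500)
        assert np.all(dosage == 2)
        assert not unred.any()

    def test_triploid_mix_recovery(self, rng):
        cfg = MatingConfig()
        dosage, unred = sample_gametes_vector(np.full(20_000, 3), cfg, rng, generation=500)
        mix = cfg.triploid_gamete_mix
        assert (dosage == 1).mean() == pytest.approx(mix["x"], abs=0.015)
        assert (dosage == 2).mean() == pytest.approx(mix["2x"], abs=0.015)
        assert (dosage == 3).mean() == pytest.approx(mix["3x"], abs=0.01)
        assert (dosage == ANEUPLOID).mean() == pytest.approx(mix["aneuploid"], abs=0.015)
        assert np.array_equal(unred, dosage == 3)

    def test_distribution_sums_to_one(self):
        cfg = MatingConfig(unreduced_rate_2x=0.1)
        for ploidy in (2, 3, 4):
            dist = gamete_class_distribution(ploidy, cfg)
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_config_validation(self):
        with pytest.raises(MatingConfigError):
            MatingConfig(unreduced_rate_2x=1.5)
        with pytest.raises(MatingConfigError):
            MatingConfig(selfing_rate={2: 0.6, 3: 0.0, 4: 0.0}, apomixis_rate={2: 0.6, 3: 0.0, 4: 0.0})
        with pytest.raises(MatingConfigError):
            MatingConfig(triploid_gamete_mix={"x": 0.5, "2x": 0.1, "3x": 0.1, "aneuploid": 0.1})


class TestPathwayChoice:
    def test_pure_selfing(self, rng):
        cfg = MatingConfig(selfing_rate={2: 1.0, 3: 0.0, 4: 0.0})
        assert all(choose_pathway(cfg, rng, ploidy=2) == "self" for _ in range(50))

    def test_default_is_outcrossing(self, rng):
        cfg = MatingConfig()
        assert all(choose_pathway(cfg, rng, ploidy=2) == "outcross" for _ in range(50))

    def test_multinomial_recovery(self, rng):
        cfg = MatingConfig(selfing_rate={2: 0.5, 3: 0, 4: 0}, apomixis_rate={2: 0.5, 3: 0, 4: 0})
        draws = [choose_pathway(cfg, rng, ploidy=2) for _ in range(10_000)]
        assert draws.count("self") / 10_000 == pytest.approx(0.5, abs=0.015)
        assert draws.count("apomixis") / 10_000 == pytest.approx(0.5, abs=0.015)

    def test_bearer_specific_rates(self, rng):
        cfg = MatingConfig(selfing_rate={2: 0.0, 3: 0.0, 4: 1.0})
        assert choose_pathway(cfg, rng, ploidy=2) == "outcross"
        assert choose_pathway(cfg, rng, ploidy=4) == "self"


class TestPollenDonor:
    def test_single_candidate_always_chosen(self, rng):
        mother = _plant(0, x=5, y=5)
        donor = _plant(1, x=6, y=5)
        cfg = MatingConfig()
        assert all(
            select_pollen_donor(mother, [mother, donor], rng, cfg) is donor for _ in range(20)
        )

    def test_isolated_mother_aborts(self, rng):
        mother = _plant(0, x=5, y=5)
        far = _plant(1, x=50, y=50)  # beyond the truncation radius
        assert select_pollen_donor(mother, [mother, far], rng, MatingConfig()) is None

    def test_distance_weighting_odds(self, rng):
        mother = _plant(0, x=0, y=0)
        near = _plant(1, x=1, y=0)
        far = _plant(2, x=6, y=0)
        cfg = MatingConfig()
        picks = [select_pollen_donor(mother, [mother, near, far], rng, cfg) for _ in range(4000)]
        n_near = sum(p is near for p in picks)
        ratio = n_near / max(1, 4000 - n_near)
        expected = math.exp(5 / cfg.pollen_lambda)  # ~22.8 : 1
        assert 0.6 * expected < ratio < 1.6 * expected

    def test_kernel_matrix_shape_and_center(self):
        cfg = MatingConfig()
        k = pollen_kernel_matrix(cfg)
        assert k.shape == (21, 21)
        assert k[10, 10] == 0.0  # the mother herself is never a donor
        assert k[10, 11] == pytest.approx(math.exp(-1 / cfg.pollen_lambda))
        assert k[0, 0] == 0.0  # corner is beyond the truncation radius

    def test_global_mode_ignores_distance(self, rng):
        mother = _plant(0, x=0, y=0)
        far = _plant(1, x=90, y=90)
        cfg = MatingConfig(pollen_global=True)
        assert select_pollen_donor(mother, [mother, far], rng, cfg) is far


class TestSeedFormation:
    def test_reduced_reduced_gives_diploid(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=0.0)
        seed = form_seed(_plant(0), "outcross", cfg, rng, donor=_plant(1), generation=500)
        assert seed is not None and seed.ploidy == 2 and seed.event_type is None

    def test_bilateral_tetraploid(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=1.0, onset_generation=0)
        seed = form_seed(_plant(0), "outcross", cfg, rng, donor=_plant(1), generation=500)
        assert seed is not None and seed.ploidy == 4 and seed.event_type == "bilateral"

    def test_triploid_bridge_seed(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=1.0, triploid_seed_viability=1.0, onset_generation=0)
        mother = _plant(0)
        donor = _plant(1, ploidy=4)  # reduced 2x gamete
        # mother's female gamete is unreduced 2x; 2x + 2x = 4x, one unreduced
        seed = form_seed(mother, "outcross", cfg, rng, donor=donor, generation=500)
        assert seed is not None and seed.ploidy == 4 and seed.event_type is None  # 4x parent

    def test_pollen_limited_abort(self, rng):
        seed = form_seed(_plant(0), "outcross", MatingConfig(), rng, donor=None, generation=500)
        assert seed is None

    def test_apomictic_clone(self, rng):
        mother = _plant(0, ploidy=4, ia=[1, 2, 3, 4, 5], event_id=7)
        seed = form_seed(mother, "apomixis", MatingConfig(), rng, generation=500)
        assert seed.ploidy == 4
        assert np.array_equal(seed.ia, mother.ia)
        assert seed.event_inherited == 7

    def test_inviable_triploid_block(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=1.0, triploid_seed_viability=0.0, onset_generation=0)
        mother = _plant(0)
        donor = _plant(1, ploidy=3)
        # every cross involving a 3x parent (or 3x product) dies at viability 0
        for _ in range(30):
            assert form_seed(mother, "outcross", cfg, rng, donor=donor, generation=500) is None

    def test_selfing_uses_mother_as_donor(self, rng):
        cfg = MatingConfig(unreduced_rate_2x=0.0, selfing_rate={2: 1.0, 3: 0, 4: 0})
        mother = _plant(0, ia=[2, 2, 2, 2, 2])
        seed = form_seed(mother, "self", cfg, rng, generation=500)
        assert seed.ploidy == 2
        assert np.array_equal(seed.ia, mother.ia)


class TestEventClassification:
    def _g(self, dosage, klass, parent):
        return GameteSpec(dosage, klass, parent)

    def test_bilateral_unilateral_none(self):
        unred2 = self._g(2, "unreduced", 2)
        red1 = self._g(1, "reduced", 2)
        assert classify_polyploidization(unred2, unred2, 4) == "bilateral"
        assert classify_polyploidization(unred2, red1, 3) == "unilateral"
        assert classify_polyploidization(red1, red1, 2) is None

    def test_reduced_reduced_tetraploid_is_not_an_event(self):
        red2_3x = self._g(2, "reduced", 3)
        red2_4x = self._g(2, "reduced", 4)
        assert classify_polyploidization(red2_3x, red2_4x, 4) is None
        assert is_new_event(red2_3x, red2_4x, 4) is None

    def test_tetraploid_parent_extends_not_founds(self):
        unred2 = self._g(2, "unreduced", 2)
        red2_4x = self._g(2, "reduced", 4)
        # classified unilateral, but propagates the 4x parent's lineage
        assert classify_polyploidization(unred2, red2_4x, 4) == "unilateral"
        assert is_new_event(unred2, red2_4x, 4) is None

    def test_new_origins_from_non_tetraploid_parents(self):
        unred2 = self._g(2, "unreduced", 2)
        red1 = self._g(1, "reduced", 2)
        red2_3x = self._g(2, "reduced", 3)
        assert is_new_event(unred2, unred2, 4) == "bilateral"
        assert is_new_event(unred2, red1, 3) == "unilateral"
        assert is_new_event(red2_3x, unred2, 4) == "unilateral"


class TestInheritance:
    def test_apomixis_exact_copy(self, rng):
        ia = np.array([1.0, 2, 3, 4, 5])
        child = inherit_adaptivity("apomixis", ia, None, rng)
        assert np.array_equal(child, ia)

    def test_midparent(self, rng):
        child = inherit_adaptivity(
            "outcross", np.full(5, 10.0), np.full(5, 20.0), rng, segregation_sd=0.0
        )
        assert np.allclose(child, 15.0)

    def test_selfing_identical_parents(self, rng):
        ia = np.array([3.0, 1, 4, 1, 5])
        child = inherit_adaptivity("self", ia, ia, rng, segregation_sd=0.0)
        assert np.array_equal(child, ia)

    def test_segregation_noise(self, rng):
        ia = np.full(5, 10.0)
        children = np.stack(
            [inherit_adaptivity("outcross", ia, ia, rng, segregation_sd=1.0) for _ in range(200)]
        )
        assert children.std() == pytest.approx(1.0, rel=0.2)

    def test_sexual_requires_father(self, rng):
        with pytest.raises(MatingConfigError):
            inherit_adaptivity("outcross", np.zeros(5), None, rng)


class TestShiftedOptimum:
    def test_assigned_plant_is_optimal_on_its_patch(self, default_grid, rng):
        patches = choose_optimum_patches(default_grid, 20.0, rng)
        assert len(patches) == 30
        d = np.hypot(patches[:, 0] - 49.5, patches[:, 1] - 49.5)
        assert np.all(np.abs(d - 20.0) <= 2.0)
        ia = assign_shifted_optimum(np.zeros(5), patches, default_grid, rng)
        match = [
            np.allclose(ia, default_grid.layers[:, y, x]) for x, y in patches
        ]
        assert any(match)  # IA literally equals some optimum patch's V (E = 1 there)

    def test_zero_shift_is_the_founder_area(self, default_grid, rng):
        patches = choose_optimum_patches(default_grid, 0.0, rng, ring_halfwidth=3.0)
        d = np.hypot(patches[:, 0] - 49.5, patches[:, 1] - 49.5)
        assert np.all(d <= 3.0)

    def test_empty_optimum_set_rejected(self, default_grid, rng):
        with pytest.raises(MatingConfigError):
            assign_shifted_optimum(np.zeros(5), np.empty((0, 2), dtype=int), default_grid, rng)
        with pytest.raises(MatingConfigError):
            choose_optimum_patches(default_grid, 500.0, rng)
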