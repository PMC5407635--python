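"""Input derivation: filtering, pedotransfer, stone correction, schedules,
fertilizer partitioning."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from soiln2o import derive as dv
from soiln2o import synthgen as sg
from soiln2o.params import ConfigError, GeneratorConfig, SimParams, \
    default_crop_table


def mkpoint(**kw):
    base = dict(point_id="T0", lon=5.0, lat=45.0, land_use="arable",
                clay=20.0, silt=40.0, sand=40.0, rv=10.0, soc=15.0,
                ph=6.5, region_id="C1R1", country_id="C1")
    base.update(kw)
    return sg.SoilPoint(**base)


class TestFilterBySoc:
    def test_nothing_removed_below_threshold(self):
        pts = [mkpoint(point_id=f"P{i}", soc=50.0 + i) for i in range(5)]
        kept, removed = dv.filter_by_soc(pts)
        assert removed == [] and kept == pts

    def test_exact_count_and_order(self):
        rng = np.random.default_rng(0)
        soc = rng.uniform(1, 400, 200)
        pts = [mkpoint(point_id=f"P{i}", soc=s) for i, s in enumerate(soc)]
        kept, removed = dv.filter_by_soc(pts, 200.0)
        assert len(removed) == int((soc > 200).sum())      # brute-force count
        assert kept + removed != []  # partition
        assert {p.point_id for p in kept} | {p.point_id for p in removed} \
            == {p.point_id for p in pts}
        assert [p.point_id for p in kept] == \
            [p.point_id for p in pts if p.soc <= 200]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            dv.filter_by_soc([mkpoint()], threshold=0.0)


class TestStoneCorrect:
    def test_identity_at_zero_rv(self):
        assert dv.stone_correct(0.37, 0.0) == 0.37

    def test_printed_formula_value(self):
        assert dv.stone_correct(0.30, 20.0) == pytest.approx(0.24)

    @given(rv=st.floats(0.0, 99.0), v=st.floats(0.0, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_linear_and_monotone(self, rv, v):
        out = dv.stone_correct(v, rv)
        assert out == pytest.approx(v * (1 - rv / 100))
        assert out <= v

    def test_rejects_out_of_range_rv(self):
        for rv in (-1.0, 100.0, 120.0):
            with pytest.raises(ValueError):
                dv.stone_correct(0.3, rv)


class TestHydraulicPtf:
    def test_clay_rich_holds_more_than_sand_rich(self, params):
        rich = dv.hydraulic_ptf(60.0, 5.0, 15.0, params)
        sandy = dv.hydraulic_ptf(5.0, 80.0, 15.0, params)
        assert rich.field_capacity > sandy.field_capacity
        assert rich.wilting_point > sandy.wilting_point

    def test_fc_non_decreasing_in_soc_at_loam(self, params):
        fc = [dv.hydraulic_ptf(20.0, 40.0, soc, params).field_capacity
              for soc in (10.0, 20.0, 40.0)]
        assert fc == sorted(fc)

    def test_ordering_invariant_random_inputs(self, params):
        rng = np.random.default_rng(1)
        for _ in range(300):
            clay = rng.uniform(1, 70)
            sand = rng.uniform(1, 95 - clay)
            soc = rng.lognormal(np.log(15), 0.8)
            hp = dv.hydraulic_ptf(clay, sand, min(soc, 200), params)
            hp.validate()     # 0 < wp < fc < porosity <= 1, ksat > 0

    def test_rejects_bad_texture(self, params):
        with pytest.raises(ValueError):
            dv.hydraulic_ptf(80.0, 80.0, 10.0, params)


class TestBulkDensity:
    def test_strictly_decreasing_in_soc(self, params):
        assert dv.bulk_density_ptf(10.0, 20, 40, params) > \
            dv.bulk_density_ptf(100.0, 20, 40, params)

    def test_extreme_soc_clamped_with_warning(self, params, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="soiln2o.derive"):
            bd = dv.bulk_density_ptf(1500.0, 20, 40, params)
        assert 0.5 <= bd <= 2.2

    def test_rejects_nonpositive_soc(self, params):
        with pytest.raises(ValueError):
            dv.bulk_density_ptf(0.0, 20, 40, params)


class TestSocStock:
    def test_hand_unit_conversion(self):
        # 20 g/kg x 1.25 g/cm3 x 20 cm, stone-free: 50 Mg C/ha
        assert dv.soc_stock(20.0, 1.25, 20.0, 0.0) == pytest.approx(50.0)

    def test_stone_factor_is_linear(self):
        assert dv.soc_stock(20.0, 1.25, 20.0, 50.0) == pytest.approx(
            0.5 * dv.soc_stock(20.0, 1.25, 20.0, 0.0))

    def test_zero_soc_gives_zero(self):
        assert dv.soc_stock(0.0, 1.25, 20.0, 0.0) == 0.0

    def test_roundtrip_with_bulk_density(self, params):
        """BD feeding the stock formula reproduces a spreadsheet-style
        hand calculation."""
        soc, clay, sand, rv = 25.0, 30.0, 30.0, 12.0
        bd = dv.bulk_density_ptf(soc, clay, sand, params)
        om = soc / 10 * params.om_factor
        bd_min = params.bd_mineral_base + params.bd_mineral_sand_coeff * sand
        bd_hand = 100.0 / (om / params.bd_om + (100 - om) / bd_min)
        assert bd == pytest.approx(bd_hand)
        assert dv.soc_stock(soc, bd, 20.0, rv) == pytest.approx(
            soc / 1000 * bd_hand * 20 * (1 - rv / 100) * 100)


class TestBuildSchedule:
    def stats(self, cfg, **kw):
        st_ = sg.gen_region_stats(["C1R1"], seed=1, cfg=cfg)["C1R1"]
        return dataclasses.replace(st_, **kw)

    def test_single_crop_region_repeats_it(self, cfg, params):
        stats = self.stats(cfg, crop_shares={"potato": 1.0})
        s = dv.build_schedule(mkpoint(), stats, default_crop_table(), 1,
                              n_years=4, params=params)
        assert s.rotation == ("potato",) * 4

    def test_zero_livestock_means_zero_manure(self, cfg, params):
        stats = self.stats(cfg, livestock_density=0.0)
        s = dv.build_schedule(mkpoint(), stats, default_crop_table(), 1,
                              n_years=2, params=params)
        assert s.manure_n == 0.0

    def test_grassland_gets_permanent_grass(self, cfg, params):
        stats = self.stats(cfg)
        s = dv.build_schedule(mkpoint(land_use="grassland"), stats,
                              default_crop_table(), 1, 3, params)
        assert s.rotation == ("grass",) * 3 and not s.irrigated

    def test_rotation_frequencies_match_shares(self, cfg, params):
        """10 000 sampled rotation years follow the regional crop shares
        (chi-square goodness of fit)."""
        shares = {"winter_wheat": 0.5, "grain_maize": 0.3, "potato": 0.2}
        stats = self.stats(cfg, crop_shares=shares)
        cal = default_crop_table()
        counts = {c: 0 for c in shares}
        for i in range(2500):
            s = dv.build_schedule(mkpoint(point_id=f"P{i}"), stats, cal,
                                  seed=i, n_years=4, params=params)
            for c in s.rotation:
                counts[c] += 1
        n = sum(counts.values())
        _, p = chisquare([counts[c] for c in shares],
                         [shares[c] * n for c in shares])
        assert p > 0.001

    def test_missing_crop_named_in_error(self, cfg, params):
        stats = self.stats(cfg, crop_shares={"winter_wheat": 1.0})
        cal = {k: v for k, v in default_crop_table().items()
               if k != "winter_wheat"}
        with pytest.raises(ConfigError, match="winter_wheat"):
            dv.build_schedule(mkpoint(), stats, cal, 1, 2, params)


class TestPartitionFertilizer:
    def sched(self, pid, rotation, manure=0.0):
        return dv.ManagementSchedule(pid, rotation, (0.0,) * len(rotation),
                                     manure, False)

    def test_uniform_requirement_gives_total_over_area(self):
        pts = [mkpoint(point_id=f"P{i}") for i in range(4)]
        schedules = {p.point_id: self.sched(p.point_id, ("potato",) * 2)
                     for p in pts}
        areas = {p.point_id: 250.0 for p in pts}
        out = dv.partition_fertilizer(70_000.0, pts, schedules, areas,
                                      {"potato": 140.0})
        for s in out.values():
            assert s.mineral_n_by_year == pytest.approx((70.0, 70.0))

    def test_mass_conservation(self):
        rng = np.random.default_rng(3)
        pts = [mkpoint(point_id=f"P{i}") for i in range(30)]
        crops = ("potato", "winter_wheat", "pulses")
        schedules = {p.point_id: self.sched(
            p.point_id, tuple(rng.choice(crops, 3))) for p in pts}
        areas = {p.point_id: float(rng.uniform(50, 500)) for p in pts}
        req = {"potato": 140.0, "winter_wheat": 150.0, "pulses": 10.0}
        total = 1.7e6
        out = dv.partition_fertilizer(total, pts, schedules, areas, req)
        assigned = sum(areas[pid] * np.mean(s.mineral_n_by_year)
                       for pid, s in out.items())
        assert assigned == pytest.approx(total, rel=1e-6)

    def test_rates_proportional_to_requirements(self):
        pts = [mkpoint(point_id="A"), mkpoint(point_id="B")]
        schedules = {"A": self.sched("A", ("potato",)),
                     "B": self.sched("B", ("sugar_beet",))}
        areas = {"A": 100.0, "B": 100.0}
        out = dv.partition_fertilizer(30_000.0, pts, schedules, areas,
                                      {"potato": 100.0, "sugar_beet": 200.0})
        ra = out["A"].mineral_n_by_year[0]
        rb = out["B"].mineral_n_by_year[0]
        assert rb / ra == pytest.approx(2.0)

    def test_zero_requirement_with_positive_total_rejected(self):
        pts = [mkpoint(point_id="A")]
        schedules = {"A": self.sched("A", ("potato",))}
        with pytest.raises(ValueError, match="zero"):
            dv.partition_fertilizer(1000.0, pts, schedules, {"A": 10.0},
                                    {"potato": 0.0})


def test_derived_inputs_invariants_hold_cohortwide(cfg, params):
    """Every derived record from a large random cohort passes all type
    invariants (property sweep)."""
    pts = sg.gen_points(2000, seed=21, cfg=cfg)
    kept, _ = dv.filter_by_soc(pts, cfg.soc_exclude_threshold)
    stats = sg.gen_region_stats(cfg.region_ids, seed=21, cfg=cfg)
    cal = default_crop_table()
    for p in kept:
        sched = dv.build_schedule(p, stats[p.region_id], cal, seed=1,
                                  n_years=2, params=params)
        di = dv.derive_point(p, stats[p.region_id], sched, params)
        di.validate()
        assert di.hydraulics.field_capacity <= \
            dv.hydraulic_ptf(p.clay, p.sand, p.soc, params).field_capacity
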