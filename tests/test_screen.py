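"""Tests for library enumeration, parameter composition and the simulator."""

import numpy as np
import pytest

from mirsense import (
    ComponentVariant,
    ConfigurationError,
    DataCompletenessError,
    DomainError,
    activator_constructs,
    compose_parameters,
    default_library,
    enumerate_library,
    flow_score,
    normalize_to_output_pool,
    performance_summary,
    simulate_screen,
)
from mirsense.screen import BLOCKS


def minimal_library(**overrides):
    """One variant per block, identity multipliers unless overridden."""
    defaults = {
        "activator_promoter": [("CMV", {})],
        "activator_protein": [("tTA", {})],
        "activator_targets": [("3prime", {})],
        "ff4_cassette": [("intron_only", {})],
        "output_promoter": [("EF1A", {})],
        "output_targets": [("3F", {})],
    }
    defaults.update(overrides)
    return [
        ComponentVariant(block, name, mult)
        for block, members in defaults.items()
        for name, mult in members
    ]


class TestEnumeration:
    def test_default_library_size(self, compositions):
        assert len(compositions) == 96

    def test_eight_activator_constructs(self, compositions):
        assert len(activator_constructs(compositions)) == 8

    def test_single_variant_per_block(self):
        assert len(enumerate_library(minimal_library())) == 1

    def test_empty_block_rejected(self, library):
        without_outputs = [v for v in library if v.block != "output_targets"]
        with pytest.raises(ConfigurationError):
            enumerate_library(without_outputs)

    def test_wells_are_bijective(self, compositions):
        wells = [c.well for c in compositions]
        assert len(set(wells)) == 96
        assert set(wells) == {f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)}

    def test_rows_share_activator_construct(self, compositions):
        by_row = {}
        for comp in compositions:
            by_row.setdefault(comp.well[0], set()).add(comp.activator_construct)
        assert all(len(constructs) == 1 for constructs in by_row.values())

    def test_cassette_split_across_columns(self, compositions):
        for comp in compositions:
            column = int(comp.well[1:])
            expected = "intron_only" if column <= 6 else "cit_embedded"
            assert comp.ff4_cassette == expected

    def test_inducible_promoter_matches_activator(self, compositions):
        for comp in compositions:
            expected = "TRE" if comp.activator_protein == "tTA" else "PIR"
            assert comp.inducible_promoter == expected


class TestComposeParameters:
    def test_identity_multipliers(self, basic):
        lib = minimal_library()
        comp = enumerate_library(lib)[0]
        assert compose_parameters(basic, comp, lib) == basic

    def test_ubc_promoter_scales_activator_pool(self, basic, library, compositions):
        ubc = next(
            c
            for c in compositions
            if c.activator_promoter == "UbC"
            and c.activator_protein == "tTA"
            and c.ff4_cassette == "intron_only"
        )
        params = compose_parameters(basic, ubc, library)
        assert params.act_max == pytest.approx(2926.5)

    def test_factors_compose_multiplicatively(self, basic):
        lib = minimal_library(
            activator_promoter=[("CMV", {"act_max": 0.5})],
            activator_protein=[("tTA", {"act_max": 4.0})],
        )
        comp = enumerate_library(lib)[0]
        params = compose_parameters(basic, comp, lib)
        assert params.act_max == pytest.approx(basic.act_max * 2.0, rel=1e-12)

    def test_unknown_variant_rejected(self, basic, library, compositions):
        incomplete = [v for v in library if v.name != "PIT2"]
        pit2 = next(c for c in compositions if c.activator_protein == "PIT2")
        with pytest.raises(KeyError):
            compose_parameters(basic, pit2, incomplete)

    def test_block_scope_enforced(self):
        with pytest.raises(ConfigurationError):
            ComponentVariant("output_targets", "bad", {"act_max": 2.0})

    def test_equivalent_to_manual_parameter_edit(self, basic, library, compositions):
        comp = compositions[13]
        composed = compose_parameters(basic, comp, library)
        by_key = {(v.block, v.name): v.multipliers for v in library}
        manual = {name: getattr(basic, name) for name in basic.field_names()}
        for block in BLOCKS:
            for param, factor in by_key[(block, comp.variant_of(block))].items():
                manual[param] *= factor
        assert composed.to_dict() == pytest.approx(manual)


class TestSimulateScreen:
    def test_noiseless_ratios_equal_model(self, noiseless_table, basic, library):
        frame = noiseless_table.to_frame()
        for comp in noiseless_table.compositions[:10]:
            params = compose_parameters(basic, comp, library)
            expected = performance_summary(params).dynamic_range_practical
            rows = frame[frame["composition_id"] == comp.composition_id]
            on = rows.loc[rows["condition"] == "on", "raw_value"].iloc[0]
            off = rows.loc[rows["condition"] == "off", "raw_value"].iloc[0]
            assert on / off == pytest.approx(expected, rel=1e-12)

    def test_same_seed_reproduces_bit_identically(self, library, basic):
        a = simulate_screen(library, basic, seed=42)
        b = simulate_screen(library, basic, seed=42)
        assert a.records == b.records

    def test_different_seeds_differ(self, library, basic):
        a = simulate_screen(library, basic, seed=1)
        b = simulate_screen(library, basic, seed=2)
        assert a.records != b.records

    def test_record_completeness(self, library, basic):
        table = simulate_screen(library, basic, seed=3, n_replicates=2)
        assert len(table.records) == 96 * 4 * 2

    def test_replicate_cv_concentrates_near_nominal(self, library, basic):
        """Sample CVs at n=3 scatter widely but stay within [0.05, 0.5]
        for >= 90% of condition groups (Monte-Carlo over seeds)."""
        fractions = []
        for seed in range(5):
            frame = simulate_screen(
                library, basic, seed=seed, noise_cv=0.2, n_replicates=3
            ).to_frame()
            grouped = frame.groupby(["composition_id", "condition"])["raw_value"]
            cv = grouped.std(ddof=1) / grouped.mean()
            fractions.append(((cv >= 0.05) & (cv <= 0.5)).mean())
        assert np.mean(fractions) >= 0.90

    def test_invalid_settings_rejected(self, library, basic):
        with pytest.raises(DomainError):
            simulate_screen(library, basic, seed=1, noise_cv=-0.1)
        with pytest.raises(DomainError):
            simulate_screen(library, basic, seed=1, n_replicates=0)


class TestNormalization:
    def test_unreduced_pool_normalizes_to_one(self, library, basic):
        table = simulate_screen(
            library, basic, seed=0, noise_cv=0.0, control_leakage=1.0
        )
        table = normalize_to_output_pool(table)
        frame = table.to_frame()
        only = frame[frame["condition"] == "output_only"]
        assert np.allclose(only["normalized_value"], 1.0)

    def test_on_off_ratio_preserved(self, noiseless_table):
        frame = noiseless_table.to_frame()
        for _, rows in frame.groupby("composition_id"):
            on = rows[rows["condition"] == "on"].iloc[0]
            off = rows[rows["condition"] == "off"].iloc[0]
            assert on["raw_value"] / off["raw_value"] == pytest.approx(
                on["normalized_value"] / off["normalized_value"], rel=1e-12
            )

    def test_missing_control_names_construct(self, library, basic):
        table = simulate_screen(library, basic, seed=0, noise_cv=0.0)
        target = table.compositions[0].output_construct
        pruned = [
            r
            for r in table.records
            if not (
                r.condition == "output_plus_ff4"
                and table.composition(r.composition_id).output_construct == target
            )
        ]
        from dataclasses import replace

        with pytest.raises(DataCompletenessError, match="-".join(target)):
            normalize_to_output_pool(replace(table, records=pruned))


class TestTrendsOfDefaultTable:
    """The default multiplier table reproduces the qualitative screen trends."""

    @staticmethod
    def _means(table, selector):
        frame = table.to_frame()
        ids = [c.composition_id for c in table.compositions if selector(c)]
        rows = frame[frame["composition_id"].isin(ids)]
        return {
            cond: rows.loc[rows["condition"] == cond, "raw_value"].mean()
            for cond in ("on", "off")
        }

    def test_weak_activator_promoter_raises_on_and_off(self, noiseless_table):
        ubc = self._means(noiseless_table, lambda c: c.activator_promoter == "UbC")
        cmv = self._means(noiseless_table, lambda c: c.activator_promoter == "CMV")
        assert ubc["on"] > cmv["on"]
        assert ubc["off"] > cmv["off"]

    def test_dual_utr_targets_raise_on_only(self, noiseless_table):
        dual = self._means(noiseless_table, lambda c: c.activator_targets == "5and3prime")
        single = self._means(noiseless_table, lambda c: c.activator_targets == "3prime")
        assert dual["on"] > single["on"]
        assert dual["off"] == pytest.approx(single["off"], rel=1e-12)

    def test_exon_embedded_cassette_raises_off_more_than_on(self, noiseless_table):
        cit = self._means(noiseless_table, lambda c: c.ff4_cassette == "cit_embedded")
        intron = self._means(noiseless_table, lambda c: c.ff4_cassette == "intron_only")
        on_ratio = cit["on"] / intron["on"]
        off_ratio = cit["off"] / intron["off"]
        assert off_ratio > on_ratio > 1.0


class TestParameterRecovery:
    """Brute-force inversion of condition means on a 2-variant sub-library
    recovers the act_max and mirff4_max multipliers."""

    def test_multipliers_recoverable_from_noiseless_screen(self, basic):
        lib = minimal_library(
            activator_promoter=[("CMV", {"act_max": 1.0}), ("UbC", {"act_max": 0.3})],
            ff4_cassette=[
                ("intron_only", {"mirff4_max": 1.0}),
                ("cit_embedded", {"mirff4_max": 0.3}),
            ],
        )
        table = simulate_screen(lib, basic, seed=0, noise_cv=0.0, n_replicates=1)
        frame = table.to_frame()

        def off_of(promoter, cassette):
            comp = next(
                c
                for c in table.compositions
                if c.activator_promoter == promoter and c.ff4_cassette == cassette
            )
            rows = frame[frame["composition_id"] == comp.composition_id]
            return rows.loc[rows["condition"] == "off", "raw_value"].iloc[0]

        def ff4_from_off(off):
            # invert the output stage: ff4 = ic50_ff4 * (out_max/off - 1)
            return basic.ic50_ff4 * (basic.out_max / off - 1.0)

        def act_from_ff4(ff4, mirff4_max):
            # invert the induction stage: act = kd * ff4 / (mirff4_max - ff4)
            return basic.kd * ff4 / (mirff4_max - ff4)

        ff4_intron = ff4_from_off(off_of("CMV", "intron_only"))
        ff4_cit = ff4_from_off(off_of("CMV", "cit_embedded"))
        # at zero input the activator is identical, so the cassette factor is
        # the ratio of implied saturating pools
        act = act_from_ff4(ff4_intron, basic.mirff4_max)
        implied_pool_cit = ff4_cit * (basic.kd + act) / act
        assert implied_pool_cit / basic.mirff4_max == pytest.approx(0.3, rel=1e-9)

        act_cmv = act_from_ff4(ff4_from_off(off_of("CMV", "intron_only")), basic.mirff4_max)
        act_ubc = act_from_ff4(
            ff4_from_off(off_of("UbC", "intron_only")), basic.mirff4_max
        )
        assert act_ubc / act_cmv == pytest.approx(0.3, rel=1e-9)


class TestFlowScore:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1000.0, 0.5, 1000.0, 0.5), 1.0),
            ((2000.0, 0.25, 1000.0, 0.5), 1.0),
            ((300.0, 0.4, 1000.0, 0.6), 0.2),
        ],
    )
    def test_score_values(self, args, expected):
        assert flow_score(*args) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(DomainError):
            flow_score(100.0, 0.5, 0.0, 0.5)
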