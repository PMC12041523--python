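"""Internal-standard quantification, differential abundance, VIP selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lipotrace.lipidomics import (
    InternalStandardMap,
    LipidTable,
    StandardCoverageError,
    class_profiles,
    differential,
    load_class_aliases,
    load_standards,
    normalize_sample,
    normalize_to_is,
    select_vip,
    vip_scores,
)

from .oracles import nipals_pls1_vip, welch_t_p


def _one_sample_table(species, classes, intensities, sample="s1"):
    return LipidTable(
        intensities=pd.DataFrame([intensities], index=[sample], columns=species),
        species_class=pd.Series(classes, index=species),
    )


class TestNormalizeToIS:
    def test_pc_species_at_standard_intensity_gets_standard_amount(self):
        """A PC analyte at intensity ratio 1 to PC(14:0)2 is assigned 2 nmol."""
        table = _one_sample_table(
            ["PC(34:1)", "PC(14:0)2"], ["PC", "PC"], [5e5, 5e5]
        )
        amounts = normalize_to_is(table)
        assert amounts.loc["s1", "PC(34:1)"] == 2.0

    def test_tag_species_at_half_standard_intensity(self):
        """TAG standard is 0.5 nmol, so a half-intensity analyte gets 0.25."""
        table = _one_sample_table(
            ["TAG(52:2)", "TAG(14:0)2"], ["TAG", "TAG"], [2.5e5, 5e5]
        )
        amounts = normalize_to_is(table)
        assert amounts.loc["s1", "TAG(52:2)"] == 0.25

    def test_zero_intensity_maps_to_zero_amount(self):
        table = _one_sample_table(
            ["SM(d34:1)", "SM(d18:1/12:0)"], ["SM", "SM"], [0.0, 5e5]
        )
        assert normalize_to_is(table).loc["s1", "SM(d34:1)"] == 0.0

    def test_per_sample_gain_cancels(self, lipid_sim):
        """Multiplying one sample's whole row by any gain leaves amounts put."""
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        boosted = LipidTable(
            table.intensities.copy(), table.species_class, table.groups
        )
        boosted.intensities.iloc[0] *= 11.3
        amounts2 = normalize_to_is(boosted)
        np.testing.assert_allclose(
            amounts.to_numpy(), amounts2.to_numpy(), rtol=1e-12
        )

    def test_subclass_falls_back_to_parent_standard(self):
        table = _one_sample_table(
            ["PC(O-34:1)", "PC(14:0)2"], ["PC[O]", "PC"], [5e5, 5e5]
        )
        assert normalize_to_is(table).loc["s1", "PC(O-34:1)"] == 2.0

    def test_uncovered_class_raises(self):
        table = _one_sample_table(["XY(1:0)"], ["XY"], [1e5])
        with pytest.raises(StandardCoverageError):
            normalize_to_is(table)

    def test_zero_standard_intensity_names_the_sample(self):
        table = _one_sample_table(
            ["PC(34:1)", "PC(14:0)2"], ["PC", "PC"], [5e5, 0.0]
        )
        with pytest.raises(ValueError, match="s1"):
            normalize_to_is(table)

    def test_packaged_map_covers_all_printed_amounts(self):
        standards = load_standards()
        assert standards.standard_for("PC") == ("PC(14:0)2", 2.0)
        assert standards.standard_for("TAG") == ("TAG(14:0)2", 0.5)
        assert standards.standard_for("SM") == ("SM(d18:1/12:0)", 2.129)
        assert standards.standard_for("PS")[1] == 5.0
        assert standards.standard_for("LPG")[1] == 0.02
        assert len(standards.classes) == 22

    def test_duplicate_class_standard_rejected(self):
        df = pd.DataFrame(
            {"standard": ["a", "b"], "nmol": [1.0, 2.0]},
            index=pd.Index(["PC", "PC"], name="class"),
        )
        with pytest.raises(ValueError, match="more than one"):
            InternalStandardMap(df)

    def test_alias_table_loads(self):
        aliases = load_class_aliases()
        assert aliases["PC[O]"] == "PC" and aliases["TAG[O]"] == "TAG"


class TestNormalizeSample:
    def test_single_species_total_pool_fraction_one(self):
        amounts = pd.DataFrame({"PC(34:1)": [3.7]}, index=["s1"])
        out = normalize_sample(amounts, "total_pool")
        assert out.iloc[0, 0] == 1.0

    def test_doubling_leaves_total_pool_unchanged(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        np.testing.assert_allclose(
            normalize_sample(amounts, "total_pool").to_numpy(),
            normalize_sample(amounts * 2, "total_pool").to_numpy(),
            rtol=1e-12,
        )

    @given(
        arrays(
            float,
            (4, 6),
            elements=st.floats(min_value=1e-3, max_value=1e3),
        )
    )
    def test_fractions_sum_to_one(self, values):
        amounts = pd.DataFrame(values)
        sums = normalize_sample(amounts, "total_pool").sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_protein_mode(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        out = normalize_sample(amounts, "protein", table.protein_ug)
        expected = amounts.iloc[0] / table.protein_ug.iloc[0]
        np.testing.assert_allclose(out.iloc[0], expected, rtol=1e-12)

    def test_protein_mode_requires_metadata(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        with pytest.raises(ValueError, match="protein"):
            normalize_sample(amounts, "protein")


class TestClassProfiles:
    def test_single_class_is_one(self):
        amounts = pd.DataFrame({"PC_a": [1.0], "PC_b": [2.0]}, index=["s"])
        classes = pd.Series({"PC_a": "PC", "PC_b": "PC"})
        assert class_profiles(amounts, classes).loc["PC", "s"] == 1.0

    def test_two_equal_classes_split_half(self):
        amounts = pd.DataFrame(
            {"PC_a": [1.0], "PC_b": [2.0], "TAG_a": [3.0]}, index=["s"]
        )
        classes = pd.Series({"PC_a": "PC", "PC_b": "PC", "TAG_a": "TAG"})
        prof = class_profiles(amounts, classes)
        assert prof.loc["PC", "s"] == 0.5 and prof.loc["TAG", "s"] == 0.5

    def test_matches_groupby_oracle(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        prof = class_profiles(amounts, table.species_class)
        for sample in amounts.index:
            total = amounts.loc[sample].sum()
            for cls in prof.index:
                cols = [
                    c for c in amounts.columns if table.species_class[c] == cls
                ]
                expected = amounts.loc[sample, cols].sum() / total
                assert prof.loc[cls, sample] == pytest.approx(expected, rel=1e-12)


class TestDifferential:
    def test_identical_groups_give_zero_fc_p_one(self, rng):
        block = rng.uniform(1, 10, size=(4, 5))
        amounts = pd.DataFrame(np.vstack([block, block]))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=amounts.index)
        out = differential(amounts, groups)
        np.testing.assert_allclose(out["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0, atol=1e-12)

    def test_matches_textbook_welch_computation(self, rng):
        amounts = pd.DataFrame(rng.uniform(0.5, 8.0, size=(6, 4)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=amounts.index)
        out = differential(amounts, groups, reference="a")
        for j in range(4):
            a = np.log2(amounts.iloc[3:, j])  # case = 'b'
            b = np.log2(amounts.iloc[:3, j])
            t_o, p_o = welch_t_p(a, b)
            assert out["t"].iloc[j] == pytest.approx(t_o, rel=1e-10)
            assert out["p"].iloc[j] == pytest.approx(p_o, rel=1e-10)

    def test_seeded_species_hits_volcano_flags(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        out = differential(amounts, table.groups, reference="HD")
        row = out.loc["PC_sp1"]
        assert row["log2fc"] == pytest.approx(3.0, abs=0.3)
        assert row["p"] <= 0.01 and row["tier"] <= 0.01 and row["large_fc"]

    def test_single_group_rejected(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        with pytest.raises(ValueError, match="two groups"):
            differential(amounts, pd.Series("a", index=amounts.index))


class TestVip:
    def test_single_predictor_is_exactly_one(self, rng):
        amounts = pd.DataFrame({"only": rng.uniform(1, 5, 8)})
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=amounts.index)
        res = vip_scores(amounts, groups, ncomp=2)
        assert res.vip["only"] == pytest.approx(1.0, abs=1e-12)

    def test_exchangeable_predictors_share_vip_one(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        amounts = pd.DataFrame({"a": y + 1.0, "b": y + 1.0})
        groups = pd.Series(["lo"] * 3 + ["hi"] * 3)
        res = vip_scores(amounts, groups, ncomp=2)
        np.testing.assert_allclose(res.vip, 1.0, atol=1e-9)

    def test_sum_of_squares_equals_species_count(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        for ncomp in (1, 2, 3):
            res = vip_scores(amounts, table.groups, ncomp=ncomp)
            assert (res.vip**2).sum() == pytest.approx(len(res.vip), abs=1e-9)

    def test_matches_independent_nipals_oracle(self, rng):
        X = rng.normal(size=(10, 8))
        y01 = np.array([0.0] * 5 + [1.0] * 5)
        amounts = pd.DataFrame(X)
        groups = pd.Series(np.where(y01 == 0, "a", "b"))
        res = vip_scores(amounts, groups, ncomp=2)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        oracle = nipals_pls1_vip(Xs, y01 - y01.mean(), ncomp=2)
        np.testing.assert_allclose(res.vip.to_numpy(), oracle, atol=1e-6)

    def test_zero_variance_species_dropped_with_warning(self, rng):
        amounts = pd.DataFrame(
            {"flat": np.ones(8), "var": rng.uniform(1, 5, 8)}
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = vip_scores(amounts, groups)
        assert res.dropped == ["flat"] and "flat" not in res.vip.index

    def test_selection_and_zscores(self, lipid_sim):
        table, _ = lipid_sim
        amounts = normalize_to_is(table)
        res = vip_scores(amounts, table.groups)
        selected, z = select_vip(res, amounts, threshold=1.0)
        assert "PC_sp1" in selected  # the seeded discriminative species
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_empty_selection_allowed(self, rng):
        amounts = pd.DataFrame(rng.normal(10, 1, size=(8, 3)))
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        res = vip_scores(amounts, groups)
        res.vip[:] = 0.5
        selected, z = select_vip(res, amounts)
        assert selected == [] and z.shape[1] == 0

    def test_selection_contains_volcano_hits_in_low_noise_limit(self):
        from lipotrace.simulate import LipidSimParams, gen_lipid_table

        table, _ = gen_lipid_table(
            LipidSimParams(
                n_samples_per_group=8, cv=0.02,
                group_log2fc={"PC_sp1": 3.0, "TAG_sp2": -2.5}, seed=33,
            )
        )
        amounts = normalize_to_is(table)
        diff = differential(amounts, table.groups, reference="HD")
        hits = set(diff.index[diff.significant & diff.large_fc])
        selected, _ = select_vip(vip_scores(amounts, table.groups), amounts)
        assert hits <= set(selected)
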