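"""Pedigree metrics: validation, imputation, F, Ne, EDR statistics."""

import numpy as np
import pandas as pd
import pytest

import breedstruct as bs
from breedstruct.pedigree import PedigreeError

from conftest import (
    brute_force_marginal_contributions,
    enumerate_edr_genomes_exact,
    make_ped,
    random_pedigree,
    wright_path_f,
)


class TestValidation:
    def test_duplicate_id_raises(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            make_ped([("A", "0", "0", "M", 2000), ("A", "0", "0", "F", 2001)])

    def test_own_parent_flagged(self):
        ped = make_ped([("A", "A", "0", "M", 2000)])
        flags = bs.validate_pedigree(ped)
        assert any(f["id"] == "A" and "own parent" in f["problem"] for f in flags)

    def test_two_cycle_flags_both(self):
        ped = make_ped([
            ("A", "B", "0", "M", 2000),
            ("B", "A", "0", "M", 2001),
        ])
        flags = bs.validate_pedigree(ped)
        cyclic = {f["id"] for f in flags if "cycle" in f["problem"]}
        assert cyclic == {"A", "B"}

    def test_child_born_before_dam_flagged(self):
        ped = make_ped([
            ("M1", "0", "0", "F", 1995),
            ("C1", "0", "M1", "M", 1990),
        ])
        flags = bs.validate_pedigree(ped)
        assert any(f["id"] == "C1" and "before dam" in f["problem"] for f in flags)

    def test_sex_inconsistent_parent_flagged(self):
        ped = make_ped([
            ("A", "0", "0", "F", 2000),
            ("B", "A", "0", "M", 2001),   # sire A is female
        ])
        flags = bs.validate_pedigree(ped)
        assert any(f["id"] == "B" for f in flags)

    def test_clean_pedigree_unflagged(self, cousin_ped):
        assert bs.validate_pedigree(cousin_ped) == []


class TestImputation:
    @pytest.mark.parametrize(
        "rows,target,expected",
        [
            # dam born 1990 -> 1990 + 2-year generation interval
            ([("D", "0", "0", "F", 1990), ("X", "0", "D", "M", None)], "X", 1992),
            # full sibling dated -> copied
            ([("S", "0", "0", "M", 1990), ("D", "0", "0", "F", 1990),
              ("A", "S", "D", "M", 2000), ("X", "S", "D", "F", None)], "X", 2000),
            # only offspring dated -> 2000 - 2
            ([("X", "0", "0", "M", None), ("C", "X", "0", "F", 2000)], "X", 1998),
        ],
    )
    def test_priority_rules(self, rows, target, expected):
        ped = make_ped(rows)
        imputed, flagged = bs.impute_birth_years(ped)
        row = imputed.df[imputed.df["id"] == target].iloc[0]
        assert row["birth_year"] == expected
        assert target in flagged

    def test_isolated_individual_untouched(self):
        ped = make_ped([("X", "0", "0", "M", None)])
        imputed, flagged = bs.impute_birth_years(ped)
        assert pd.isna(imputed.df["birth_year"].iloc[0])
        assert flagged == []


class TestReferencePedigree:
    def test_manual_transitive_closure(self):
        # 2 founders -> 4 mid-generation -> 1 dog in window; 1 unrelated dog
        ped = make_ped([
            ("F1", "0", "0", "M", 1990),
            ("F2", "0", "0", "F", 1990),
            ("M1", "F1", "F2", "M", 1995),
            ("M2", "F1", "F2", "F", 1995),
            ("M3", "F1", "M2", "M", 2000),
            ("M4", "M1", "F2", "F", 2000),
            ("R", "M3", "M4", "M", 2010),
            ("U", "0", "0", "F", 2010),   # unrelated, outside window
        ])
        with pytest.raises(PedigreeError, match="no individual born"):
            bs.build_reference_pedigree(ped, (1890, 1899))
        refped = bs.build_reference_pedigree(ped, (2010, 2010))
        assert set(refped.reference_ids) == {"R", "U"}
        # now a window holding only R: closure must be R + its 6 ancestors
        ped2 = ped.subset([i for i in ped.ids if i != "U"])
        refped2 = bs.build_reference_pedigree(ped2, (2010, 2010))
        assert set(refped2.closure_ids) == {"F1", "F2", "M1", "M2", "M3", "M4", "R"}

    def test_parentless_window_dog_is_own_edr(self):
        ped = make_ped([("X", "0", "0", "M", 2010)])
        refped = bs.build_reference_pedigree(ped, (2005, 2015))
        assert refped.closure_ids == ["X"]
        c = bs.edr_effective(refped)
        assert dict(c.p_i) == {"X": 1.0}
        assert c.edr_e == 1.0

    def test_window_covering_all_keeps_all(self, cousin_ped):
        refped = bs.build_reference_pedigree(cousin_ped, (1990, 2010))
        assert set(refped.closure_ids) == set(cousin_ped.ids)


class TestCompleteness:
    def test_complete_to_generation_three(self):
        # full binary ancestry exactly 3 generations deep
        rows = []
        for g, prefix, n in ((3, "G3", 8), (2, "G2", 4), (1, "G1", 2)):
            for i in range(n):
                if g == 3:
                    sire = dam = "0"
                else:
                    sire = f"G{g+1}_{2*i}"
                    dam = f"G{g+1}_{2*i+1}"
                rows.append((f"G{g}_{i}", sire, dam, "MF"[i % 2], 1990 + (4 - g)))
        rows.append(("X", "G1_0", "G1_1", "M", 1994))
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (1994, 1994))
        rep = bs.completeness(refped, max_generations=10)
        assert rep.g_e == pytest.approx(3.0)
        assert rep.proportions[:3] == pytest.approx([1, 1, 1])
        assert rep.proportions[3:] == pytest.approx(0)

    def test_no_parents_ge_zero(self):
        ped = make_ped([("X", "0", "0", "M", 2000)])
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        assert bs.completeness(refped).g_e == 0.0

    def test_single_known_parent_half(self):
        ped = make_ped([
            ("S", "0", "0", "M", 1990),
            ("X", "S", "0", "M", 2000),
        ])
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        rep = bs.completeness(refped)
        assert rep.proportions[0] == pytest.approx(0.5)
        assert rep.g_e == pytest.approx(0.5)


class TestInbreeding:
    def test_classic_values(self, fullsib_ped, halfsib_ped, cousin_ped):
        assert bs.inbreeding_coefficient(fullsib_ped, "E") == pytest.approx(0.25)
        assert bs.inbreeding_coefficient(halfsib_ped, "F") == pytest.approx(0.125)
        assert bs.inbreeding_coefficient(cousin_ped, "K") == pytest.approx(0.0625)

    def test_depth_truncation_removes_deep_ancestor(self, deep_common_ancestor_ped):
        refped = bs.build_reference_pedigree(deep_common_ancestor_ped, (1906, 1906))
        f5 = bs.inbreeding(refped, depth=5).f["X"]
        ffull = bs.inbreeding(refped, depth="full").f["X"]
        assert f5 == 0.0
        assert ffull > 0.0
        assert ffull == pytest.approx(wright_path_f(deep_common_ancestor_ped, "X"))
        assert ffull == pytest.approx(0.5 ** 11)

    def test_tabular_equals_wright_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ped = random_pedigree(rng, int(rng.integers(8, 25)))
            refped = bs.build_reference_pedigree(
                ped, (2000, 2000 + len(ped.ids)))
            f = bs.inbreeding(refped, depth="full").f
            for ind in ped.ids[-5:]:
                assert f[ind] == pytest.approx(
                    wright_path_f(ped, ind), abs=1e-12)

    def test_truncation_monotone_in_depth(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ped = random_pedigree(rng, 25)
            refped = bs.build_reference_pedigree(ped, (2000, 2030))
            f5 = bs.inbreeding(refped, depth=5).f
            f10 = bs.inbreeding(refped, depth=10).f
            ffull = bs.inbreeding(refped, depth="full").f
            assert np.all(f5.values <= f10.values + 1e-12)
            assert np.all(f10.values <= ffull.values + 1e-12)


class TestEffectivePopulationSize:
    def test_closed_form(self):
        res = bs.effective_population_size(0.10, 0.05)
        assert res.delta_f == pytest.approx(0.05 / 0.95)
        assert res.ne == pytest.approx(9.5, abs=0.01)

    def test_no_increase_is_undefined(self):
        res = bs.effective_population_size(0.05, 0.05)
        assert not res.defined
        assert res.ne is None
        assert "non-increasing" in res.reason

    def test_unrelated_parents(self):
        assert bs.effective_population_size(0.05, 0.0).ne == pytest.approx(10.0)


class TestContributions:
    def test_equal_founders_edr_e_is_n(self):
        rows = []
        for i in range(4):
            rows.append((f"F{i}", "0", "0", "MF"[i % 2], 1990))
        rows.append(("C1", "F0", "F1", "M", 1995))
        rows.append(("C2", "F2", "F3", "F", 1995))
        rows.append(("X", "C1", "C2", "M", 2000))
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        c = bs.edr_effective(refped)
        assert c.edr_e == pytest.approx(4.0)
        assert c.p_i.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unequal_contributions_closed_form(self):
        # contributions (0.5, 0.25, 0.25): EDR_e = 1/0.375
        rows = [
            ("F1", "0", "0", "M", 1990),
            ("F2", "0", "0", "F", 1990),
            ("F3", "0", "0", "M", 1990),
            ("C", "F3", "F2", "F", 1995),
            ("X", "F1", "C", "M", 2000),
        ]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        c = bs.edr_effective(refped)
        assert c.edr_e == pytest.approx(1 / 0.375)

    def test_single_founder_everything(self):
        ped = make_ped([("F", "0", "0", "M", 1990)])
        refped = bs.build_reference_pedigree(ped, (1990, 1990))
        assert bs.edr_effective(refped).edr_e == pytest.approx(1.0)

    def test_founders_only_marginal_equals_proportional(self):
        # reference individuals descend directly from founders, so no
        # internal ancestor can funnel contributions: marginal == proportional
        rows = [(f"F{i}", "0", "0", "MF"[i % 2], 1990) for i in range(4)]
        rows += [("C1", "F0", "F1", "M", 1995), ("C2", "F2", "F3", "F", 1995)]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (1995, 1995))
        c = bs.edr_ancestors(refped)
        assert c.edr_a == pytest.approx(c.edr_e)
        assert sorted(c.p_k) == pytest.approx([0.25] * 4)

    def test_total_bottleneck_single_ancestor(self):
        rows = [
            ("F1", "0", "0", "M", 1980), ("F2", "0", "0", "F", 1980),
            ("A", "F1", "F2", "M", 1985), ("D", "0", "0", "F", 1985),
            ("X", "A", "D", "M", 1990), ("Y", "A", "D", "F", 1990),
            ("Z", "X", "Y", "M", 1995),
        ]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (1995, 1995))
        c = bs.edr_ancestors(refped)
        # every lineage passes through A and D; two ancestors explain all
        assert c.p_k.index[0] in {"A", "D"}
        assert c.p_k.iloc[0] == pytest.approx(0.5)
        assert c.edr_a == pytest.approx(2.0)
        assert bs.bottleneck_ratio(c) > 1.0

    def test_marginal_contributions_match_path_enumeration_oracle(self):
        # 12-individual pedigree funnelled through a bottleneck ancestor
        rows = [
            ("F1", "0", "0", "M", 1980), ("F2", "0", "0", "F", 1980),
            ("F3", "0", "0", "M", 1980), ("F4", "0", "0", "F", 1980),
            ("A", "F1", "F2", "M", 1985),
            ("B", "F3", "F4", "F", 1985),
            ("C", "A", "B", "M", 1990),
            ("D", "A", "B", "F", 1990),
            ("E", "C", "F2", "F", 1992),
            ("X", "C", "D", "M", 1995),
            ("Y", "C", "E", "F", 1995),
            ("Z", "C", "D", "M", 1995),
        ]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (1995, 1995))
        mine = bs.edr_ancestors(refped)
        oracle = brute_force_marginal_contributions(refped)
        assert list(mine.p_k.index) == list(oracle.index)
        assert mine.p_k.values == pytest.approx(oracle.values, abs=1e-9)
        assert mine.edr_a < mine.edr_e
        assert mine.edr_a == pytest.approx(1.0 / float((oracle**2).sum()))

    def test_marginal_contributions_non_increasing(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            ped = random_pedigree(rng, 25)
            refped = bs.build_reference_pedigree(ped, (2015, 2030))
            c = bs.edr_ancestors(refped)
            diffs = np.diff(c.p_k.values)
            assert np.all(diffs <= 1e-9)
            assert c.p_k.sum() <= 1.0 + 1e-9


class TestEdrGenomes:
    def test_reference_equals_edrs_gives_r_one(self):
        rows = [(f"F{i}", "0", "0", "MF"[i % 2], 2000) for i in range(3)]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        c = bs.edr_genomes(refped, reps=200, seed=0)
        assert np.allclose(c.r_i.values, 1.0)
        assert c.edr_g == pytest.approx(c.edr_e)

    def test_single_offspring_retains_half(self):
        rows = [
            ("F1", "0", "0", "M", 1990), ("F2", "0", "0", "F", 1990),
            ("X", "F1", "F2", "M", 2000),
        ]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        reps = 4000
        c = bs.edr_genomes(refped, reps=reps, seed=2)
        se = np.sqrt(0.5 * 0.5 / reps)  # one fair coin per allele
        for r in c.r_i.values:
            assert abs(r - 0.5) < 3 * se

    def test_matches_exhaustive_enumeration(self):
        rows = [
            ("F1", "0", "0", "M", 1990), ("F2", "0", "0", "F", 1990),
            ("C", "F1", "F2", "M", 1995), ("D", "F1", "F2", "F", 1995),
            ("E", "C", "D", "M", 2000), ("G", "C", "D", "F", 2000),
        ]
        ped = make_ped(rows)
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        exact = enumerate_edr_genomes_exact(refped)
        ests = [
            bs.edr_genomes(refped, reps=5000, seed=s).edr_g for s in range(6)
        ]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - exact) < 3 * se

    def test_reps_validation(self):
        ped = make_ped([("F", "0", "0", "M", 2000)])
        refped = bs.build_reference_pedigree(ped, (2000, 2000))
        with pytest.raises(ValueError):
            bs.edr_genomes(refped, reps=0)


class TestDiversityOrdering:
    def test_ordering_on_simulated_closed_populations(self):
        # the founder-genome <= ancestors <= founders ordering emerges in
        # multi-generation closed pedigrees where drift erodes alleles
        for seed in range(3):
            cfg = bs.SimConfig(
                n_founders=8, start_year=1980, end_year=2000,
                closure_year=1984, litters_per_year=5, litter_size_mean=3,
                immigrants_per_year=1, seed=100 + seed,
            )
            ped, _ = bs.simulate_pedigree(cfg)
            refped = bs.build_reference_pedigree(ped, (1995, 2000))
            ca = bs.edr_ancestors(refped)
            cg = bs.edr_genomes(refped, reps=1000, seed=seed)
            assert cg.edr_g <= ca.edr_a + 1e-6
            assert ca.edr_a <= ca.edr_e + 1e-9

    def test_bottleneck_ratio_arithmetic(self):
        c = bs.ContributionSet(
            p_i=pd.Series(dtype=float), edr_e=22.0, edr_a=6.0)
        assert bs.bottleneck_ratio(c) == pytest.approx(22 / 6)
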