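"""Inherited/novel/lost scoring, origin attribution, clonal matching, rates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_state_matrix
from epimsap.inheritance import (
    F1Origin,
    F2Origin,
    InheritanceClass,
    Pedigree,
    attribute_origin_f1,
    attribute_origin_f2,
    clonal_match,
    estimate_epimutation_rates,
    inheritance_records,
    score_inheritance,
    state_inheritance_bias,
)
from epimsap.state_calling import METH_INDICATIVE, MethState

STATES = [MethState.NONMETH, MethState.FULLMETH, MethState.CG_METH, MethState.INDET]
ALL5 = STATES + [MethState.MISSING]


def arr(*vals):
    return np.array([int(v) for v in vals], dtype=np.int8)


class TestScoreInheritance:
    def test_matching_methylation_is_inherited(self):
        out = score_inheritance(arr(MethState.FULLMETH), arr(MethState.FULLMETH))
        assert out[0] == InheritanceClass.INHERITED

    def test_new_methylation_is_novel(self):
        out = score_inheritance(arr(MethState.NONMETH), arr(MethState.CG_METH))
        assert out[0] == InheritanceClass.NOVEL

    def test_parental_methylation_absent_is_lost(self):
        out = score_inheritance(arr(MethState.CG_METH), arr(MethState.NONMETH))
        assert out[0] == InheritanceClass.LOST

    def test_exhaustive_enumeration_against_textual_rules(self):
        """All 5x5x5 (mother, father, offspring) combinations follow the
        three verbal rules and form a partition of the scored loci."""
        indicative = set(int(s) for s in METH_INDICATIVE)
        for m, p, o in itertools.product(ALL5, repeat=3):
            out = score_inheritance(np.array([arr(m), arr(p)]), arr(o))[0]
            parents = [int(v) for v in (m, p) if v != MethState.MISSING]
            if o == MethState.MISSING or not parents:
                assert out == InheritanceClass.EXCLUDED
            elif int(o) in parents:
                assert out == InheritanceClass.INHERITED
            elif int(o) in indicative:
                assert out == InheritanceClass.NOVEL
            else:
                # offspring unmethylated, matching no parent: the parental
                # methylation was lost
                assert out == InheritanceClass.LOST
                assert all(v in indicative for v in parents)

    def test_symmetric_in_parents(self, rng):
        m = rng.integers(0, 4, size=50).astype(np.int8)
        p = rng.integers(0, 4, size=50).astype(np.int8)
        o = rng.integers(0, 4, size=50).astype(np.int8)
        a = score_inheritance(np.array([m, p]), o)
        b = score_inheritance(np.array([p, m]), o)
        np.testing.assert_array_equal(a, b)


class TestOriginF1:
    def test_maternal_only(self):
        out = attribute_origin_f1(
            arr(MethState.CG_METH), arr(MethState.NONMETH), arr(MethState.CG_METH)
        )
        assert out[0] == F1Origin.F0M_ONLY

    def test_both_parents(self):
        out = attribute_origin_f1(
            arr(MethState.FULLMETH), arr(MethState.FULLMETH), arr(MethState.FULLMETH)
        )
        assert out[0] == F1Origin.F0M_P

    def test_swapping_parents_swaps_maternal_paternal_counts(self, rng):
        m = rng.integers(0, 4, size=200).astype(np.int8)
        p = rng.integers(0, 4, size=200).astype(np.int8)
        o = rng.integers(0, 4, size=200).astype(np.int8)
        a = pd.Series(attribute_origin_f1(m, p, o)).value_counts()
        b = pd.Series(attribute_origin_f1(p, m, o)).value_counts()
        assert a.get(F1Origin.F0M_ONLY, 0) == b.get(F1Origin.F0P_ONLY, 0)
        assert a.get(F1Origin.F0M_P, 0) == b.get(F1Origin.F0M_P, 0)

    def test_random_trios_match_rule_oracle(self, rng):
        m = rng.integers(-1, 4, size=500).astype(np.int8)
        p = rng.integers(-1, 4, size=500).astype(np.int8)
        o = rng.integers(-1, 4, size=500).astype(np.int8)
        out = attribute_origin_f1(m, p, o)
        for k in range(500):
            if -1 in (m[k], p[k], o[k]):
                expected = F1Origin.UNATTRIBUTABLE
            elif o[k] == m[k] == p[k]:
                expected = F1Origin.F0M_P
            elif o[k] == m[k]:
                expected = F1Origin.F0M_ONLY
            elif o[k] == p[k]:
                expected = F1Origin.F0P_ONLY
            else:
                expected = F1Origin.DE_NOVO
            assert out[k] == expected

    def test_absent_parent_profile_unattributable(self):
        out = attribute_origin_f1(None, arr(MethState.NONMETH), arr(MethState.NONMETH))
        assert out[0] == F1Origin.UNATTRIBUTABLE


class TestOriginF2:
    def test_state_traced_through_f1_is_f0_origin(self):
        s = MethState.CG_METH
        out = attribute_origin_f2(arr(s), arr(s), arr(MethState.NONMETH), arr(s))
        assert out[0] == F2Origin.F0_M

    def test_state_absent_in_all_ancestors_is_de_novo(self):
        out = attribute_origin_f2(
            arr(MethState.NONMETH), arr(MethState.NONMETH),
            arr(MethState.NONMETH), arr(MethState.INDET),
        )
        assert out[0] == F2Origin.DE_NOVO

    def test_enumeration_partitions_all_quartets(self):
        """Every (f0m, f1m, f1p, f2) state quartet lands in exactly one
        category, and the category definitions hold."""
        for f0m, f1m, f1p, f2 in itertools.product(STATES, repeat=4):
            out = attribute_origin_f2(arr(f0m), arr(f1m), arr(f1p), arr(f2))[0]
            assert isinstance(out, F2Origin)
            if f2 == f1m and f2 == f0m:
                assert out == F2Origin.F0_M
            elif f2 == f1m and f2 == f1p:
                assert out == F2Origin.F1_MP
            elif f2 == f1m:
                assert out == F2Origin.F1_M
            elif f2 == f1p:
                assert out == F2Origin.F1_P
            else:
                assert out == F2Origin.DE_NOVO

    def test_f0_father_upgrades_to_both_parents_category(self):
        s = MethState.FULLMETH
        out = attribute_origin_f2(arr(s), arr(s), arr(MethState.NONMETH), arr(s), f0_father=arr(s))
        assert out[0] == F2Origin.F0_MP

    def test_missing_f0_mother_with_f1_match_is_unattributable(self):
        s = MethState.CG_METH
        out = attribute_origin_f2(None, arr(s), arr(MethState.NONMETH), arr(s))
        assert out[0] == F2Origin.UNATTRIBUTABLE


def clone_pedigree(n_off, families=("famA",)):
    rows = []
    for fam in families:
        rows.append(dict(individual=f"{fam}_M", family=fam, generation="CLONE_MOTHER",
                         mother=None, father=None, mode="asexual"))
        for i in range(n_off):
            rows.append(dict(individual=f"{fam}_C{i}", family=fam,
                             generation="CLONE_OFFSPRING", mother=f"{fam}_M",
                             father=None, mode="asexual"))
    return Pedigree(pd.DataFrame(rows))


class TestClonalMatch:
    def test_identical_offspring_matches_fully(self):
        sm = make_state_matrix(["ufhi" * 5, "ufhi" * 5], sample_ids=["famA_M", "famA_C0"])
        per_off, per_fam = clonal_match(sm, clone_pedigree(1))
        assert per_off.matched_fraction.iloc[0] == 1.0
        assert per_fam["famA"] == 1.0

    def test_direct_count(self):
        mother = "u" * 100
        child = "f" * 10 + "u" * 90
        sm = make_state_matrix([mother, child], sample_ids=["famA_M", "famA_C0"])
        per_off, _ = clonal_match(sm, clone_pedigree(1))
        assert per_off.matched_fraction.iloc[0] == pytest.approx(0.90)

    def test_switch_rate_simulation_recovers_match_rate(self, rng):
        # flip each locus with probability 0.44; expect matching ~0.56
        L, rate = 2000, 0.44
        mother = rng.integers(0, 4, size=L).astype(np.int8)
        flip = rng.random(L) < rate
        child = mother.copy()
        child[flip] = (mother[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
        from epimsap.state_calling import StateMatrix

        sm = StateMatrix(["famA_M", "famA_C0"], [f"L{j}" for j in range(L)],
                         np.stack([mother, child]))
        per_off, _ = clonal_match(sm, clone_pedigree(1))
        se = np.sqrt(rate * (1 - rate) / L)
        assert abs(per_off.matched_fraction.iloc[0] - (1 - rate)) < 3 * se

    def test_missing_cells_excluded_from_denominator(self):
        sm = make_state_matrix(["uuuu", "u.uf"], sample_ids=["famA_M", "famA_C0"])
        per_off, _ = clonal_match(sm, clone_pedigree(1))
        assert per_off.n_loci.iloc[0] == 3
        assert per_off.matched_fraction.iloc[0] == pytest.approx(2 / 3)


class TestPedigreeValidation:
    def test_cycle_detected(self):
        rows = pd.DataFrame(
            [
                dict(individual="a", family="f", generation="F1", mother="b", father="b"),
                dict(individual="b", family="f", generation="F1", mother="a", father="a"),
            ]
        )
        rows["mode"] = "sexual"
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(rows)

    def test_unknown_parent_rejected(self):
        rows = pd.DataFrame(
            [dict(individual="a", family="f", generation="F1", mother="ghost",
                  father="ghost", mode="sexual")]
        )
        with pytest.raises(ValueError, match="ghost"):
            Pedigree(rows)

    def test_tsv_round_trip(self, tmp_path, pedigree_data):
        _, ped = pedigree_data
        path = tmp_path / "ped.tsv"
        ped.write_tsv(path)
        back = Pedigree.read_tsv(path)
        assert back.families == ped.families


class TestInheritanceRecords:
    def test_origin_categories_partition_scored_loci(self, pedigree_data):
        sm, ped = pedigree_data
        recs = inheritance_records(sm, ped)
        # every scored (offspring, locus) appears exactly once with one origin
        counts = recs.groupby(["offspring", "locus"]).size()
        assert (counts == 1).all()
        per_off = recs.groupby("offspring").size()
        assert (per_off == sm.n_loci).all()

    def test_zero_switch_rates_give_full_closure(self):
        from epimsap import SimConfig, simulate_pedigree

        cfg = SimConfig(seed=5, n_loci=150, gain_rate=0.0, loss_rate=0.0,
                        sexual_families=2, f2_per_family=3,
                        clonal_families=2, clonal_offspring=(2, 2))
        sm, ped = simulate_pedigree(cfg)
        recs = inheritance_records(sm, ped)
        clone = recs[recs["generation"] == "CLONE_OFFSPRING"]
        assert (clone["origin"] == "matches_mother").all()
        sexual = recs[recs["mode"] == "sexual"]
        assert (sexual["classification"] == "inherited").all()
        assert not (sexual["origin"] == "de_novo").any()

    def test_bias_null_simulation_mostly_nonsignificant(self, pedigree_data):
        sm, ped = pedigree_data
        recs = inheritance_records(sm, ped)
        bias = state_inheritance_bias(recs[recs["mode"] == "sexual"])
        pvals = []
        for res in bias.values():
            if res.by_state is not None:
                pvals.extend(res.by_state.dunn["p_adjusted"].tolist())
        # no planted state bias beyond the baseline-frequency structure:
        # the bulk of comparisons should be unremarkable
        assert np.mean(np.array(pvals) > 0.05) > 0.5

    def test_bias_direction_flags_match_proportions(self, pedigree_data):
        sm, ped = pedigree_data
        recs = inheritance_records(sm, ped)
        sexual = recs[recs["mode"] == "sexual"]
        bias = state_inheritance_bias(sexual)
        for origin, res in bias.items():
            if res.by_state is None:
                continue
            for _, row in res.by_state.dunn.iterrows():
                # recompute mean per-offspring proportions directly
                def mean_prop(state):
                    vals = []
                    for _, sub in sexual.groupby(["family", "offspring"]):
                        at = sub[sub["state"] == state]
                        if len(at):
                            vals.append((at["origin"] == origin).mean())
                    return np.mean(vals)

                if abs(row.z) > 1e-9:
                    expected = "(+/-)" if mean_prop(row.group_a) >= mean_prop(row.group_b) else "(-/+)"
                    # z sign follows mean *ranks*; for clear separations the
                    # flag follows the mean proportions too
                    if abs(row.z) > 1.0:
                        assert row.direction == expected


class TestEpimutationRates:
    def test_zero_change_family_gives_zero_rates(self):
        sm = make_state_matrix(["ufhi" * 10, "ufhi" * 10], sample_ids=["famA_M", "famA_C0"])
        rates = estimate_epimutation_rates(sm, clone_pedigree(1), n_boot=20, seed=0)
        assert rates.gain == 0.0 and rates.loss == 0.0
        assert rates.gain_degenerate and rates.loss_degenerate

    def test_recovers_planted_rates(self):
        from epimsap import SimConfig, simulate_pedigree

        cfg = SimConfig(seed=31, n_loci=2000, gain_rate=0.02, loss_rate=0.05,
                        sexual_families=0, f2_per_family=0)
        sm, ped = simulate_pedigree(cfg)
        rates = estimate_epimutation_rates(sm, ped, n_boot=200, seed=1)
        assert rates.gain == pytest.approx(0.02, abs=0.01)
        assert rates.loss == pytest.approx(0.05, abs=0.015)
        # intervals bracket the point estimates and have plausible width
        assert rates.gain_ci[0] <= rates.gain <= rates.gain_ci[1]
        assert rates.loss_ci[0] <= rates.loss <= rates.loss_ci[1]
        assert rates.loss_ci[1] - rates.loss_ci[0] < 0.05

    def test_invariant_to_locus_permutation(self, pedigree_data, rng):
        from epimsap.state_calling import StateMatrix

        sm, ped = pedigree_data
        a = estimate_epimutation_rates(sm, ped, n_boot=10, seed=3)
        perm = rng.permutation(sm.n_loci)
        sm2 = StateMatrix(sm.sample_ids, [sm.locus_ids[j] for j in perm],
                          sm.calls[:, perm], sm.metadata)
        b = estimate_epimutation_rates(sm2, ped, n_boot=10, seed=3)
        assert a.gain == b.gain and a.loss == b.loss
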