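"""Synthetic study generator: determinism, designed community structure,
error-model statistics, alignment-scorer behavior, chemistry and phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aquamicrobe import synthetic as syn
from aquamicrobe.association import mann_whitney_u
from aquamicrobe.io_formats import ReadRecord
from aquamicrobe.nitrogen import tank_aucs


class TestReferenceDB:
    def test_counts_and_names(self):
        db = syn.generate_reference_db(5, 3, 0.02, 0.20, seed=1)
        assert len(db.sequences) == 15
        assert len(db.genera) == 5
        assert all(len(m) == 3 for m in db.genera.values())

    def test_same_seed_identical(self):
        a = syn.generate_reference_db(seed=7)
        b = syn.generate_reference_db(seed=7)
        assert a.sequences == b.sequences

    def test_different_seed_differs(self):
        assert syn.generate_reference_db(seed=1).sequences != \
            syn.generate_reference_db(seed=2).sequences

    def test_divergence_ordering_enforced(self):
        with pytest.raises(ValueError):
            syn.generate_reference_db(within_genus_divergence=0.3,
                                      between_genus_divergence=0.2)

    def test_lengths_in_16s_band(self, ref_db):
        assert all(1300 <= len(s) <= 1600 for s in ref_db.sequences.values())


class TestCommunities:
    def test_bookkeeping_with_missing_sample(self, design, profiles):
        # 6 tanks x 3 compartments x 3 days, minus the designed missing
        # sample, with the six per-tank day-0 root cells collapsed into one
        # shared rockwool sample
        expect = 6 * 3 * 3 - len(design.missing_samples) - 6 + 1
        assert len(profiles) == expect
        shared = [p for p in profiles if p.tank == 0]
        assert len(shared) == 1
        assert shared[0].compartment == "root" and shared[0].day == 0

    def test_eit_root_day61_pathogen_band(self, design, ref_db, profiles):
        for p in profiles:
            if p.compartment == "root" and p.day == 61:
                frac = p.abundances[design.pathogen_genus]
                if design.inoculum_of(p.tank) == "EIT":
                    assert 0.5 <= frac <= 0.8
                else:
                    assert frac < 0.2

    def test_biofilter_pathogen_band(self, design, profiles):
        for p in profiles:
            if p.compartment == "biofilter":
                assert 0.0 < p.abundances[design.pathogen_genus] < 0.35

    def test_profiles_normalized(self, profiles):
        for p in profiles:
            assert sum(p.abundances.values()) == pytest.approx(1.0, abs=1e-12)


class TestReads:
    def test_zero_error_reads_are_exact_copies(self, ref_db, root_day61_profile):
        reads, truth = syn.simulate_reads(
            root_day61_profile, ref_db, 50, syn.ErrorModel().zeroed(), seed=3
        )
        for r in reads:
            assert r.sequence == ref_db.sequences[truth.loc[r.read_id, "ref_id"]]

    def test_median_quality_near_fifteen(self, ref_db, root_day61_profile):
        reads, _ = syn.simulate_reads(root_day61_profile, ref_db, 1000, seed=4)
        med = np.median(np.concatenate([r.qualities for r in reads]))
        assert abs(med - 15) <= 2

    def test_source_draw_is_multinomial(self, ref_db, root_day61_profile):
        """Chi-square goodness of fit of source counts vs profile at n=10k."""
        n = 10_000
        _, truth = syn.simulate_reads(root_day61_profile, ref_db, n, seed=5)
        obs = truth["genus"].value_counts()
        genera = list(root_day61_profile.abundances)
        probs = np.array([root_day61_profile.abundances[g] for g in genera])
        observed = np.array([obs.get(g, 0) for g in genera])
        res = stats.chisquare(observed, probs / probs.sum() * n)
        assert res.pvalue > 0.001

    def test_deterministic_given_seed(self, ref_db, root_day61_profile):
        a, _ = syn.simulate_reads(root_day61_profile, ref_db, 20, seed=9)
        b, _ = syn.simulate_reads(root_day61_profile, ref_db, 20, seed=9)
        assert [(r.read_id, r.sequence, r.qualities.tolist()) for r in a] == \
            [(r.read_id, r.sequence, r.qualities.tolist()) for r in b]

    def test_empty_profile_rejected(self, ref_db, root_day61_profile):
        with pytest.raises(ValueError):
            syn.simulate_reads(root_day61_profile, ref_db, 0, seed=1)


class TestScorer:
    def test_exact_read_scores_one(self, ref_db):
        ref = ref_db.ref_ids[0]
        seq = ref_db.sequences[ref]
        read = ReadRecord("x", seq, np.full(len(seq), 30))
        alns = syn.score_alignments([read], ref_db)
        best = max(alns, key=lambda a: a.identity)
        assert best.ref_id == ref
        assert best.identity == pytest.approx(1.0)

    def test_equidistant_refs_get_equal_score(self):
        db = syn.generate_reference_db(2, 2, 0.02, 0.2, seed=11)
        g = list(db.genera.values())[0]
        a, b = (db.sequences[r] for r in g[:2])
        # chimeric read: first half of a, second half of b
        half = len(a) // 2
        read_seq = a[:half] + b[half:]
        read = ReadRecord("x", read_seq, np.full(len(read_seq), 30))
        alns = {x.ref_id: x.identity for x in syn.score_alignments([read], db)}
        assert abs(alns[g[0]] - alns[g[1]]) < 0.05

    def test_max_candidates_honored(self, ref_db, root_day61_profile):
        reads, _ = syn.simulate_reads(root_day61_profile, ref_db, 30, seed=12)
        alns = syn.score_alignments(reads, ref_db, max_candidates=2)
        per_read = pd.Series([a.read_id for a in alns]).value_counts()
        assert per_read.max() <= 2

    def test_short_read_skipped(self, ref_db):
        read = ReadRecord("tiny", "ACGT", np.full(4, 30))
        assert syn.score_alignments([read], ref_db) == []

    def test_score_equals_match_fraction(self, ref_db, root_day61_profile):
        reads, _ = syn.simulate_reads(root_day61_profile, ref_db, 10, seed=13)
        for a in syn.score_alignments(reads, ref_db):
            assert 0 <= a.n_matches <= a.block_len


class TestChemistry:
    def test_grid_density_and_nonnegativity(self, design):
        chem = syn.simulate_water_chemistry(design, seed=1)
        per = chem.groupby(["tank", "analyte"]).size()
        assert (per >= 30).all()
        assert (chem["value"] >= 0).all()

    def test_spike_adds_nitrate_mass_at_identical_seed(self, design):
        import dataclasses

        spiked = syn.simulate_water_chemistry(design, seed=21)
        no_spike = syn.simulate_water_chemistry(
            dataclasses.replace(design, nitrate_spike_tank=None), seed=21
        )
        a = tank_aucs(spiked, "nitrate")
        b = tank_aucs(no_spike, "nitrate")
        assert a[3] > b[3]
        for tank in (1, 2, 4, 5, 6):
            assert a[tank] == pytest.approx(b[tank])


class TestPhenotypes:
    def test_thirteen_plants_per_tank(self, design, profiles):
        pheno = syn.simulate_phenotypes(design, profiles, seed=2)
        assert pheno.groupby("tank")["plant"].nunique().eq(13).all()

    def test_heights_monotone_per_plant(self, design, profiles):
        pheno = syn.simulate_phenotypes(design, profiles, seed=3)
        for _, grp in pheno.sort_values("day").groupby("plant"):
            assert (np.diff(grp["height_cm"].to_numpy()) >= -1e-9).all()

    def test_paperlike_effects_reduce_eit_growth(self, design, profiles):
        pheno = syn.simulate_phenotypes(design, profiles, seed=4)
        final = pheno[pheno["day"] == pheno["day"].max()]
        cit = final[final["tank"].isin(design.cit_tanks)]["height_cm"]
        eit = final[final["tank"].isin(design.eit_tanks)]["height_cm"]
        assert eit.mean() < cit.mean()
        _, p = mann_whitney_u(cit, eit)
        assert p < 0.001

    def test_null_effects_show_no_inoculum_difference(self, design, profiles):
        """Zero effect sizes: Mann-Whitney p on final heights is typically
        non-significant (median over 20 seeds)."""
        import dataclasses

        null = dataclasses.replace(design, pathogen_growth_effect=0.0,
                                   diazotroph_growth_effect=0.0)
        ps = []
        for seed in range(20):
            pheno = syn.simulate_phenotypes(null, profiles, seed=seed)
            final = pheno[pheno["day"] == pheno["day"].max()]
            cit = final[final["tank"].isin(design.cit_tanks)]["height_cm"]
            eit = final[final["tank"].isin(design.eit_tanks)]["height_cm"]
            ps.append(mann_whitney_u(cit, eit)[1])
        assert np.median(ps) > 0.05


class TestDesignValidation:
    def test_arm_partition_enforced(self):
        with pytest.raises(ValueError):
            syn.StudyDesign(cit_tanks=(1, 2), eit_tanks=(3, 4, 5, 6))

    def test_desk_scale_shrinks_libraries(self, design):
        small = design.desk_scale(8.0)
        assert small.library_size_range[1] < design.library_size_range[1]
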