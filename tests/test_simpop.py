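"""Simulator behavior: inheritance rules, determinism, overlay, synthesizers."""

import numpy as np
import pandas as pd
import pytest

from ylinkkit import simpop
from ylinkkit.core import HET, MISSING


def tiny_config(**kw):
    base = dict(
        pop_size=30,
        burn_in_generations=60,
        sample_males=5,
        sample_females=5,
        mu_per_locus={"A": 0.01, "X": 0.01, "Y": 0.01},
        n_loci={"A": 20, "X": 20, "Y": 20},
        n_y_lineages=2,
        seed=0,
    )
    base.update(kw)
    return simpop.WFConfig(**base)


class TestEngine:
    def test_zero_mutation_rate_zero_segregating(self):
        pop = simpop.simulate_wf(tiny_config(mu_per_locus={"A": 0.0, "X": 0.0, "Y": 0.0}))
        for c in "AXY":
            assert pop.segregating_mutations(c) == set()

    def test_sample_size_exceeding_sex_count_errors(self):
        with pytest.raises(ValueError, match="males"):
            simpop.WFConfig(pop_size=200, sample_males=101)

    def test_deterministic_given_seed(self):
        a = simpop.simulate_wf(tiny_config(seed=7))
        b = simpop.simulate_wf(tiny_config(seed=7))
        assert a.individuals == b.individuals
        assert a.y == b.y
        assert a.autosomal == b.autosomal
        assert a.x == b.x

    def test_y_transmission_father_to_son(self):
        """Every male's Y equals his father's Y plus new mutations only."""
        pop = simpop.simulate_wf(tiny_config(seed=3), record_y_pedigree=True)
        history = pop.y_pedigree["history"]
        store = pop.y_pedigree["store"]
        n_loci = pop.config.n_loci["Y"]
        for gen in range(1, len(history)):
            fathers, y_now = history[gen]
            _, y_prev = history[gen - 1]
            for i in range(y_now.shape[1]):
                for l in range(n_loci):
                    child = set(store.resolve(int(y_now[l, i])))
                    father = set(store.resolve(int(y_prev[l, fathers[i]])))
                    assert father <= child

    def test_sex_copy_numbers(self):
        pop = simpop.simulate_wf(tiny_config())
        for name in pop.males:
            assert len(pop.x[name]) == 1 and name in pop.y
        for name in pop.females:
            assert len(pop.x[name]) == 2 and name not in pop.y

    def test_theta_ratio_smoke(self):
        # full-scale calibration lives in the acceptance suite; here only a
        # sanity band on a small config
        pop = simpop.simulate_wf(tiny_config(pop_size=100, burn_in_generations=800,
                                             sample_males=10, sample_females=10, seed=5))
        x_a, y_a = pop.theta_ratios()
        assert 0.3 < x_a < 1.3
        assert 0.02 < y_a < 0.8


class TestLayout:
    def test_interval_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            simpop.SimLayout(
                chrom_lengths={"c": 100}, sex_chrom="c",
                par=(0, 50), stratum2=(40, 70), stratum1=(70, 100),
                degenerate_subintervals=[],
            )
        with pytest.raises(ValueError, match="stratum1"):
            simpop.SimLayout(
                chrom_lengths={"c": 100}, sex_chrom="c",
                par=(0, 30), stratum2=(30, 60), stratum1=(60, 100),
                degenerate_subintervals=[(10, 20)],
            )

    def test_default_layout_valid(self):
        layout = simpop.default_layout()
        assert layout.sex_chrom in layout.chrom_lengths
        assert len(layout.grid()) > 0


@pytest.fixture(scope="module")
def small():
    pop = simpop.simulate_wf(tiny_config(seed=2))
    layout = simpop.small_layout()
    cohort, truth = simpop.overlay_layout(pop, layout, seed=3)
    return pop, layout, cohort, truth


class TestOverlay:
    def test_single_shared_y_mutation_full_linkage(self):
        # hand-built population: one Y mutation carried by every male
        from ylinkkit.simpop import SampledPopulation

        inds = [("M00", "M"), ("M01", "M"), ("F00", "F"), ("F01", "F")]
        pop = SampledPopulation(
            individuals=inds,
            autosomal={i: (frozenset(), frozenset()) for i, _ in inds},
            x={"M00": (frozenset(),), "M01": (frozenset(),),
               "F00": (frozenset(), frozenset()), "F01": (frozenset(), frozenset())},
            y={"M00": frozenset([999]), "M01": frozenset([999])},
            config=tiny_config(pop_size=30, sample_males=2, sample_females=2, n_y_lineages=1),
        )
        cohort, truth = simpop.overlay_layout(
            pop, simpop.small_layout(), seed=0,
            stratum2_frac=0.0, stratum1_mappable_frac=1.0, marker_snps_per_lineage=0,
        )
        assert cohort.n_sites == 1
        male_cols = [0, 1]
        female_cols = [2, 3]
        assert (cohort.gt[0, male_cols] == HET).all()
        assert (cohort.gt[0, female_cols] == 0).all()
        assert truth["fully_male_linked_positions"] == [
            (str(cohort.chrom[0]), int(cohort.pos[0]))
        ]

    def test_lineage_classes_recorded(self, small):
        pop, layout, cohort, truth = small
        assert len(set(truth["lineage_of"].values())) == pop.config.n_y_lineages
        assert set(truth["lineage_of"]) == set(pop.males)

    def test_zero_stratum2_fraction_confines_sex_signal(self):
        pop = simpop.simulate_wf(tiny_config(seed=4))
        layout = simpop.small_layout()
        cohort, truth = simpop.overlay_layout(
            pop, layout, seed=5, stratum2_frac=0.0, stratum1_mappable_frac=1.0
        )
        s1 = layout.stratum1
        for chrom, pos in truth["male_limited_positions"]:
            assert chrom == layout.sex_chrom
            assert s1[0] < pos <= s1[1]

    def test_phased_matrix_consistent_with_genotypes(self, small):
        _, _, cohort, _ = small
        np.testing.assert_array_equal(
            cohort.gt, cohort.hap[:, 0::2] + cohort.hap[:, 1::2]
        )

    def test_male_hap2_is_y_in_stratum1(self, small):
        pop, layout, cohort, truth = small
        # female hap columns never carry the male-limited allele
        ml = set(map(tuple, truth["male_limited_positions"]))
        female_cols = []
        for j, (name, sex) in enumerate(pop.individuals):
            if sex == "F":
                female_cols += [2 * j, 2 * j + 1]
        for i in range(cohort.n_sites):
            if (str(cohort.chrom[i]), int(cohort.pos[i])) in ml:
                assert not cohort.hap[i, female_cols].any()


class TestDepth:
    def test_factor_one_equal_means(self):
        layout = simpop.small_layout()
        inds = [("M00", "M"), ("F00", "F")]
        depth = simpop.synth_depth(layout, inds, mean_depth={"M": 30, "F": 30},
                                   degeneracy_factor=1.0, seed=0)
        assert abs(depth.loc["M00"].mean() - depth.loc["F00"].mean()) < 2.0

    def test_factor_half_in_degenerate_windows(self):
        layout = simpop.small_layout()
        inds = [(f"M{i:02d}", "M") for i in range(30)] + [(f"F{i:02d}", "F") for i in range(30)]
        depth = simpop.synth_depth(layout, inds, mean_depth={"M": 40, "F": 40},
                                   degeneracy_factor=0.5, seed=1)
        grid = layout.grid()
        degen = [
            i for i, (c, s, e) in enumerate(grid.windows)
            if c == layout.sex_chrom
            and any(s < de and e > ds for ds, de in layout.degenerate_subintervals)
        ]
        other = [i for i in range(len(grid)) if i not in degen]
        males = depth.loc[[n for n, s in inds if s == "M"]]
        females = depth.loc[[n for n, s in inds if s == "F"]]
        ratio_degen = males.iloc[:, degen].values.mean() / females.iloc[:, degen].values.mean()
        ratio_other = males.iloc[:, other].values.mean() / females.iloc[:, other].values.mean()
        assert ratio_degen == pytest.approx(0.5, abs=0.05)
        assert ratio_other == pytest.approx(1.0, abs=0.05)

    def test_deterministic(self):
        layout = simpop.small_layout()
        inds = [("M00", "M"), ("F00", "F")]
        a = simpop.synth_depth(layout, inds, seed=9)
        b = simpop.synth_depth(layout, inds, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_factor_errors(self):
        with pytest.raises(ValueError):
            simpop.synth_depth(simpop.small_layout(), [("M00", "M")], degeneracy_factor=-1)


class TestSequences:
    def test_insertion_of_100_gives_80_planted_kmers(self, seq_bundle):
        _, _, manifest = simpop.synth_sequences(
            seq_bundle["cohort"], seq_bundle["pop"], seq_bundle["layout"],
            seq_bundle["truth"]["lineage_of"], y_insertion_length=100, seed=17,
        )
        assert all(v == 80 for v in manifest["planted_count_per_lineage"].values())

    def test_same_lineage_same_insertion(self, seq_bundle):
        manifest = seq_bundle["manifest"]
        pop = seq_bundle["pop"]
        lineage_of = seq_bundle["truth"]["lineage_of"]
        males = pop.males
        # all males share lineage 0 in this bundle: identical planted content
        assert len(set(lineage_of.values())) == 1
        sex_chrom = seq_bundle["layout"].sex_chrom
        y_seqs = {
            seq_bundle["sequences"][m][f"{m}_{sex_chrom}_h2"][
                manifest["insert_point_0based"] : manifest["insert_point_0based"]
                + manifest["y_insertion_length"]
            ]
            for m in males
        }
        assert len(y_seqs) == 1

    def test_insertion_longer_than_stratum_errors(self, seq_bundle):
        with pytest.raises(ValueError, match="stratum"):
            simpop.synth_sequences(
                seq_bundle["cohort"], seq_bundle["pop"], seq_bundle["layout"],
                seq_bundle["truth"]["lineage_of"], y_insertion_length=200_000,
            )

    def test_reference_base_matches_ref_allele(self, seq_bundle):
        cohort = seq_bundle["cohort"]
        ref = seq_bundle["reference"]
        for i in range(0, cohort.n_sites, 25):
            assert ref[str(cohort.chrom[i])][int(cohort.pos[i]) - 1] == str(cohort.ref[i])


class TestMolecules:
    def test_lengths_within_range(self, sim_bundle):
        mols = simpop.synth_molecules(sim_bundle["pop"], simpop.molecule_layout(),
                                      molecule_length=(20_000, 60_000),
                                      n_per_individual=50, seed=0, y_inversion=None)
        lengths = mols["end"] - mols["start"]
        assert (lengths >= 1).all() and (lengths <= 60_000).all()

    def test_invalid_range_errors(self, sim_bundle):
        with pytest.raises(ValueError):
            simpop.synth_molecules(sim_bundle["pop"], simpop.molecule_layout(),
                                   molecule_length=(60_000, 20_000))

    def test_inversion_outside_stratum1_errors(self, sim_bundle):
        with pytest.raises(ValueError):
            simpop.synth_molecules(sim_bundle["pop"], simpop.molecule_layout(),
                                   y_inversion=(0, 500_000))


def test_write_fixtures_round_trip(tmp_path):
    from ylinkkit import io

    manifest = simpop.write_fixtures(
        tmp_path, seed=0,
        config=tiny_config(),
        layout=simpop.small_layout(),
    )
    cohort = io.read_vcf(manifest["paths"]["vcf"])
    labels = io.read_sex_tsv(manifest["paths"]["sex"])
    bed = io.read_bed(manifest["paths"]["strata"])
    mols = io.read_molecules_tsv(manifest["paths"]["molecules"])
    assert cohort.n_sites > 0
    assert set(labels.mapping.values()) == {"M", "F"}
    assert len(bed) >= 3
    assert len(mols) > 0
    # determinism: a second bundle from the same seed is byte-identical
    import filecmp
    out2 = tmp_path / "again"
    simpop.write_fixtures(out2, seed=0, config=tiny_config(), layout=simpop.small_layout())
    assert filecmp.cmp(manifest["paths"]["vcf"], out2 / "cohort.vcf", shallow=False)
    assert filecmp.cmp(manifest["paths"]["depth"], out2 / "depth.tsv", shallow=False)
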