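"""The planted-truth generator: determinism, structure, recoverability."""

import math

import numpy as np
import pytest

from crossomics.harmonize import gene_sets_by_condition, harmonize_all
from crossomics.io_model import read_entry, read_gene_list, read_gmt, read_manifest
from crossomics.regulation import build_regulation_matrix
from crossomics.synthetic import (
    SimulationConfig,
    agreement_for_concordance,
    generate_condition_truth,
    generate_universe,
    simulate,
)


def harmonized_groups(bundle):
    manifest = read_manifest(bundle.manifest_path)
    universe = read_gene_list(manifest.population_path)
    tables = [read_entry(e) for e in manifest.entries]
    groups, audit = harmonize_all(tables, universe)
    return groups, audit


class TestUniverse:
    def test_size_and_uniqueness(self):
        uni = generate_universe(SimulationConfig(universe_size=10))
        assert len(uni) == len(set(uni)) == 10

    def test_default_matches_coding_genome_size(self, default_bundle):
        symbols = read_gene_list(default_bundle.population_path)
        assert len(symbols) == 19324

    def test_deterministic(self):
        cfg = SimulationConfig(universe_size=100)
        assert generate_universe(cfg) == generate_universe(cfg)


class TestTruth:
    def test_concordance_one_gives_identical_directions(self):
        cfg = SimulationConfig(universe_size=2000, n_shared=200, concordance=1.0)
        truth = generate_condition_truth(cfg)
        first = truth.base_dir[cfg.conditions[0]]
        for cond in cfg.conditions[1:]:
            assert {g: truth.base_dir[cond][g] for g in truth.shared} == {
                g: first[g] for g in truth.shared
            }

    def test_concordance_zero_two_conditions_all_opposite(self):
        cfg = SimulationConfig(
            universe_size=2000, conditions=("A", "B"), n_shared=100, concordance=0.0
        )
        truth = generate_condition_truth(cfg)
        assert all(
            truth.base_dir["A"][g] == -truth.base_dir["B"][g] for g in truth.shared
        )

    def test_half_concordance_agreement_fraction(self):
        cfg = SimulationConfig(
            universe_size=15000, n_shared=10_000, n_pairwise=0, n_private=0,
            n_singletons=0, concordance=0.5,
        )
        truth = generate_condition_truth(cfg)
        a, b = cfg.conditions[:2]
        agree = sum(
            truth.base_dir[a][g] == truth.base_dir[b][g] for g in truth.shared
        ) / len(truth.shared)
        assert abs(agree - 0.5) <= 0.015  # 3 sigma binomial at n=1e4

    def test_low_uniform_concordance_needs_two_conditions(self):
        with pytest.raises(ValueError, match="two conditions"):
            SimulationConfig(concordance=0.2).validate()

    def test_infeasible_allocation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationConfig(universe_size=100, n_shared=200).validate()

    def test_agreement_solves_pair_concordance(self):
        for c in (0.5, 0.75, 0.9, 1.0):
            a = agreement_for_concordance(c)
            assert a * a + (1 - a) * (1 - a) == pytest.approx(c)

    def test_groups_are_disjoint(self):
        cfg = SimulationConfig(universe_size=3000, n_shared=50, n_pairwise=10,
                               n_private=60, n_singletons=20)
        truth = generate_condition_truth(cfg)
        groups = [set(truth.shared)]
        groups += [set(v) for v in truth.pairwise.values()]
        groups += [set(v) for v in truth.private.values()]
        groups += [{s["gene"] for s in truth.singletons}]
        total = sum(len(g) for g in groups)
        assert len(set().union(*groups)) == total


class TestBundleStructure:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, universe_size=1500, n_shared=20, n_pairwise=3,
                               n_private=25, n_singletons=6, n_background=30,
                               transcriptomic_studies=3, proteomic_studies=2,
                               n_decoy_terms=10)
        b1 = simulate(cfg, tmp_path / "one")
        b2 = simulate(cfg, tmp_path / "two")
        files1 = sorted(p.name for p in (tmp_path / "one").iterdir())
        files2 = sorted(p.name for p in (tmp_path / "two").iterdir())
        assert files1 == files2
        for name in files1:
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes(), name

    def test_adding_a_study_never_perturbs_existing_files(self, tmp_path):
        base = dict(seed=5, universe_size=1500, n_shared=20, n_pairwise=3,
                    n_private=25, n_singletons=0, n_background=30,
                    proteomic_studies=2, n_decoy_terms=10)
        simulate(SimulationConfig(transcriptomic_studies=3, **base), tmp_path / "a")
        simulate(SimulationConfig(transcriptomic_studies=4, **base), tmp_path / "b")
        for name in (p.name for p in (tmp_path / "a").iterdir()):
            if "tx_04" in name or name in ("manifest.yaml", "truth.json"):
                continue
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_manifest_is_ready_to_run(self, small_bundle):
        manifest = read_manifest(small_bundle.manifest_path)
        conds = len(small_bundle.config.conditions)
        expected = conds * (
            small_bundle.config.transcriptomic_studies
            + small_bundle.config.proteomic_studies
            + 1  # genomic list
        )
        assert len(manifest.entries) == expected
        assert manifest.population_path.exists()
        assert manifest.gmt_paths

    def test_gmt_has_planted_and_decoy_terms(self, small_bundle):
        coll = read_gmt(small_bundle.gmt_path)
        assert "PLANTED_SHARED" in coll.sets
        assert sum(1 for t in coll.sets if t.startswith("DECOY_")) == 20
        planted = coll.sets["PLANTED_SHARED"].members
        # strength 1.0: every member comes from the shared group
        assert planted <= set(small_bundle.truth.shared)

    def test_significant_rows_respect_fdr_alpha(self, small_bundle):
        manifest = read_manifest(small_bundle.manifest_path)
        entry = next(e for e in manifest.entries if e.layer == "transcriptomic")
        table = read_entry(entry)
        alpha = small_bundle.config.fdr_alpha
        planted = small_bundle.truth.condition_genes(entry.condition)
        for rec in table.records:
            if rec.gene in planted:
                assert 0 < rec.fdr <= alpha
        background = [r for r in table.records if r.gene not in planted
                      and not any(s["gene"] == r.gene for s in small_bundle.truth.singletons)]
        assert background and all(r.fdr > alpha for r in background)


class TestRecovery:
    def test_noise_free_unanimity_and_base_direction(self, small_bundle):
        groups, _ = harmonized_groups(small_bundle)
        truth = small_bundle.truth
        conds = list(truth.conditions)
        matrix = build_regulation_matrix(
            [r for (c, l), recs in groups.items() if l == "transcriptomic" for r in recs],
            truth.shared, conds,
        )
        for gene in truth.shared:
            for cond in conds:
                assert matrix.values.loc[gene, cond] == truth.base_dir[cond][gene]

    def test_recurrence_filter_removes_exactly_the_singletons(self, small_bundle):
        groups, _ = harmonized_groups(small_bundle)
        truth = small_bundle.truth
        surviving = set().union(
            *(gene_sets_by_condition(groups, "transcriptomic").values())
        )
        singleton_genes = {s["gene"] for s in truth.singletons}
        assert surviving.isdisjoint(singleton_genes)
        planted = set(truth.shared)
        for members in truth.pairwise.values():
            planted |= set(members)
        for members in truth.private.values():
            planted |= set(members)
        assert planted <= surviving

    def test_planted_center_equals_transcriptomic_intersection(self, small_bundle):
        groups, _ = harmonized_groups(small_bundle)
        sets = gene_sets_by_condition(groups, "transcriptomic")
        centre = set.intersection(*sets.values())
        assert centre == set(small_bundle.truth.shared)

    def test_flip_noise_sign_disagreement_rate(self, tmp_path):
        # with s studies and flip probability eps, a planted gene's recovered
        # mean direction disagrees with its base direction when more than
        # half the studies flip: P(Bin(s, eps) > s/2)
        s, eps = 9, 0.2
        cfg = SimulationConfig(
            seed=21, universe_size=3000, n_shared=400, n_pairwise=0, n_private=0,
            n_singletons=0, n_background=0, transcriptomic_studies=s,
            proteomic_studies=0, flip_noise=eps, concordance=1.0,
        )
        bundle = simulate(cfg, tmp_path / "noisy")
        groups, _ = harmonized_groups(bundle)
        truth = bundle.truth
        from scipy.stats import binom

        expected = binom.sf(s // 2, s, eps)
        trials, disagreements = 0, 0
        matrix = build_regulation_matrix(
            [r for (c, l), recs in groups.items() if l == "transcriptomic" for r in recs],
            truth.shared, list(truth.conditions),
        )
        for cond in truth.conditions:
            for gene in truth.shared:
                v = matrix.values.loc[gene, cond]
                trials += 1
                if np.sign(v) != truth.base_dir[cond][gene]:
                    disagreements += 1
        rate = disagreements / trials
        sigma = math.sqrt(expected * (1 - expected) / trials)
        assert abs(rate - expected) <= 3 * sigma


class TestExpectedCorrelation:
    @pytest.mark.parametrize("c", [0.5, 0.75, 1.0])
    def test_two_condition_concordance_maps_to_r(self, tmp_path, c):
        cfg = SimulationConfig(
            seed=13, universe_size=2000, conditions=("X", "Y"), n_shared=150,
            n_pairwise=0, n_private=0, n_singletons=0, n_background=0,
            transcriptomic_studies=10, proteomic_studies=0, concordance=c,
        )
        bundle = simulate(cfg, tmp_path / f"c{c}")
        groups, _ = harmonized_groups(bundle)
        matrix = build_regulation_matrix(
            [r for (cc, l), recs in groups.items() if l == "transcriptomic" for r in recs],
            bundle.truth.shared, ["X", "Y"],
        )
        r = np.corrcoef(matrix.values["X"], matrix.values["Y"])[0, 1]
        if c == 1.0:
            assert r == pytest.approx(1.0)
        else:
            assert abs(r - (2 * c - 1)) <= 0.1
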