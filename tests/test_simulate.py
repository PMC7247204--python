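"""Synthetic-data generator: determinism, planted structure, event models."""

import filecmp

import numpy as np
import pytest

from spidel.simulate import (
    GroupSpec,
    SimulationConfig,
    _RefIndex,
    simulate_experiment,
    simulate_mutant,
    simulate_reference,
)
from spidel.spectrum import SpectrumClass


def _count_runs(seq: str, min_len: int = 4) -> int:
    count, i = 0, 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            count += 1
        i = j
    return count


class TestReference:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=1)
        assert simulate_reference(cfg).sequence == simulate_reference(cfg).sequence

    def test_planted_run_density(self):
        cfg = SimulationConfig(seed=1, ref_length=6000, run_enrichment=2.0)
        ref = simulate_reference(cfg)
        planted = len(ref.features)
        assert 3 <= planted <= 25  # Poisson(12), generous band
        for start, end in ref.features.values():
            assert len(set(ref.sequence[start:end])) == 1
            assert 4 <= end - start <= 6

    def test_zero_enrichment_matches_iid_background(self):
        # Expected maximal runs of length >= 4 in iid uniform sequence:
        # ~ L * (3/4) * (1/4)^3 per interior start.
        cfg = SimulationConfig(seed=3, ref_length=6000, run_enrichment=0.0)
        counts = [
            _count_runs(simulate_reference(SimulationConfig(seed=s, ref_length=6000,
                                                            run_enrichment=0.0)).sequence)
            for s in range(30)
        ]
        expected = 6000 * (3 / 4) * (1 / 4) ** 3
        assert abs(np.mean(counts) - expected) < 0.2 * expected
        assert not simulate_reference(cfg).features


class TestSimulateMutant:
    def test_all_mass_on_slippage_gives_run_deletions(self, rng):
        cfg = SimulationConfig(seed=2, ref_length=2000)
        ref = simulate_reference(cfg)
        index = _RefIndex(ref)
        params = {"slippage_1bp": 1.0, "other_1bp": 0, "dsb_deletion": 0,
                  "pure_insertion": 0, "complex": 0}
        for _ in range(50):
            _, cls, call = simulate_mutant(ref, cfg, rng, params, index)
            assert cls is SpectrumClass.DEL1_RUN
            assert call.size == 1 and call.in_run

    def test_certain_junction_insertion(self, rng):
        cfg = SimulationConfig(seed=2, ref_length=2000, junction_insertion_prob=1.0)
        ref = simulate_reference(cfg)
        index = _RefIndex(ref)
        params = {"slippage_1bp": 0, "other_1bp": 0, "dsb_deletion": 1.0,
                  "pure_insertion": 0, "complex": 0}
        for _ in range(30):
            _, cls, call = simulate_mutant(ref, cfg, rng, params, index)
            assert cls is SpectrumClass.DELGT2_INS
            assert call.inserted_seq
            assert 1 <= len(call.inserted_seq) <= 22

    def test_ground_truth_reproduces_mutant(self, rng):
        cfg = SimulationConfig(seed=4, ref_length=2000)
        ref = simulate_reference(cfg)
        index = _RefIndex(ref)
        params = {"slippage_1bp": 0.25, "other_1bp": 0.25, "dsb_deletion": 0.25,
                  "pure_insertion": 0.25, "complex": 0}
        for _ in range(100):
            mutant, _, call = simulate_mutant(ref, cfg, rng, params, index)
            assert call.apply(ref) == mutant

    def test_mh_bias_increases_homology_fraction(self):
        # paired seeds across three bias levels
        fractions = []
        for bias in (0.0, 2.0, 5.0):
            cfg = SimulationConfig(seed=6, ref_length=3000, mh_bias=bias,
                                   junction_insertion_prob=0.0, min_size=2, max_size=50)
            ref = simulate_reference(cfg)
            index = _RefIndex(ref)
            params = {"slippage_1bp": 0, "other_1bp": 0, "dsb_deletion": 1.0,
                      "pure_insertion": 0, "complex": 0}
            rng = np.random.default_rng(99)
            calls = [simulate_mutant(ref, cfg, rng, params, index)[2] for _ in range(400)]
            fractions.append(np.mean([c.mh_len >= 1 for c in calls]))
        assert fractions[0] < fractions[1] < fractions[2]

    def test_class_ratios_converge_to_spectrum_params(self, rng):
        # law-of-large-numbers check at the irradiated wild-type ratios
        cfg = SimulationConfig(seed=8, ref_length=3000)
        ref = simulate_reference(cfg)
        index = _RefIndex(ref)
        params = {"slippage_1bp": 0.42, "other_1bp": 0.08, "dsb_deletion": 0.49,
                  "pure_insertion": 0.0, "complex": 0.01}
        n = 4000
        counts = {k: 0 for k in params}
        key_of = {
            SpectrumClass.DEL1_RUN: "slippage_1bp",
            SpectrumClass.DEL1_OTHER: "other_1bp",
            SpectrumClass.DELGT2_MH: "dsb_deletion",
            SpectrumClass.DELGT2_NOMH: "dsb_deletion",
            SpectrumClass.DELGT2_INS: "dsb_deletion",
            SpectrumClass.INSERTION: "pure_insertion",
            SpectrumClass.COMPLEX: "complex",
        }
        for _ in range(n):
            _, cls, _ = simulate_mutant(ref, cfg, rng, params, index)
            counts[key_of[cls]] += 1
        for key, p in params.items():
            tol = 4 * np.sqrt(p * (1 - p) / n) + 1e-9
            assert abs(counts[key] / n - p) <= tol


class TestSimulateExperiment:
    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=42)
        paths_a = simulate_experiment(cfg).write(tmp_path / "a")
        paths_b = simulate_experiment(cfg).write(tmp_path / "b")
        for name in paths_a:
            assert filecmp.cmp(paths_a[name], paths_b[name], shallow=False), name

    def test_group_structure(self):
        exp = simulate_experiment(SimulationConfig(seed=1))
        by_group = {}
        for a in exp.assays:
            by_group.setdefault(a.group, []).append(a)
        assert {g: len(v) for g, v in by_group.items()} == {
            ("WT", 0.0, "brain"): 10,
            ("WT", 10.0, "brain"): 8,
            ("scid", 0.0, "brain"): 6,
            ("scid", 10.0, "brain"): 7,
        }
        for a in exp.assays:
            assert 300_000 <= a.rescued_pfu <= 500_000

    def test_truth_entries_match_records(self):
        exp = simulate_experiment(SimulationConfig(seed=5))
        assert len(exp.truth) == len(exp.records)
        assert sum(a.confirmed_mutants for a in exp.assays) == len(exp.records)

    def test_mean_mf_recovered_across_replicates(self):
        # Poisson oracle: group mean MF within 3 SE of truth over replicates
        true_mf = 5e-6
        group = GroupSpec("WT", 10.0, "brain", 8, true_total_mf=true_mf)
        means = []
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, ref_length=500, groups=(group,))
            exp = simulate_experiment(cfg)
            mfs = [a.confirmed_mutants / a.rescued_pfu for a in exp.assays]
            means.append(np.mean(mfs))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - true_mf) <= 3 * se
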