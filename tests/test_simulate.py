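"""Synthetic dataset generation and the degradation transforms."""

import pytest

from spinanneal.io import ResidueTypeStats
from spinanneal.simulate import (
    DegradationSpec,
    degrade,
    generate_dataset,
    inject_artifacts,
)


class TestGeneration:
    def test_one_hsqc_peak_per_amide(self):
        truth = generate_dataset(sequence="ACDEFGHIKLMNQRSTVWYA" * 2, seed=0)
        assert len(truth.peak_lists["HSQC"]) == 40  # no prolines

    def test_prolines_emit_no_amide_peaks(self):
        truth = generate_dataset(sequence="APGAV", seed=1)
        roots = {truth.peak_truth[p.id][0] for p in truth.all_peaks}
        assert 2 not in roots

    def test_n_terminus_has_no_predecessor_peaks(self):
        truth = generate_dataset(sequence="AKVS", seed=2)
        first = [
            truth.peak_truth[p.id][1]
            for p in truth.all_peaks
            if truth.peak_truth[p.id][0] == 1
        ]
        assert all(not any(lab.endswith("-1") for lab in types) for types in first)

    def test_glycine_emits_no_cb(self):
        truth = generate_dataset(sequence="AGKV", seed=3)
        for p in truth.all_peaks:
            root, types = truth.peak_truth[p.id]
            for lab in types:
                if lab == "CB":
                    assert truth.sequence[root - 1] != "G"
                if lab == "CB-1":
                    assert truth.sequence[root - 2] != "G"

    def test_determinism_per_seed(self):
        a = generate_dataset(length=15, seed=4)
        b = generate_dataset(length=15, seed=4)
        c = generate_dataset(length=15, seed=5)
        shifts = lambda t: [p.shifts for p in t.all_peaks]  # noqa: E731
        assert shifts(a) == shifts(b)
        assert shifts(a) != shifts(c)
        assert a.sequence == b.sequence

    def test_noise_free_positions_equal_truth(self):
        truth = generate_dataset(sequence="AKVS", seed=6, noise=0)
        for p in truth.peak_lists["HSQC"]:
            root, _ = truth.peak_truth[p.id]
            assert p.shifts == (truth.shifts[root]["H"], truth.shifts[root]["N"])

    def test_degenerate_pair_option_creates_overlap_group(self):
        from spinanneal.assembly import assemble_spin_systems

        truth = generate_dataset(length=14, seed=9, noise=0, degenerate_pairs=2)
        groups = assemble_spin_systems(truth.all_peaks)
        assert any(len(g.members) > 1 for g in groups)

    def test_residual_outliers_near_one_third(self, stats):
        """~32% of shifts fall outside one SD of the residue-type mean."""
        total = 0
        outside = 0
        for seed in range(5):
            truth = generate_dataset(length=500, seed=seed)
            for n, per in truth.shifts.items():
                aa = truth.sequence[n - 1]
                for res, value in per.items():
                    z = abs(value - stats.mean(aa, res)) / stats.sd(aa, res)
                    total += 1
                    outside += z > 1.0
        assert total > 10000
        assert abs(outside / total - 0.3173) < 0.02


class TestDegrade:
    def test_full_retention_is_identity(self):
        truth = generate_dataset(length=20, seed=10)
        out = degrade(truth, DegradationSpec(seed=1))
        assert {k: [p.id for p in v] for k, v in out.items()} == {
            k: [p.id for p in v] for k, v in truth.peak_lists.items()
        }

    def test_zero_co_retention_empties_co_lists(self):
        truth = generate_dataset(length=20, seed=10)
        spec = DegradationSpec(retention={"CA": 1.0, "CB": 1.0, "CO": 0.0}, seed=1)
        out = degrade(truth, spec)
        assert out["HNCO"] == []
        assert out["HNCACO"] == []
        assert len(out["HNCA"]) == len(truth.peak_lists["HNCA"])

    def test_retention_probability_is_respected(self):
        truth = generate_dataset(length=150, seed=12)
        spec = DegradationSpec(retention={"CA": 1.0, "CB": 0.25, "CO": 1.0}, seed=3)
        out = degrade(truth, spec)
        n_cb = lambda lists: sum(  # noqa: E731
            1
            for pl in lists.values()
            for p in pl
            if any("CB" in lab for lab in truth.peak_truth[p.id][1])
        )
        frac = n_cb(out) / n_cb(truth.peak_lists)
        assert abs(frac - 0.25) < 0.08

    def test_spin_system_deletion_random(self):
        truth = generate_dataset(length=50, seed=13)
        spec = DegradationSpec(spin_system_retention=0.6, seed=4)
        out = degrade(truth, spec)
        amide = [n for n, r in truth.reference.items() if r is not None]
        kept_roots = {truth.peak_truth[p.id][0] for pl in out.values() for p in pl}
        assert len(kept_roots) == len(amide) - round(0.4 * len(amide))

    def test_contiguous_deletion_forms_runs_of_five(self):
        sequence = "ADKFGSVLTEWYQHIMRNCA" * 3  # proline-free: every residue has an amide
        truth = generate_dataset(sequence=sequence, seed=14)
        spec = DegradationSpec(
            spin_system_retention=0.6, deletion_mode="contiguous5", seed=5
        )
        out = degrade(truth, spec)
        kept_roots = {truth.peak_truth[p.id][0] for pl in out.values() for p in pl}
        amide = {n for n, r in truth.reference.items() if r is not None}
        deleted = sorted(amide - kept_roots)
        # maximal consecutive blocks are unions of disjoint five-residue runs
        runs = []
        for n in deleted:
            if runs and n - runs[-1][-1] == 1:
                runs[-1].append(n)
            else:
                runs.append([n])
        assert all(len(r) % 5 == 0 for r in runs)
        assert sum(len(r) for r in runs) >= 0.3 * len(amide)


class TestArtifacts:
    def test_zero_fraction_is_identity(self):
        truth = generate_dataset(length=20, seed=15)
        out = inject_artifacts(
            truth.peak_lists, 0.0, sequence=truth.sequence, seed=1
        )
        assert sum(map(len, out.values())) == len(truth.all_peaks)

    def test_target_fraction_reached(self, stats):
        truth = generate_dataset(length=30, seed=16)
        out = inject_artifacts(
            truth.peak_lists, 0.20, stats, truth.sequence, seed=2
        )
        carbon = [
            p
            for name, pl in out.items()
            for p in pl
            if name != "HSQC"
        ]
        n_art = sum(1 for p in carbon if p.id.startswith("artifact:"))
        assert n_art / len(carbon) == pytest.approx(0.20, abs=0.01)

    def test_artifacts_carry_maximum_intensity(self, stats):
        truth = generate_dataset(length=25, seed=17)
        out = inject_artifacts(truth.peak_lists, 0.2, stats, truth.sequence, seed=3)
        for name, pl in out.items():
            real_max = max(
                (p.intensity for p in truth.peak_lists[name] if p.intensity), default=None
            )
            for p in pl:
                if p.id.startswith("artifact:"):
                    assert p.intensity == real_max
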