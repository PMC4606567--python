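"""Synthetic-acquisition generator: determinism, self-consistency,
parameter recovery, lock-mass efficacy, dilution series."""

import numpy as np
import pytest

from lipidshot.app import PipelineConfig, run_quantify
from lipidshot.lipid_model import (
    MolecularSpeciesAnnotation,
    SpeciesAnnotation,
    default_standards,
)
from lipidshot.simulate import (
    GroundTruth,
    GroundTruthSpecies,
    NoiseModel,
    reference_plasma_fixture,
    simulate_dilution_series,
    simulate_run,
)
from lipidshot.spectra_io import write_run


def small_truth():
    """A compact ground truth with a double-bond-overlap pair and two
    deconvolvable species whose DIA windows do not co-isolate anything."""
    def sp(name, conc, fracs=()):
        from lipidshot.lipid_model import parse_species_name

        ann = parse_species_name(name)
        return GroundTruthSpecies(ann, conc, fracs)

    pc341_a = MolecularSpeciesAnnotation("PC", ((18, 1, 0), (16, 0, 0)))
    pc341_b = MolecularSpeciesAnnotation("PC", ((17, 1, 0), (17, 0, 0)))
    pe360 = MolecularSpeciesAnnotation("PE", ((19, 0, 0), (17, 0, 0)))
    return GroundTruth(
        species=[
            sp("PC 34:1", 250.0, ((pc341_a, 0.7), (pc341_b, 0.3))),
            sp("PC 34:2", 120.0,
               ((MolecularSpeciesAnnotation("PC", ((18, 1, 0), (16, 1, 0))), 1.0),)),
            sp("PE 36:0", 40.0, ((pe360, 1.0),)),
            sp("SM 34:1;2", 90.0),
            sp("Chol", 1500.0),
        ]
    )


class TestDeterminism:
    def test_same_seed_byte_identical_tsv(self, tmp_path):
        gt = small_truth()
        noise = NoiseModel(intensity_cv=0.1, mz_jitter_ppm=0.5, seed=7)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_run(simulate_run(gt, noise=noise), p1)
        write_run(simulate_run(gt, noise=noise), p2)
        assert p1.read_text() == p2.read_text()

    def test_different_seed_different_jitter(self, tmp_path):
        gt = small_truth()
        a = simulate_run(gt, noise=NoiseModel(mz_jitter_ppm=0.5, seed=1))
        b = simulate_run(gt, noise=NoiseModel(mz_jitter_ppm=0.5, seed=2))
        pa = a.ms1["pos_wide"][0].mz_array()
        pb = b.ms1["pos_wide"][0].mz_array()
        assert pa.shape == pb.shape
        assert np.max(np.abs(pa - pb)) > 1e-5  # sub-ppm jitter differs by seed


class TestSelfConsistency:
    def test_standards_only_recovers_spiked_amounts(self):
        lip = run_quantify(simulate_run(GroundTruth(species=[])))
        amounts = {s.class_name: s.amount_pmol for s in default_standards()}
        assert len(lip.standards) == 18  # LPG has no registry class by default
        for row in lip.standards:
            assert row.concentration_um == pytest.approx(
                amounts[row.class_name], rel=1e-9
            )
        assert lip.species == []  # nothing endogenous, nothing invented

    def test_small_truth_recovery_with_overlap_pair(self):
        gt = small_truth()
        lip = run_quantify(simulate_run(gt))
        got = {s.annotation.name: s.concentration_um for s in lip.species}
        for s in gt.species:
            assert got[s.annotation.name] == pytest.approx(
                s.concentration_um, rel=1e-9
            ), s.annotation.name

    def test_molecular_fraction_recovery_without_shared_chains(self):
        gt = small_truth()
        lip = run_quantify(simulate_run(gt))
        fr = {
            (m.parent.name, m.annotation.name): m.fraction
            for m in lip.molecular
        }
        assert fr[("PC 34:1", "PC 18:1/16:0")] == pytest.approx(0.7, rel=1e-9)
        assert fr[("PC 34:1", "PC 17:1/17:0")] == pytest.approx(0.3, rel=1e-9)
        # conservation of the parent concentration
        total = sum(
            m.concentration_um for m in lip.molecular if m.parent.name == "PC 34:1"
        )
        assert total == pytest.approx(250.0, rel=1e-9)

    def test_species_level_classes_never_deconvolved(self):
        lip = run_quantify(simulate_run(small_truth()))
        assert all(
            m.annotation.class_name not in ("SM", "TAG", "Chol")
            for m in lip.molecular
        )


class TestLockMassEfficacy:
    def test_offset_breaks_tight_tier_and_recalibration_rescues(self, registry):
        from lipidshot.identify import match_ms1, segment_for_target
        from lipidshot.lipid_model import enumerate_species
        from lipidshot.spectra_io import (
            LOCK_APPLIED,
            average_scans,
            lockmass_recalibrate,
            replace_status,
        )

        gt = small_truth()
        run = simulate_run(gt, noise=NoiseModel(calibration_offset_ppm=5.0))
        db = [
            e for e in enumerate_species(registry)
            if e.class_def.polarity == "negative"
            and segment_for_target(run.method, e.class_def, e.mz) is not None
            and segment_for_target(run.method, e.class_def, e.mz).name == "neg_wide"
        ]
        truth_names = {s.annotation.name for s in gt.species}
        raw = average_scans(run.ms1["neg_wide"])

        def truth_hits(matches):
            return {
                m.entry.annotation.name
                for m in matches
                if m.entry.annotation.name in truth_names
            }

        # 5 ppm systematic error, 2 ppm tier: every true species is lost
        assert truth_hits(match_ms1(replace_status(raw, LOCK_APPLIED), db)) == set()
        # without the lock the 8 ppm tier still catches them
        assert truth_hits(match_ms1(raw, db)) >= {"PC 34:1", "PC 34:2", "SM 34:1;2"}
        # after recalibration the 2 ppm tier catches them all
        rec = lockmass_recalibrate(raw, 529.46262)
        assert rec.lockmass_status == LOCK_APPLIED
        assert truth_hits(match_ms1(rec, db)) >= {"PC 34:1", "PC 34:2", "SM 34:1;2"}

    def test_full_pipeline_immune_to_offset(self):
        gt = small_truth()
        lip = run_quantify(
            simulate_run(gt, noise=NoiseModel(calibration_offset_ppm=5.0))
        )
        got = {s.annotation.name: s.concentration_um for s in lip.species}
        for s in gt.species:
            assert got[s.annotation.name] == pytest.approx(
                s.concentration_um, rel=1e-9
            )


class TestDilutionSeries:
    def test_run_count(self):
        gt = small_truth()
        runs = simulate_dilution_series(gt, "PC 34:1", [1, 2, 4, 8], 3)
        assert len(runs) == 4 and all(len(r) == 3 for r in runs)

    def test_noise_free_series_is_perfectly_linear(self):
        from lipidshot.qc_stats import DoseResponse, dose_response_fit

        gt = small_truth()
        levels = [10.0, 30.0, 100.0, 300.0]
        runs = simulate_dilution_series(gt, "PC 34:1", levels, 1)
        measured = []
        for reps in runs:
            lip = run_quantify(reps[0])
            measured.append([
                s.concentration_um for s in lip.species
                if s.annotation.name == "PC 34:1"
            ])
        slope, r2 = dose_response_fit(DoseResponse(levels, measured))
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_unknown_probe_rejected(self):
        with pytest.raises(KeyError):
            simulate_dilution_series(small_truth(), "PC 40:0", [1.0, 2.0, 4.0], 1)


class TestReferenceFixture:
    def test_breadth_and_span(self, plasma_truth):
        assert len(plasma_truth.species) == 224
        classes = {s.annotation.class_name for s in plasma_truth.species}
        assert len(classes) == 22
        concs = [s.concentration_um for s in plasma_truth.species]
        assert min(concs) <= 0.06 and max(concs) >= 2400.0

    def test_fraction_sets_sum_to_one(self, plasma_truth):
        for s in plasma_truth.species:
            if s.fractions:
                assert sum(f for _, f in s.fractions) == pytest.approx(1.0)

    def test_contains_double_bond_overlap_pairs(self, plasma_truth):
        keys = {
            (s.annotation.class_name, s.annotation.total_c,
             s.annotation.total_db, s.annotation.total_oh)
            for s in plasma_truth.species
        }
        pairs = [
            k for k in keys
            if (k[0], k[1], k[2] + 1, k[3]) in keys
        ]
        assert len(pairs) >= 10
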