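"""MS1 matching tiers, DIA window assignment, fragment confirmation."""

import numpy as np
import pytest

from lipidshot.chem_core import ELECTRON_MASS, adduct_mz, monoisotopic_mass, parse_formula
from lipidshot.identify import (
    ToleranceRule,
    assign_msms_window,
    confirm_fragments,
    fragment_mz_for_chain,
    match_ms1,
    segment_for_target,
)
from lipidshot.lipid_model import (
    ChainBounds,
    SpeciesAnnotation,
    enumerate_species,
    parse_species_name,
    species_formula,
)
from lipidshot.spectra_io import (
    LOCK_APPLIED,
    LOCK_UNAVAILABLE,
    Ms1Spectrum,
    MsmsScan,
    Peak,
    default_method_template,
)


def entry_for(registry, name):
    ann = parse_species_name(name)
    f = species_formula(ann, registry)
    from lipidshot.lipid_model import DbEntry

    cdef = registry[ann.class_name]
    return DbEntry(ann, f, adduct_mz(f, cdef.adduct), cdef)


def spectrum_with(peaks, status=LOCK_APPLIED, polarity="negative",
                  window=(520.0, 940.0), segment="neg_wide"):
    return Ms1Spectrum(polarity, window, [Peak(m, i) for m, i in peaks],
                       lockmass_status=status, segment=segment)


class TestMatchTolerance:
    def test_within_locked_tier(self, registry):
        e = entry_for(registry, "PC 34:1")
        s = spectrum_with([(e.mz * (1 + 1.0e-6), 100.0)])
        (m,) = match_ms1(s, [e])
        assert m.mass_error_ppm == pytest.approx(1.0, abs=1e-6)
        assert m.tolerance_used_ppm == 2.0

    def test_tier_switch_on_lock_status(self, registry):
        e = entry_for(registry, "PC 34:1")
        peaks = [(e.mz * (1 + 3.0e-6), 100.0)]
        assert match_ms1(spectrum_with(peaks, LOCK_APPLIED), [e]) == []
        (m,) = match_ms1(spectrum_with(peaks, LOCK_UNAVAILABLE), [e])
        assert m.tolerance_used_ppm == 8.0

    def test_boundary_inclusive_and_sign_symmetric(self, registry):
        e = entry_for(registry, "PC 34:1")
        for sign in (+1, -1):
            s = spectrum_with([(e.mz * (1 + sign * 2.0e-6), 100.0)])
            (m,) = match_ms1(s, [e])
            assert abs(m.mass_error_ppm) == pytest.approx(2.0, abs=1e-6)

    def test_ambiguity_group_shared_peak(self, registry):
        e1 = entry_for(registry, "PC 34:1")
        # a fake second entry 1 ppm above (same class def for simplicity)
        from lipidshot.lipid_model import DbEntry

        e2 = DbEntry(SpeciesAnnotation("PC", 34, 1, 1), e1.formula,
                     e1.mz * (1 + 1.0e-6), e1.class_def)
        s = spectrum_with([(e1.mz, 100.0)])
        got = match_ms1(s, [e1, e2])
        assert len(got) == 2
        primary = [g for g in got if g.is_primary]
        assert len(primary) == 1
        assert primary[0].entry is e1
        assert len(primary[0].ambiguity_group) == 1

    def test_each_entry_matches_nearest_peak_only(self, registry):
        e = entry_for(registry, "PC 34:1")
        s = spectrum_with([(e.mz * (1 - 1.5e-6), 50.0),
                           (e.mz * (1 + 0.5e-6), 60.0)])
        (m,) = [g for g in match_ms1(s, [e]) if g.entry is e]
        assert m.mass_error_ppm == pytest.approx(0.5, abs=1e-6)


class TestWindowAssignment:
    def scans(self, centers):
        return [MsmsScan("negative", c, segment="neg_dia") for c in centers]

    def test_interval_arithmetic(self):
        sc = assign_msms_window(655.47, self.scans([654.5, 655.5, 656.5]))
        assert sc.precursor_window_center == 655.5

    def test_boundary_assigned_upward(self):
        sc = assign_msms_window(656.0, self.scans([654.5, 655.5, 656.5]))
        assert sc.precursor_window_center == 656.5

    def test_out_of_range(self):
        assert assign_msms_window(99.0, self.scans([654.5])) is None

    def test_default_template_unique_assignment(self, registry):
        method = default_method_template()
        pos = [MsmsScan("positive", c, segment="pos_dia")
               for c in method["pos_dia"].inclusion_centers()]
        neg = [MsmsScan("negative", c, segment="neg_dia")
               for c in method["neg_dia"].inclusion_centers()]
        for e in enumerate_species(registry)[::53]:
            scans = pos if e.class_def.polarity == "positive" else neg
            lo = scans[0].precursor_window_center - 0.5
            hi = scans[-1].precursor_window_center + 0.5
            if lo <= e.mz < hi:
                hits = [s for s in scans if s.contains_precursor(e.mz)]
                assert len(hits) == 1


class TestSegmentForTarget:
    def test_sterol_window_reserved(self, registry):
        m = default_method_template()
        assert segment_for_target(m, registry["Chol"], 404.39).name == "pos_sterol"
        # a CE ion at that m/z would not use the sterol window
        assert segment_for_target(m, registry["CE"], 404.39) is None

    def test_lyso_prefers_low_mass_window(self, registry):
        m = default_method_template()
        assert segment_for_target(m, registry["LPC"], 540.0).name == "neg_lyso"
        assert segment_for_target(m, registry["PC"], 540.0).name == "neg_wide"


class TestConfirmFragments:
    def acyl_mz(self, chain):
        return fragment_mz_for_chain("acyl-anion", chain, 0.0)

    def test_pc_complementary_acyl_anions(self, registry):
        ann = SpeciesAnnotation("PC", 34, 1)
        f = species_formula(ann, registry)
        prec = adduct_mz(f, registry["PC"].adduct)
        scan = MsmsScan("negative", round(prec - 0.3) + 0.5, peaks=[
            Peak(self.acyl_mz((16, 0, 0)), 300.0),   # ~255.2330
            Peak(self.acyl_mz((18, 1, 0)), 500.0),   # ~281.2486
        ], segment="neg_dia")
        assert scan.peaks[0].mz == pytest.approx(255.2330, abs=5e-4)
        assert scan.peaks[1].mz == pytest.approx(281.2486, abs=5e-4)
        conf = confirm_fragments(ann, prec, scan, registry,
                                 chain_bounds=ChainBounds(14, 22, 0, 3))
        assert conf.identified
        cand = {c.chains: ch for c, ch in conf.channels.items()}
        assert cand == {((18, 1, 0), (16, 0, 0)): [500.0, 300.0]}

    def test_incomplete_candidate_not_confirmed(self, registry):
        ann = SpeciesAnnotation("PC", 34, 1)
        prec = adduct_mz(species_formula(ann, registry), registry["PC"].adduct)
        scan = MsmsScan("negative", round(prec - 0.3) + 0.5, peaks=[
            Peak(self.acyl_mz((16, 0, 0)), 300.0),  # lone anion
        ], segment="neg_dia")
        conf = confirm_fragments(ann, prec, scan, registry,
                                 chain_bounds=ChainBounds(14, 22, 0, 3))
        assert not conf.identified and conf.channels == {}

    def test_tag_chain_loss_is_confidence_without_molecular_output(
        self, registry
    ):
        ann = SpeciesAnnotation("TAG", 51, 0)
        f = species_formula(ann, registry)
        prec = adduct_mz(f, registry["TAG"].adduct)
        frag = fragment_mz_for_chain("neutral-loss-of-chain", (17, 0, 0), prec)
        scan = MsmsScan("positive", round(prec - 0.3) + 0.5,
                        peaks=[Peak(frag, 40.0)], segment="pos_dia")
        conf = confirm_fragments(ann, prec, scan, registry)
        assert conf.identified          # satisfies the MS-plus-MSMS mode
        assert conf.channels == {}      # but never yields molecular species

    def test_empty_scan_leaves_msonly_classes_unaffected(self, registry):
        ann = SpeciesAnnotation("PC", 34, 1)
        prec = adduct_mz(species_formula(ann, registry), registry["PC"].adduct)
        scan = MsmsScan("negative", round(prec - 0.3) + 0.5, peaks=[],
                        segment="neg_dia")
        conf = confirm_fragments(ann, prec, scan, registry)
        assert not conf.identified
        # an MS-only class needs no fragments at all
        assert registry["SM"].identification_mode == "MS-only"
        assert registry["SM"].fragment_rules == ()

    def test_ce_sterol_cation(self, registry):
        ann = SpeciesAnnotation("CE", 20, 0)
        f = species_formula(ann, registry)
        prec = adduct_mz(f, registry["CE"].adduct)
        sterol = monoisotopic_mass(parse_formula("C27H45")) - ELECTRON_MASS
        assert sterol == pytest.approx(369.3516, abs=5e-4)
        scan = MsmsScan("positive", round(prec - 0.3) + 0.5,
                        peaks=[Peak(sterol, 10.0)], segment="pos_dia")
        conf = confirm_fragments(ann, prec, scan, registry)
        assert conf.identified and conf.channels == {}
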