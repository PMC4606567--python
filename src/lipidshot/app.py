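"""Pipeline orchestration: spectra in, quantified lipidome and QC reports out.

The quantification workflow is::

    read -> average repeat scans per segment -> lock-mass recalibration
         -> MS1 matching (tiered ppm tolerance) -> DIA fragment confirmation
         -> type I + II de-isotoping -> internal-standard quantification
         -> molecular-species deconvolution -> anticoagulant correction

Every stage logs machine-parsable ``key=value`` counts.  Configuration
defaults reproduce the reference acquisition and identification settings
(2/8 ppm tolerance tiers, 1.0 Da DIA isolation, per-class standards).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .identify import (
    Confirmation,
    Identification,
    ToleranceRule,
    assign_msms_window,
    confirm_fragments,
    match_ms1,
    segment_for_target,
)
from .lipid_model import (
    MOLECULAR,
    MS_PLUS_MSMS,
    ChainBounds,
    DbEntry,
    InternalStandard,
    MolecularSpeciesAnnotation,
    Registry,
    SpeciesAnnotation,
    build_default_registry,
    default_ranges,
    default_standards,
    enumerate_species,
    standard_for_class,
)
from .qc_stats import (
    QuartileReport,
    ReplicateTable,
    pearson_log,
    quartile_cv_report,
)
from .quantify import (
    DEFAULT_OVERLAP_TOL_DA,
    MeasuredSpecies,
    MolecularQuant,
    QuantifiedLipidome,
    SpeciesQuant,
    citrate_correct,
    deconvolve_molecular_species,
    deisotope_type1,
    quantify_species,
)
from .spectra_io import (
    AcquisitionRun,
    Ms1Spectrum,
    average_scans,
    lockmass_recalibrate,
    read_run,
    read_run_mzml,
)

__all__ = ["PipelineConfig", "run_quantify", "run_qc"]

log = logging.getLogger("lipidshot")


@dataclass(frozen=True)
class PipelineConfig:
    tolerances: ToleranceRule = field(default_factory=ToleranceRule)
    deisotope_mode: str = "unresolved"  # unresolved | resolved | off
    deisotope_cross_class: bool = True
    overlap_tol_da: float = DEFAULT_OVERLAP_TOL_DA
    include_m4: bool = True
    n_peaks: int = 4
    cluster_tol_ppm: float = 5.0
    lock_search_tol_ppm: float = 10.0
    chain_bounds: ChainBounds = field(default_factory=ChainBounds)
    min_fragment_intensity: float = 0.0
    plasma_ul: Optional[float] = None  # None: take from the run metadata
    anticoagulant: Optional[str] = None  # None: take from the run metadata
    registry: Optional[Registry] = None
    standards: Optional[Sequence[InternalStandard]] = None
    ranges: Optional[dict] = None

    def __post_init__(self):
        if self.plasma_ul is not None and self.plasma_ul <= 0:
            raise ValueError("plasma volume must be positive")


def _prepare_spectra(
    run: AcquisitionRun, cfg: PipelineConfig
) -> Dict[str, Ms1Spectrum]:
    """Average repeat scans per MS1 segment and apply lock-mass correction."""
    out: Dict[str, Ms1Spectrum] = {}
    for seg in run.method.ms1_segments():
        spectra = run.ms1.get(seg.name, [])
        if not spectra:
            continue
        avg = average_scans(spectra, cfg.cluster_tol_ppm)
        if seg.lock_mz is not None:
            avg = lockmass_recalibrate(avg, seg.lock_mz, cfg.lock_search_tol_ppm)
        out[seg.name] = avg
        log.info(
            "stage=prepare segment=%s scans=%d peaks=%d lock=%s",
            seg.name, len(spectra), len(avg.peaks), avg.lockmass_status,
        )
    return out


def run_quantify(
    run: Union[AcquisitionRun, str],
    config: Optional[PipelineConfig] = None,
    input_format: str = "tsv",
) -> QuantifiedLipidome:
    """Execute the full quantification pipeline on one acquisition."""
    cfg = config or PipelineConfig()
    if isinstance(run, str):
        run = read_run(run) if input_format == "tsv" else read_run_mzml(run)
    if not run.ms1:
        raise ValueError("empty run: no MS1 spectra")
    reg = cfg.registry or build_default_registry()
    standards = list(cfg.standards) if cfg.standards is not None else default_standards()
    plasma_ul = cfg.plasma_ul if cfg.plasma_ul is not None else run.plasma_ul
    anticoagulant = cfg.anticoagulant or run.anticoagulant

    db = enumerate_species(reg, cfg.ranges)
    spectra = _prepare_spectra(run, cfg)

    # --- MS1 matching per segment, restricted to that segment's classes ----
    seg_db: Dict[str, List[DbEntry]] = {}
    for e in db:
        seg = segment_for_target(run.method, e.class_def, e.mz)
        if seg is not None:
            seg_db.setdefault(seg.name, []).append(e)
    idents: List[Identification] = []
    for seg_name, spectrum in spectra.items():
        found = match_ms1(spectrum, seg_db.get(seg_name, []), cfg.tolerances)
        idents.extend(found)
        log.info("stage=match segment=%s candidates=%d matched=%d",
                 seg_name, len(seg_db.get(seg_name, [])), len(found))

    # --- targeted matching of the internal standards -----------------------
    std_peaks: Dict[str, Tuple[InternalStandard, float, float, object]] = {}
    for std in standards:
        if std.class_name not in reg:
            log.info("stage=standards name=%s status=class-not-in-registry",
                     std.name)
            continue
        cdef = reg[std.class_name]
        from .chem_core import adduct_mz

        f = std.neutral_formula(reg)
        mz = adduct_mz(f, cdef.adduct)
        seg = segment_for_target(run.method, cdef, mz)
        spectrum = spectra.get(seg.name) if seg is not None else None
        if spectrum is None:
            continue
        tol = cfg.tolerances.for_spectrum(spectrum) * mz * 1e-6
        best = None
        for p in spectrum.peaks:
            d = abs(p.mz - mz)
            if d <= tol and (best is None or d < abs(best.mz - mz)):
                best = p
        if best is not None:
            std_peaks[cdef.class_name] = (std, best.mz, best.intensity, f,
                                          seg.name)
    log.info("stage=standards found=%d of=%d", len(std_peaks), len(standards))

    # --- MS/MS confirmation (every candidate, so that fragment evidence can
    # arbitrate ambiguity groups: exact cross-class isobars exist, e.g. a
    # deprotonated PS and the acetate adduct of a PC four carbons lighter
    # share one elemental composition and are separable only by fragments)
    for d in idents:
        cdef = d.entry.class_def
        if not cdef.fragment_rules:
            continue
        scan = assign_msms_window(d.entry.mz, run.all_msms(cdef.polarity))
        if scan is None:
            continue
        conf = confirm_fragments(
            d.entry.annotation, d.entry.mz, scan, reg,
            tol_ppm=cfg.tolerances.msms_ppm,
            chain_bounds=cfg.chain_bounds,
            min_intensity=cfg.min_fragment_intensity,
        )
        d.confirmation = conf
        if conf.identified:
            d.mode_satisfied = MS_PLUS_MSMS

    def acceptable(d: Identification) -> bool:
        mode = d.entry.class_def.identification_mode
        return mode != MS_PLUS_MSMS or d.mode_satisfied == MS_PLUS_MSMS

    def fragment_score(d: Identification) -> float:
        """Summed intensity of the identifying fragment evidence; when two
        isobaric annotations survive confirmation, the one explaining more
        of the fragment current in its window wins."""
        return d.confirmation.evidence if d.confirmation is not None else 0.0

    # re-rank each peak's ambiguity group: confirmed candidates outrank
    # unconfirmed ones, stronger fragment evidence outranks weaker, then
    # smaller mass error wins
    accepted: List[Identification] = []
    seen_groups = set()
    for d in idents:
        gid = (d.segment, d.peak.mz)
        if gid in seen_groups:
            continue
        seen_groups.add(gid)
        group = [d] + d.ambiguity_group
        group.sort(key=lambda g: (not acceptable(g), -fragment_score(g),
                                  abs(g.mass_error_ppm), g.entry.mz))
        for k, g in enumerate(group):
            g.is_primary = k == 0
        if acceptable(group[0]):
            accepted.append(group[0])
    log.info("stage=confirm matched=%d accepted=%d", len(idents), len(accepted))

    # --- isotope-peak exclusion: an identification whose matched peak sits
    # on an isotopologue position of another accepted species (different
    # class; within-class overlap is corrected arithmetically by type I
    # de-isotoping) and whose intensity is essentially explained by that
    # species' predicted envelope is a misassigned isotope peak, not a lipid
    from .chem_core import NEUTRON_SHIFT, isotope_distribution

    kept: List[Identification] = []
    by_seg: Dict[str, List[Identification]] = {}
    for d in accepted:
        by_seg.setdefault(d.segment, []).append(d)
    n_iso = 0
    for d in accepted:
        phantom = False
        for e in by_seg[d.segment]:
            if e is d or e.entry.annotation.class_name == d.entry.annotation.class_name:
                continue
            for k in range(1, cfg.n_peaks):
                pos = e.peak.mz + k * NEUTRON_SHIFT
                if abs(d.peak.mz - pos) <= d.peak.mz * d.tolerance_used_ppm * 1e-6:
                    env = isotope_distribution(e.entry.formula, cfg.n_peaks)
                    predicted = e.peak.intensity * float(env[k] / env[0])
                    if predicted >= 0.8 * d.peak.intensity:
                        phantom = True
                    break
            if phantom:
                break
        if phantom:
            n_iso += 1
        else:
            kept.append(d)
    accepted = kept
    log.info("stage=isotope-exclusion removed=%d kept=%d", n_iso, len(accepted))

    # --- de-isotoping per class series --------------------------------------
    std_sumcomp = {
        cls: (s.annotation.class_name, s.annotation.total_c,
              s.annotation.total_db, s.annotation.total_oh)
        for cls, (s, _, _, _, _) in std_peaks.items()
    }
    series: Dict[str, List[MeasuredSpecies]] = {}
    ident_for: Dict[Tuple[str, str], Identification] = {}
    for d in accepted:
        ann = d.entry.annotation
        m = MeasuredSpecies(ann, d.entry.formula, d.peak.mz, d.peak.intensity,
                            segment=d.segment)
        series.setdefault(ann.class_name, []).append(m)
        ident_for[(ann.class_name, ann.name)] = d
    # labeled standards (formula overrides) are not database entries; append
    # them to their class series from the targeted match
    for cls, (std, mz, inten, f, seg_name) in std_peaks.items():
        key = (cls, std.annotation.total_c, std.annotation.total_db,
               std.annotation.total_oh)
        in_series = any(
            (s.annotation.class_name, s.annotation.total_c,
             s.annotation.total_db, s.annotation.total_oh) == key
            and std.formula_override is None
            for s in series.get(cls, [])
        )
        if not in_series:
            series.setdefault(cls, []).append(
                MeasuredSpecies(std.annotation, f, mz, inten, segment=seg_name)
            )

    corrected: Dict[str, List[MeasuredSpecies]] = {}
    n_clamped = 0
    for cls, members in series.items():
        corr = deisotope_type1(
            members, cfg.overlap_tol_da, cfg.n_peaks, cfg.include_m4,
            mode=cfg.deisotope_mode,
        )
        n_clamped += sum(m.clamped for m in corr)
        corrected[cls] = corr
    if cfg.deisotope_cross_class and cfg.deisotope_mode == "unresolved":
        from .quantify import deisotope_cross_class

        deisotope_cross_class(
            [m for members in corrected.values() for m in members],
            cfg.cluster_tol_ppm, cfg.n_peaks,
        )
    log.info("stage=deisotope series=%d clamped=%d", len(corrected), n_clamped)

    # --- quantification ------------------------------------------------------
    def find_corrected(cls: str, std: InternalStandard) -> Optional[MeasuredSpecies]:
        key = (std.annotation.total_c, std.annotation.total_db,
               std.annotation.total_oh)
        for m in corrected.get(cls, []):
            if (m.annotation.total_c, m.annotation.total_db,
                    m.annotation.total_oh) == key:
                if std.formula_override is None or m.formula == std.neutral_formula(reg):
                    return m
        return None

    lipidome = QuantifiedLipidome(
        sample_id=run.sample_id, anticoagulant=anticoagulant,
        plasma_ul=plasma_ul,
    )
    std_corr: Dict[str, Tuple[InternalStandard, MeasuredSpecies]] = {}
    for cls, (std, _, _, f, _) in std_peaks.items():
        m = find_corrected(cls, std)
        if m is not None and m.intensity > 0:
            std_corr[cls] = (std, m)

    n_species = n_mol = 0
    for cls, members in corrected.items():
        cdef = reg[cls]
        ref = standard_for_class(cls, [s for s, _ in std_corr.values()])
        if ref is None:
            log.info("stage=quantify class=%s status=no-standard skipped=%d",
                     cls, len(members))
            continue
        std, std_meas = std_corr[ref.class_name]
        f_std = std.neutral_formula(reg)
        for m in members:
            is_std_row = (
                cls in std_sumcomp
                and (m.annotation.class_name, m.annotation.total_c,
                     m.annotation.total_db, m.annotation.total_oh)
                == std_sumcomp[cls]
                # a labeled standard is distinguished from an isobaric-class
                # endogenous species by its (override) formula
                and (std_peaks[cls][0].formula_override is None
                     or m.formula == std_peaks[cls][0].formula_override)
            )
            conc = quantify_species(
                m.intensity, m.formula, std_meas.intensity, f_std,
                std.amount_pmol, plasma_ul, cfg.n_peaks,
            )
            d = ident_for.get((cls, m.annotation.name))
            quant = SpeciesQuant(
                annotation=m.annotation,
                concentration_um=conc,
                class_name=cls,
                is_standard=is_std_row,
                ambiguous=bool(d and d.ambiguity_group),
                ambiguous_with=tuple(
                    o.entry.annotation.name for o in (d.ambiguity_group if d else [])
                ),
                clamped=m.clamped,
                mass_error_ppm=d.mass_error_ppm if d else 0.0,
            )
            if is_std_row:
                lipidome.standards.append(quant)
                continue
            lipidome.species.append(quant)
            n_species += 1
            # molecular-species output
            if cdef.structural_level != MOLECULAR:
                continue
            if cdef.n_chains == 1:
                mol = MolecularSpeciesAnnotation(
                    cls, ((m.annotation.total_c, m.annotation.total_db,
                           m.annotation.total_oh),)
                )
                lipidome.molecular.append(
                    MolecularQuant(mol, m.annotation, 1.0, conc)
                )
                n_mol += 1
                continue
            conf = d.confirmation if d else None
            if conf is not None and conf.channels:
                for mol, frac, c_um in deconvolve_molecular_species(
                    conc, conf.channels
                ):
                    lipidome.molecular.append(
                        MolecularQuant(mol, m.annotation, frac, c_um)
                    )
                    n_mol += 1
    log.info("stage=quantify species=%d molecular=%d standards=%d",
             n_species, n_mol, len(lipidome.standards))

    lipidome.species.sort(key=lambda s: (s.class_name, s.annotation.name))
    lipidome.molecular.sort(
        key=lambda m: (m.annotation.class_name, m.parent.name, m.annotation.name)
    )
    if anticoagulant.lower() == "citrate":
        lipidome = citrate_correct(lipidome)
        log.info("stage=anticoagulant correction=citrate factor=1.1")
    return lipidome


def run_qc(
    lipidomes: Sequence[QuantifiedLipidome],
    groups: Optional[Sequence[str]] = None,
) -> Dict[str, object]:
    """Replicate QC over >= 2 lipidomes: abundance-quartile CV report
    (overall and per grouping level) and the pairwise Pearson log-correlation
    matrix."""
    if len(lipidomes) < 2:
        raise ValueError("need at least 2 lipidomes for QC")
    table = ReplicateTable.from_lipidomes(lipidomes, groups)
    report = quartile_cv_report(table)
    per_group: Dict[str, QuartileReport] = {}
    if groups is not None:
        for g in sorted(set(groups)):
            cols = [c for c, lab in zip(table.values.columns, groups) if lab == g]
            if len(cols) >= 2:
                per_group[g] = quartile_cv_report(
                    ReplicateTable(table.values[cols])
                )
    n = len(lipidomes)
    r = np.ones((n, n))
    maps = [
        {s.annotation.name: s.concentration_um for s in l.species
         if s.concentration_um > 0}
        for l in lipidomes
    ]
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = pearson_log(maps[i], maps[j],
                                            warn_on_mismatch=False)
    return {
        "table": table,
        "quartile_report": report,
        "per_group_reports": per_group,
        "pearson_matrix": pd.DataFrame(r),
    }
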