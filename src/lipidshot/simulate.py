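"""Synthetic-acquisition generator.

Produces :class:`~lipidshot.spectra_io.AcquisitionRun` objects from a
declared ground-truth lipidome under the segmented direct-infusion method
template, so the full identify/de-isotope/quantify/deconvolve pipeline can
be exercised end-to-end against known answers without any external data.

What is emulated
    * MS1 isotope envelopes (M+0..M+3) at the class adduct m/z, intensity
      proportional to concentration;
    * centroid merging of the M+2 isotopologue of a species with the
      monoisotopic peak of its same-class neighbor one double bond up
      (the overlap that type I de-isotoping removes), using the same merge
      window as the corrector so closed-loop recovery is exact;
    * repeat MS1 scans per segment (default two, mirroring the instrument's
      microscan averaging) with per-species multiplicative lognormal
      intensity noise, ppm mass jitter, a systematic calibration offset,
      and the lock-mass background ion carrying the same offset;
    * DIA MS/MS scans on the inclusion-list grid with acyl-anion or chain
      neutral-loss fragments proportional to molecular-species fraction x
      fragment yield x precursor intensity.

Not emulated: ion suppression and matrix effects, chemical noise beyond a
uniform random baseline, profile peak shapes, and retention time (there is
none in direct infusion).  Parameter-recovery tests therefore demonstrate
the correctness of the computational chain, not robustness to effects the
generator does not produce.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem_core import (
    ElementalFormula,
    NEUTRON_SHIFT,
    adduct_mz,
    isotope_distribution,
)
from .identify import fragment_mz_for_chain, segment_for_target
from .lipid_model import (
    DECONVOLUTION,
    IDENTIFICATION,
    InternalStandard,
    MolecularSpeciesAnnotation,
    Registry,
    SpeciesAnnotation,
    build_default_registry,
    default_standards,
    enumerate_species,
    species_formula,
    standard_for_class,
)
from .quantify import DEFAULT_OVERLAP_TOL_DA
from .spectra_io import (
    AcquisitionRun,
    MethodTemplate,
    Ms1Spectrum,
    MsmsScan,
    Peak,
    default_method_template,
)

__all__ = [
    "GroundTruthSpecies",
    "GroundTruth",
    "NoiseModel",
    "simulate_run",
    "simulate_dilution_series",
    "reference_plasma_fixture",
    "RESPONSE_PER_UM",
    "LOCK_INTENSITY",
]

#: Detector response: counts per uM of analyte per scan.  The absolute scale
#: cancels in ratio-based quantification; it only sets where the additive
#: noise floor bites.
RESPONSE_PER_UM = 1000.0

#: Intensity of the lock-mass background ion.
LOCK_INTENSITY = 5.0e4


@dataclass(frozen=True)
class GroundTruthSpecies:
    annotation: SpeciesAnnotation
    concentration_um: float
    #: molecular-species fractions, summing to 1 (empty for species-level
    #: classes; single entry with fraction 1 for single-chain classes)
    fractions: Tuple[Tuple[MolecularSpeciesAnnotation, float], ...] = ()

    def __post_init__(self):
        if self.concentration_um < 0:
            raise ValueError("negative concentration")
        if self.fractions:
            tot = sum(f for _, f in self.fractions)
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(f"fractions sum to {tot}, not 1")


@dataclass
class GroundTruth:
    species: List[GroundTruthSpecies]
    standards: List[InternalStandard] = field(default_factory=default_standards)
    plasma_ul: float = 1.0
    anticoagulant: str = "edta"

    def concentration_of(self, name: str) -> float:
        for s in self.species:
            if s.annotation.name == name:
                return s.concentration_um
        raise KeyError(name)


@dataclass(frozen=True)
class NoiseModel:
    """All sources of imperfection, each off by default.

    intensity_cv
        Multiplicative lognormal noise, one factor per species per scan
        (electrospray intensity fluctuations are scale-proportional).
    mz_jitter_ppm
        Per-peak Gaussian mass jitter, ppm standard deviation.
    calibration_offset_ppm
        Systematic multiplicative mass offset, shared by every peak of a
        segment including the lock-mass ion (hence removable by lock-mass
        recalibration where a lock is defined).
    baseline_peaks
        Count of uniform random background peaks per MS1 spectrum.
    additive_sd
        Additive Gaussian intensity noise (counts), clipped at zero; sets a
        noise floor for limit-of-quantification scenarios.
    fragment_yield
        DIA channel intensity per unit precursor intensity.
    scans_per_segment
        Repeat MS1 scans emitted per segment (averaged downstream).
    seed
        Fixes the run byte-for-byte; per-spectrum substreams are derived by
        hashing (seed, segment, scan).
    """

    intensity_cv: float = 0.0
    mz_jitter_ppm: float = 0.0
    calibration_offset_ppm: float = 0.0
    baseline_peaks: int = 0
    additive_sd: float = 0.0
    fragment_yield: float = 0.05
    scans_per_segment: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.intensity_cv, self.mz_jitter_ppm, self.additive_sd,
               self.fragment_yield) < 0 or self.baseline_peaks < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.scans_per_segment < 1:
            raise ValueError("need at least one scan per segment")


def _substream(seed: int, *keys) -> np.random.Generator:
    token = ":".join([str(seed)] + [str(k) for k in keys])
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little") % (2**63))


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=n) - sigma * sigma / 2.0)


@dataclass(frozen=True)
class _Ion:
    name: str
    class_name: str
    formula: ElementalFormula
    mz: float
    concentration_um: float
    is_standard: bool
    fractions: Tuple[Tuple[MolecularSpeciesAnnotation, float], ...]
    fragment_rules: tuple
    polarity: str
    segment: str


def _ions_for(gt: GroundTruth, reg: Registry, method: MethodTemplate,
              overlap_tol_da: float) -> List[_Ion]:
    import warnings

    ions: List[_Ion] = []

    def push(name, cdef, f, conc, is_std, fractions):
        mz = adduct_mz(f, cdef.adduct)
        seg = segment_for_target(method, cdef, mz)
        if seg is None:
            warnings.warn(f"{name}: m/z {mz:.4f} outside all scan windows; omitted")
            return
        ions.append(
            _Ion(name, cdef.class_name, f, mz, conc, is_std, tuple(fractions),
                 cdef.fragment_rules, cdef.polarity, seg.name)
        )

    for s in gt.species:
        cdef = reg[s.annotation.class_name]
        f = species_formula(s.annotation, reg)
        push(s.annotation.name, cdef, f, s.concentration_um, False, s.fractions)
    for std in gt.standards:
        if std.class_name not in reg:
            continue
        cdef = reg[std.class_name]
        f = std.neutral_formula(reg)
        ann = std.annotation
        fractions = ()
        if isinstance(ann, MolecularSpeciesAnnotation):
            fractions = ((ann, 1.0),)
        # standard amount is pmol per extraction of gt.plasma_ul uL plasma;
        # its effective infusate concentration is amount / volume
        push(std.name, cdef, f, std.amount_pmol / gt.plasma_ul, True, fractions)
    return ions


def simulate_run(
    gt: GroundTruth,
    method: Optional[MethodTemplate] = None,
    noise: Optional[NoiseModel] = None,
    reg: Optional[Registry] = None,
    overlap_tol_da: float = DEFAULT_OVERLAP_TOL_DA,
    n_peaks: int = 4,
    sample_id: str = "sim",
) -> AcquisitionRun:
    """Render a ground truth into a complete synthetic acquisition."""
    if method is None:
        method = default_method_template()
    if noise is None:
        noise = NoiseModel()
    if reg is None:
        reg = build_default_registry()
    ions = _ions_for(gt, reg, method, overlap_tol_da)
    run = AcquisitionRun(method, sample_id=sample_id, plasma_ul=gt.plasma_ul,
                         anticoagulant=gt.anticoagulant)

    by_segment: Dict[str, List[_Ion]] = {}
    for ion in ions:
        by_segment.setdefault(ion.segment, []).append(ion)
    for seg_ions in by_segment.values():
        seg_ions.sort(key=lambda i: (i.mz, i.name))

    offset_factor = 1.0 + noise.calibration_offset_ppm * 1e-6

    # ---- MS1 segments -----------------------------------------------------
    for seg in method.ms1_segments():
        seg_ions = by_segment.get(seg.name, [])
        # precompute merge targets: the M+k isotopologue of a lighter ion
        # that falls within the merge window of a heavier same-class
        # monoisotopic peak is centroided onto the heavier peak
        mono_by_class: Dict[str, List[_Ion]] = {}
        for ion in seg_ions:
            mono_by_class.setdefault(ion.class_name, []).append(ion)
        merge_to: Dict[Tuple[str, int], str] = {}  # (ion.name, k) -> target name
        for ion in seg_ions:
            for k in range(1, n_peaks):
                pos = ion.mz + k * NEUTRON_SHIFT
                for other in mono_by_class[ion.class_name]:
                    if other.name != ion.name and abs(other.mz - pos) <= overlap_tol_da:
                        merge_to[(ion.name, k)] = other.name
                        break

        mz_of = {ion.name: ion.mz for ion in seg_ions}
        for scan_idx in range(noise.scans_per_segment):
            rng = _substream(noise.seed, seg.name, scan_idx)
            factors = _lognormal_factor(rng, noise.intensity_cv, len(seg_ions))
            accum: Dict[float, float] = {}
            for ion, fac in zip(seg_ions, factors):
                total = ion.concentration_um * RESPONSE_PER_UM * fac
                env = isotope_distribution(ion.formula, n_peaks)
                for k in range(n_peaks):
                    target = merge_to.get((ion.name, k))
                    mz = mz_of[target] if target else ion.mz + k * NEUTRON_SHIFT
                    accum[mz] = accum.get(mz, 0.0) + total * float(env[k])
            if seg.lock_mz is not None:
                accum[seg.lock_mz] = accum.get(seg.lock_mz, 0.0) + LOCK_INTENSITY
            if noise.baseline_peaks:
                lo, hi = seg.window
                for mz in rng.uniform(lo, hi, size=noise.baseline_peaks):
                    accum[float(mz)] = accum.get(float(mz), 0.0) + float(
                        rng.lognormal(math.log(100.0), 1.0)
                    )
            peaks = []
            for mz in sorted(accum):
                inten = accum[mz]
                if noise.additive_sd > 0:
                    inten = max(0.0, inten + rng.normal(0.0, noise.additive_sd))
                m = mz * offset_factor
                if noise.mz_jitter_ppm > 0:
                    m *= 1.0 + rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6
                lo, hi = seg.window
                if lo <= m <= hi and inten > 0:
                    peaks.append(Peak(m, inten))
            run.add_ms1(
                Ms1Spectrum(seg.polarity, seg.window, peaks,
                            scan_index=scan_idx, segment=seg.name)
            )

    # ---- DIA segments -----------------------------------------------------
    for seg in method.segments:
        if seg.scan_type != "MSMS-DIA":
            continue
        centers = seg.inclusion_centers()
        start = centers[0] if centers.size else 0.0
        step = seg.inclusion[2] if seg.inclusion else 1.0
        scans: Dict[int, List[Tuple[float, float]]] = {}
        for ion in ions:
            if ion.polarity != seg.polarity or not ion.fragment_rules:
                continue
            # half-open [center-step/2, center+step/2) grid
            ci = int(math.floor((ion.mz - (start - step / 2)) / step))
            if ci < 0 or ci >= centers.size:
                continue
            rng = _substream(noise.seed, seg.name, ion.name)
            fac = float(_lognormal_factor(rng, noise.intensity_cv, 1)[0])
            precursor_int = ion.concentration_um * RESPONSE_PER_UM * fac
            frags = scans.setdefault(ci, [])
            for rule in ion.fragment_rules:
                if rule.rule_kind == "fixed-fragment":
                    from .chem_core import ELECTRON_MASS, monoisotopic_mass

                    mz = (monoisotopic_mass(rule.fixed_formula)
                          - rule.fixed_charge * ELECTRON_MASS)
                    frags.append((mz, noise.fragment_yield * precursor_int))
                    continue
                for mol, frac in ion.fractions:
                    for chain in mol.chains:
                        mz = fragment_mz_for_chain(rule.rule_kind, chain, ion.mz)
                        frags.append(
                            (mz, frac * noise.fragment_yield * precursor_int)
                        )
        for ci in sorted(scans):
            accum: Dict[float, float] = {}
            for mz, inten in scans[ci]:
                accum[mz] = accum.get(mz, 0.0) + inten
            rng = _substream(noise.seed, seg.name, "jitter", ci)
            peaks = []
            for mz in sorted(accum):
                m = mz * offset_factor
                if noise.mz_jitter_ppm > 0:
                    m *= 1.0 + rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6
                peaks.append(Peak(m, accum[mz]))
            run.add_msms(
                MsmsScan(seg.polarity, float(centers[ci]),
                         isolation_width=1.0, normalized_collision_energy=seg.nce,
                         peaks=peaks, segment=seg.name, scan_index=ci)
            )
    return run


def simulate_dilution_series(
    gt: GroundTruth,
    probe_species: str,
    levels_um: Sequence[float],
    n_replicates: int,
    noise: Optional[NoiseModel] = None,
    **kwargs,
) -> List[List[AcquisitionRun]]:
    """One ground truth per spiked level of ``probe_species``; replicates
    differ only by the noise realization (seed derived from base seed,
    level and replicate index).  Returns runs grouped by level."""
    if list(levels_um) != sorted(levels_um):
        raise ValueError("levels must be sorted ascending")
    if noise is None:
        noise = NoiseModel()
    out: List[List[AcquisitionRun]] = []
    for li, level in enumerate(levels_um):
        species = []
        found = False
        for s in gt.species:
            if s.annotation.name == probe_species:
                species.append(replace(s, concentration_um=float(level)))
                found = True
            else:
                species.append(s)
        if not found:
            raise KeyError(f"probe species {probe_species!r} not in ground truth")
        level_gt = GroundTruth(species, gt.standards, gt.plasma_ul,
                               gt.anticoagulant)
        reps = []
        for ri in range(n_replicates):
            n = replace(noise, seed=noise.seed + 1009 * li + ri + 1)
            reps.append(
                simulate_run(level_gt, noise=n,
                             sample_id=f"dil_L{li}_R{ri}", **kwargs)
            )
        out.append(reps)
    return out


# ---------------------------------------------------------------------------
# Reference plasma fixture

# Per-class plan for the synthetic reference plasma: number of species and
# the concentration span (uM) they are logarithmically spread over.  The
# spans sit inside each class's plausible plasma dynamic range, with the
# bulk of the molar amount in Chol, PC, CE, SM and TAG, as in real plasma.
_FIXTURE_PLAN: List[Tuple[str, int, float, float]] = [
    ("PC", 30, 5.0, 2500.0),
    ("PC O-", 10, 5.0, 100.0),
    ("PE", 20, 1.0, 250.0),
    ("PE O-", 8, 1.0, 50.0),
    ("PS", 8, 0.25, 25.0),
    ("PI", 12, 0.25, 250.0),
    ("PA", 6, 1.0, 25.0),
    ("PG", 6, 0.25, 25.0),
    ("LPC", 12, 2.5, 250.0),
    ("LPC O-", 4, 2.5, 25.0),
    ("LPE", 8, 0.15, 15.0),
    ("LPE O-", 3, 0.15, 5.0),
    ("LPI", 4, 0.25, 25.0),
    ("LPS", 3, 1.0, 10.0),
    ("LPA", 3, 0.25, 10.0),
    ("SM", 20, 0.4, 1000.0),
    ("Cer", 12, 0.05, 50.0),
    ("HexCer", 6, 1.5, 30.0),
    ("DAG", 10, 0.5, 100.0),
    ("TAG", 26, 1.0, 250.0),
    ("CE", 26, 2.0, 500.0),
    ("Chol", 1, 2400.0, 2400.0),
]

#: Phantom guard (ppm): a fixture species is skipped when any of its
#: isotopologue positions lies this close to the database target of an
#: MS1-only class in the same polarity.  Collisions with fragment-confirmed
#: classes need no phantom guard — the pipeline arbitrates those by MS/MS
#: evidence — but an MS1-only phantom cannot be rejected and would pollute
#: its class's de-isotoping series.
_COLLISION_PPM = 3.0

#: Merge guard (ppm): isotopologue positions of two *different* classes this
#: close coalesce into one centroid during scan averaging (and physically,
#: at the operating resolving power), which no cross-class correction
#: untangles; the fixture keeps such pairs out.  Same-class overlaps stay —
#: they are exactly what type I de-isotoping corrects.
_MERGE_PPM = 7.0


def _class_grid(class_name: str) -> List[Tuple[int, int, int]]:
    """Deterministic, plausibility-ordered (C, DB, OH) candidates per class."""
    out = []
    if class_name in ("SM", "Cer", "HexCer"):
        for c in (34, 36, 38, 40, 42, 33, 35, 41, 43, 44, 32, 37, 39, 45, 46):
            for db in (1, 2, 0, 3, 4):
                out.append((c, db, 2))
    elif class_name == "Chol":
        out.append((0, 0, 0))
    elif class_name == "CE":
        for c in (16, 18, 20, 22, 15, 17, 19, 21, 14, 23, 24, 12, 13, 25, 26):
            for db in (1, 2, 0, 3, 4, 5, 6):
                out.append((c, db, 0))
    elif class_name == "TAG":
        for c in (50, 52, 54, 48, 56, 51, 53, 49, 55, 46, 58, 47, 57, 44, 60):
            for db in (2, 3, 1, 4, 5, 0, 6, 7, 8):
                out.append((c, db, 0))
    elif class_name == "DAG":
        for c in (34, 36, 32, 38, 33, 35, 37, 30, 40):
            for db in (1, 2, 0, 3, 4):
                out.append((c, db, 0))
    elif class_name.startswith("L"):
        for c in (16, 18, 20, 17, 19, 22, 15, 14, 21, 24):
            for db in (0, 1, 2, 3, 4):
                out.append((c, db, 0))
    else:  # diacyl glycerophospholipids
        for c in (34, 36, 38, 32, 40, 33, 35, 37, 31, 39, 30, 42, 41, 44):
            for db in (1, 2, 0, 3, 4, 5, 6):
                out.append((c, db, 0))
    return out


def _two_decompositions(c: int, db: int):
    """Two chain decompositions of a diacyl sum composition with four
    pairwise distinct chains, disjoint between the candidates, whose
    cross-pairings do not re-sum to the composition — the regime in which
    acyl-anion deconvolution recovers the molar fractions exactly (a
    candidate with two identical chains maps both of them onto a single
    anion peak, whose current cannot be attributed per chain)."""
    c1 = c // 2 + 1
    c2 = c - c1
    da, dbx = db - db // 2, db // 2
    d1 = ((c1, da, 0), (c2, dbx, 0))
    d2 = ((c1 + 1, da, 0), (c2 - 1, dbx, 0))
    chains = d1 + d2
    if len(set(chains)) != 4:
        return None
    ok = all(8 <= cc <= 26 and dd <= min(6, cc) for cc, dd, _ in chains)
    return (d1, d2) if ok else None


def _three_decomposition(c: int, db: int):
    c1 = c - 2 * (c // 3)
    c2 = c3 = c // 3
    splits = [db - 2 * (db // 3), db // 3, db // 3]
    chains = tuple(
        (cc, min(dd, 6, cc), 0) for cc, dd in zip((c1, c2, c3), splits)
    )
    if all(8 <= cc <= 26 for cc, _, _ in chains):
        return chains
    return None


def reference_plasma_fixture(
    reg: Optional[Registry] = None,
    n_species: int = 224,
) -> GroundTruth:
    """A synthetic plasma-like ground truth: ``n_species`` species across the
    22 classes, concentrations spanning ~0.05-2500 uM, with molecular-species
    fractions (0.7/0.3 over two disjoint decompositions) for the classes that
    deconvolve.  Entirely synthetic: the composition emulates the breadth and
    per-class magnitudes of pooled human plasma, not any measured sample.

    Species whose isotopologue positions would collide with another class's
    database target (within the collision guard) are skipped, as are sum
    compositions occupied by an internal standard, keeping identification
    unambiguous by construction.
    """
    if reg is None:
        reg = build_default_registry()
    method = default_method_template()
    standards = default_standards()
    db = enumerate_species(reg)

    # per-polarity sorted m/z of MS1-only-class database targets, for the
    # collision guard (fragment-confirmed classes are arbitrated by MS/MS)
    by_pol: Dict[str, List[Tuple[float, str]]] = {"positive": [], "negative": []}
    for e in db:
        if e.class_def.identification_mode == "MS-only":
            by_pol[e.class_def.polarity].append((e.mz, e.annotation.class_name))
    for v in by_pol.values():
        v.sort()

    # sum compositions occupied by unlabeled standards (a labeled standard
    # such as cholesterol-D6 is mass-shifted away from its endogenous twin)
    std_sumcomps = set()
    for std in standards:
        if std.formula_override is not None:
            continue
        ann = std.annotation
        std_sumcomps.add((ann.class_name,
                          ann.total_c, ann.total_db, ann.total_oh))

    def collides(cdef, mz: float) -> bool:
        arr = by_pol[cdef.polarity]
        mzs = [m for m, _ in arr]
        for k in range(0, 4):
            pos = mz + k * NEUTRON_SHIFT
            tol = pos * _COLLISION_PPM * 1e-6
            i = int(np.searchsorted(mzs, pos))
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(arr):
                    m, cls = arr[j]
                    if cls != cdef.class_name and abs(m - pos) <= tol:
                        return True
        return False

    # occupied isotopologue positions of already-chosen species (and of the
    # internal standards, reserved up front), per polarity, with class labels
    taken: Dict[str, List[Tuple[float, str]]] = {"positive": [], "negative": []}

    def occupy(cdef, mz: float) -> None:
        for k in range(0, 4):
            taken[cdef.polarity].append((mz + k * NEUTRON_SHIFT,
                                         cdef.class_name))

    def merges(cdef, mz: float) -> bool:
        for k in range(0, 4):
            pos = mz + k * NEUTRON_SHIFT
            tol = pos * _MERGE_PPM * 1e-6
            for m, cls in taken[cdef.polarity]:
                if cls != cdef.class_name and abs(m - pos) <= tol:
                    return True
        return False

    # reserve every standard's ion, including the optional-LPG one, so the
    # fixture stays valid whether or not that 23rd class is enabled
    reg_std = build_default_registry(include_lpg=True)
    for std in standards:
        if std.class_name in reg_std:
            cdef = reg_std[std.class_name]
            occupy(cdef, adduct_mz(std.neutral_formula(reg_std), cdef.adduct))

    def duplicate_ion(cdef, mz: float) -> bool:
        return any(abs(mz - m) < 5e-4 for m in taken_mz[cdef.polarity])

    chosen: List[GroundTruthSpecies] = []
    for class_name, count, lo, hi in _FIXTURE_PLAN:
        cdef = reg[class_name]
        picked = 0
        for c, dbs, oh in _class_grid(class_name):
            if picked >= count:
                break
            if (class_name, c, dbs, oh) in std_sumcomps:
                continue
            try:
                ann = SpeciesAnnotation(class_name, c, dbs, oh)
                f = species_formula(ann, reg)
            except ValueError:
                continue
            mz = adduct_mz(f, cdef.adduct)
            if segment_for_target(method, cdef, mz) is None:
                continue
            if collides(cdef, mz) or merges(cdef, mz):
                continue
            fractions: Tuple[Tuple[MolecularSpeciesAnnotation, float], ...] = ()
            if cdef.n_chains == 1 and cdef.structural_level == "molecular-species":
                fractions = ((MolecularSpeciesAnnotation(class_name, ((c, dbs, oh),)), 1.0),)
            elif cdef.n_chains == 2 and cdef.structural_level == "molecular-species":
                dec = _two_decompositions(c, dbs)
                if dec is not None:
                    d1, d2 = dec
                    fractions = (
                        (MolecularSpeciesAnnotation(class_name, d1), 0.7),
                        (MolecularSpeciesAnnotation(class_name, d2), 0.3),
                    )
                else:
                    continue
            elif cdef.n_chains == 3:
                dec = _three_decomposition(c, dbs)
                if dec is None:
                    continue
                fractions = ((MolecularSpeciesAnnotation(class_name, dec), 1.0),)
            elif cdef.n_chains == 2 and cdef.fragment_rules:
                continue
            chosen.append(GroundTruthSpecies(ann, 0.0, fractions))
            occupy(cdef, mz)
            picked += 1

    # deterministic trim to exactly n_species: repeatedly drop the
    # last-picked species of the currently most populous class
    if len(chosen) < n_species:
        raise RuntimeError(
            f"fixture produced only {len(chosen)} species (< {n_species})"
        )
    by_class: Dict[str, List[GroundTruthSpecies]] = {}
    for s in chosen:
        by_class.setdefault(s.annotation.class_name, []).append(s)
    n_total = len(chosen)
    while n_total > n_species:
        biggest = max(sorted(by_class), key=lambda k: len(by_class[k]))
        by_class[biggest].pop()
        n_total -= 1

    # concentrations are assigned after the trim, log-spread over each
    # class's span, so the fixture always covers its full dynamic range
    final: List[GroundTruthSpecies] = []
    spans = {cls: (lo, hi) for cls, _, lo, hi in _FIXTURE_PLAN}
    for cls, _, lo, hi in _FIXTURE_PLAN:
        members = by_class.get(cls, [])
        k = len(members)
        for i, s in enumerate(members):
            conc = lo if k == 1 else lo * (hi / lo) ** (i / (k - 1))
            final.append(replace(s, concentration_um=float(conc)))
    return GroundTruth(final, standards=standards)
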