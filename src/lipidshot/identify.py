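"""MS1 matching, DIA window assignment, and MS/MS fragment confirmation.

Matching is tolerance-tiered: 2 ppm where the spectrum was lock-mass
corrected, 8 ppm where the lock was unavailable; MS/MS scans are never
lock-corrected and always use the wide tier.  An MS1 peak may satisfy several
database entries; all co-matching annotations are kept as one ambiguity group
with the nearest flagged primary, and downstream quantification uses the
primary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem_core import ELECTRON_MASS, adduct_mz, monoisotopic_mass
from .lipid_model import (
    ADDUCTS,
    CONFIDENCE,
    DECONVOLUTION,
    IDENTIFICATION,
    MOLECULAR,
    MS_PLUS_MSMS,
    ChainBounds,
    DbEntry,
    MolecularSpeciesAnnotation,
    Registry,
    SpeciesAnnotation,
    acyl_anion_formula,
    candidate_chain_pairs,
)
from .spectra_io import (
    LOCK_APPLIED,
    Ms1Spectrum,
    MsmsScan,
    Peak,
)

__all__ = [
    "ToleranceRule",
    "Identification",
    "FragmentMatch",
    "Confirmation",
    "match_ms1",
    "assign_msms_window",
    "confirm_fragments",
    "fragment_mz_for_chain",
]


def segment_for_target(method, class_def, mz: float):
    """The MS1 segment in which a class's ions are monitored.

    The dedicated narrow positive window is reserved for the sterol ion;
    lyso classes prefer the low-mass negative window; everything else takes
    the first wide window of its polarity that covers the target m/z.
    Returns the :class:`~lipidshot.spectra_io.SegmentDef` or None when the
    target lies outside every eligible window.
    """
    is_sterol = class_def.backbone == "sterol"
    is_lyso = class_def.n_chains == 1 and class_def.backbone == "glycerophospho"
    candidates = []
    for seg in method.ms1_segments():
        if seg.polarity != class_def.polarity:
            continue
        lo, hi = seg.window
        if not (lo <= mz <= hi):
            continue
        narrow = hi - lo < 50
        if narrow != is_sterol:
            continue
        candidates.append(seg)
    if not candidates:
        return None
    if is_lyso:
        candidates.sort(key=lambda s: s.window[0])
    else:
        candidates.sort(key=lambda s: -s.window[0])
    return candidates[0]


@dataclass(frozen=True)
class ToleranceRule:
    """lockmass_status -> ppm tolerance."""

    locked_ppm: float = 2.0
    unlocked_ppm: float = 8.0
    msms_ppm: float = 8.0

    def for_spectrum(self, s: Ms1Spectrum) -> float:
        return self.locked_ppm if s.lockmass_status == LOCK_APPLIED else self.unlocked_ppm


@dataclass
class Identification:
    entry: DbEntry
    peak: Peak
    mass_error_ppm: float
    tolerance_used_ppm: float
    segment: str
    is_primary: bool = True
    ambiguity_group: List["Identification"] = field(default_factory=list)
    mode_satisfied: str = "MS-only"
    confirmation: Optional["Confirmation"] = None

    @property
    def annotation(self) -> SpeciesAnnotation:
        return self.entry.annotation

    @property
    def accepted(self) -> bool:
        return self.mode_satisfied == self.entry.class_def.identification_mode


def match_ms1(
    spectrum: Ms1Spectrum,
    db: Sequence[DbEntry],
    tol_rule: Optional[ToleranceRule] = None,
) -> List[Identification]:
    """Match database entries against an averaged MS1 spectrum.

    Each entry of matching polarity whose target m/z falls in the spectrum
    window is matched to its nearest peak if |error| <= tolerance (inclusive).
    Entries matched to the same peak form a mutual ambiguity group; the
    nearest entry is primary (ties broken toward the lower target m/z for
    determinism).
    """
    if tol_rule is None:
        tol_rule = ToleranceRule()
    tol_ppm = tol_rule.for_spectrum(spectrum)
    mzs = spectrum.mz_array()
    if mzs.size == 0:
        return []
    lo, hi = spectrum.window
    by_peak: Dict[int, List[Identification]] = {}
    for entry in db:
        if entry.class_def.polarity != spectrum.polarity:
            continue
        if not (lo <= entry.mz <= hi):
            continue
        i = int(np.searchsorted(mzs, entry.mz))
        best = None
        for j in (i - 1, i):
            if 0 <= j < mzs.size:
                if best is None or abs(mzs[j] - entry.mz) < abs(mzs[best] - entry.mz):
                    best = j
        err_ppm = (mzs[best] - entry.mz) / entry.mz * 1e6
        # inclusive at the boundary, robust to float representation
        if abs(err_ppm) <= tol_ppm * (1.0 + 1e-9):
            ident = Identification(
                entry=entry,
                peak=spectrum.peaks[best],
                mass_error_ppm=float(err_ppm),
                tolerance_used_ppm=tol_ppm,
                segment=spectrum.segment,
            )
            by_peak.setdefault(best, []).append(ident)
    out: List[Identification] = []
    for idents in by_peak.values():
        idents.sort(key=lambda d: (abs(d.mass_error_ppm), d.entry.mz))
        for k, d in enumerate(idents):
            d.is_primary = k == 0
            d.ambiguity_group = [o for o in idents if o is not d]
        out.extend(idents)
    out.sort(key=lambda d: d.entry.mz)
    return out


def assign_msms_window(
    target_mz: float, scans: Sequence[MsmsScan]
) -> Optional[MsmsScan]:
    """The DIA scan whose half-open isolation interval contains the target.

    Under the default 1 Da grid / 1.0 Da width template this is unique; a
    target on a window boundary is assigned upward (half-open convention).
    Returns None when the target is outside the inclusion-list range.
    """
    for scan in scans:
        if scan.contains_precursor(target_mz):
            return scan
    return None


@dataclass(frozen=True)
class FragmentMatch:
    rule_kind: str
    roles: Tuple[str, ...]
    chain: Optional[Tuple[int, int, int]]
    expected_mz: float
    found_mz: float
    intensity: float
    error_ppm: float


@dataclass
class Confirmation:
    """Outcome of fragment confirmation for one candidate set."""

    scan: MsmsScan
    matches: List[FragmentMatch]
    #: per *complete* candidate molecular species (every chain fragment
    #: observed): the intensity of each of its deconvolution channels, one
    #: value per chain; a chain shared between candidates is attributed to
    #: every candidate listing it
    channels: Dict[MolecularSpeciesAnnotation, List[float]]
    #: True when the class's identification-grade fragment evidence was
    #: found: a complete candidate for chain-resolved classes, any matched
    #: identification-role fragment otherwise
    identified: bool = False

    @property
    def evidence(self) -> float:
        """Summed intensity of the identifying fragment evidence; used to
        arbitrate between co-matching isobaric annotations."""
        if self.channels:
            return float(sum(sum(ch) for ch in self.channels.values()))
        return float(
            sum(m.intensity for m in self.matches if IDENTIFICATION in m.roles)
        )


def fragment_mz_for_chain(
    rule_kind: str,
    chain: Tuple[int, int, int],
    precursor_mz: float,
) -> float:
    """Expected fragment m/z for a chain under a fragment rule.

    acyl-anion: the deprotonated fatty acid RCOO- (negative mode).
    neutral-loss-of-chain: ammoniated precursor losing the fatty acid plus
    ammonia, leaving the diacylglycerol-type cation (positive mode).
    """
    if rule_kind == "acyl-anion":
        anion = acyl_anion_formula(chain)
        return monoisotopic_mass(anion) + ELECTRON_MASS
    if rule_kind == "neutral-loss-of-chain":
        c, db, oh = chain
        fa_mass = monoisotopic_mass(acyl_anion_formula(chain)) + 1.00782503207
        nh3 = 3 * 1.00782503207 + 14.0030740048
        return precursor_mz - fa_mass - nh3
    raise ValueError(f"rule kind {rule_kind} has no per-chain fragment")


def _peak_at(scan: MsmsScan, mz: float, tol_ppm: float) -> Optional[Peak]:
    best = None
    tol = mz * tol_ppm * 1e-6
    for p in scan.peaks:
        d = abs(p.mz - mz)
        if d <= tol and (best is None or d < abs(best.mz - mz)):
            best = p
    return best


def confirm_fragments(
    species: SpeciesAnnotation,
    precursor_mz: float,
    scan: MsmsScan,
    reg: Registry,
    tol_ppm: float = 8.0,
    chain_bounds: Optional[ChainBounds] = None,
    min_intensity: float = 0.0,
    known_candidates: Optional[Sequence[MolecularSpeciesAnnotation]] = None,
) -> Confirmation:
    """Match class fragment rules in the assigned DIA scan.

    For chain-resolved classes the candidate set is every chain decomposition
    of the sum composition within ``chain_bounds`` (or ``known_candidates``
    if given); each candidate's deconvolution-channel intensities are read
    from the scan, with a missing fragment contributing zero.

    A chain-resolved candidate counts only when *all* of its complementary
    chain fragments are present above ``min_intensity``: a single stray
    anion from a co-isolated isobar must not validate (nor enter the
    deconvolution of) a composition it cannot fully explain.  Confirmation
    for the MS-plus-MSMS identification mode therefore requires a complete
    candidate for chain-resolved classes, or any matched identification-role
    fragment otherwise.
    """
    cdef = reg[species.class_name]
    matches: List[FragmentMatch] = []
    channels: Dict[MolecularSpeciesAnnotation, List[float]] = {}
    identified = False

    candidates: List[MolecularSpeciesAnnotation] = []
    probe_chains: List[Tuple[int, int, int]] = []
    if any(r.rule_kind != "fixed-fragment" for r in cdef.fragment_rules):
        if known_candidates is not None:
            candidates = list(known_candidates)
        elif cdef.structural_level == MOLECULAR:
            candidates = candidate_chain_pairs(species, reg, chain_bounds)
        else:
            # species-level classes with chain rules (TAG): probe single
            # chains for confirming losses, never to report chain assignments
            b = chain_bounds or ChainBounds()
            hi_c = min(b.max_c, species.total_c - (cdef.n_chains - 1) * b.min_c)
            for c in range(b.min_c, hi_c + 1):
                for db in range(b.min_db, min(b.max_db, species.total_db, c) + 1):
                    probe_chains.append((c, db, 0))

    for rule in cdef.fragment_rules:
        if rule.rule_kind == "fixed-fragment":
            mz = monoisotopic_mass(rule.fixed_formula) - rule.fixed_charge * ELECTRON_MASS
            p = _peak_at(scan, mz, tol_ppm)
            if p is not None and p.intensity > min_intensity:
                matches.append(
                    FragmentMatch(rule.rule_kind, rule.roles, None, mz, p.mz,
                                  p.intensity, (p.mz - mz) / mz * 1e6)
                )
                if rule.has_role(IDENTIFICATION):
                    identified = True
            continue
        seen_chain_mz: Dict[Tuple[int, int, int], Optional[Peak]] = {}
        for chain in probe_chains:
            mz = fragment_mz_for_chain(rule.rule_kind, chain, precursor_mz)
            p = _peak_at(scan, mz, tol_ppm)
            if p is not None and p.intensity > min_intensity:
                matches.append(
                    FragmentMatch(rule.rule_kind, rule.roles, chain, mz, p.mz,
                                  p.intensity, (p.mz - mz) / mz * 1e6)
                )
                if rule.has_role(IDENTIFICATION):
                    identified = True
        for cand in candidates:
            ch_int: List[float] = []
            complete = True
            for chain in cand.chains:
                if chain not in seen_chain_mz:
                    mz = fragment_mz_for_chain(rule.rule_kind, chain, precursor_mz)
                    seen_chain_mz[chain] = _peak_at(scan, mz, tol_ppm)
                p = seen_chain_mz[chain]
                if p is not None and p.intensity > min_intensity:
                    mz = fragment_mz_for_chain(rule.rule_kind, chain, precursor_mz)
                    matches.append(
                        FragmentMatch(rule.rule_kind, rule.roles, chain, mz,
                                      p.mz, p.intensity,
                                      (p.mz - mz) / mz * 1e6)
                    )
                    ch_int.append(p.intensity)
                else:
                    ch_int.append(0.0)
                    complete = False
            if not complete:
                continue
            if rule.has_role(IDENTIFICATION):
                identified = True
            if rule.has_role(DECONVOLUTION):
                channels[cand] = ch_int
    # dedupe identical fragment matches (same chain may appear in many candidates)
    unique: Dict[Tuple[str, Optional[Tuple[int, int, int]]], FragmentMatch] = {}
    for m in matches:
        unique.setdefault((m.rule_kind, m.chain), m)
    return Confirmation(scan=scan, matches=list(unique.values()),
                        channels=channels, identified=identified)
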