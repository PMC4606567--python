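"""Elemental-formula arithmetic, monoisotopic masses, adduct m/z, isotope envelopes.

This module is the numerical substrate for everything else in the package:
the simulator and the quantification pipeline share one isotope table and one
envelope algorithm, so that predicted and "measured" isotope patterns agree
exactly in closed-loop tests.

Isotope masses and abundances are pinned to the 2021 IUPAC/CIAAW values
(via the NIST Atomic Weights and Isotopic Compositions compilation) and
committed here as constants: identification works at 2 ppm, where even the
electron mass (0.55 mDa) matters, so the constants must be bit-stable across
environments.

The deuterium label ``D`` is treated as its own element with a single isotope
(²H) at abundance 1, which is how isotopically labeled internal standards such
as cholesterol-D6 behave in practice (the label positions do not exchange).
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "NEUTRON_SHIFT",
    "ISOTOPE_TABLE",
    "ElementalFormula",
    "AdductSpec",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_distribution",
    "isotope_pattern",
]

#: Electron rest mass in Da (CODATA 2018).
ELECTRON_MASS = 0.000548579909

#: m/z spacing between successive isotopologue centroids of a carbon-rich ion.
#: For lipids the M+k centroid is dominated by the k x 13C isotopologue, so the
#: 13C-12C mass difference is the practical per-nucleon shift.
NEUTRON_SHIFT = 13.00335483507 - 12.0  # 1.00335483507

# Per element: list of (exact mass Da, abundance fraction), lightest first.
# Abundances sum to 1 per element (asserted at import).
ISOTOPE_TABLE: Dict[str, List[Tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    # D = pure deuterium label (non-exchanging), modeled as monoisotopic.
    "D": [(2.01410177785, 1.0)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317012, 0.00038), (17.9991610, 0.00205)],
    "P": [(30.9737616320, 1.0)],
    "S": [
        (31.9720710015, 0.9499),
        (32.9714587615, 0.0075),
        (33.9678670040, 0.0425),
        (35.9670807620, 0.0001),
    ],
}

for _el, _iso in ISOTOPE_TABLE.items():
    _tot = sum(a for _, a in _iso)
    if abs(_tot - 1.0) > 1e-9:
        raise AssertionError(f"isotope abundances for {_el} sum to {_tot}")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: element symbol -> non-negative count.

    Zero-count elements are never stored.  Supports ``+`` and ``-``;
    subtraction raises if any count would go negative.
    """

    counts: Tuple[Tuple[str, int], ...]

    @staticmethod
    def from_dict(d: Mapping[str, int]) -> "ElementalFormula":
        for el, n in d.items():
            if el not in ISOTOPE_TABLE:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        items = tuple(sorted((el, int(n)) for el, n in d.items() if n > 0))
        return ElementalFormula(items)

    def to_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula.from_dict(d)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise ValueError(
                    f"subtraction yields negative count for {el} "
                    f"({self} - {other})"
                )
        return ElementalFormula.from_dict(d)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def atom_count(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:
        return write_formula(self)


def formula(d: Mapping[str, int]) -> ElementalFormula:
    """Shorthand constructor from a plain dict."""
    return ElementalFormula.from_dict(d)


def parse_formula(text: str) -> ElementalFormula:
    """Parse an element-count string such as ``"C27H40D6O"``.

    Grammar: a sequence of ``Element[count]`` tokens; omitted count means 1.
    Repeated element tokens accumulate.  Raises ``ValueError`` on unknown
    symbols or stray characters.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPE_TABLE:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula.from_dict(counts)


_HILL_ORDER = {"C": 0, "H": 1, "D": 2}


def write_formula(f: ElementalFormula) -> str:
    """Canonical writer: Hill-like order C, H, D, then alphabetical."""

    def key(item: Tuple[str, int]):
        el, _ = item
        return (_HILL_ORDER.get(el, 3), el)

    parts = []
    for el, n in sorted(f.counts, key=key):
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (lightest-isotope) mass of a neutral composition, Da."""
    if not f:
        raise ValueError("empty formula has no mass")
    return sum(ISOTOPE_TABLE[el][0][0] * n for el, n in f.counts)


@dataclass(frozen=True)
class AdductSpec:
    """Ionization rule: a formula delta and a signed unit charge.

    ``delta_sign`` +1 adds the delta formula to the neutral species, -1
    removes it (deprotonation).  All ions handled here are singly charged.
    """

    name: str
    delta_formula: ElementalFormula
    delta_sign: int
    charge: int

    def __post_init__(self):
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")
        if self.delta_sign not in (-1, 1):
            raise ValueError("delta_sign must be +1 or -1")


#: The three adducts the acquisition scheme uses: ammoniated cations for the
#: apolar classes, deprotonated or acetylated anions for the polar classes.
ADDUCTS: Dict[str, AdductSpec] = {
    "plus-NH4": AdductSpec("plus-NH4", formula({"N": 1, "H": 4}), +1, +1),
    "minus-H": AdductSpec("minus-H", formula({"H": 1}), -1, -1),
    "plus-OAc": AdductSpec("plus-OAc", formula({"C": 2, "H": 3, "O": 2}), +1, -1),
}


def adduct_mz(f: ElementalFormula, adduct: AdductSpec) -> float:
    """m/z of the singly charged ion formed from neutral ``f`` by ``adduct``.

    The electron mass is accounted for: a 2 ppm tolerance at m/z 400 is
    0.8 mDa while the electron is 0.55 mDa, so neglecting it would eat most
    of the matching window.
    """
    if adduct.delta_sign > 0:
        ion = f + adduct.delta_formula
    else:
        ion = f - adduct.delta_formula
    m = monoisotopic_mass(ion) - adduct.charge * ELECTRON_MASS
    return m / abs(adduct.charge)


# ---------------------------------------------------------------------------
# Isotope envelopes

def _element_polynomial(el: str, count: int, n_peaks: int) -> Tuple[np.ndarray, np.ndarray]:
    """(abundance, abundance-weighted mass) polynomials on the nucleon-shift
    grid for ``count`` atoms of ``el``, truncated to ``n_peaks`` bins.

    Exponentiation by squaring over truncated convolution; exact to float
    precision for the retained bins because truncation only drops heavier
    bins, which never feed back into lighter ones.
    """
    isotopes = ISOTOPE_TABLE[el]
    base_mass = isotopes[0][0]
    # single-atom polynomial on integer nucleon shifts
    shifts = [int(round(m - base_mass)) for m, _ in isotopes]
    size = max(shifts) + 1
    p = np.zeros(min(size, n_peaks))
    pm = np.zeros_like(p)
    for (m, a), s in zip(isotopes, shifts):
        if s < n_peaks:
            p[s] += a
            pm[s] += a * m
    # accumulate by binary exponentiation
    acc = np.zeros(n_peaks)
    acc_m = np.zeros(n_peaks)
    acc[0] = 1.0
    base_p, base_m = p, pm
    k = count
    while k > 0:
        if k & 1:
            acc, acc_m = _convolve_weighted(acc, acc_m, base_p, base_m, n_peaks)
        k >>= 1
        if k:
            base_p, base_m = _convolve_weighted(base_p, base_m, base_p, base_m, n_peaks)
    return acc, acc_m


def _convolve_weighted(
    pa: np.ndarray, ma: np.ndarray, pb: np.ndarray, mb: np.ndarray, n_peaks: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Convolve two (abundance, abundance*mass) polynomial pairs, truncated."""
    p = np.convolve(pa, pb)[:n_peaks]
    # d(mass-weighted) distributes: (ma*pb + pa*mb)
    m = (np.convolve(ma, pb) + np.convolve(pa, mb))[:n_peaks]
    return p, m


def isotope_distribution(f: ElementalFormula, n_peaks: int = 4) -> np.ndarray:
    """Relative abundances of M+0 ... M+(n_peaks-1), renormalized to sum 1.

    Isotopologues are aggregated on the nucleon-shift index (unit-mass bins),
    which is the granularity of centroided Orbitrap data at R = 140 000: the
    13C2 and 18O isotopologues of a lipid, ~2.4 mDa apart, centroid together.
    For lipid-sized formulas the discarded M+4+ tail is below 0.1%, hence the
    default of four peaks.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    return np.array(_distribution_cached(f.counts, n_peaks))


@functools.lru_cache(maxsize=65536)
def _distribution_cached(counts: Tuple[Tuple[str, int], ...], n_peaks: int
                         ) -> Tuple[float, ...]:
    p = np.zeros(n_peaks)
    p[0] = 1.0
    for el, n in counts:
        q, _ = _element_polynomial(el, n, n_peaks)
        p = np.convolve(p, q)[:n_peaks]
    return tuple(p / p.sum())


def isotope_pattern(
    f: ElementalFormula, n_peaks: int = 4
) -> List[Tuple[float, float]]:
    """(abundance-weighted neutral mass, relative abundance) per M+k bin.

    Bins with zero abundance are reported with mass ``nan``.  Abundances are
    renormalized as in :func:`isotope_distribution`.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    p = np.zeros(n_peaks)
    m = np.zeros(n_peaks)
    p[0] = 1.0
    for el, n in f.counts:
        q, qm = _element_polynomial(el, n, n_peaks)
        p, m = _convolve_weighted(p, m, q, qm, n_peaks)
    total = p.sum()
    out = []
    for k in range(n_peaks):
        if p[k] > 0:
            out.append((m[k] / p[k], p[k] / total))
        else:
            out.append((float("nan"), 0.0))
    return out


def monoisotopic_fraction(f: ElementalFormula, n_peaks: int = 4) -> float:
    """Fraction of the (truncated, renormalized) envelope in the M+0 peak.

    This is the p0 used by the type II de-isotoping correction.
    """
    return float(isotope_distribution(f, n_peaks)[0])
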