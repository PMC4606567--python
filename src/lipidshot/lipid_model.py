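"""Lipid nomenclature, class registry, formula derivation, species enumeration.

The registry covers the 22 quantifiable lipid classes of the direct-infusion
plasma method: glycerophospholipids and their lyso and ether (O-) forms,
sphingolipids (SM, Cer, HexCer), glycerolipids (DAG, TAG), cholesterol and
cholesteryl esters.  Each class carries its ionization adduct, scan polarity,
identification mode (MS1-only vs MS1 plus MS/MS confirmation) and the
structural level that can honestly be reported (sum-composition species vs
chain-resolved molecular species), plus the fragment rules used for MS/MS
confirmation and molecular-species deconvolution.

Shorthand nomenclature follows the common convention::

    CLASS [O-]C:DB[;OH]            sum-composition species, e.g. "PC 34:1"
    CLASS C:DB[;OH]/C:DB[;OH]...   molecular species, e.g. "PC 17:0/17:0"

``;OH`` counts hydroxylations (2 for the usual sphingoid species, as in
"SM 42:1;2"); the ``O-`` prefix marks an ether (plasmanyl/plasmenyl-type)
linkage.  sn-position and double-bond position are never claimed: direct
infusion MS/MS cannot resolve them, so "/" is purely a list separator and
chains are kept in a canonical descending (C, DB) order.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .chem_core import (
    ADDUCTS,
    AdductSpec,
    ElementalFormula,
    adduct_mz,
    formula,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "Chain",
    "SpeciesAnnotation",
    "MolecularSpeciesAnnotation",
    "FragmentRule",
    "LipidClassDef",
    "Registry",
    "InternalStandard",
    "ChainBounds",
    "EnumerationRanges",
    "parse_species_name",
    "write_species_name",
    "species_formula",
    "acyl_anion_formula",
    "build_default_registry",
    "default_standards",
    "default_ranges",
    "enumerate_species",
    "candidate_chain_pairs",
]

# ---------------------------------------------------------------------------
# Annotations

Chain = Tuple[int, int, int]  # (carbons, double bonds, hydroxyls)


@dataclass(frozen=True)
class SpeciesAnnotation:
    """Sum-composition identity: class + total carbons:double-bonds;hydroxyls."""

    class_name: str
    total_c: int
    total_db: int
    total_oh: int = 0

    def __post_init__(self):
        if self.total_db > self.total_c:
            raise ValueError(
                f"{self.class_name} {self.total_c}:{self.total_db}: "
                "more double bonds than carbons"
            )
        if self.total_oh < 0 or self.total_db < 0 or self.total_c < 0:
            raise ValueError("negative composition")

    @property
    def ether(self) -> bool:
        return self.class_name.endswith("O-")

    @property
    def name(self) -> str:
        return write_species_name(self)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class MolecularSpeciesAnnotation:
    """Chain-resolved identity; chains in canonical descending (C, DB) order."""

    class_name: str
    chains: Tuple[Chain, ...]

    def __post_init__(self):
        for c, db, oh in self.chains:
            if db > c or min(c, db, oh) < 0:
                raise ValueError(f"invalid chain {c}:{db};{oh}")
        object.__setattr__(self, "chains", canonical_chain_order(self.chains))

    @property
    def total_c(self) -> int:
        return sum(c for c, _, _ in self.chains)

    @property
    def total_db(self) -> int:
        return sum(db for _, db, _ in self.chains)

    @property
    def total_oh(self) -> int:
        return sum(oh for _, _, oh in self.chains)

    @property
    def ether(self) -> bool:
        return self.class_name.endswith("O-")

    def sum_composition(self) -> SpeciesAnnotation:
        return SpeciesAnnotation(
            self.class_name, self.total_c, self.total_db, self.total_oh
        )

    @property
    def name(self) -> str:
        return write_species_name(self)

    def __str__(self) -> str:
        return self.name


Annotation = Union[SpeciesAnnotation, MolecularSpeciesAnnotation]


def canonical_chain_order(chains: Sequence[Chain]) -> Tuple[Chain, ...]:
    """Descending (OH, C, DB): the hydroxylated long-chain base leads, then
    longer and more unsaturated chains.  Matches the usual shorthand where
    the sphingoid base is written first (e.g. SM 18:1;2/12:0)."""
    return tuple(sorted(chains, key=lambda ch: (-ch[2], -ch[0], -ch[1])))


# ---------------------------------------------------------------------------
# Name grammar

_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z][A-Za-z0-9]*)"
    r"(?:\s+(?P<ether>O-)?(?P<body>\d[\d:;/]*))?\s*$"
)
_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;(\d+))?$")


def parse_species_name(text: str) -> Annotation:
    """Parse a shorthand lipid name.

    Chain-separated names ("PC 17:0/17:0") yield a
    :class:`MolecularSpeciesAnnotation`; sum-only names ("PC 34:1") a
    :class:`SpeciesAnnotation`.  Chain-less classes ("Chol") parse as a
    species with zero totals.
    """
    m = _NAME_RE.match(text)
    if not m:
        raise ValueError(f"malformed lipid name: {text!r}")
    cls = m.group("cls")
    if m.group("ether"):
        cls = cls + " O-"
    body = m.group("body")
    if body is None:
        return SpeciesAnnotation(cls, 0, 0, 0)
    parts = body.split("/")
    chains: List[Chain] = []
    for part in parts:
        cm = _CHAIN_RE.match(part)
        if not cm:
            raise ValueError(f"malformed chain token {part!r} in {text!r}")
        c, db = int(cm.group(1)), int(cm.group(2))
        oh = int(cm.group(3)) if cm.group(3) else 0
        chains.append((c, db, oh))
    if len(parts) == 1:
        c, db, oh = chains[0]
        return SpeciesAnnotation(cls, c, db, oh)
    return MolecularSpeciesAnnotation(cls, tuple(chains))


def _chain_token(ch: Chain) -> str:
    c, db, oh = ch
    return f"{c}:{db}" + (f";{oh}" if oh else "")


def write_species_name(a: Annotation) -> str:
    """Canonical writer; inverse of :func:`parse_species_name`."""
    if isinstance(a, MolecularSpeciesAnnotation):
        body = "/".join(_chain_token(ch) for ch in a.chains)
    else:
        if a.total_c == 0 and a.total_db == 0 and a.total_oh == 0:
            return a.class_name
        body = _chain_token((a.total_c, a.total_db, a.total_oh))
    if a.class_name.endswith(" O-"):
        return f"{a.class_name[:-3]} O-{body}"
    return f"{a.class_name} {body}"


# ---------------------------------------------------------------------------
# Fragment rules

IDENTIFICATION = "identification"
DECONVOLUTION = "deconvolution-channel"
CONFIDENCE = "confidence-only"


@dataclass(frozen=True)
class FragmentRule:
    """How a class fragments in DIA MS/MS and what the fragment is used for.

    rule_kind:
      * ``acyl-anion``          deprotonated fatty-acid fragment (RCOO-) per chain
      * ``neutral-loss-of-chain`` precursor minus (fatty acid + NH3), per chain
      * ``fixed-fragment``      a fixed product ion (e.g. the sterol cation)

    roles: which of identification / deconvolution-channel / confidence-only
    the matched fragment serves.  A deconvolution channel is ipso facto
    identifying (its presence proves the chain), so classes deconvolved from
    acyl anions list both roles on one rule.
    """

    rule_kind: str
    polarity: str
    roles: Tuple[str, ...]
    fixed_formula: Optional[ElementalFormula] = None
    fixed_charge: int = 0

    def has_role(self, role: str) -> bool:
        return role in self.roles


def acyl_anion_formula(chain: Chain) -> ElementalFormula:
    """Neutral-composition formula of the acyl anion RCOO- of a chain.

    A fatty acid C:DB;OH is C_c H_{2c-2d} O_{2+oh}; the anion has one H less.
    The ion m/z adds back the electron mass (handled by the caller through
    the minus-H adduct convention).
    """
    c, db, oh = chain
    h = 2 * c - 1 - 2 * db
    if h < 0 or c < 1:
        raise ValueError(f"chain {chain} has no acyl anion")
    return formula({"C": c, "H": h, "O": 2 + oh})


# ---------------------------------------------------------------------------
# Class definitions and formula rules

MS_ONLY = "MS-only"
MS_PLUS_MSMS = "MS-plus-MSMS"
SPECIES = "species"
MOLECULAR = "molecular-species"


@dataclass(frozen=True)
class LipidClassDef:
    class_name: str
    polarity: str  # "positive" | "negative"
    adduct: AdductSpec
    identification_mode: str  # MS_ONLY | MS_PLUS_MSMS
    structural_level: str  # SPECIES | MOLECULAR
    n_chains: int  # 0 sterol, 1 lyso/CE, 2 diacyl & sphingo, 3 TAG
    backbone: str  # "glycerophospho" | "glycerol" | "sterol" | "sterol-ester" | "sphingoid"
    base_formula: Optional[ElementalFormula] = None  # backbone incl. head group
    head_formula: Optional[ElementalFormula] = None  # sphingoid head addition
    fragment_rules: Tuple[FragmentRule, ...] = ()

    def __post_init__(self):
        for r in self.fragment_rules:
            if r.has_role(DECONVOLUTION) and self.structural_level != MOLECULAR:
                raise ValueError(
                    f"{self.class_name}: deconvolution channel on a "
                    "species-level class"
                )


# Backbone compositions (fully hydroxylated, before esterification).
_GLYCEROL = parse_formula("C3H8O3")
_GPA = parse_formula("C3H9O6P")  # glycerophosphate
_GPC = parse_formula("C8H20NO6P")  # glycerophosphocholine
_GPE = parse_formula("C5H14NO6P")  # glycerophosphoethanolamine
_GPG = parse_formula("C6H15O8P")  # glycerophosphoglycerol
_GPI = parse_formula("C9H19O11P")  # glycerophosphoinositol
_GPS = parse_formula("C6H14NO8P")  # glycerophosphoserine
_CHOLESTEROL = parse_formula("C27H46O")
_SM_HEAD = parse_formula("C5H12NO3P")  # phosphocholine (condensed)
_HEX_HEAD = parse_formula("C6H10O5")  # hexose (condensed)
_STEROL_CATION = parse_formula("C27H45")  # cholestadienyl fragment ion


def species_formula(a: Annotation, reg: "Registry") -> ElementalFormula:
    """Neutral elemental formula of a species or molecular species.

    A molecular species and its sum composition map to the identical formula
    (positional isomers are isobaric), so the rule only needs totals plus the
    ether flag.
    """
    cdef = reg[a.class_name]
    if isinstance(a, MolecularSpeciesAnnotation):
        if len(a.chains) != cdef.n_chains:
            raise ValueError(
                f"{a.name}: {len(a.chains)} chains but class "
                f"{cdef.class_name} has {cdef.n_chains}"
            )
    c, db, oh = a.total_c, a.total_db, a.total_oh
    bb = cdef.backbone
    if bb == "sterol":
        if c or db or oh:
            raise ValueError(f"{cdef.class_name} takes no chain composition")
        return _CHOLESTEROL
    if bb == "sphingoid":
        # long-chain base + N-acyl, expressed on totals: C_c H_{2c+1-2db} N O_{1+oh}
        h = 2 * c + 1 - 2 * db
        f = formula({"C": c, "H": h, "N": 1, "O": 1 + oh})
        if cdef.head_formula is not None:
            f = f + cdef.head_formula
        return f
    # ester backbones: each esterified chain adds C_c H_{2c-2-2d} O (+O per OH);
    # an ether linkage adds C_c H_{2c-2d} instead (i.e. + H2 - O vs the ester).
    if c <= 0:
        raise ValueError(f"{a.name}: chain carbons required for {cdef.class_name}")
    n = cdef.n_chains
    h = 2 * c - 2 * n - 2 * db
    f = cdef.base_formula + formula({"C": c, "H": h, "O": n + oh})
    if a.ether:
        f = (f + formula({"H": 2})) - formula({"O": 1})
    return f


# ---------------------------------------------------------------------------
# Registry

class Registry:
    """Mapping of class name -> LipidClassDef with normalized lookup."""

    def __init__(self, classes: Iterable[LipidClassDef]):
        self._classes: Dict[str, LipidClassDef] = {}
        for c in classes:
            key = self._norm(c.class_name)
            if key in self._classes:
                raise ValueError(f"duplicate class {c.class_name}")
            self._classes[key] = c

    @staticmethod
    def _norm(name: str) -> str:
        return re.sub(r"\s+", " ", name.strip()).upper()

    def __getitem__(self, name: str) -> LipidClassDef:
        key = self._norm(name)
        if key not in self._classes:
            raise KeyError(f"unknown lipid class {name!r}")
        return self._classes[key]

    def __contains__(self, name: str) -> bool:
        return self._norm(name) in self._classes

    def __iter__(self):
        return iter(self._classes.values())

    def __len__(self) -> int:
        return len(self._classes)

    def class_names(self) -> List[str]:
        return [c.class_name for c in self]


def _acyl_rules(polarity: str, deconv: bool) -> Tuple[FragmentRule, ...]:
    roles = (IDENTIFICATION, DECONVOLUTION) if deconv else (IDENTIFICATION,)
    return (FragmentRule("acyl-anion", polarity, roles),)


def build_default_registry(include_lpg: bool = False) -> Registry:
    """The default 22-class registry of the plasma method.

    Negative-mode glycerophospholipid classes that fragment efficiently are
    confirmed and deconvolved from their acyl anions; DAG uses positive-mode
    chain neutral losses; TAG chain losses only raise confidence (three-chain
    combinatorics defeat molecular assignment without separation); sphingoid
    and ether classes are identified on precursor mass alone.  Cholesterol is
    kept at species level: a sterol has no chains to resolve.

    ``include_lpg`` adds LPG as an optional 23rd class (an internal standard
    for it exists even though it is not part of the default panel).
    """
    nl_pos_id = (FragmentRule("neutral-loss-of-chain", "positive", (IDENTIFICATION,)),)
    nl_pos_deconv = (
        FragmentRule(
            "neutral-loss-of-chain", "positive", (IDENTIFICATION, DECONVOLUTION)
        ),
    )
    sterol_frag = (
        FragmentRule(
            "fixed-fragment",
            "positive",
            (IDENTIFICATION,),
            fixed_formula=_STEROL_CATION,
            fixed_charge=+1,
        ),
    )
    acyl_neg = _acyl_rules("negative", deconv=True)
    acyl_neg_conf = (FragmentRule("acyl-anion", "negative", (CONFIDENCE,)),)

    oac = ADDUCTS["plus-OAc"]
    mh = ADDUCTS["minus-H"]
    nh4 = ADDUCTS["plus-NH4"]

    defs = [
        LipidClassDef("Cer", "negative", oac, MS_ONLY, SPECIES, 2, "sphingoid"),
        LipidClassDef("Chol", "positive", nh4, MS_ONLY, SPECIES, 0, "sterol"),
        LipidClassDef(
            "DAG", "positive", nh4, MS_PLUS_MSMS, MOLECULAR, 2, "glycerol",
            base_formula=_GLYCEROL, fragment_rules=nl_pos_deconv,
        ),
        LipidClassDef(
            "HexCer", "negative", oac, MS_ONLY, SPECIES, 2, "sphingoid",
            head_formula=_HEX_HEAD,
        ),
        LipidClassDef(
            "LPA", "negative", mh, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPA, fragment_rules=acyl_neg_conf,
        ),
        LipidClassDef(
            "LPC", "negative", oac, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPC, fragment_rules=acyl_neg_conf,
        ),
        LipidClassDef(
            "LPC O-", "negative", oac, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPC,
        ),
        LipidClassDef(
            "LPE", "negative", mh, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPE, fragment_rules=acyl_neg_conf,
        ),
        LipidClassDef(
            "LPE O-", "negative", mh, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPE,
        ),
        LipidClassDef(
            "LPI", "negative", mh, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPI, fragment_rules=acyl_neg_conf,
        ),
        LipidClassDef(
            "LPS", "negative", mh, MS_ONLY, MOLECULAR, 1, "glycerophospho",
            base_formula=_GPS, fragment_rules=acyl_neg_conf,
        ),
        LipidClassDef(
            "PA", "negative", mh, MS_PLUS_MSMS, MOLECULAR, 2, "glycerophospho",
            base_formula=_GPA, fragment_rules=acyl_neg,
        ),
        LipidClassDef(
            "PC", "negative", oac, MS_PLUS_MSMS, MOLECULAR, 2, "glycerophospho",
            base_formula=_GPC, fragment_rules=acyl_neg,
        ),
        LipidClassDef(
            "PC O-", "negative", oac, MS_ONLY, SPECIES, 2, "glycerophospho",
            base_formula=_GPC,
        ),
        LipidClassDef(
            "PE", "negative", mh, MS_PLUS_MSMS, MOLECULAR, 2, "glycerophospho",
            base_formula=_GPE, fragment_rules=acyl_neg,
        ),
        LipidClassDef(
            "PE O-", "negative", mh, MS_ONLY, SPECIES, 2, "glycerophospho",
            base_formula=_GPE,
        ),
        LipidClassDef(
            "PG", "negative", mh, MS_PLUS_MSMS, MOLECULAR, 2, "glycerophospho",
            base_formula=_GPG, fragment_rules=acyl_neg,
        ),
        LipidClassDef(
            "PI", "negative", mh, MS_PLUS_MSMS, MOLECULAR, 2, "glycerophospho",
            base_formula=_GPI, fragment_rules=acyl_neg,
        ),
        LipidClassDef(
            "PS", "negative", mh, MS_PLUS_MSMS, MOLECULAR, 2, "glycerophospho",
            base_formula=_GPS, fragment_rules=acyl_neg,
        ),
        LipidClassDef(
            "CE", "positive", nh4, MS_PLUS_MSMS, MOLECULAR, 1, "sterol-ester",
            base_formula=_CHOLESTEROL, fragment_rules=sterol_frag,
        ),
        LipidClassDef("SM", "negative", oac, MS_ONLY, SPECIES, 2, "sphingoid",
                      head_formula=_SM_HEAD),
        LipidClassDef(
            "TAG", "positive", nh4, MS_PLUS_MSMS, SPECIES, 3, "glycerol",
            base_formula=_GLYCEROL, fragment_rules=nl_pos_id,
        ),
    ]
    if include_lpg:
        defs.append(
            LipidClassDef(
                "LPG", "negative", mh, MS_ONLY, MOLECULAR, 1, "glycerophospho",
                base_formula=_GPG, fragment_rules=acyl_neg_conf,
            )
        )
    return Registry(defs)


# ---------------------------------------------------------------------------
# Internal standards

@dataclass(frozen=True)
class InternalStandard:
    """A per-class spiked species of known amount (pmol per 1 uL plasma).

    ``formula_override`` handles isotopically labeled standards whose formula
    is not derivable from the shorthand name (cholesterol-D6).
    """

    annotation: Annotation
    amount_pmol: float
    formula_override: Optional[ElementalFormula] = None
    label: Optional[str] = None

    def __post_init__(self):
        if self.amount_pmol <= 0:
            raise ValueError("standard amount must be positive")

    @property
    def class_name(self) -> str:
        return self.annotation.class_name

    @property
    def name(self) -> str:
        return self.label or self.annotation.name

    def neutral_formula(self, reg: Registry) -> ElementalFormula:
        if self.formula_override is not None:
            return self.formula_override
        return species_formula(self.annotation, reg)


def default_standards() -> List[InternalStandard]:
    """The 19-component internal standard mixture, pmol per 1 uL plasma.

    One synthetic, plasma-absent species per quantifiable class; odd-carbon
    or short chains keep them clear of endogenous peaks, and the cholesterol
    standard is deuterated (D6) since unlabeled cholesterol is endogenous.
    """
    def std(name: str, pmol: float, override: str | None = None,
            label: str | None = None) -> InternalStandard:
        return InternalStandard(
            parse_species_name(name),
            pmol,
            parse_formula(override) if override else None,
            label,
        )

    return [
        std("LPG 17:1", 50),
        std("LPA 17:0", 50),
        std("PC 17:0/17:0", 500),
        std("HexCer 18:1;2/12:0", 30),
        std("PS 17:0/17:0", 50),
        std("PG 17:0/17:0", 50),
        std("PA 17:0/17:0", 50),
        std("LPI 17:1", 50),
        std("LPS 17:1", 50),
        std("Chol", 1000, override="C27H40D6O", label="Chol D6"),
        std("DAG 17:0/17:0", 100),
        std("TAG 17:0/17:0/17:0", 50),
        std("Cer 18:1;2/17:0", 50),
        std("SM 18:1;2/12:0", 200),
        std("LPC 12:0", 50),
        std("LPE 17:1", 30),
        std("PE 17:0/17:0", 50),
        std("CE 20:0", 100),
        std("PI 16:0/16:0", 50),
    ]


#: Ether classes are quantified against the standard of their diacyl
#: counterpart (they share the head group, hence the response factor).
STANDARD_CLASS_ALIASES: Dict[str, str] = {
    "PC O-": "PC",
    "PE O-": "PE",
    "LPC O-": "LPC",
    "LPE O-": "LPE",
}


def standard_for_class(
    class_name: str, standards: Sequence[InternalStandard]
) -> Optional[InternalStandard]:
    """The standard quantifying ``class_name`` (ether classes borrow their
    diacyl counterpart's standard); None if the class has no standard."""
    target = STANDARD_CLASS_ALIASES.get(class_name, class_name)
    norm = Registry._norm
    for s in standards:
        if norm(s.class_name) == norm(target):
            return s
    return None


# ---------------------------------------------------------------------------
# Enumeration

@dataclass(frozen=True)
class ClassRanges:
    min_c: int
    max_c: int
    min_db: int
    max_db: int
    oh_values: Tuple[int, ...] = (0,)


EnumerationRanges = Dict[str, ClassRanges]


def default_ranges() -> EnumerationRanges:
    """Default composition grid per class, covering the breadth of the plasma
    lipidome while keeping the database compact.  Odd and even carbon numbers
    are both enumerated (the internal standards are odd-chain)."""
    diacyl = ClassRanges(26, 44, 0, 10)
    lyso = ClassRanges(14, 24, 0, 6)
    sphingo = ClassRanges(26, 48, 0, 4, oh_values=(2,))
    r: EnumerationRanges = {
        "PA": diacyl, "PC": diacyl, "PE": diacyl, "PG": diacyl,
        "PI": diacyl, "PS": diacyl, "PC O-": diacyl, "PE O-": diacyl,
        "LPA": lyso, "LPC": lyso, "LPC O-": lyso, "LPE": lyso,
        "LPE O-": lyso, "LPI": lyso, "LPS": lyso,
        "SM": sphingo, "Cer": sphingo, "HexCer": sphingo,
        "CE": ClassRanges(10, 26, 0, 8),
        "DAG": ClassRanges(24, 40, 0, 10),
        "TAG": ClassRanges(36, 60, 0, 12),
        "Chol": ClassRanges(0, 0, 0, 0),
    }
    return r


@dataclass(frozen=True)
class DbEntry:
    annotation: SpeciesAnnotation
    formula: ElementalFormula
    mz: float
    class_def: LipidClassDef


def enumerate_species(
    reg: Registry, ranges: Optional[EnumerationRanges] = None
) -> List[DbEntry]:
    """Enumerate the target database: one entry per (class, C, DB, OH) cell,
    deterministic and duplicate-free, sorted by (class, m/z)."""
    if ranges is None:
        ranges = default_ranges()
    entries: List[DbEntry] = []
    for cdef in reg:
        rr = ranges.get(cdef.class_name)
        if rr is None:
            continue
        if rr.min_c > rr.max_c or rr.min_db > rr.max_db:
            raise ValueError(f"invalid ranges for {cdef.class_name}")
        if cdef.backbone == "sterol":
            ann = SpeciesAnnotation(cdef.class_name, 0, 0, 0)
            f = species_formula(ann, reg)
            entries.append(DbEntry(ann, f, adduct_mz(f, cdef.adduct), cdef))
            continue
        for c in range(rr.min_c, rr.max_c + 1):
            for db in range(rr.min_db, rr.max_db + 1):
                for oh in rr.oh_values:
                    try:
                        ann = SpeciesAnnotation(cdef.class_name, c, db, oh)
                        f = species_formula(ann, reg)
                    except ValueError:
                        continue
                    entries.append(
                        DbEntry(ann, f, adduct_mz(f, cdef.adduct), cdef)
                    )
    entries.sort(key=lambda e: (e.annotation.class_name, e.mz))
    return entries


@dataclass(frozen=True)
class ChainBounds:
    min_c: int = 8
    max_c: int = 26
    min_db: int = 0
    max_db: int = 6


def candidate_chain_pairs(
    s: SpeciesAnnotation, reg: Registry, bounds: Optional[ChainBounds] = None
) -> List[MolecularSpeciesAnnotation]:
    """All chain decompositions of a sum composition within per-chain bounds.

    Unordered combinations of ``n_chains`` chains whose (C, DB, OH) totals
    equal the species totals; used as the candidate set for MS/MS
    deconvolution.  Only defined for molecular-species-level classes.
    """
    cdef = reg[s.class_name]
    if cdef.structural_level != MOLECULAR:
        raise ValueError(f"{cdef.class_name} is reported at species level")
    if bounds is None:
        bounds = ChainBounds()
    n = cdef.n_chains
    out: List[MolecularSpeciesAnnotation] = []
    seen = set()
    c_range = range(bounds.min_c, bounds.max_c + 1)
    db_range = range(bounds.min_db, bounds.max_db + 1)
    oh_opts = range(0, s.total_oh + 1)

    def rec(idx: int, prev: Chain, rem_c: int, rem_db: int, rem_oh: int,
            acc: List[Chain]):
        if idx == n - 1:
            last = (rem_c, rem_db, rem_oh)
            if (
                bounds.min_c <= rem_c <= bounds.max_c
                and bounds.min_db <= rem_db <= bounds.max_db
                and rem_db <= rem_c
            ):
                chains = canonical_chain_order(acc + [last])
                if chains not in seen:
                    seen.add(chains)
                    out.append(MolecularSpeciesAnnotation(s.class_name, chains))
            return
        for c in c_range:
            if c > rem_c:
                break
            for db in db_range:
                if db > rem_db or db > c:
                    continue
                for oh in oh_opts:
                    if oh > rem_oh:
                        continue
                    rec(idx + 1, (c, db, oh), rem_c - c, rem_db - db,
                        rem_oh - oh, acc + [(c, db, oh)])

    rec(0, (0, 0, 0), s.total_c, s.total_db, s.total_oh, [])
    out.sort(key=lambda m: m.chains)
    return out
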