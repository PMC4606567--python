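"""YAML configuration: standards, registry overrides, ground truth, noise.

Configs override the built-in defaults rather than replace them: a
standards file lists the spiked species and amounts; a registry file tweaks
per-class acquisition fields (adduct, polarity, identification mode,
reporting level) of the default panel; ground-truth and noise files
serialize simulator inputs for reproducible scenario definitions.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Union

import yaml

from .lipid_model import (
    ADDUCTS,
    InternalStandard,
    MolecularSpeciesAnnotation,
    Registry,
    build_default_registry,
    parse_formula,
    parse_species_name,
)
from .simulate import GroundTruth, GroundTruthSpecies, NoiseModel

__all__ = [
    "load_standards",
    "load_registry",
    "load_ground_truth",
    "save_ground_truth",
    "load_noise_model",
]


def _load(source) -> object:
    if isinstance(source, (dict, list)):
        return source
    with open(source, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_standards(source) -> List[InternalStandard]:
    """Standards from a YAML list of ``{name, pmol, formula?, label?}``."""
    data = _load(source)
    out = []
    for item in data:
        out.append(
            InternalStandard(
                annotation=parse_species_name(item["name"]),
                amount_pmol=float(item["pmol"]),
                formula_override=(
                    parse_formula(item["formula"]) if item.get("formula") else None
                ),
                label=item.get("label"),
            )
        )
    return out


def load_registry(source, base: Optional[Registry] = None) -> Registry:
    """Registry with per-class overrides from a YAML mapping
    ``class -> {adduct?, polarity?, identification_mode?, structural_level?}``.

    Unlisted classes keep their defaults; ``include_lpg: true`` at the top
    level enables the optional 23rd class before overrides apply.
    """
    data = dict(_load(source) or {})
    include_lpg = bool(data.pop("include_lpg", False))
    if base is None:
        base = build_default_registry(include_lpg=include_lpg)
    defs = []
    for cdef in base:
        override = None
        for key, val in data.items():
            if Registry._norm(key) == Registry._norm(cdef.class_name):
                override = val
                break
        if override:
            kwargs = {}
            if "adduct" in override:
                kwargs["adduct"] = ADDUCTS[override["adduct"]]
            for field in ("polarity", "identification_mode", "structural_level"):
                if field in override:
                    kwargs[field] = override[field]
            cdef = replace(cdef, **kwargs)
        defs.append(cdef)
    return Registry(defs)


def load_ground_truth(source) -> GroundTruth:
    """Ground truth from YAML: ``species`` (name, concentration_um, optional
    fractions as ``{name: fraction}``), optional ``standards``,
    ``plasma_ul``, ``anticoagulant``."""
    data = _load(source)
    species = []
    for item in data["species"]:
        fractions = tuple(
            (parse_species_name(n), float(f))
            for n, f in (item.get("fractions") or {}).items()
        )
        species.append(
            GroundTruthSpecies(
                parse_species_name(item["name"]),
                float(item["concentration_um"]),
                fractions,
            )
        )
    kwargs = {}
    if "standards" in data:
        kwargs["standards"] = load_standards(data["standards"])
    return GroundTruth(
        species,
        plasma_ul=float(data.get("plasma_ul", 1.0)),
        anticoagulant=data.get("anticoagulant", "edta"),
        **kwargs,
    )


def save_ground_truth(gt: GroundTruth, path) -> None:
    doc = {
        "plasma_ul": gt.plasma_ul,
        "anticoagulant": gt.anticoagulant,
        "species": [
            {
                "name": s.annotation.name,
                "concentration_um": s.concentration_um,
                **(
                    {"fractions": {m.name: f for m, f in s.fractions}}
                    if s.fractions
                    else {}
                ),
            }
            for s in gt.species
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_noise_model(source) -> NoiseModel:
    data = dict(_load(source) or {})
    return NoiseModel(**data)
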