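"""Platform assessment statistics.

Coefficient-of-variation quartile reports over replicate concentration
tables, log-log dose-response fits with a limit-of-quantification rule,
Pearson correlation of lipidomes on the log scale, and class / double-bond
composition profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .lipid_model import parse_species_name
from .quantify import QuantifiedLipidome

__all__ = [
    "ReplicateTable",
    "QuartileRow",
    "QuartileReport",
    "DoseResponse",
    "cv_percent",
    "quartile_cv_report",
    "dose_response_fit",
    "loq_estimate",
    "pearson_log",
    "class_profile",
    "double_bond_profile",
]


@dataclass
class ReplicateTable:
    """species x replicate matrix of concentrations (uM) with group labels."""

    values: pd.DataFrame  # index: species names, columns: replicate ids
    groups: Optional[pd.Series] = None  # replicate id -> group label

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("negative concentrations in replicate table")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 replicates")

    @staticmethod
    def from_lipidomes(
        lipidomes: Sequence[QuantifiedLipidome],
        groups: Optional[Sequence[str]] = None,
    ) -> "ReplicateTable":
        """Assemble a table over the species common to every lipidome."""
        frames = {}
        for i, l in enumerate(lipidomes):
            col = f"{l.sample_id}:{i}"
            frames[col] = {
                s.annotation.name: s.concentration_um
                for s in l.species
                if not s.is_standard
            }
        df = pd.DataFrame(frames).dropna(axis=0, how="any")
        if df.empty:
            raise ValueError("no species shared across all lipidomes")
        g = pd.Series(list(groups), index=df.columns) if groups is not None else None
        return ReplicateTable(df, g)


def cv_percent(values: Sequence[float]) -> float:
    """Sample coefficient of variation, percent: sd(n-1)/mean x 100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean * 100.0)


@dataclass
class QuartileRow:
    quartile: int  # 1 = most abundant
    conc_range_um: Tuple[float, float]
    n_species: int
    coverage_mol_percent: float
    mean_cv_percent: float
    cv_sd_across_groups: Optional[float] = None
    per_group_cv: Optional[Dict[str, float]] = None


@dataclass
class QuartileReport:
    rows: List[QuartileRow]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quartile": r.quartile,
                "conc_lo_uM": r.conc_range_um[0],
                "conc_hi_uM": r.conc_range_um[1],
                "n_species": r.n_species,
                "coverage_mol_percent": r.coverage_mol_percent,
                "mean_cv_percent": r.mean_cv_percent,
                "cv_sd_across_groups": r.cv_sd_across_groups,
            }
            for r in self.rows
        )


def quartile_cv_report(table: ReplicateTable) -> QuartileReport:
    """Abundance-quartile CV analysis of a replicate table.

    Species are sorted by mean concentration descending (ties broken by
    name), split into four equal-count groups (remainder going to the most
    abundant quartiles), and the per-species CVs are averaged within each
    quartile.  Coverage is each quartile's share of the summed mean
    concentration (mol%).  When group labels are present the mean CV is also
    computed within each group and the across-group sd reported.
    """
    df = table.values
    if df.shape[0] < 4:
        raise ValueError("need at least 4 species for quartiles")
    means = df.mean(axis=1)
    order = sorted(df.index, key=lambda name: (-means[name], name))
    quartiles = np.array_split(np.array(order, dtype=object), 4)
    grand = means.sum()
    rows: List[QuartileRow] = []
    for qi, names in enumerate(quartiles, start=1):
        names = list(names)
        sub = df.loc[names]
        cvs = sub.apply(lambda r: cv_percent(r.values), axis=1)
        per_group = None
        sd_across = None
        if table.groups is not None:
            per_group = {}
            for g, cols in table.groups.groupby(table.groups).groups.items():
                gsub = sub[list(cols)]
                if gsub.shape[1] >= 2:
                    per_group[g] = float(
                        gsub.apply(lambda r: cv_percent(r.values), axis=1).mean()
                    )
            if len(per_group) >= 2:
                sd_across = float(np.std(list(per_group.values()), ddof=1))
        qmeans = means[names]
        rows.append(
            QuartileRow(
                quartile=qi,
                conc_range_um=(float(qmeans.min()), float(qmeans.max())),
                n_species=len(names),
                coverage_mol_percent=float(qmeans.sum() / grand * 100.0),
                mean_cv_percent=float(cvs.mean()),
                cv_sd_across_groups=sd_across,
                per_group_cv=per_group,
            )
        )
    return QuartileReport(rows)


@dataclass
class DoseResponse:
    """Replicate measurements at each spiked concentration (uM)."""

    spiked_um: List[float]
    measured: List[List[float]]  # per level: replicate values

    def __post_init__(self):
        if any(c <= 0 for c in self.spiked_um):
            raise ValueError("spiked concentrations must be positive")
        if sorted(self.spiked_um) != list(self.spiked_um):
            raise ValueError("spiked concentrations must be sorted ascending")
        if len(self.measured) != len(self.spiked_um):
            raise ValueError("one measurement list per level required")

    def level_means(self) -> np.ndarray:
        return np.array([np.mean(v) for v in self.measured])


def dose_response_fit(
    d: DoseResponse, restrict_from_level: int = 0
) -> Tuple[float, float]:
    """Least-squares line on log10(measured mean) vs log10(spiked).

    Returns (slope, r^2).  A proportional response gives slope 1 with the
    scale factor absorbed by the intercept.
    """
    x = np.log10(np.asarray(d.spiked_um[restrict_from_level:], dtype=float))
    y_lin = d.level_means()[restrict_from_level:]
    if x.size < 3:
        raise ValueError("need at least 3 concentrations")
    if (y_lin <= 0).any():
        raise ValueError("non-positive measured values in log domain")
    y = np.log10(y_lin)
    res = _stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def loq_estimate(
    d: DoseResponse,
    cv_threshold_percent: float = 20.0,
    slope_band: Tuple[float, float] = (0.9, 1.1),
) -> Optional[float]:
    """Limit of quantification from a dilution series.

    The smallest spiked concentration c such that (a) the replicate CV at
    every level >= c stays below ``cv_threshold_percent`` and (b) the log-log
    fit restricted to levels >= c has slope within ``slope_band``.  Returns
    None when no level qualifies (reported as above-range).
    """
    n = len(d.spiked_um)
    cvs = [cv_percent(v) if len(v) >= 2 else 0.0 for v in d.measured]
    for start in range(0, n - 2):
        if any(cv >= cv_threshold_percent for cv in cvs[start:]):
            continue
        slope, _ = dose_response_fit(d, restrict_from_level=start)
        if slope_band[0] <= slope <= slope_band[1]:
            return float(d.spiked_um[start])
    return None


def pearson_log(
    a: Dict[str, float], b: Dict[str, float], warn_on_mismatch: bool = True
) -> float:
    """Pearson r of two lipidomes on log10 concentrations of shared species.

    Concentrations span several orders of magnitude, so the log scale keeps
    the correlation from being driven entirely by the most abundant species.
    """
    import warnings

    shared = sorted(set(a) & set(b))
    if warn_on_mismatch and (len(shared) < len(a) or len(shared) < len(b)):
        warnings.warn(
            f"species sets differ; correlating {len(shared)} shared species"
        )
    if len(shared) < 3:
        raise ValueError("need at least 3 shared species")
    xs = np.log10([a[k] for k in shared])
    ys = np.log10([b[k] for k in shared])
    return float(_stats.pearsonr(xs, ys).statistic)


def _species_rows(l: QuantifiedLipidome):
    return [s for s in l.species if not s.is_standard]


def class_profile(l: QuantifiedLipidome) -> pd.DataFrame:
    """Per-class total concentration (uM) and mol% of the lipidome."""
    rows = _species_rows(l)
    if not rows:
        raise ValueError("empty lipidome")
    df = pd.DataFrame(
        {"class": s.class_name, "concentration_uM": s.concentration_um}
        for s in rows
    )
    out = df.groupby("class", sort=True)["concentration_uM"].sum().reset_index()
    out["mol_percent"] = out["concentration_uM"] / out["concentration_uM"].sum() * 100
    return out


def double_bond_profile(
    l: QuantifiedLipidome, per_class: bool = False
) -> pd.DataFrame:
    """Concentration aggregated by total double-bond count, as mol%."""
    rows = _species_rows(l)
    if not rows:
        raise ValueError("empty lipidome")
    recs = []
    for s in rows:
        ann = s.annotation
        recs.append(
            {
                "class": s.class_name,
                "double_bonds": ann.total_db,
                "concentration_uM": s.concentration_um,
            }
        )
    df = pd.DataFrame(recs)
    keys = ["class", "double_bonds"] if per_class else ["double_bonds"]
    out = df.groupby(keys, sort=True)["concentration_uM"].sum().reset_index()
    if per_class:
        out["mol_percent"] = out.groupby("class")["concentration_uM"].transform(
            lambda v: v / v.sum() * 100
        )
    else:
        out["mol_percent"] = out["concentration_uM"] / out["concentration_uM"].sum() * 100
    return out
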