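"""Synthetic tissue generator with ground truth.

Emulates the cell maps the analysis assumes: TMA cores (0.6 mm discs) and
large sections (rectangles with a tumor-stroma borderline) populated by

* homogeneous Poisson fields per subpopulation at stated intensities
  (cells/mm²), generated on a 10% enlarged region and clipped so border
  intensities are unbiased;
* planted pairwise spatial attraction as a parent-offspring (Neyman-Scott)
  coupling: a fraction κ of parent cells each spawn one offspring cell at a
  Gaussian(σ) displacement — exact simulation with direct control of the
  contact enrichment, no MCMC.  The offspring subpopulation's independent
  intensity is reduced by κ·λ_parent (clamped at 0) so planted expected
  densities and fractions stay exact under attraction;
* planted nests: uniform discs of a fixed cell count;
* functional-marker positivity drawn per (subpopulation, marker) Bernoulli
  rate.  Positivity vectors are made exactly consistent with the true
  subpopulation under the default gating rules, so phenotype assignment
  recovers the truth with 100% accuracy.

The MSI/MSS presets plant the study conditions: total T-cell densities of
1,628 (MSI) and 1,028 (MSS) cells/mm², a Tc1/Th1-dominant vs a
Treg/Th17/Th2-enriched composition, Tc1-Th1 and Tc1-DC vs Treg-Th17 and
Treg-DC attraction, and elevated vs baseline TIM-3/PD-1/CTLA-4 rates.  The
MSI_LIKE preset is the MSI composition carried under an MSS label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CellTable, MarkerPanel, RegionGeometry, core_area
from .errors import ConfigurationError
from .phenotyping import IMMUNE_SUBPOPULATIONS, T_SUBPOPULATIONS
from .spatial import signed_distance_to_polyline, zone_cells

__all__ = [
    "Attraction",
    "NestSpec",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "generate_sample",
    "generate_cohort",
    "generate_large_section",
    "preset",
    "PRESET_NAMES",
    "MSI_T_FRACTIONS",
    "MSS_T_FRACTIONS",
    "threshold_positivity",
    "config_to_dict",
    "config_from_dict",
]

#: Markers set positive for each true subpopulation (all other gate markers
#: negative); functional markers are drawn independently and never enter the
#: gates, so truth is exactly recoverable.
SUBPOP_POSITIVE: dict[str, frozenset[str]] = {
    "Tc1": frozenset({"CD3", "CD8", "T-bet"}),
    "Tc2": frozenset({"CD3", "CD8", "GATA3"}),
    "Tc17": frozenset({"CD3", "CD8", "RORgt"}),
    "Tcreg": frozenset({"CD3", "CD8", "FOXP3"}),
    "Tcf": frozenset({"CD3", "CD8", "BCL6"}),
    "Tc-NKT": frozenset({"CD3", "CD8", "CD56"}),
    "Tc-other": frozenset({"CD3", "CD8"}),
    "Th1": frozenset({"CD3", "CD4", "T-bet"}),
    "Th2": frozenset({"CD3", "CD4", "GATA3"}),
    "Th17": frozenset({"CD3", "CD4", "RORgt"}),
    "Treg": frozenset({"CD3", "CD4", "FOXP3"}),
    "Tfh": frozenset({"CD3", "CD4", "BCL6"}),
    "Th-NKT": frozenset({"CD3", "CD4", "CD56"}),
    "Th-other": frozenset({"CD3", "CD4"}),
    "T-other": frozenset({"CD3"}),
    "DC": frozenset({"CD11c"}),
    "NK": frozenset({"CD56"}),
    "Tumor": frozenset({"panCK"}),
    "Endothelial": frozenset({"CD31"}),
    "Other": frozenset(),
}

FUNCTIONAL_DRAWN: tuple[str, ...] = (
    "TIM-3", "PD-1", "CTLA-4", "GranzymeB", "Ki67", "HLA-DR", "CD27", "CD45RA",
)

_RESOURCE_GUARD_CELLS = 1_000_000
_ENLARGE = 1.1  # linear enlargement of the generation region


@dataclass(frozen=True)
class Attraction:
    """Parent-offspring coupling: a fraction ``kappa`` of ``parent`` cells
    each spawn one ``offspring`` cell displaced by an isotropic Gaussian of
    scale ``sigma_um``.  κ = 0 means independence."""

    parent: str
    offspring: str
    kappa: float
    sigma_um: float

    def __post_init__(self) -> None:
        if not 0 <= self.kappa:
            raise ConfigurationError(f"attraction kappa must be >= 0, got {self.kappa}")
        if not self.sigma_um > 0:
            raise ConfigurationError(f"attraction sigma_um must be > 0, got {self.sigma_um}")


@dataclass(frozen=True)
class NestSpec:
    """Planted nests: ``count`` uniform discs of radius ``radius_um``, each
    holding ``cells_per_nest`` cells of ``population``."""

    population: str
    count: int
    radius_um: float
    cells_per_nest: int

    def __post_init__(self) -> None:
        if self.count < 0 or self.cells_per_nest < 0:
            raise ConfigurationError("nest count and cells_per_nest must be >= 0")
        if not self.radius_um > 0:
            raise ConfigurationError(f"nest radius_um must be > 0, got {self.radius_um}")


@dataclass
class SimulationConfig:
    """All planted parameters of one synthetic sample.

    Exactly one of ``disc_radius_um`` (TMA core) or ``rect_um`` (large
    section, with an optional borderline ``geometry``) defines the tissue.
    ``intensities`` are expected cells/mm² per subpopulation.
    ``functional_rates[subpop][marker]`` overrides
    ``default_functional_rates[marker]`` (which applies to immune
    subpopulations only).
    """

    intensities: dict[str, float]
    disc_radius_um: float | None = 300.0
    rect_um: tuple[float, float] | None = None
    geometry: RegionGeometry | None = None
    attractions: tuple[Attraction, ...] = ()
    nests: tuple[NestSpec, ...] = ()
    functional_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    default_functional_rates: dict[str, float] = field(default_factory=dict)
    emit_intensities: bool = False
    panel: MarkerPanel = field(default_factory=MarkerPanel.default)
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.disc_radius_um is None) == (self.rect_um is None):
            raise ConfigurationError("exactly one of disc_radius_um or rect_um is required")
        if self.disc_radius_um is not None and not self.disc_radius_um > 0:
            raise ConfigurationError("disc_radius_um must be > 0")
        if self.rect_um is not None:
            w, h = self.rect_um
            if not (w > 0 and h > 0):
                raise ConfigurationError("rect_um sides must be > 0")
        self.attractions = tuple(self.attractions)
        self.nests = tuple(self.nests)
        for s, lam in self.intensities.items():
            if lam < 0:
                raise ConfigurationError(f"intensity for {s!r} must be >= 0, got {lam}")
            if s not in SUBPOP_POSITIVE:
                raise ConfigurationError(f"unknown subpopulation {s!r} in intensities")
        for attr in self.attractions:
            for s in (attr.parent, attr.offspring):
                if s not in self.intensities:
                    raise ConfigurationError(f"attraction references {s!r} without an intensity")
        for rates in list(self.functional_rates.values()) + [self.default_functional_rates]:
            for m, p in rates.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(f"rate for {m!r} must be in [0, 1], got {p}")

    @property
    def area_mm2(self) -> float:
        if self.disc_radius_um is not None:
            return core_area(2.0 * self.disc_radius_um / 1000.0)
        w, h = self.rect_um
        return w * h / 1e6


@dataclass
class GroundTruth:
    """Row-for-row truth sidecar of a generated table: the true
    subpopulation, planted nest id (-1 = none) and region per cell, plus the
    config that generated it."""

    cells: pd.DataFrame  # cell_id, true_subpopulation, nest_id, region
    config: SimulationConfig


@dataclass
class Cohort:
    """A generated patient cohort: one table + truth per sample, and a label
    frame with the reported group (MSI/MSS) and the planted MSI-like truth."""

    tables: list[CellTable]
    truths: list[GroundTruth]
    labels: pd.DataFrame  # sample_id, group, msi_like


# -- geometric helpers ---------------------------------------------------------


def _sample_region(config: SimulationConfig, rng: np.random.Generator,
                   n: int, enlarged: bool) -> np.ndarray:
    if config.disc_radius_um is not None:
        r = config.disc_radius_um * (_ENLARGE if enlarged else 1.0)
        rad = r * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2 * np.pi
        return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    w, h = config.rect_um
    if enlarged:
        pad_w, pad_h = w * (_ENLARGE - 1) / 2, h * (_ENLARGE - 1) / 2
        x = rng.uniform(-pad_w, w + pad_w, n)
        y = rng.uniform(-pad_h, h + pad_h, n)
    else:
        x = rng.uniform(0, w, n)
        y = rng.uniform(0, h, n)
    return np.column_stack([x, y])


def _inside(config: SimulationConfig, pts: np.ndarray) -> np.ndarray:
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    if config.disc_radius_um is not None:
        return (pts ** 2).sum(axis=1) <= config.disc_radius_um ** 2
    w, h = config.rect_um
    return (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)


def _enlarged_area_mm2(config: SimulationConfig) -> float:
    return config.area_mm2 * _ENLARGE ** 2


def _independent_intensity(config: SimulationConfig, subpop: str) -> float:
    lam = config.intensities[subpop]
    for attr in config.attractions:
        if attr.offspring == subpop:
            lam -= attr.kappa * config.intensities[attr.parent]
    return max(lam, 0.0)


def _guard_expected_cells(config: SimulationConfig, factor: float = 1.0) -> None:
    expected = sum(config.intensities.values()) * _enlarged_area_mm2(config) * factor
    expected += sum(n.count * n.cells_per_nest for n in config.nests)
    if expected > _RESOURCE_GUARD_CELLS:
        raise ConfigurationError(
            f"expected cell count {expected:.0f} exceeds the {_RESOURCE_GUARD_CELLS} guard"
        )


def _base_and_offspring(
    config: SimulationConfig,
    rng: np.random.Generator,
    boost: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson fields plus attraction offspring on the enlarged region.

    ``boost`` multiplies a subpopulation's generation intensity (used by the
    large-section generator, which thins back per region afterwards).
    Returns (points, subpop labels), unclipped.
    """
    area_enl = _enlarged_area_mm2(config)
    base: dict[str, np.ndarray] = {}
    pts_list, lab_list = [], []
    for subpop in config.intensities:
        lam = _independent_intensity(config, subpop) * (boost or {}).get(subpop, 1.0)
        n = rng.poisson(lam * area_enl)
        pts = _sample_region(config, rng, n, enlarged=True)
        base[subpop] = pts
        pts_list.append(pts)
        lab_list.append(np.full(n, subpop, dtype=object))
    for attr in config.attractions:
        parents = base[attr.parent]
        pick = rng.random(len(parents)) < attr.kappa
        off = parents[pick] + rng.normal(0.0, attr.sigma_um, (int(pick.sum()), 2))
        pts_list.append(off)
        lab_list.append(np.full(len(off), attr.offspring, dtype=object))
    pts = np.vstack(pts_list) if pts_list else np.empty((0, 2))
    labs = np.concatenate(lab_list) if lab_list else np.empty(0, dtype=object)
    return pts, labs


def _plant_nests(
    config: SimulationConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nest cells fully inside the true region: (points, labels, nest ids)."""
    pts_list, lab_list, nid_list = [], [], []
    next_id = 0
    for spec in config.nests:
        for _ in range(spec.count):
            if config.disc_radius_um is not None:
                rmax = max(config.disc_radius_um - spec.radius_um, 0.0)
                rad = rmax * math.sqrt(rng.random())
                ang = rng.random() * 2 * math.pi
                centre = np.array([rad * math.cos(ang), rad * math.sin(ang)])
            else:
                w, h = config.rect_um
                centre = np.array([
                    rng.uniform(spec.radius_um, max(w - spec.radius_um, spec.radius_um)),
                    rng.uniform(spec.radius_um, max(h - spec.radius_um, spec.radius_um)),
                ])
            m = spec.cells_per_nest
            rad = spec.radius_um * np.sqrt(rng.random(m))
            ang = rng.random(m) * 2 * np.pi
            pts_list.append(centre + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]))
            lab_list.append(np.full(m, spec.population, dtype=object))
            nid_list.append(np.full(m, next_id, dtype=int))
            next_id += 1
    if not pts_list:
        return np.empty((0, 2)), np.empty(0, dtype=object), np.empty(0, dtype=int)
    return np.vstack(pts_list), np.concatenate(lab_list), np.concatenate(nid_list)


def _draw_markers(
    config: SimulationConfig, rng: np.random.Generator, subpop: np.ndarray,
) -> pd.DataFrame:
    n = len(subpop)
    panel = config.panel
    col = {m: i for i, m in enumerate(panel.names)}
    flags = np.zeros((n, len(panel)), dtype=np.int8)
    for s in sorted(set(subpop)):
        mask = subpop == s
        n_s = int(mask.sum())
        for m in SUBPOP_POSITIVE.get(s, frozenset()):
            if m in col:
                flags[mask, col[m]] = 1
        for m in FUNCTIONAL_DRAWN:
            if m not in col:
                continue
            rate = config.functional_rates.get(s, {}).get(
                m,
                config.default_functional_rates.get(m, 0.0)
                if s in IMMUNE_SUBPOPULATIONS else 0.0,
            )
            if rate > 0:
                flags[mask, col[m]] = (rng.random(n_s) < rate).astype(np.int8)
    return pd.DataFrame(flags, columns=list(panel.names))


def threshold_positivity(intensities: np.ndarray, threshold: float = 128.0) -> np.ndarray:
    """Convert 0-255 staining intensities to 0/1 positivity flags."""
    vals = np.asarray(intensities, dtype=float)
    return (vals >= threshold).astype(np.int8)


def _assemble_table(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    pts: np.ndarray,
    subpop: np.ndarray,
    nest_id: np.ndarray,
    region: np.ndarray | None,
) -> tuple[CellTable, GroundTruth]:
    n = len(pts)
    cells = pd.DataFrame({
        "cell_id": [f"{sample_id}-c{i:06d}" for i in range(n)],
        "sample_id": sample_id,
        "x_um": pts[:, 0],
        "y_um": pts[:, 1],
    })
    flags = _draw_markers(config, rng, subpop)
    cells = pd.concat([cells, flags], axis=1)
    if config.emit_intensities:
        for m in config.panel:
            pos = flags[m].to_numpy(dtype=bool)
            vals = np.where(pos, rng.uniform(140, 255, n), rng.uniform(0, 115, n))
            cells[f"{m}_int"] = vals
    table = CellTable(panel=config.panel, cells=cells,
                      area_mm2=config.area_mm2, geometry=config.geometry)
    truth = GroundTruth(
        cells=pd.DataFrame({
            "cell_id": table.cells["cell_id"].to_numpy(),
            "true_subpopulation": subpop,
            "nest_id": nest_id,
            "region": region if region is not None else np.full(n, "UNASSIGNED", dtype=object),
        }),
        config=config,
    )
    return table, truth


# -- public generators ---------------------------------------------------------


def generate_sample(
    config: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "S0",
) -> tuple[CellTable, GroundTruth]:
    """One synthetic sample (TMA core or plain rectangle) with ground truth."""
    _guard_expected_cells(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pts, labs = _base_and_offspring(config, rng)
    keep = _inside(config, pts)
    pts, labs = pts[keep], labs[keep]
    nest_pts, nest_labs, nest_ids = _plant_nests(config, rng)
    all_pts = np.vstack([pts, nest_pts])
    all_labs = np.concatenate([labs, nest_labs])
    all_nids = np.concatenate([np.full(len(pts), -1, dtype=int), nest_ids])
    return _assemble_table(config, rng, sample_id, all_pts, all_labs, all_nids, None)


def generate_large_section(
    config: SimulationConfig,
    factors: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
    sample_id: str = "LS0",
) -> tuple[CellTable, GroundTruth]:
    """A large section with region-differential intensities.

    ``factors[subpop][region]`` scales that subpopulation's intensity in that
    region (regions: CT, IM_TUMOR, IM_STROMA, OUTSIDE; default factor 1).
    Implemented as generation at the per-subpopulation maximum factor followed
    by region-wise thinning, which yields an exact inhomogeneous Poisson
    field.  Requires a rectangle plus borderline geometry.
    """
    if config.rect_um is None or config.geometry is None:
        raise ConfigurationError("large sections need rect_um and a borderline geometry")
    factors = {s: dict(f) for s, f in (factors or {}).items()}
    for s, f in factors.items():
        if s not in config.intensities:
            raise ConfigurationError(f"factor references {s!r} without an intensity")
        if any(v < 0 for v in f.values()):
            raise ConfigurationError(f"factors for {s!r} must be >= 0")
    fmax = {s: max(f.values()) if f else 1.0 for s, f in factors.items()}
    _guard_expected_cells(config, factor=max([1.0, *fmax.values()]))
    rng = np.random.default_rng(config.seed if seed is None else seed)

    pts, labs = _base_and_offspring(config, rng, boost=fmax)
    region = _regions_of(config.geometry, pts)
    accept = rng.random(len(pts))
    prob = np.ones(len(pts))
    for s, f in factors.items():
        mask = labs == s
        if not mask.any():
            continue
        per_region = np.array([f.get(r, 1.0) for r in region[mask]])
        prob[mask] = per_region / fmax[s]
    keep = (accept < prob) & _inside(config, pts)
    pts, labs, region = pts[keep], labs[keep], region[keep]

    nest_pts, nest_labs, nest_ids = _plant_nests(config, rng)
    nest_region = _regions_of(config.geometry, nest_pts)
    all_pts = np.vstack([pts, nest_pts])
    all_labs = np.concatenate([labs, nest_labs])
    all_nids = np.concatenate([np.full(len(pts), -1, dtype=int), nest_ids])
    all_region = np.concatenate([region, nest_region])
    return _assemble_table(config, rng, sample_id, all_pts, all_labs, all_nids, all_region)


def _regions_of(geometry: RegionGeometry, pts: np.ndarray) -> np.ndarray:
    if len(pts) == 0:
        return np.empty(0, dtype=object)
    signed = signed_distance_to_polyline(pts, geometry.borderline)
    tumor_side = (signed > 0 if geometry.tumor_side == "left" else signed < 0) | (signed == 0)
    in_band = np.abs(signed) <= geometry.margin_width_um
    return np.where(
        in_band,
        np.where(tumor_side, "IM_TUMOR", "IM_STROMA"),
        np.where(tumor_side, "CT", "OUTSIDE"),
    ).astype(object)


# -- presets and cohorts -------------------------------------------------------

PRESET_NAMES = ("MSI", "MSS", "MSI_LIKE")

#: Planted T-cell composition (% of T cells); each sums to 100.
MSI_T_FRACTIONS: dict[str, float] = {
    "Tc1": 22.0, "Tc2": 3.0, "Tc17": 3.0, "Tcreg": 2.0, "Tcf": 1.0,
    "Tc-NKT": 2.0, "Tc-other": 12.0,
    "Th1": 18.0, "Th2": 4.0, "Th17": 4.0, "Treg": 6.0, "Tfh": 2.0,
    "Th-NKT": 2.0, "Th-other": 19.0,
}
MSS_T_FRACTIONS: dict[str, float] = {
    "Tc1": 6.0, "Tc2": 5.0, "Tc17": 5.0, "Tcreg": 3.0, "Tcf": 2.0,
    "Tc-NKT": 2.0, "Tc-other": 14.0,
    "Th1": 7.0, "Th2": 10.0, "Th17": 10.0, "Treg": 13.0, "Tfh": 3.0,
    "Th-NKT": 2.0, "Th-other": 18.0,
}

#: Planted total T-cell density (cells/mm²) and its between-patient
#: coefficient of variation, matching the reported cohort mean ± SD.
TOTAL_T_DENSITY = {"MSI": 1628.0, "MSS": 1028.0, "MSI_LIKE": 1628.0}
DENSITY_CV = {"MSI": 1687.0 / 1628.0, "MSS": 1113.0 / 1028.0, "MSI_LIKE": 1687.0 / 1628.0}

_EXTRA_INTENSITIES = {
    "MSI": {"DC": 120.0, "NK": 60.0, "Tumor": 800.0, "Endothelial": 150.0, "Other": 300.0},
    "MSS": {"DC": 100.0, "NK": 50.0, "Tumor": 800.0, "Endothelial": 150.0, "Other": 300.0},
}
_EXTRA_INTENSITIES["MSI_LIKE"] = _EXTRA_INTENSITIES["MSI"]

_ATTRACTIONS = {
    "MSI": (Attraction("Tc1", "Th1", 0.5, 5.0), Attraction("Tc1", "DC", 0.3, 5.0)),
    "MSS": (Attraction("Treg", "Th17", 0.5, 5.0), Attraction("Treg", "DC", 0.3, 5.0)),
}
_ATTRACTIONS["MSI_LIKE"] = _ATTRACTIONS["MSI"]

_FUNCTIONAL_RATES = {
    "MSI": {"TIM-3": 0.35, "PD-1": 0.30, "CTLA-4": 0.25, "GranzymeB": 0.20,
            "Ki67": 0.25, "HLA-DR": 0.20, "CD27": 0.30, "CD45RA": 0.20},
    "MSS": {"TIM-3": 0.15, "PD-1": 0.12, "CTLA-4": 0.10, "GranzymeB": 0.15,
            "Ki67": 0.15, "HLA-DR": 0.20, "CD27": 0.30, "CD45RA": 0.20},
}
_FUNCTIONAL_RATES["MSI_LIKE"] = _FUNCTIONAL_RATES["MSI"]

#: Between-patient composition jitter: per-sample fractions are drawn from a
#: Dirichlet with this concentration around the preset fractions.
DIRICHLET_CONCENTRATION = 150.0


def preset(name: str) -> SimulationConfig:
    """The MSI, MSS or MSI_LIKE study-condition configuration (0.6 mm core)."""
    key = str(name).upper()
    if key not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    fractions = MSI_T_FRACTIONS if key in ("MSI", "MSI_LIKE") else MSS_T_FRACTIONS
    total = TOTAL_T_DENSITY[key]
    intensities = {s: total * f / 100.0 for s, f in fractions.items()}
    intensities.update(_EXTRA_INTENSITIES[key])
    return SimulationConfig(
        intensities=intensities,
        disc_radius_um=300.0,
        attractions=_ATTRACTIONS[key],
        default_functional_rates=dict(_FUNCTIONAL_RATES[key]),
    )


def _vary_config(
    config: SimulationConfig,
    fractions: Mapping[str, float],
    total: float,
    cv: float,
    rng: np.random.Generator,
) -> SimulationConfig:
    """Per-patient variability: lognormal total density (mean preserved) and
    Dirichlet-jittered composition around the preset fractions."""
    sigma2 = math.log1p(cv ** 2)
    mult = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2))
    names = list(fractions)
    alpha = DIRICHLET_CONCENTRATION * np.array([fractions[s] for s in names]) / 100.0
    jittered = rng.dirichlet(alpha)
    intensities = dict(config.intensities)
    for s, f in zip(names, jittered):
        intensities[s] = total * mult * f
    for s in intensities:
        if s not in fractions:
            intensities[s] = config.intensities[s] * mult
    return replace(config, intensities=intensities)


def generate_cohort(
    n_msi: int,
    n_mss: int,
    frac_msi_like: float = 0.0,
    seed: int | None = None,
) -> Cohort:
    """Independent samples from the presets, with between-patient variability.

    MSI-like patients replace a ``frac_msi_like`` fraction of the MSS arm
    (MSI composition, MSS label); their identity is recorded in the label
    frame as planted truth.
    """
    if n_msi < 0 or n_mss < 0:
        raise ConfigurationError("cohort arm sizes must be >= 0")
    if not 0 <= frac_msi_like <= 1:
        raise ConfigurationError("frac_msi_like must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_like = int(round(frac_msi_like * n_mss))
    like_pos = set(rng.choice(n_mss, size=n_like, replace=False).tolist()) if n_like else set()

    tables: list[CellTable] = []
    truths: list[GroundTruth] = []
    rows = []
    base = {key: preset(key) for key in PRESET_NAMES}
    for i in range(n_msi):
        sid = f"MSI{i:03d}"
        cfg = _vary_config(base["MSI"], MSI_T_FRACTIONS, TOTAL_T_DENSITY["MSI"],
                           DENSITY_CV["MSI"], rng)
        t, g = generate_sample(cfg, seed=int(rng.integers(2 ** 31)), sample_id=sid)
        tables.append(t)
        truths.append(g)
        rows.append({"sample_id": sid, "group": "MSI", "msi_like": False})
    for i in range(n_mss):
        sid = f"MSS{i:03d}"
        key = "MSI_LIKE" if i in like_pos else "MSS"
        fracs = MSI_T_FRACTIONS if key == "MSI_LIKE" else MSS_T_FRACTIONS
        cfg = _vary_config(base[key], fracs, TOTAL_T_DENSITY[key], DENSITY_CV[key], rng)
        t, g = generate_sample(cfg, seed=int(rng.integers(2 ** 31)), sample_id=sid)
        tables.append(t)
        truths.append(g)
        rows.append({"sample_id": sid, "group": "MSS", "msi_like": key == "MSI_LIKE"})
    return Cohort(tables=tables, truths=truths, labels=pd.DataFrame(rows))


# -- structured-text config ----------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    d: dict = {
        "intensities": dict(config.intensities),
        "attractions": [
            {"parent": a.parent, "offspring": a.offspring,
             "kappa": a.kappa, "sigma_um": a.sigma_um}
            for a in config.attractions
        ],
        "nests": [
            {"population": n.population, "count": n.count,
             "radius_um": n.radius_um, "cells_per_nest": n.cells_per_nest}
            for n in config.nests
        ],
        "functional_rates": {s: dict(r) for s, r in config.functional_rates.items()},
        "default_functional_rates": dict(config.default_functional_rates),
        "emit_intensities": config.emit_intensities,
        "seed": config.seed,
    }
    if config.disc_radius_um is not None:
        d["disc_radius_um"] = config.disc_radius_um
    if config.rect_um is not None:
        d["rect_um"] = list(config.rect_um)
    if config.geometry is not None:
        d["geometry"] = {
            "borderline": config.geometry.borderline.tolist(),
            "tumor_side": config.geometry.tumor_side,
            "margin_width_um": config.geometry.margin_width_um,
        }
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    geometry = None
    if "geometry" in d and d["geometry"]:
        g = d["geometry"]
        geometry = RegionGeometry(
            borderline=np.asarray(g["borderline"], dtype=float),
            tumor_side=g.get("tumor_side", "left"),
            margin_width_um=float(g.get("margin_width_um", 360.0)),
        )
    return SimulationConfig(
        intensities=dict(d["intensities"]),
        disc_radius_um=d.get("disc_radius_um"),
        rect_um=tuple(d["rect_um"]) if d.get("rect_um") else None,
        geometry=geometry,
        attractions=tuple(Attraction(**a) for a in d.get("attractions", ())),
        nests=tuple(NestSpec(**n) for n in d.get("nests", ())),
        functional_rates={s: dict(r) for s, r in d.get("functional_rates", {}).items()},
        default_functional_rates=dict(d.get("default_functional_rates", {})),
        emit_intensities=bool(d.get("emit_intensities", False)),
        seed=d.get("seed"),
    )
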