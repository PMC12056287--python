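"""Gate cells into T-cell subpopulations and summarise per-sample composition.

The default taxonomy follows the standard transcription-factor hierarchy for
T cells measured by multiplexed immunofluorescence:

* T cell := CD3⁺; cytotoxic := CD3⁺CD8⁺CD4⁻; helper := CD3⁺CD4⁺CD8⁻.
* Within each arm the subset is decided by the highest-priority positive
  subset marker, FOXP3 > T-bet > GATA3 > RORγT > BCL6 > CD56 (Treg identity
  dominates when several transcription factors are co-expressed), falling
  back to "-other" when none is positive:
  Tcreg/Tc1/Tc2/Tc17/Tcf/Tc-NKT/Tc-other and Treg/Th1/Th2/Th17/Tfh/Th-NKT/
  Th-other.
* CD3⁺ cells that are CD4⁺CD8⁺ or CD4⁻CD8⁻ are "T-other" (lineage OTHER_T)
  so the subpopulation labels remain a partition of all CD3⁺ cells.
* Non-T gates: DC := CD3⁻CD11c⁺, NK := CD3⁻CD56⁺CD11c⁻, tumor :=
  CD3⁻panCK⁺, endothelium := CD3⁻CD31⁺, else OTHER.

Functional markers (TIM-3, PD-1, CTLA-4, GranzymeB, Ki67, HLA-DR, CD27,
CD45RA) do not enter the gates; their per-cell flags are copied through so
per-subpopulation positive fractions can be reported.  The taxonomy is
configurable: any priority-ordered list of :class:`GatingRule` can replace
the default (first match by descending priority wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .datamodel import CellTable, MarkerPanel
from .errors import ConfigurationError

__all__ = [
    "LINEAGES",
    "T_LINEAGES",
    "T_SUBPOPULATIONS",
    "IMMUNE_SUBPOPULATIONS",
    "FUNCTIONAL_MARKERS",
    "SUBSET_MARKER_PRIORITY",
    "GatingRule",
    "default_gating_rules",
    "assign_phenotypes",
    "CompositionProfile",
    "composition",
    "functional_fractions",
    "profiles_to_frame",
]

LINEAGES: tuple[str, ...] = (
    "CYTOTOXIC_T", "HELPER_T", "OTHER_T", "DC", "NK", "TUMOR", "ENDOTHELIAL", "OTHER",
)
T_LINEAGES: tuple[str, ...] = ("CYTOTOXIC_T", "HELPER_T", "OTHER_T")
#: Lineages counted as immune cells in spatial interaction analysis.
IMMUNE_LINEAGES: tuple[str, ...] = T_LINEAGES + ("DC", "NK")

#: Subset-marker priority used to resolve multi-positive T cells.
SUBSET_MARKER_PRIORITY: tuple[str, ...] = ("FOXP3", "T-bet", "GATA3", "RORgt", "BCL6", "CD56")

_CYTOTOXIC_SUBSET = {
    "FOXP3": "Tcreg", "T-bet": "Tc1", "GATA3": "Tc2",
    "RORgt": "Tc17", "BCL6": "Tcf", "CD56": "Tc-NKT",
}
_HELPER_SUBSET = {
    "FOXP3": "Treg", "T-bet": "Th1", "GATA3": "Th2",
    "RORgt": "Th17", "BCL6": "Tfh", "CD56": "Th-NKT",
}

#: The 15-label partition of CD3⁺ cells.
T_SUBPOPULATIONS: tuple[str, ...] = (
    "Tc1", "Tc2", "Tc17", "Tcreg", "Tcf", "Tc-NKT", "Tc-other",
    "Th1", "Th2", "Th17", "Treg", "Tfh", "Th-NKT", "Th-other",
    "T-other",
)
IMMUNE_SUBPOPULATIONS: tuple[str, ...] = T_SUBPOPULATIONS + ("DC", "NK")

FUNCTIONAL_MARKERS: tuple[str, ...] = (
    "TIM-3", "PD-1", "CTLA-4", "GranzymeB", "Ki67", "HLA-DR", "CD27", "CD45RA",
)

LINEAGE_BY_SUBPOP: dict[str, str] = {
    **{s: "CYTOTOXIC_T" for s in T_SUBPOPULATIONS if s.startswith("Tc")},
    **{s: "HELPER_T" for s in T_SUBPOPULATIONS if s.startswith("Th") or s in ("Treg", "Tfh")},
    "T-other": "OTHER_T",
    "DC": "DC", "NK": "NK", "Tumor": "TUMOR", "Endothelial": "ENDOTHELIAL", "Other": "OTHER",
}


@dataclass(frozen=True)
class GatingRule:
    """One gate: a cell matches when all ``required_pos`` markers are positive
    and all ``required_neg`` are negative.  Rules are applied in descending
    ``priority``; the first match assigns ``label`` (and ``lineage``)."""

    label: str
    required_pos: frozenset[str]
    required_neg: frozenset[str]
    priority: int
    lineage: str = "OTHER"

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_pos", frozenset(self.required_pos))
        object.__setattr__(self, "required_neg", frozenset(self.required_neg))
        overlap = self.required_pos & self.required_neg
        if overlap:
            raise ConfigurationError(
                f"rule {self.label!r}: markers both required and excluded: {sorted(overlap)}"
            )
        if self.lineage not in LINEAGES:
            raise ConfigurationError(f"rule {self.label!r}: unknown lineage {self.lineage!r}")


def default_gating_rules() -> list[GatingRule]:
    """The default taxonomy as an explicit priority-ordered rule list."""
    rules: list[GatingRule] = []
    for i, marker in enumerate(SUBSET_MARKER_PRIORITY):
        rules.append(GatingRule(
            _CYTOTOXIC_SUBSET[marker], frozenset({"CD3", "CD8", marker}),
            frozenset({"CD4"}), 1000 - i, "CYTOTOXIC_T"))
    for i, marker in enumerate(SUBSET_MARKER_PRIORITY):
        rules.append(GatingRule(
            _HELPER_SUBSET[marker], frozenset({"CD3", "CD4", marker}),
            frozenset({"CD8"}), 900 - i, "HELPER_T"))
    rules.append(GatingRule("Tc-other", frozenset({"CD3", "CD8"}), frozenset({"CD4"}), 800, "CYTOTOXIC_T"))
    rules.append(GatingRule("Th-other", frozenset({"CD3", "CD4"}), frozenset({"CD8"}), 790, "HELPER_T"))
    # CD4+CD8+ double positives and CD4-CD8- double negatives land here.
    rules.append(GatingRule("T-other", frozenset({"CD3"}), frozenset(), 700, "OTHER_T"))
    rules.append(GatingRule("DC", frozenset({"CD11c"}), frozenset({"CD3"}), 600, "DC"))
    rules.append(GatingRule("NK", frozenset({"CD56"}), frozenset({"CD3", "CD11c"}), 590, "NK"))
    rules.append(GatingRule("Tumor", frozenset({"panCK"}), frozenset({"CD3"}), 580, "TUMOR"))
    rules.append(GatingRule("Endothelial", frozenset({"CD31"}), frozenset({"CD3"}), 570, "ENDOTHELIAL"))
    rules.append(GatingRule("Other", frozenset(), frozenset(), 0, "OTHER"))
    return rules


def assign_phenotypes(
    table: CellTable,
    rules: Sequence[GatingRule] | None = None,
) -> pd.DataFrame:
    """Assign each cell a lineage, a subpopulation, and functional flags.

    Returns a frame aligned to ``table.cells`` with columns ``cell_id``,
    ``sample_id``, ``lineage``, ``subpopulation`` and one boolean column per
    functional marker present in the panel.  Deterministic and independent of
    row order given the rule priorities.
    """
    rules = list(rules) if rules is not None else default_gating_rules()
    if not rules:
        raise ConfigurationError("empty gating rule set")
    labels = [r.label for r in rules]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("gating rule labels must be unique")
    referenced = set().union(*(r.required_pos | r.required_neg for r in rules))
    missing = referenced - set(table.panel.names)
    if missing:
        raise ConfigurationError(
            f"gating rules reference markers absent from panel: {sorted(missing)}"
        )

    pos = table.positivity_matrix().to_numpy()
    col = {m: i for i, m in enumerate(table.panel.names)}
    n = len(pos)
    subpop = np.full(n, "", dtype=object)
    lineage = np.full(n, "", dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in sorted(rules, key=lambda r: -r.priority):
        match = unassigned.copy()
        for m in rule.required_pos:
            match &= pos[:, col[m]]
        for m in rule.required_neg:
            match &= ~pos[:, col[m]]
        subpop[match] = rule.label
        lineage[match] = rule.lineage
        unassigned &= ~match
    if unassigned.any():
        # only possible without a catch-all rule in a custom rule set
        subpop[unassigned] = "Other"
        lineage[unassigned] = "OTHER"

    out = pd.DataFrame({
        "cell_id": table.cells["cell_id"].to_numpy(),
        "sample_id": table.cells["sample_id"].to_numpy(),
        "lineage": lineage,
        "subpopulation": subpop,
    })
    for marker in FUNCTIONAL_MARKERS:
        if marker in table.panel:
            out[marker] = pos[:, col[marker]]
    return out


@dataclass
class CompositionProfile:
    """Per-sample immune composition summary.

    ``fractions`` are % of all CD3⁺ T cells per T subpopulation (they sum to
    100 when the sample has T cells); ``densities`` are cells/mm² per immune
    subpopulation; ``functional_fractions`` is the % of marker-positive cells
    per (subpopulation, functional marker), NaN where the subpopulation is
    empty (excluded per the zero-denominator rule).  ``excluded`` marks
    samples with zero T cells, whose fractions are undefined.
    """

    sample_id: str
    n_t_cells: int
    area_mm2: float
    fractions: pd.Series
    densities: pd.Series
    total_t_density: float
    functional_fractions: pd.DataFrame
    excluded: bool


def _resolve_area(table: CellTable, area_mm2: float | None) -> float:
    if area_mm2 is not None:
        return float(area_mm2)
    if table.area_mm2 is not None:
        return float(table.area_mm2)
    coords = table.coordinates
    if len(coords) < 3:
        raise ConfigurationError(
            "no tissue area available: provide area_mm2 or a table with >=3 cells "
            "for a convex-hull fallback"
        )
    hull_um2 = ConvexHull(coords).volume  # 2-D hull: volume attribute is the area
    return float(hull_um2 / 1e6)


def composition(
    table: CellTable,
    assignment: pd.DataFrame,
    area_mm2: float | None = None,
    subpopulations: Sequence[str] = T_SUBPOPULATIONS,
) -> list[CompositionProfile]:
    """Per-sample composition profiles (one per sample id, in order seen).

    Fractions are 100·n_s/n_T over the T-cell partition; densities are
    n_s/area for every immune subpopulation plus the total T-cell density.
    Samples without T cells are flagged ``excluded`` (fractions NaN), never
    silently zero-filled.
    """
    if len(assignment) != table.n_cells:
        raise ConfigurationError("assignment and table have different lengths")
    area = _resolve_area(table, area_mm2)
    profiles: list[CompositionProfile] = []
    for sample_id, grp in assignment.groupby("sample_id", sort=False):
        is_t = grp["lineage"].isin(T_LINEAGES)
        n_t = int(is_t.sum())
        counts = grp["subpopulation"].value_counts()
        sub_counts = pd.Series(
            [int(counts.get(s, 0)) for s in subpopulations],
            index=list(subpopulations), dtype=float,
        )
        if n_t > 0:
            fractions = 100.0 * sub_counts / n_t
        else:
            fractions = pd.Series(np.nan, index=sub_counts.index)
        dens_index = list(subpopulations) + ["DC", "NK"]
        densities = pd.Series(
            [float(counts.get(s, 0)) / area for s in dens_index], index=dens_index,
        )
        func = functional_fractions(grp, subpopulations=subpopulations)
        profiles.append(CompositionProfile(
            sample_id=str(sample_id),
            n_t_cells=n_t,
            area_mm2=area,
            fractions=fractions,
            densities=densities,
            total_t_density=n_t / area,
            functional_fractions=func,
            excluded=(n_t == 0),
        ))
    return profiles


def functional_fractions(
    assignment: pd.DataFrame,
    subpopulations: Sequence[str] = T_SUBPOPULATIONS,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """% of marker-positive cells per (subpopulation, functional marker).

    Empty subpopulations yield NaN ("no value") per the zero-denominator
    exclusion rule; downstream comparisons drop them rather than propagate.
    """
    available = [m for m in FUNCTIONAL_MARKERS if m in assignment.columns]
    if markers is None:
        markers = available
    else:
        unknown = [m for m in markers if m not in available]
        if unknown:
            raise ConfigurationError(f"unknown functional marker(s): {unknown}")
    subpops = list(subpopulations)
    pos = {s: i for i, s in enumerate(subpops)}
    codes = np.array([pos.get(s, -1) for s in assignment["subpopulation"]], dtype=np.int64)
    known = codes >= 0
    counts = np.bincount(codes[known], minlength=len(subpops)).astype(float)
    vals = np.full((len(subpops), len(markers)), np.nan)
    nonempty = counts > 0
    for j, m in enumerate(markers):
        mk = assignment[m].to_numpy(dtype=bool)
        hits = np.bincount(codes[known & mk], minlength=len(subpops)).astype(float)
        vals[nonempty, j] = 100.0 * hits[nonempty] / counts[nonempty]
    return pd.DataFrame(vals, index=subpops, columns=list(markers), dtype=float)


def profiles_to_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Flatten profiles into a samples × features matrix for cohort analysis.

    Columns: ``frac_<subpop>`` (% of T cells), ``density_total_T`` (cells/mm²)
    and ``func_<subpop>_<marker>`` (% positive).  Excluded samples keep NaN
    fractions and are dropped feature-wise by the comparison stage.
    """
    rows = {}
    for p in profiles:
        row: dict[str, float] = {}
        for s, v in p.fractions.items():
            row[f"frac_{s}"] = v
        row["density_total_T"] = p.total_t_density
        for s in p.functional_fractions.index:
            for m in p.functional_fractions.columns:
                row[f"func_{s}_{m}"] = p.functional_fractions.loc[s, m]
        rows[p.sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame
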