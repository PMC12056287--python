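# spatialtme

Spatial analysis of the T-cell tumor microenvironment from multiplexed
immunofluorescence cell maps.

Multiplexed immunohistochemistry pipelines emit one row per segmented cell:
coordinates in μm plus a positive/negative call for each marker of a panel
(here the 20-marker T-cell/antigen-presenting-cell panel: CD3, CD8, CD4,
FOXP3, T-bet, GATA3, RORγT, BCL6, CD27, CD56, CD11c, TIM-3, PD-1, CTLA-4,
panCK, Ki67, CD31, GranzymeB, HLA-DR, CD45RA — RORγT is spelled `RORgt` in
file headers).  `spatialtme` turns such tables into the quantities a
tumor-immunology study reports:

* **Phenotypes** — cells are gated into cytotoxic (CD3⁺CD8⁺CD4⁻) and helper
  (CD3⁺CD4⁺CD8⁻) T cells, then into Tc1/Tc2/Tc17/Tcreg/Tcf/Tc-NKT and
  Th1/Th2/Th17/Treg/Tfh/Th-NKT by transcription-factor positivity with the
  priority FOXP3 > T-bet > GATA3 > RORγT > BCL6 > CD56, plus dendritic cells,
  NK cells, tumor epithelium and endothelium.  Output: per-sample
  subpopulation fractions (% of CD3⁺ cells), densities (cells/mm²) and
  functional-marker positive fractions.
* **Spatial interactions** — a cell-to-cell contact is a centre distance of
  8 μm or less.  For each subpopulation pair (A, B) the package reports the
  *(p)-normalized interaction* `contacts(A,B) / total immune contacts` and the
  *normalized interaction* `contacts(A,B) / (n_A + n_B)`, with significance
  against the random background assessed by permuting subpopulation labels
  over the fixed cell positions: `p = (1 + #{null ≥ obs}) / (1 + n_perm)`.
* **T-cell nests** — DBSCAN over T-cell coordinates with Eps = 40 μm and
  MinPts = 27 (self-inclusive counts); Eps can be re-calibrated on annotated
  data as the crossing of the sensitivity and specificity curves.
* **Zoning** — signed distance to a tumor-stroma borderline assigns cells to
  the tumor centre (CT), the 360 μm invasive-margin bands, or the outside.
* **Cohort statistics** — per-feature Welch t-tests with Benjamini-Hochberg
  adjustment (volcano tables), and X-shift-style KNN-density clustering
  (`XShiftCluster`, a scikit-learn estimator) to find patient subgroups such
  as MSS patients with an MSI-like immune phenotype.
* **Synthetic tissue generator** — Poisson cell fields on TMA cores or large
  sections, planted pairwise attraction (Neyman-Scott parent-offspring
  coupling), planted nests and functional-marker rates, with ground-truth
  sidecars.  `preset("MSI")` / `preset("MSS")` encode the contrasting study
  conditions (1,628 vs 1,028 T cells/mm², Tc1/Th1- vs Treg/Th17/Th2-dominant
  composition, Tc1–Th1/Tc1–DC vs Treg–Th17/Treg–DC attraction, elevated vs
  baseline checkpoint-marker rates).

## Worked example

```python
import spatialtme as st

table, truth = st.generate_sample(st.preset("MSI"), seed=1)
assignment = st.assign_phenotypes(table)
profile = st.composition(table, assignment)[0]
print(f"{table.n_cells} cells, total T density "
      f"{profile.total_t_density:.0f} cells/mm2, "
      f"Tc1 {profile.fractions['Tc1']:.1f}% of T cells")

graph = st.build_contact_graph(table)          # 8 um contact rule
res = st.interaction_statistics(graph, assignment, n_perm=1000, seed=2)
row = res.set_index(["subpop_a", "subpop_b"]).loc[("Tc1", "Th1")]
print(f"Tc1-Th1: {int(row.contact_count)} contacts, "
      f"normalized {row.normalized:.4f}, z {row.z:.1f}, p {row.p_perm:.4f}")
```

prints

```
899 cells, total T density 1687 cells/mm2, Tc1 21.4% of T cells
Tc1-Th1: 42 contacts, normalized 0.2143, z 8.7, p 0.0010
```

— a single 0.6 mm MSI-preset core: the realised T-cell density sits near the
planted 1,628 cells/mm², and the planted Tc1–Th1 attraction yields far more
contacts than the label-permutation null (p at the resolution floor of 1,000
permutations).

The same stages are available from the shell:

```bash
spatialtme run --out demo_out --seed 11      # packaged demo manifest
spatialtme simulate --out sim --n-msi 5 --n-mss 5 --seed 3
spatialtme interactions --cells sim/cells_MSI000.tsv --out inter.tsv --seed 1
```

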