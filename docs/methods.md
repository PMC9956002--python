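# Methods

## The model

`tbsmap` treats transient surface binding as a pattern in a binary residue ×
frame contact record. A residue is "in contact" in a frame when any of its
atoms lies within a cutoff of any atom of any free ligand copy; the record of
one (substrate, replica) simulation is therefore a sparse boolean matrix, and
everything downstream — clustering, time tables, selection — is a function of
that matrix and the frame spacing Δt.

Assumptions worth stating explicitly:

- **Occupancy, not energetics.** Site importance is measured purely by how
  long the ligand sits there (frames × Δt); no interaction energies are
  estimated.
- **Co-contact implies co-location.** Two residues belong to the same site
  when the ligand touches them in overlapping frame sets. This is a temporal
  proxy for spatial adjacency; it fails only if two distant patches are
  visited in lock-step, which is vanishingly unlikely for diffusing ligands.
- **Replicas are exchangeable.** Stage-2 clustering compares replicas only
  through residue membership sets, because frame indices are not comparable
  across independent simulations.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `cutoff_angstrom` | 2.7 | Å | contact distance, boundary inclusive (≤) |
| `dt_ps` | 2 | ps | time between saved frames |
| `jaccard_cutoff` | 0.65 | – | dendrogram cut height (distance scale) |
| `min_cluster_size` | 3 | residues | smallest admissible local cluster |
| `linkage` | average | – | also `single`, `complete` |
| `aggregator` | median | – | site time from member cluster times; `sum` for cumulative tables |
| `fraction` | 0.33 | – | key-site threshold relative to the longest site time |
| `ddg_max_kcal_mol` | 0.5 | kcal/mol | stability filter (positive = destabilizing) |
| `max_size` / `max_variants_per_position` | 10 / 3 | mutants | library truncation |

The 0.65 cutoff is interpreted as a **distance** cutoff on dendrogram
heights (clusters share ≥ 35 % support on average), the natural convention
for hierarchical clustering libraries; it is configurable for users who want
the similarity reading. The fraction default is 0.33 rather than exactly 1/3
so that a site at ratio 0.331 of the maximum — a case that occurs in the
packaged reference table (32.0 ns vs 96.6 ns) — is admitted.

The longest site time used as the selection denominator is taken over *all*
sites, excluded ones included: the excluded tunnel-entrance site is still
part of the surface, and its (typically longest) time sets the scale. With
the packaged table both conventions give the same selections.

## Clustering: determinism and numerics

The agglomeration is implemented in-package (Lance–Williams updates) rather
than delegated, because reproducibility demands a defined tie rule: Jaccard
distances between small supports are small-denominator rationals and collide
often, and library implementations do not specify tie order. Here, candidate
merges within 1e-9 of the minimum are tied and resolved by the ascending
smallest-original-member pair; merging stops at the first height above
`cutoff + 1e-12` (all three linkages are monotone, so this equals cutting the
completed dendrogram). Tests cross-check the implementation against a
brute-force oracle that recomputes every linkage distance directly from the
original item-pair matrix, and against scipy's `linkage`/`fcluster` on
tie-free instances.

Degenerate inputs: residues with empty supports never enter clustering (the
metric is undefined on two empty sets; the pairwise helper warns and returns
0 if forced); an empty contact matrix yields an empty cluster list, not an
error; a both-empty `jaccard_distance` call returns 0 with a warning.

Local-cluster time is the **union** of member frame supports × Δt, so frames
in which several members touch the ligand are not double-counted; per-residue
times are kept separately for profiling. Whether a published per-site table
was produced by a median over local clusters or by a cumulative sum cannot be
decided from the table alone, so both aggregators ship and neither is claimed
to reproduce published tables from raw trajectories.

Percent changes in WT/mutant comparisons use the WT time as base; a site with
zero WT time is reported as `new` without a percentage, and a site unchanged
at zero reports 0 %.

## Contact detection numerics

Distances are compared as squared quantities, so a ligand atom written at an
axis-aligned offset of exactly 2.700 Å from a residue atom is recorded as a
contact (d² and cutoff² are the same double). PDB coordinates are rounded
back to their native three decimals after parsing, since the parser's float32
storage would otherwise perturb printed distances by ~1e-7 Å — enough to
break boundary-exact comparisons. The multi-model PDB path applies no
periodic-image correction; trajectories must be imaged beforehand, or a
reader for an imaged format plugged in via the `Trajectory` contract. All
atoms (including hydrogens) enter the distance test by default; a
`heavy_atoms_only` flag drops hydrogens from both selections for users who
prefer a heavy-atom convention.

## The synthetic generator

The generator emulates the statistical structure the clustering assumes:
disjoint planted residue groups contacted together in episodes. Episodes
start per frame with probability `event_rate_per_frame` when idle and last
a geometric number of frames (memoryless dwell, mean `mean_dwell_frames`);
during an episode each member contacts independently with `co_contact_prob`;
background contacts are i.i.d. per residue-frame. The stationary occupied
fraction is `dwell / ((1−r)/r + dwell)`.

Reference condition: 48 residues, 2500 frames at 2 ps (5 ns), four 5-residue
sites, event rate 0.004/frame, mean dwell 25 frames (50 ps), co-contact 0.95,
background 0.005. This gives ~9 % per-site occupancy — sparse matrices, as
transient binding produces — while a denser draft regime (~29 % occupancy)
was rejected because independently planted sites then overlap in time so much
that cross-site Jaccard distances approach the 0.65 cutoff, contradicting the
premise that distinct sites are visited at distinct times.

What the generator does **not** model: spatial geometry (contacts are
labels, not coordinates), correlated ligand diffusion between sites,
non-exponential dwell distributions, drift in binding propensity over the
trajectory, and replica-to-replica systematic differences. Passing the
recovery tests therefore shows the clustering correctly inverts the episodic
co-contact model, not that it is robust to every artefact of real MD data.

Problem sizes in the test and acceptance runs (10 replicas × 2500 frames ×
48 residues, 20 seeds; 200 random oracle instances of ≤ 8 items) were chosen
so the full pipeline remains a seconds-scale computation while keeping
per-site statistics (≈ 9–10 episodes per replica) informative.

## Design choices that were genuinely open

- **Linkage**: average, because it is the standard choice for binary
  fingerprints under Jaccard and resists the chaining that single linkage
  shows on overlapping supports. Single and complete remain available.
- **Pooled median for key residues**: the residue-selection median is
  computed over all profiled residues pooled across substrates, mirroring a
  cross-substrate library; a per-substrate variant can be obtained by running
  selection per substrate column.
- **ΔΔG sign**: positive = destabilizing (the common FoldX output
  orientation); `flip_ddg_sign` accommodates tables using the stability-gain
  convention, since published figures do not always state the orientation.
  The 0.5 kcal/mol neutrality threshold is an implementation default — no
  universal numeric threshold for "does not destabilize" exists.
- **Exclusion semantics**: a site is dropped when it shares ≥ 1 residue with
  the exclusion list (configurable overlap); site-id exclusion is also
  supported for workflows starting from a published table without residue
  memberships.

## Known limitations

- No periodic-boundary handling in the PDB reader (see above).
- Stage-2 features ignore how often a replica produced a local cluster; a
  site seen in one replica and a site seen in ten are distinguished only by
  their time tables.
- The physicochemical score is a coarse 3-level ordinal on five amino-acid
  classes; it deliberately encodes preference for character-changing swaps
  rather than any quantitative substitution matrix.
- Site ids are stable only within a run (ordered by total time); comparing
  runs requires matching sites by residue overlap.
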