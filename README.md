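# tbsmap

Transient binding-site mapping at enzyme surfaces, and smart-library design
from the sites it finds.

Free substrate molecules diffusing around an enzyme in a molecular-dynamics
simulation repeatedly touch the protein surface in short-lived episodes.
Groups of residues that are contacted *together* form transient binding
sites — shallow, often non-obvious surface patches that can modulate enzyme
activity when mutated, a useful engineering target once the obvious hot spots
(active site, tunnel mouths, allosteric pockets) have been exhausted.
`tbsmap` turns per-frame enzyme–ligand contacts into such sites and then into
a small, ranked library of single-point mutants for experimental testing.

The package is for computational protein engineers and simulation analysts;
it consumes either multi-model PDB trajectories or precomputed contact
tables, and a FoldX-style ΔΔG scan (it never runs MD or FoldX itself).

## Method

1. **Contact maps.** For each saved frame *f* and protein residue *r*, the
   binary matrix gets entry *(r, f)* when min atom–atom distance between *r*
   and any copy of the ligand is ≤ 2.7 Å (boundary inclusive). With frame
   spacing Δt (default 2 ps), a residue's interaction time is
   `t(r) = |{f : (r,f)}| · Δt`, and these matrices are sparse because
   transient binding is rare.
2. **Two-stage clustering.** Stage 1 clusters the residues of one replica by
   the Jaccard distance `d(A,B) = 1 − |A∩B|/|A∪B|` between their frame
   supports (agglomerative, average linkage, dendrogram cut at distance
   0.65); groups of ≥ 3 residues are *local clusters*. Stage 2 clusters the
   local clusters of all replicas by the same metric on their residue
   membership sets; the resulting *global clusters* are the transient binding
   sites, each with a per-substrate time table (median over member local
   clusters by default; a cumulative `sum` aggregator is also provided).
3. **Key residues.** Per substrate, sites with time ≥ 0.33 × the longest
   site time are kept, after dropping sites that overlap a user-supplied
   exclusion list (e.g. tunnel-entrance residues). A residue's profile is the
   median of its interaction times over the local clusters containing it;
   residues at or above the median over all profiled residues are *key*.
4. **Library design.** Candidate mutations at key residues pass a stability
   filter (ΔΔG ≤ 0.5 kcal/mol, positive = destabilizing) and are ranked by
   physicochemical-change score (prefer aliphatic↔aromatic,
   charged→uncharged, positive↔negative), then ΔΔG, then interaction time —
   truncated to ≤ 3 variants per position and 10 mutants overall.

A seeded synthetic generator plants co-contacted residue groups with
geometric dwell times and background noise, so the whole pipeline is testable
without MD data; a packaged site × substrate time table from a published
haloalkane-dehalogenase study drives the worked examples.

## Worked example

Generate ten synthetic replicas with four planted sites, cluster them, select
key residues, and design a library against a synthetic ΔΔG scan:

```python
from tbsmap import RunConfig, default_spec, generate_replicas, run_pipeline
from tbsmap.synthetic_data import generate_ddg_table

matrices = generate_replicas(default_spec(seed=7), 10)
ddg = generate_ddg_table(range(1, 49), seed=7)
result = run_pipeline(RunConfig(seed=7), matrices, "out/", ddg=ddg)
print(open("out/library.tsv").read())
```

Output (`out/library.tsv`):

```text
#config_hash=d68e0d2834a2
rank	mutation	ddg_kcal_mol	physchem_score	median_time_ns
1	V12W	-3.88	2	0.45
2	R25T	-3.23	2	0.49
3	V12R	-2.30	2	0.45
...
10	G24F	-1.29	2	0.49
```

The four planted sites are recovered exactly (see `out/sites.json` and
`out/table.tsv`); key residues 11–15 and 21–25 belong to the two
longest-bound sites, and every proposed mutant passes the stability filter
with the strongest physicochemical change (score 2). The `#config_hash`
header ties each file to the configuration that produced it.

The same pipeline runs from the shell:

```sh
tbsmap simulate --seed 7 --replicas 10 --out contacts/
tbsmap run --contacts 'contacts/SYN_*.tsv' --ddg ddg.tsv --out out/
tbsmap report            # prints the packaged site × substrate table
```

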