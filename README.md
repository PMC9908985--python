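# foldassign

Classify predicted protein structure models into domain superfamilies.

Structure predictors now emit orders of magnitude more models than any
curated classification contains, and most of those models are protein
*domains* glued together with disordered linkers, low-confidence
regions, and occasional nonsense. `foldassign` is a toolkit for the
people who curate domain classifications (and anyone who wants
classification-grade domains out of a predicted proteome): it
quality-filters models, carves them into domains, validates candidate
superfamily assignments by structure comparison, and groups whatever
remains into putative new families.

## What it does

Given predicted models (PDB files with per-residue pLDDT in the
B-factor column, long proteins as 1400-residue windows stepped by 200),
a table of candidate domain hits, optional per-domain superfamily
predictions with probabilities, and a library of reference domains
labelled with CATH-style `C.A.T.H` codes, a run will:

1. **Resolve** overlapping hits into the score-maximal non-overlapping
   domain layout per protein (exact optimum over the conflict graph;
   discontinuous domains handled by residue sets).
2. **Chop** each domain from the model window that fully contains it,
   preserving UniProt numbering, with provenance headers (sequence MD5,
   source file, family) in each output PDB.
3. **Quality-filter**: mean pLDDT ≥ 70; no single run of ≥5 residues
   below pLDDT 70 covering >30% of the domain; ≤65% of residues outside
   secondary-structure elements (built-in hydrogen-bond assigner, or an
   external per-residue annotation); ≥40 residues; ≥3 elements; packing
   density (mean neighbours within 5 Å per hydrophobic residue) and
   solvent-excluded-surface area/volume below calibrated cuts. The two
   globularity cuts are 95th percentiles of a reference distribution —
   calibrate them on your own reference set (`foldassign calibrate`);
   the literature values 9.75 and 0.494 ship as documented defaults.
4. **Assign** each confident domain through a cascade, stopping at the
   first accepted hit: candidate superfamily (from an HMM match, or
   from an embedding predictor when its probability is ≥ 0.40) → its
   topology → its architecture → all superfamilies → peer domains
   assigned earlier in the run. Acceptance is per score type: ≥60%
   query overlap always, plus bitscore ≥106/165 (class-specific) for
   bitscore backends, 80/100 for SSAP-style backends, or TM-score ≥0.5
   for the built-in comparator — a deterministic sequence-independent
   TM-score aligner (iterated gapless seeding, Kabsch superposition,
   dynamic-programming re-alignment, d0 = 1.24·(L−15)^⅓ − 1.8).
5. **Cluster** unassigned domains by all-vs-all comparison and single
   linkage at a fixed cutoff (= connected components of the thresholded
   similarity graph), then **triage** each cluster's representative:
   matches a known-but-unclassified structure, spans more than one
   domain (partial-query/full-target match over ≥40 residues), or is a
   putative new superfamily.

Every run writes TSV artifacts per stage, a JSON-lines audit record per
domain, and a summary whose counts must conserve (chopped = QC pass +
QC fail; QC pass = assigned + unassigned; unassigned = Σ cluster
members) — a rerun with the same config and seed is byte-identical.

A `synthetic` module generates every input class with recorded ground
truth — ideal helices/sheets/bundles built in internal coordinates,
planted QC violations, perturbed homolog pairs, fragmented long
proteins, hit and prediction tables — so the full pipeline runs and is
tested without downloading anything.

## Worked example

Generate a synthetic study set (21 proteins, 22 planted domains, a
3-superfamily reference library, an unclassified-structure library, and
calibrated thresholds), then run the whole protocol:

```
foldassign make-fixtures demo --seed 11
foldassign run-all --models demo/models --hits demo/hits.tsv \
    --predictions demo/predictions.tsv --library demo/library.tsv \
    --pdb-unclassified demo/pdb_unclassified.tsv \
    --thresholds demo/thresholds.json --out demo/out --seed 11
```

which prints:

```
metric	value
n_models	23
n_proteins	21
n_hits	23
n_selected_hits	22
n_rejected_hits	1
n_subsize_regions	0
n_unchoppable	0
n_chopped	22
n_qc_pass	19
n_qc_fail	3
n_assigned	11
n_unassigned	8
n_clusters	4
pct_qc_pass	86.4
pct_assigned_of_confident	57.9
qc_fail[max_ses_per_volume]	1
qc_fail[max_single_lur_fraction]	1
qc_fail[min_mean_plddt]	1
assigned[all_scan]	2
assigned[predicted_superfamily_scan]	9
clusters[multidomain]	1
clusters[pdb_unclassified_match]	1
clusters[putative_new]	2
source[CATH-HMM]	chopped=9 qc_pass=8 assigned=8
source[NewFam]	chopped=11 qc_pass=9 assigned=1
source[Pfam]	chopped=2 qc_pass=2 assigned=2
```

Reading this: 23 model files (21 proteins — one arrives as two
overlapping windows) yielded 22 chopped domains after one overlapping
hit was rejected at resolution. Three domains failed QC, one per
planted defect (low confidence, a long low-confidence region, spread
unpacked helices). Of the 19 confident domains, 11 were assigned — 9
directly in their predicted superfamily, 2 recovered by the
all-superfamily scan after a low-probability prediction was discarded —
and the percentages (86.4% confident, 57.9% assigned) are derived from
those counts. The 8 unassigned domains formed 4 clusters: two putative
new superfamilies, one cluster matching the unclassified-structure
library, and one two-domain concatenation flagged as multidomain. All
of this matches the generator's planted ground truth.

The library API mirrors the CLI (`foldassign.run`, `qc_verdict`,
`resolve_hits`, `cascade_assign`, `single_linkage`, ...); see
`docs/methods.md` for the models, defaults and their rationale.

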