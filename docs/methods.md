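# Methods

`foldassign` classifies predicted protein structure models into domain
superfamilies. This note describes the models and procedures it
implements, the defaults and why they were chosen, what the synthetic
data emulates (and does not), and the numerical choices that affect
results.

## Protocol overview

A run processes a set of single-chain predicted models (PDB files with
per-residue pLDDT in the B-factor column) through six stages:

1. **Parse** — non-ATOM records are ignored; multi-chain files, altlocs
   and insertion codes are rejected (they do not occur in predicted
   monomer models, and silently accepting them risks mis-numbering).
   Sequence MD5 digests track identical sequences across naming schemes.
2. **Resolve** — candidate domain hits (HMM matches, uncharacterised
   family matches, or unmatched domain-sized regions) are reduced to the
   score-maximal subset in which no two hits share more than an
   `overlap_tolerance` of residues (default 10).
3. **Chop** — each resolved region is excised from the model fragment
   that fully contains it, preserving residue numbering.
4. **Quality control** — each chopped domain passes a filter battery
   (below) or is excluded with the violated rules recorded.
5. **Cascade assignment** — confident domains are compared against a
   labelled reference library, stopping at the first accepted hit:
   candidate superfamily → its topology → its architecture → all
   superfamilies → peers assigned earlier in the same run.
6. **Cluster & triage** — unassigned domains are compared all-vs-all;
   single-linkage clusters at a fixed cutoff (connected components of
   the thresholded similarity graph) become putative new families, each
   triaged by its representative into known-but-unclassified structure,
   multidomain region, or genuinely novel candidate.

Counts are conserved across stages (chopped = QC pass + QC fail;
QC pass = assigned + unassigned; unassigned = Σ cluster members) and the
run aborts if they are not. Reruns with the same config and seed are
byte-identical.

## Quality filters

| rule | cut | direction |
|---|---|---|
| mean pLDDT | 70 | `< 70` fails |
| single Long Unordered Region (LUR) | 30% of residues | strictly `>` fails |
| unordered fraction | 65% | strictly `>` fails |
| residue count | 40 | `< 40` fails |
| secondary-structure elements | 3 | `< 3` fails |
| packing density | calibrated (shipped default 9.75) | `>` cut fails |
| SES area / volume | calibrated (shipped default 0.494) | `>` cut fails |

A LUR is a run of ≥5 consecutive residues with pLDDT < 70. The
single-LUR rule fails only when one such run exceeds 30% of the domain;
several shorter runs do not trip it (pervasive disorder is handled by
the unordered-fraction rule). All violated rules are recorded, not just
the first, and a metric that is undefined for a model (e.g. packing
density with no hydrophobic residue) is recorded as a failure of its
rule — a domain the metrics cannot vouch for is rejected conservatively.

**Secondary structure** comes from a built-in Kabsch–Sander-style
assigner: the backbone amide H is reconstructed on the bisector of the
C(i−1)→N and CA→N directions, H-bonds are scored with the classic
electrostatic model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
at the −0.5 kcal/mol cutoff, runs of i→i+4 bonds give helix, bridge
ladders give strand, and elements are cleaned (minimum helix 4, minimum
strand 3, single-residue gaps absorbed). An externally computed
per-residue annotation (e.g. from a DSSP run) can be supplied in its
place through `qc_verdict(..., ss=...)`.

**Packing density** is the mean number of neighbour residues within
5 Å of each hydrophobic residue ({A,V,L,I,M,F,W,C}; configurable), where
residues are neighbours when any heavy-atom pair is within the cutoff
and sequence neighbours count. This is the simplest reading of the
metric; calibration absorbs the convention.

**SES area/volume** uses a grid construction: the solvent-accessible
solid is the union of atoms inflated by the probe radius (1.4 Å);
eroding it back by the probe — morphological closing of the van der
Waals union — leaves the solvent-excluded solid. The signed field is
analytic (exact) near the accessible surface and a Euclidean distance
transform inside; volume is the voxel count and area comes from a
marching-cubes triangulation of the eroded level set. The default voxel
is 0.4 Å, at which halving the voxel changes area by <2% and volume by
<3% on compact test folds, and a single sphere recovers the closed-form
area/volume = 3/r within 5%.

**Calibration.** The two globularity cuts are defined as the 95th
percentile (linear interpolation between order statistics) of the metric
distributions over a trusted reference set. The values 9.75 and 0.494
obtained on a large hand-curated classified-domain reference with the
original tooling ship as documented defaults, but both metrics are
implementation-coupled percentiles by construction: a different surface
algorithm, neighbour convention or side-chain representation shifts the
distribution. Recalibrating on a reference set scored with *this*
package (`calibrate_thresholds`, or the `calibrate` CLI verb) is the
recommended path, and is what the test suite does with its synthetic
reference battery: Cβ-only synthetic folds measure SES/vol ≈ 0.55–0.78
where full-side-chain structures measured ≈ 0.49, so the shipped
defaults would reject every synthetic fixture.

## Fragmented proteins

Long proteins arrive as overlapping prediction windows of 1400 residues
whose starts step by 200 (a final window is pinned to the C-terminus).
Fragment files follow the `<id>-F<k>.pdb` naming convention and keep
protein (UniProt) numbering. A domain is chopped from the fragment that
fully contains it; among several candidates the fragment whose centre is
nearest the region centre wins, because window edges carry degraded
prediction confidence. A domain that fits no single window is reported
unchoppable, with the reason logged, rather than stitched together.

## Hit resolution

Resolution maximises the summed score over subsets of hits subject to a
pairwise overlap tolerance, computed exactly by branch-and-bound over
the conflict graph. Discontinuous hits conflict through their actual
residue sets, not bounding intervals, so a domain nested inside the gap
of a discontinuous domain is never wrongly blocked. Hits are ordered
canonically (score desc, length desc, start asc, family id) and the
incumbent is replaced only on strictly larger total score, so ties
resolve deterministically. The 10-residue default tolerance reflects
the tolerant-boundary behaviour of HMM hit resolution; it is
configurable and echoed into the run config.

## Structure comparison and acceptance

The built-in comparator is a sequence-independent TM-score aligner:
gapless threadings at a spread of offsets (full-chain and half-length
fragments) seed a least-squares (Kabsch) superposition; a global dynamic
programming re-alignment under the TM-weighted distance matrix
(gap penalty 0.6) and re-superposition iterate to a stable
correspondence; the superposition maximising the TM-sum is refined by
re-fitting on pairs within decreasing distance cuts (∞, 7, 4.5, 3.5 Å).
The reported score is normalised by the query length with
d0 = 1.24·(L−15)^⅓ − 1.8 (floored at 0.5 Å); the target-normalised
score is also returned. `n_aligned` counts pairs within 5 Å in the
final superposition and defines both overlap fractions. The comparator
is deterministic, exact on self-comparison (TM = 1.0, RMSD ≤ 1e−6 under
rigid motion), and on 60-residue test folds separates σ = 0.5 Å noised
copies (TM ≈ 0.9) from unrelated folds (TM ≈ 0.1) with a wide margin.

Acceptance is per score type and never crosses scales: a bitscore
backend uses the benchmarked class-specific cuts (106 for classes 1 and
3, 165 for class 2, the strictest 165 when the query has no candidate
class; class 4 requires explicit configuration), an SSAP-style backend
uses 80/100 (provisional — the benchmarked values are not in the main
protocol description), and the TM comparator uses the conventional
same-fold level 0.5. Every score type additionally requires ≥60% query
overlap. Candidate superfamilies come from an HMM match directly, or
from a sequence-embedding predictor when its probability is ≥0.40 (the
5%-error operating point); weaker predictions are discarded and the
query falls through to the all-superfamily scan. Topology and
architecture widening reuse the stage-1 cutoffs. External comparison
programs can be plugged in behind the same callable interface and bring
their own score type.

## Clustering and triage

Unassigned domains are scored once per unordered pair (canonical id
order); an edge passes at weight ≥ cutoff with both overlaps ≥60%.
Single linkage at a fixed cutoff is exactly the connected components of
the thresholded graph, computed with networkx (an independent union-find
implementation serves as the test oracle). The cluster representative
is the member with the highest mean pLDDT (configurable). Triage:
a representative accepted against the unclassified-structure library is
`pdb_unclassified_match`; a partial match against the classified library
— query overlap <60% but target overlap ≥60%, ≥40 aligned residues, and
a target-normalised score above the cut — marks the region as spanning
more than one domain (`multidomain`); anything else is `putative_new`.
The ≥40-aligned-residue requirement is this package's operationalisation
of "part of the region matches a classified domain": the matching part
must itself be domain-sized.

## Synthetic data

The `synthetic` module generates every input class with recorded ground
truth: backbones built in internal coordinates (standard bond
lengths/angles; helix φ/ψ = −57/−47, strand −139/135) so ideal helices
genuinely satisfy the i→i+4 H-bond pattern; antiparallel sheets whose
strand registry is chosen by a deterministic scan maximising inter-strand
H-bonds; up-down helix bundles on polygonal axes (compact at ≤10 Å
separation); mixed α/β folds; random-torsion compact decoys; collapsed
and spread variants as planted globularity violations; confidence-profile
injection for LUR and mean-pLDDT faults; fragmented long proteins under
the 1400/200 window scheme; and a complete end-to-end input set
(models, hits, predictions, libraries, thresholds, truth manifest).
All generators are seed-deterministic.

What the generator does *not* emulate, and what that means for the
tests: side chains are a single ideal Cβ, so absolute packing and
surface values sit on a different scale than full-atom structures
(hence calibration); loops and linkers are geometric interpolations,
not valid conformations, so secondary-structure tests assert element
cores only; and homolog pairs are made by iid Cartesian noise, which
destroys backbone H-bond geometry far faster than real homolog
divergence — sheets lose their ladders already at σ = 0.3 Å. Fixtures
that must survive QC therefore use σ ≤ 0.15 Å (sheets 0.05 Å), while
comparator and cascade benchmarks, where no QC is involved, use
σ = 0.5 Å. Fixture generators for the end-to-end set screen each
emitted instance with the package's own QC (and, for novel folds, the
comparator at TM < 0.4 against every library template), so the planted
ground truth holds by construction rather than by hope. Passing these
tests demonstrates the machinery is correct and self-consistent; it
does not measure recall on real predicted proteomes, where model error
is structured, domains are less cleanly separable, and superfamilies
are far more diverse.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
oracle comparisons on 200–1000 random instances, a cascade benchmark of
10 superfamilies × 3 representatives with 30 queries and 10 screened
decoys, and an end-to-end run of 21 proteins / 22 planted domains
(including one 1674-residue protein split into two windows). These
sizes were chosen so every property that is exact stays exact and every
separation property has a visible margin.

## Known limitations

- The built-in comparator is a TM-score aligner, not a reimplementation
  of accelerated structure search; on large libraries an external
  backend behind the comparator interface is the right tool.
- Bitscore thresholds (106/165) apply only when a backend supplies
  genuine bitscores; they are never applied to TM-scores.
- The SSAP-style acceptance default (80/100) is provisional.
- Only single-chain models are supported; mmCIF, multi-model files and
  experimental-structure idiosyncrasies (altlocs, insertion codes) are
  out of scope by design.
- Globularity thresholds are meaningful only relative to the reference
  set they were calibrated on.
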