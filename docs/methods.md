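# Methods

This note documents the models and procedures implemented in `taxomass`,
the defaults they ship with, and what the simulation-based validation does
and does not demonstrate.

## The estimation problem

Given (i) a taxonomically annotated protein sequence database, (ii) one or
more tables of scored peptide-spectrum matches (PSMs), and (iii) the number
of MS² spectra acquired, the package estimates each taxon's fraction of the
community's proteinaceous biomass. The quantity is meaningful because
protein is a large, relatively constant fraction of microbial dry mass, so
summed protein signal per taxon tracks biomass rather than cell number.

Signal is never summed per peptide-to-taxon match. Shared peptides make
peptide-level attribution systematically wrong in communities of related
organisms, so quantification operates on *inferred protein groups* only.

## Digestion and indexing

Tryptic digestion cleaves C-terminal of K/R unless followed by P. Defaults:
up to 2 missed cleavages, peptide length 6–50. These are conventional
search-engine settings; results are insensitive to them within normal
ranges. Isoleucine and leucine are isobaric, so every peptide key is
canonicalized I→L before indexing or matching. Windows containing the
undefined residue X are skipped. Decoys are full sequence reversals with
accession prefix `REV_`; they are digested and indexed exactly like
targets, and a PSM is a decoy hit only if *all* proteins carrying its
peptide are decoys (shared target/decoy peptides count as targets, the
standard competition convention). Exact duplicate sequences are collapsed
to the first-seen accession; similarity-based redundancy clustering is out
of scope.

## FDR control

Entries (PSMs, or protein groups within an engine) are ranked by
descending score with decoys ordered before targets at score ties — the
conservative choice. At each depth, FDR = #decoys / max(1, #targets), and
q-values are the running minimum of FDR from the bottom of the list. The
default PSM-level working FDR is 1%; protein-level thresholds are fixed by
the filtering strategies (5% and 1%).

## Protein inference

**Grouping.** Only identified peptides participate. Proteins with identical
identified-peptide sets merge; a protein whose set is a strict subset of
another's is absorbed into that protein's group (largest superset wins,
ties by lexicographically smallest leading accession). Members whose
evidence equals the group's full peptide set are *principal*; absorbed
members are retained for reporting but do not define the group's taxonomy.
This distinction matters: a low-coverage protein from a related species
whose few identified peptides are all shared is parsimony-absorbed, and its
taxon must not render the group ambiguous — the evidence is fully explained
by the principal protein. Conversely, two strain-level proteins identified
by exactly the same peptides are both principal, and a group spanning two
strains is reported as ambiguous at strain rank, which is the scientifically
correct statement that the data cannot distinguish them.

**Engine A** scores a group as the sum of the best PSM score per identified
peptide and converts the ranking to q-values by target-decoy competition,
emulating an additive protein-score validator.

**Engine B** is a Fido-style Bayesian model. Each group is present
independently with prior γ; a peptide with m present parent groups is
observed with probability 1 − (1−β)(1−α)^m, where α is the emission
probability of a present parent and β the noise floor. Search-engine
evidence enters as a peptide probability p (maximum over the peptide's
PSMs of a logistic transform of the within-run standardized score, clipped
to [0.01, 0.99]); a peptide contributes the soft-evidence likelihood factor
(1−p) + p·P(observed | presence vector), so p = 0 carries no evidence and
the posterior collapses to the prior — absence of identification is never
treated as evidence of absence. Posteriors are computed exactly by
enumeration over all 2^k presence vectors within each connected component
of the bipartite group–peptide graph, for components of up to
`max_exact_component` = 12 groups. Larger components are reduced in order:
peptides below the pruning floor (0.05) are discarded; groups left without
evidence take the prior; if a component is still too large, shared peptides
are removed in increasing (degree, probability) order until it splits
(removing degree-1 peptides can never split a component, so only shared
peptides are candidates). Every reduction is logged. Posterior rankings are
converted to decoy-calibrated q-values exactly as in engine A.

Defaults α = 0.9, β = 0.01, γ = 0.3 are conventional magnitudes for this
model family (a present protein usually explains its peptides; noise
identifications are rare; most database entries are absent in any one
sample); they are configurable, and the posterior *ranking* — which is what
the q-value thresholds consume — is robust to them.

**Filtering strategies.** Seven acceptance rules over the engine outputs
and peptide counts (UP = peptides unique to one group; PUP = peptides
unique to one protein sequence database-wide):

| name | rule |
|---|---|
| `SQ_5FDR` | engine A q ≤ 0.05 |
| `2UP` | `SQ_5FDR` and ≥2 UP |
| `FIDO_5FDR` | engine B q ≤ 0.05 |
| `2PUP_FIDO` | `FIDO_5FDR` and ≥2 PUP *(default)* |
| `FIDO_AND_B2` | `FIDO_5FDR` and (engine A q ≤ 0.01 with ≥2 UP) |
| `2PUP_FIDO_AND_B2` | both of the above |
| `FIDO_AND_B2_OR_3PUP` | `FIDO_5FDR` and (the 1%-clause or ≥3 PUP) |

The strategies referencing a second identification platform are modeled
with engine A at 1% FDR plus two unique peptides standing in for the second
engine; both engines are pluggable via the PSM table's engine column, so a
genuinely independent search engine's results can be substituted. Decoy
groups participate in every ranking but never appear in accepted sets.

## Quantification

Razor assignment resolves each peptide of an accepted group to exactly one
accepted group: most identified peptides, ties by larger summed PSM score,
then lexicographic group id. Three label-free methods are implemented: PSM
counts over the razor assignment, unique-peptide intensities, and
razor+unique intensities (peptide intensity = sum of its PSM precursor
intensities across runs). Each group's signal goes to the single taxon its
principal members share at the working rank; groups spanning taxa are
reported under an explicit `(ambiguous)` row and excluded from fractions by
default — aggregating to a coarser rank resolves them. Fractions are
normalized per sample over unambiguous taxa and always sum to 1.

**Incompleteness correction.** Protein databases for real communities are
incomplete, which removes PSMs and inflates the relative fractions of the
remaining taxa. Given a calibration — the fraction of acquired MS² spectra
that yielded quantified PSMs in a search with a complete database of
comparable acquisition — the expected PSM yield is rate × total MS², and
corrected fraction_i = observed PSMs_i / expected. The shortfall is
reported as an explicit unassigned fraction (both the renormalized and
unassigned views are emitted). The calibration uses the *quantified*
(razor-assigned) PSM count so corrected values are on the same scale as
complete-database fractions. Correction divides all taxa by one constant,
so it never reorders them. Corrected tables are flagged as approximations
of absolute proteinaceous biomass fractions.

## The simulator

The generator emulates the benchmark design used to validate the method: a
30-member uneven community spanning 0.08%–30% protein fraction (two strain
pairs at 99% pairwise identity, three congeneric species at 95%, three
related genera at 85%, an archaeon, a eukaryotic alga, five phages, and
thirteen unrelated bacteria), plus equal-protein (phages 10× lower) and
equal-cell variants, and pure-culture relatedness scenarios against the
shared database. Defaults: 80 proteins per bacterial taxon (archaeon 60,
eukaryote 160, phage 8), lognormal protein lengths (median ≈280 aa),
lognormal within-taxon protein abundance (σ = 1.2), an MS² budget of
130,000 spectra (one long 1D-LC-MS/MS run), identification rate 0.4, and
Gaussian score distributions for correct (μ=3.5) and false (μ=0) matches.

Relatedness is sequence-level: members of a group derive from a shared
ancestral proteome by i.i.d. substitutions at rate (1−identity)/2 per
member, so the pairwise identity hits the target and peptide sharing
emerges from digestion, not declaration. False matches are drawn from the
*whole* searched database (half target, half decoy) — this is what produces
cross-species misattribution under lenient filtering and makes decoy
counts estimate false target matches.

Two acquisition realities are modeled because the method's validated
behaviour depends on them. First, data-dependent acquisition undersamples
precursors near the limit of detection: a candidate identification of a
protein with relative abundance w succeeds with probability w/(w +
`lod_weight`), with `lod_weight` = 1e-5 (≈ the per-protein abundance of a
0.08% taxon spread over a bacterial proteome). This produces the
systematic underestimation of low-abundance taxa seen in real benchmarks
while leaving abundant taxa essentially unaffected. Second, precursor
intensities are lognormal with a weak dependence on protein abundance, so
intensity-based methods carry more dispersion than PSM counting.

Not modeled: retention time and chromatography, spectrum-level features,
per-organism detectability differences (real phages are sometimes
inexplicably undetected; simulated phages differ only by proteome size),
post-translational modifications, and shared peptides between genuinely
unrelated organisms (random sequences essentially never collide). Passing
simulation benchmarks therefore demonstrates the correctness of the
inference and quantification machinery under the stated generative
assumptions, not performance on any particular real instrument or
community.

## Problem sizes in the shipped benchmarks

Per-taxon proteome sizes are ~30× smaller than real bacterial proteomes to
keep desk-scale runs fast; spectra budgets in the relatedness scenarios
(6,000 MS² per pure-culture run) are scaled proportionately so per-protein
coverage spans the identification detection limit, as it does in real
acquisitions — at unrealistically deep coverage every protein passes every
peptide-count filter and the stringency/sensitivity trade-off cannot be
observed. The community recovery benchmark uses the full 150,000-spectra
budget; the convergence check uses 10⁶ spectra on a 5-taxon equal-protein
community.

## Numerical and edge-case choices

- Score ties in target-decoy ranking: decoys first (conservative).
- Razor ties: summed PSM score, then lexicographic group id (deterministic).
- Peptides of rejected groups are unassigned and reported as such; PSM
  conservation (taxon sums + ambiguous + unassigned = accepted PSMs) is an
  invariant under PSM-count quantification.
- A calibration implying fewer expected than observed PSMs is inconsistent;
  corrected fractions are then renormalized to 1 with a warning.
- Undetected taxa are excluded from deviation summaries (a detection
  question, not a deviation one) but counted in detection reports.
- Fold deviations are signed and symmetric: measured/input if measured ≥
  input, else −(input/measured); the centered convention subtracts the sign
  unit so equality maps to 0. Percentile summaries interpolate linearly and
  may fall in the (−1, 1) gap of the ratio convention.
- All randomness flows through one seeded generator per simulation call;
  identical configurations give byte-identical FASTA/PSM outputs.

## Known limitations

- Strain pairs above ~99% identity are quantified accurately only at
  species rank or above; strain-level fractions for such pairs are lower
  bounds (shared groups are ambiguous, and subset evidence is absorbed by
  the better-covered sibling).
- The incompleteness correction assumes the calibration run is of
  comparable acquisition quality; rate drift between runs propagates
  directly into the absolute scale.
- Exact Bayesian posteriors are guaranteed only for components within the
  enumeration limit; oversized components are pruned/split with logging,
  which perturbs posteriors near the pruning floor.
- Intensity-based quantification here uses simulated intensities with a
  simplified error model; on real data, feature-level deduplication
  (which this package does not perform) can matter.
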