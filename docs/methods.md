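# Methods

`traitrad` implements the inference chain for detecting lineage-specific
gene radiations that underlie the origin of a binary trait — the
canonical case being the betalain pigment of core Caryophyllales, whose
biosynthetic genes (DODA and CYP76AD1) each radiated into
trait-specific α and trait-independent β paralog clades.  Every stage
is exercised end-to-end on synthetic gene families with known truth.

## Homolog recovery

Candidate homologs are recovered by optimal local alignment
(Smith–Waterman with affine gaps, BLOSUM62, open 11 / extend 1, via
Biopython's `PairwiseAligner`).  Significance uses Karlin–Altschul
statistics, `E = K·m·n·exp(−λ·score)`, with the published gapped
BLOSUM62 constants (λ = 0.267, K = 0.041) and no edge-effect
correction — appropriate at the scale of a few hundred sequences.
Hits pass when `E ≤ 10` and identity ≥ 0.40 (an alternate 0.20 gate is
available for distant outgroup searches).  Identity is counted over
aligned non-gap columns, the common BLAST convention; the alternative
(full query length) is configurable because published descriptions of
such searches rarely pin this down.

## Alignment and the refinement loop

`progressive_align` is a deterministic progressive aligner: a
neighbor-joining guide tree on 3-mer cosine distances followed by
profile–profile global alignment (Gotoh affine-gap dynamic programming
over expected-substitution-score columns).  It deliberately replaces
the external MAFFT/SATé/PRANK alternation of typical transcriptome
pipelines with one reproducible engine; externally produced alignments
can be injected at any stage as FASTA.

The iterative refinement loop mirrors the published recipe and keeps
its thresholds verbatim: align → trim columns with occupancy < 0.01 →
tree; realign → trim at 0.05 → tree → cut branches longer than 1.5
substitutions/site (keeping the component with the anchor sequence) →
extract the clade containing the anchor plus its closest outgroup
lineages; realign → drop rows covering < 50% of the well-occupied core
→ trim at 0.1 → tree → drop tips with pendant branches longer than 1.0
→ final tree with bootstrap supports.  Occupancy comparisons are
inclusive (`≥`), pruning comparisons strictly greater — boundary cases
are pinned by tests.  "Poorly aligned" is not defined in most
published pipelines; the residue-coverage rule (fraction of ≥50%
occupied columns in which a row has residues, threshold 0.5) is this
package's declared operationalisation, and every removal is logged
with the rule and threshold that caused it.

## Tree inference

Gene trees are estimated desk-scale rather than by a full ML search:
maximum-likelihood pairwise distances under WAG (bounded scalar
optimization of the pair likelihood, capped at 10 substitutions/site)
feed canonical neighbor-joining (Q-criterion ties broken
lexicographically; negative branch estimates clamped to zero with the
deficit moved to the adjacent branch), followed by NNI hill-climbing
under the full WAG pruning likelihood with per-edge branch-length
optimization.  Matrix exponentials use the symmetric
`π^{1/2} Q π^{−1/2}` eigendecomposition available for every reversible
model; likelihood underflow is handled by per-node rescaling of
partials.  The per-edge optimizer refreshes inside/outside messages
once per sweep; a sweep that fails to improve the joint likelihood is
rolled back, so refinement never returns a worse tree.  Bootstrap
support resamples alignment columns and rebuilds distance/NJ trees,
scoring bipartitions on the reference topology.  Discrete-Gamma rate
heterogeneity (4 categories) is available but off by default.

## Duplication mapping

Rooted gene trees are reconciled with the species tree by standard LCA
mapping; a gene node is a duplication iff it maps to the same species
node as one of its children — the parsimony minimum.  The placement is
reported as the mapped species node together with its parent edge,
which encodes "arose just before the divergence of X": LCA mapping
localises the duplication no later than that node.  Losses are not
enumerated; loss information is summarised as a species × paralog-clade
presence/absence matrix with per-species trait states.  The two-sided
Fisher exact test on the 2×2 presence table between two clades is an
optional add-on summary, not part of the mapping.

## Trait ancestral state reconstruction (Mk1)

The binary pigment trait evolves by a one-parameter symmetric CTMC:
`P(same) = (1 + e^{−2rt})/2`.  The root prior is the stationary
(1/2, 1/2); tips coded `missing` contribute the partial likelihood
(1, 1) rather than being pruned.  The rate is fitted by Brent-style
bounded search on log r over [1e−8, 1e3] (tolerance 1e−8); boundary
optima are flagged (they are the correct MLE when all scored tips
share one state).  Marginal node posteriors come from inside/outside
message passing, equivalent to re-rooting at each node, and are
verified against exhaustive state enumeration on small trees to 1e−10.
−log L is reported alongside log L to match the sign convention of
common ASR programs.

## Codon models and selection

The codon state space is the 61 sense codons of the standard code.
GY94-style rates are zero for multi-nucleotide changes and otherwise
`π_j`, × κ for transitions, × ω for nonsynonymous changes; generators
are time-reversible by construction.  Site models M0, M1a (classes
ω0 ≤ 1 and ω1 = 1) and M2a (adds ω2 ≥ 1) and branch-site model A are
implemented over one pruning engine with compressed site patterns.
Model A's four classes are (ω0 everywhere), (1 everywhere),
(ω0 background / ω2 foreground) and (1 background / ω2 foreground)
with proportions `(p0, p1, p2·p0/(p0+p1), p2·p1/(p0+p1))`; the
foreground is every branch within the designated clade, stem included.

Mixtures are normalised by the proportion-weighted average of the
classes' background substitution rates, so one unit of branch length
is one expected substitution per codon averaged over classes and
higher-ω classes genuinely evolve faster — the standard formulation.
(Normalising each class separately was evaluated and rejected: it
removes most of the rate signal that identifies selected sites.)
Codon frequencies default to F3x4 estimated from the alignment, with
an equal-frequency option; the validation experiments simulate and fit
under equal frequencies so recovery is measured without a frequency-
model mismatch.

Fitting is multi-start L-BFGS-B (default 3 starts, tolerance 1e−7)
with box bounds: κ ∈ [0.1, 20], ω0 ∈ (0, 1], ω2 ∈ [1, 50], and the
proportion simplex parametrised as `(p0+p1, p0/(p0+p1))` so it becomes
a box.  The replicated calibration and recovery experiments use a
single informed start (the alternative warm-started from the null's
optimum), which the optimizer-contract tests show is sufficient at
those problem sizes.  The M1a-vs-M2a LRT uses χ²(2); model A vs its
ω2 = 1 null uses df 1 with an optional 50:50 χ²₀:χ²₁ mixture null —
the literature varies here, so both are available and the choice is
recorded in the result.

Site identification: NEB plugs in the MLEs; BEB averages the class
posteriors over a 10-point-per-dimension grid on (p0+p1, p0/(p0+p1),
ω0, ω2) — ω0 on (0, 1), ω2 on (1, 11) — weighting grid points by the
full-data likelihood, with the remaining parameters and the branch-
length scale fixed at their MLEs.  Both thresholds in common use
(0.95 and 0.99) are reported; neither is hard-coded as "the" answer.

## Diagnostic residues and clusters

A diagnostic site is a column where clade A is invariant for a residue
clade B never shows.  Strict mode also requires clade B invariant;
tolerant mode (default τ = 0.1) accepts a clade-B majority residue at
frequency ≥ 1 − τ, matching the "almost invariantly X and never Y"
pattern seen in real paralog contrasts.  Rows with gaps at a column
are excluded from the invariance check, but a clade more than half
gapped there makes the column ineligible.  Positions are reported in
the ungapped numbering of a designated reference sequence.

Gene-cluster detection measures the bp gap between the nearest ends of
a focal gene pair (`max(0, later.start − earlier.end − 1)`) on one
chromosome and counts annotated genes strictly between them; "c. 50 kb"
is operationalised as an inclusive ≤ 50 000 bp test (configurable).

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed:

- **Species tree**: pure-birth, 40 species, rescaled to root depth 1.0.
  Pure birth (not birth–death) because gene loss is modelled at the
  gene level, where the signal of interest lives.
- **Structure**: the outgroup is the smaller side of the root; the
  trait-bearing core clade is the larger child of the ingroup, so its
  stem — where the α/β duplication is planted — is old and the paralog
  clades are deeply diverged, as in the real gene families.
- **Trait**: one forced gain on the core-clade stem and 3 forced
  single-lineage reversals inside it; background Mk1 noise rate 0
  (every change in the default scenario is a planted event, mirroring
  a single-gain-plus-reversals history).  The forward simulator also
  runs at any rate for the parameter-recovery experiments.
- **Gene family**: the ancestral copy duplicates into α/β on the core
  stem; one further duplication inside α; every α copy is lost in each
  reversal lineage.  Gene-tree branch lengths track the species tree
  at 1.0 substitutions/codon per unit depth.
- **Codons**: 300 codons; branch-site truth κ = 2, ω0 = 0.2, ω2 = 5,
  p0 = p1 = 0.45 (p2 = 0.1), foreground = the α clade; equal codon
  frequencies.  Stop codons cannot arise (the state space excludes
  them).
- **Diagnostic residues** are imposed post hoc (overwritten columns:
  P/N and W/A), because real diagnostic sites are observed invariants,
  not a generative model.  The generator then breaks up any column
  that drifted by chance into a clade-diagnostic contrast (one
  single-nucleotide nonsynonymous change in one clade-A row), so the
  emitted data are consistent with the declared diagnostic truth by
  construction; the number of purged columns is recorded in the truth.
- **Genome**: the two focal genes 30 kb apart with exactly one
  intervening locus on one chromosome, plus unrelated loci as
  negatives.
- **Determinism**: each sub-simulator draws from its own stream
  derived from the master seed, so adding a stage never perturbs
  earlier outputs; a fixed seed fixes every emitted byte.

What the generator does *not* emulate: assembly artifacts and
frame-shifted transcripts, alignment-fragmenting indels (sequences are
generated without indels, so the aligner's hard cases come from its own
unit tests, not the scenario), incomplete lineage sorting, horizontal
transfer, and rate heterogeneity beyond the branch-site classes.
Passing the end-to-end test therefore shows the chain of inferences is
correct on clean data of realistic divergence — not that the pipeline
is robust to assembly noise.

## Validation experiments and problem sizes

The self-check battery (also run by `scripts/acceptance.py`) uses
desk-scale sizes chosen to give stable statistics in minutes: Mk1 rate
recovery on 100 forward simulations over 300-tip trees; M0 ω and
branch-site ω2 recovery on 20 seeds of 500 codons over a fixed
6-taxon tree; LRT calibration on 100 null replicates of 300 codons
(the χ²(2) reference is conservative at this boundary, so empirical
rejection sits below the nominal 5%); and BEB site detection on 20
seeds of 500 codons over a 14-taxon tree whose 8-tip foreground clade
carries ~4 substitutions/codon of total branch length — enough
foreground changes per site for posterior identification, which a
3-branch foreground cannot provide at any ω2.  The end-to-end scenario
runs at the generator defaults with 25 bootstrap replicates.

## Known limitations

- The tree engine is NJ + NNI, not SPR/TBR; on very poor starting
  topologies it can stop in a local optimum (one test exercises escape
  from a wrong start at desk scale).
- Branch-length optimization uses once-per-sweep message refreshing;
  it converges to the same optimum as exact coordinate ascent in all
  tested cases but takes more sweeps on pathological trees.
- BEB integrates over the published 4-dimensional grid only; κ and the
  branch-length scale stay at their MLEs.
- Reconciliation assumes binary rooted trees; weakly supported nodes
  are not collapsed first (a `min_support` collapse hook exists in the
  design but duplication counts are reported from the resolved tree).
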