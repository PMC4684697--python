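# Methods

This note documents the models and procedures implemented in `aropipe`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## k-mer spectrum genome-size estimation (`aropipe.kmer`)

A read of length *L* contributes *L − K + 1* k-mers, so the k-mer depth
(the spectrum's main peak *M*) underestimates base depth *N* by the
factor (L − K + 1)/L:

    M = N (L − K + 1) / L,   genome size = total bases / N.

`count_kmers` counts every length-k substring as-is; substrings spanning
non-A/C/G/T symbols are skipped. Reverse-complement (canonical) merging
is off by default — on single-stranded simulated reads the formula is
orientation-agnostic — and available via a flag for real libraries.

`find_peak` excludes the error peak by considering only multiplicities
≥ `min_multiplicity` (default 3) and returns the raw mode, ties to the
smaller multiplicity. The full estimator instead uses the refined peak:
the rounded count-weighted mean multiplicity of the above-threshold
spectrum. The rationale is numerical: the genomic portion of the
spectrum has mean multiplicity exactly equal to the k-mer depth, whereas
its raw mode wobbles between adjacent integer bins whenever the k-mer
depth falls near a bin boundary (for depth 20, L=100, k=21 the k-mer
depth is 16.0, and the mode lands on 15 or 16 depending on sampling
noise — a 6–7% swing in the genome-size estimate). The mean pools all
bins and is stable; on error-laden reads the ≥3 threshold keeps
error k-mers out of the average. Per-k estimates (k ∈ {15, 17, 19, 21})
are combined by the median, which is robust to a single discretized
outlier. *L* is taken as the modal read length when lengths vary;
occurrence totals are still exact per read.

Not modeled: heterozygosity and repeat peaks (no mixture fitting), and
disk-backed counting — the in-memory table is intended for simulated or
downsampled read sets.

## Synthetic data (`aropipe.simulate`)

The generator produces every input the pipeline consumes, with ground
truth recorded.

**Species tree.** A pure-birth tree with `n_taxa` tips (default 27,
mirroring the taxon-set size the pipeline is designed around; families
default to 177). Branch lengths are rescaled so the root-to-tip depth is
`tree_height` = 0.2 amino-acid substitutions per site, and the youngest
tips are extended by one waiting-time draw so all branches are strictly
positive while the tree stays ultrametric. The 0.2 depth keeps genuine
structure clear of the decomposition's fixed cutoffs: the deepest
genuine unrooted edge (the two basal child edges combined) stays below
the 0.3 internal-branch cutoff, and genuine terminal branches stay below
the 0.5 tip cutoff, so anything the trimmers remove is by construction
an injected artifact. It also keeps pairwise p-distances far from
saturation for the distance-based plumbing.

**Gene families.** A birth–death walk along the species tree:
duplications (default 0.5 events per unit branch length) copy a lineage,
which then evolves independently; losses (default 0.3) terminate it.
With the default tree this yields roughly one duplication per family —
families are mostly single-copy with occasional paralogy, the regime
tree-based orthology pipelines are built for. Tips are labeled
`taxon@copy`. The true ortholog partition groups tips by gene-copy
lineage: within a group every pairwise most recent common ancestor is a
speciation node. Sequences evolve along the gene tree under an
equal-exchangeability 20-state model (the amino-acid analog of
Jukes–Cantor): substitution probability over branch length *t* is
(19/20)(1 − e^(−20t/19)), with per-taxon rate multipliers applied to
terminal branches (both to the branch length and to the sequence
evolution, as an estimated tree would show). Richer inference models are
deliberately out of scope; the tests need distance monotonicity, not
model realism.

**Contaminants.** With probability `contaminant_tip_rate` one terminal
branch is multiplied by max(10, 0.6/length) — always ending above the
0.5 absolute tip cutoff — emulating a misassembled or cross-contaminated
sequence. The tip is flagged and removed from the truth partition.

**Reads.** round(G·depth/L) fixed-length reads placed uniformly;
per-base substitution errors at `error_rate`; no indels or quality
strings. Total simulated bases equal reads × read length exactly.

What the generator does **not** emulate: alignment error (simulated
alignments are exact), indels (gaps enter only where tests punch them),
rate variation across sites, GC/coverage bias in reads, and chimeric
assembly artifacts other than the long-branch contaminant. Passing
recovery tests therefore demonstrates correctness of the decomposition
logic under clean signal, not robustness to alignment noise.

## Ortholog decomposition (`aropipe.orthology`)

Order of operations (matching tree-based orthology practice): trim tips →
mask same-taxon monophyletic clusters → cut long internal branches →
taxon-coverage filter → maximum-inclusion pruning. Defaults: absolute
tip cutoff 0.5, relative tip cutoff 0.2 with factor 10, internal cutoff
0.3 (all in substitutions/site), minimum taxa 27.

Design choices where the procedure is underdetermined:

- **"Nearby tips"** for the relative rule are the tips of the sister
  clade at the tip's attachment node — locally computable and in the
  spirit of flagging a branch that dwarfs its immediate neighbourhood.
- **Masking representative**: the tip with the shortest terminal branch,
  ties broken lexicographically — the shortest branch is the least
  likely to carry artifactual length.
- **Trimming runs to a fixpoint.** Suppressing a degree-2 node after a
  removal sums the two merged branches, which can push a surviving
  terminal branch past a cutoff; sweeping until no rule fires makes the
  operation idempotent. Within a sweep all tips are judged against the
  same tree state.
- **Unrooted handling.** Candidate MI subtrees are the tip sets on both
  sides of every edge plus the whole tree, so no arbitrary rooting is
  imposed. When a rooted representation's root has exactly two children,
  the two basal edges are treated as one unrooted edge (their lengths
  summed) by the internal-branch cutter.
- **MI tie-break**: among candidates covering equally many taxa, prefer
  the smaller total branch length, then the lexicographically smallest
  tip-label set. Deterministic; no claim of optimality between ties.
- **MI emission loop**: tip cutoffs are re-applied after each extraction
  (deleting tips can lengthen merged branches), with the same 0.5/0.2
  values as pre-trimming.

Branch lengths are never rescaled by any operation; path lengths between
surviving tips are conserved to numerical precision (1e-9 in tests).

A neighbor-joining builder over Poisson-corrected distances
(d = −ln(1 − p), complete-deletion p per pair, via scikit-bio's NJ) is
included as plumbing so the full loop runs without external ML tree
software. It refuses saturated pairs (p ≥ 0.95), where the correction
diverges.

Known limitation: MI legitimately fills the slot of a lost or trimmed
taxon with a surviving paralog copy when the topology allows — the
emitted group is a valid maximum-inclusion subtree but a chimera
relative to the simulation's copy-lineage truth. Recovery is therefore
measured as pairwise co-membership precision/recall, the standard
cluster-recovery metric, rather than exact set equality.

## Supermatrix (`aropipe.supermatrix`)

Column trimming keeps columns whose non-gap fraction is ≥ `min_occupancy`
(default 0.5) — a simple occupancy surrogate for block-based alignment
trimmers, which are out of scope. Gap characters are `-` and `?`; `X`
counts as a residue. The choice of denominator for the reported gap
percentage (all taxa × all sites) and the gap-character set are
documented here because they are conventions, not identities; both are
configurable at the call sites that matter. Partition blocks use
RAxML's 1-based inclusive `MODEL, name = start-end` convention and
round-trip through the bundled parser.

## Rates and Tajima tests (`aropipe.rates`)

Lineage rate = sum of branch lengths from tip to a reference ancestor
(e.g., the ray-finned/lobe-finned split). Outgroup re-rooting splits the
attachment edge equally and preserves all tip-to-tip path lengths.

Tajima's relative rate test uses complete deletion: every column with a
character outside the 20 standard amino acids (gap, `?`, `X`, anything
else) in any of the three rows is removed. Columns where the two
ingroups agree against the outgroup, or where all three states differ,
count toward n_sites but toward neither m. The χ² p-value is computed in
closed form as erfc(√(χ²/2)) — exact for 1 df — avoiding a statistics
dependency in the hot loop; tests cross-check it against scipy's χ²
survival function. The degenerate case m_a + m_b = 0 returns χ² = 0,
p = 1 (no evidence against equal rates; the statistic is otherwise
undefined there). Whether outgroup-unique columns belong in the reported
n_sites varies between implementations; it does not affect χ² or p, and
n_sites here is reported-only. Comparisons are case-insensitive.

The batch runner shares a Bonferroni critical value α/(others ×
outgroups); with the 17-comparison × 3-outgroup roster and α = 0.05 this
is 0.05/51 ≈ 0.00098. The test assumes the outgroup is genuinely
external to both ingroup lineages; with a misplaced outgroup the
asymmetry in unique-difference counts reflects topology, not rates.

## Pigment screen (`aropipe.pigments`)

Hits are the 12 standard BLAST outfmt-6 columns with subject length
appended. Coverage uses the subject (catalog protein) length as
denominator for both the annotation-grade filter (1e-10/70%) and the
pigment filter (1e-40/70%) — one convention applied uniformly. Best hit
per gene: smallest e-value, then higher bit score, then higher percent
identity, then lexicographic subject id; the result is invariant to
input order. A gene with several functional categories appears once per
category in the report; genes with no surviving hit are kept as absent
rows. Conserved-domain confirmation is represented only as an optional
input column — no external services are queried.

## Problem sizes in the test and acceptance suites

The suites run on desk-scale versions of each analysis: 50 kb genomes at
depth 20 for k-mer recovery; 100 eight-taxon families (one contaminant
each) for ortholog recovery, evaluated at minimum taxa = 7 because the
flagged contaminant removes one taxon from its truth group by
construction; ≥500 trees of ≤10 tips for the exhaustive MI oracle; 200
equal-rate and 100 rate-shifted replicates of 10,000 sites for Tajima
calibration and power; 25 families for supermatrix bookkeeping. These
sizes exercise every code path while keeping the full suite and the
acceptance script in the seconds-to-minutes range.
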