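# Methods

This note documents the models, parameters and numerical choices behind
`groelamp`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## The marker and the primer model

The profiling method targets a hypervariable region of the single-copy
*groEL* (cpn60) chaperonin gene, positions 340–824 in the gene's 1-based
coordinates, amplified by the degenerate pair Lac_groEL_F
(`GCYGGTGCWAACCCNGTTGG`, 16 concrete oligos) and Lac_groEL_R
(`AANGTNCCVCGVATCTTGTT`, 144 concrete oligos). The amplicon is 485 bp
(`824 − 340 + 1`) and the primer-free insert 445 bp. Because *groEL* is
single copy in lactobacilli, read fractions estimate cell fractions
without copy-number correction, and gene copies computed from DNA mass
stand in for colony-forming units.

A degenerate position matches any base of its IUPAC set at zero cost;
mismatch counting is therefore asymmetric (pattern vs concrete window) and
exact. Conservation profiles use the standard sequence-logo statistic:
per-column information `2 − H` bits with Shannon entropy `H` over
gap-excluded base frequencies, `0·log 0 := 0`, all-gap columns reported as
missing.

## In-silico PCR

Binding sites are found by exhaustive window scanning. Two tolerance
parameters govern a hit: `max_mismatches` (default 2) across the whole
primer and a 3′ clamp (`clamp_len`, default 3) in which no mismatch is
allowed — a polymerase cannot extend a mispaired 3′ terminus, which is
also how PRIMER-BLAST-style screens avoid spurious calls. The defaults
are this package's choice: amplification across four related genera with
degenerate primers implies tolerance beyond exact matching, but no
published per-genus mismatch profile exists to calibrate against.

Products are predicted in both template orientations (whichever strand
carries the forward site), so the product set is invariant under
reverse-complementing the input, with coordinates mirrored. Amplicon
sequences are always written forward-primer-first. When several sites
could pair, sites are paired *mutual-nearest* (a forward site and the
nearest downstream reverse site form a product only if each is the
other's nearest partner): the shortest product dominates a real reaction,
and the rule reduces to the obvious one on the single-site templates the
marker actually produces. Products outside [100, 2000] bp are discarded —
a window bracketing the expected ~480 bp product. Coordinates are 0-based
half-open internally; the 1-based inclusive convention of the marker
literature is used only in prose and reports.

## Reference database

References that yield exactly one product are trimmed to it and become
classification targets; references with zero or multiple products are
retained but flagged (`no_product` / `multi_product`) and excluded from
classification — how real multi-product references should be handled is
genuinely open, and exclusion is the conservative choice. Species and
subspecies labels are kept verbatim (synonym merging is data curation,
not code). Serialization is plain text (FASTA + TSV + JSON metadata) and
round-trips field-for-field.

## Read processing

The pipeline applies the method's printed rules with these readings:

- **Quality filter** — a read is kept iff its *mean* Phred score is
  strictly greater than 30. "Quality higher than 30" could also mean a
  per-base minimum or an expected-error criterion; whole-read mean is the
  implemented default, and the cutoff itself is configurable.
- **Merging** — the longest exact suffix/prefix overlap of ≥ 11 bases
  (">10 bp") between R1 and the reverse-complemented R2, with 0
  mismatches by default. Searching from the longest overlap downward is
  conservative: repeat-induced ties resolve toward the longer overlap and
  hence the shorter (never chimeric-looking) merged read. Overlap bases
  take the higher-quality base and the max of the two qualities; with
  zero mismatches allowed this only affects logged qualities.
- **Primer trimming** — the forward primer must match the merged read's
  prefix and the reverse complement of the reverse primer its suffix,
  each within the pair's mismatch tolerance but *without* the 3′ clamp:
  the clamp models extension, which is irrelevant when removing
  already-sequenced primer bases, and applying it would reject legitimate
  reads carrying a sequencing error at the primer 3′ end.

## Identity, clustering and assignment

All identities are computed from a Needleman–Wunsch global alignment with
match +1, mismatch −1 and affine gaps costing 2 + 1 per gapped column,
end gaps free; identity = 100 × matches / aligned columns with
terminal-gap columns excluded from the denominator. This mimics
MatGAT-style "alignable-region" identity and avoids penalizing
length-truncated reads. The alignment engine is scikit-bio's `pair_align`;
the identity statistic and its use are this package's. The gap convention
(open charged once per gap, plus the per-column extension) is stated here
because "open 2, extend 1" is written two ways in the literature; the
choice is immaterial at the divergences that matter near the 97%
threshold.

OTU clustering is abundance-sorted greedy centroid clustering at 97%:
unique sequences in decreasing count order (ties broken lexicographically
for reproducibility) join the first existing centroid at ≥ 97% identity
or found a new OTU, so centroids are pairwise < 97% at founding time.
Classification aligns each centroid to every usable reference insert —
*insert*, not amplicon: primer-region bases are constrained by the primers
and would inflate identity. The best hit at ≥ 97% assigns its label; OTUs
whose best identity is shared by different species are reported
`unassigned` with a tie flag, because several *Lactobacillus* species are
100% identical over this marker and picking one would fabricate
precision. Whether the original analysis classified centroids or all
reads is not documented; centroid best-hit is the implemented default.
Abundance tables pool named species below 1% per sample into
`other Lactobacillus <1%`; `unassigned` is never pooled.

## Cross-alignment and the NJ tree

The identity matrix computes each unordered pair once (symmetry and the
100 diagonal hold by construction and are asserted in tests). The
closest-species report takes, per species, the maximum identity between
any of its strains and any strain of any other species (alphabetical
tie-break); rows above 97% mark species pairs that this marker cannot
separate. The neighbor-joining tree on `d = 100 − identity` is a QC
convenience: no evolutionary-model correction, no bootstrap — it is not a
publishable phylogeny and deliberately replaces nothing.

## Mock-community evaluation

`copies_from_mass` is the standard dsDNA formula with 650 g/mol per base
pair: `copies = m_ng · 6.022×10²³ / (L_bp · 10⁹ · 650)`. Expected
fractions are copy fractions. Accuracy is summarized by ordinary least
squares of observed on expected fractions (slope, intercept, R²).

The end-to-end benchmark (`run_mock_experiment`) defines its regression
x-axis as the composition *actually sequenced*: read pairs are allocated
to species by deterministic largest-remainder rounding of the mass-derived
fractions, and observed abundances are regressed on those allocated
fractions. This isolates the pipeline's quantification error from the
sequencer's multinomial sampling noise — which is the quantity a mock
community is built to measure — and makes the error-free limit exact
(slope = 1, R² = 1 to machine precision). The mass-derived theoretical
fractions are reported alongside; at depth 20,000 the two differ by less
than 5×10⁻⁵ per species. The regression uses ungrouped per-species
fractions: the <1% pooling rule is a table-presentation convention and
would destroy a regression whose design spans 0.01–50 ng.

Detection in the dilution scan is ≥ 1 assigned read by default
(configurable `min_count`); no published call threshold exists. Results
report masses and their copy-count equivalents rather than asserting
cfu/mL, since the cfu conversion depends on an unstated genome size and
elution volume.

## The synthetic-data generator

The generator emulates the *structure* that makes the marker work:

- a 445 bp hypervariable insert mutated from a common ancestor at 10%
  between species and 0.5% between strains (applied as a fixed
  `round(rate · L)` substitutions at seeded positions, so the identity
  layout — inter-species < 97% < intra-species — is stable and verified
  post hoc by alignment, with regeneration under a derived seed if a draw
  violates it);
- exact, conserved primer sites: a random expansion of each degenerate
  primer planted per record, the forward site at 1-based 340 (the 5′
  flank is therefore fixed at 339 bp; `flank_len` sets the 3′ flank);
- 2×300 bp read pairs covering the 485 bp amplicon from both ends
  (115 bp overlap), with a linear quality profile from Q38 at the 5′ end
  to Q25 at the 3′ end — representative MiSeq 2×300 behaviour — and
  substitution probabilities proportional to the per-position error
  probability `10^(−Q/10)`, rescaled to the requested mean rate. At a
  0.5% mean rate this concentrates errors in the overlap and rejects
  ~85–90% of pairs under the strict no-mismatch merge, which is why
  benchmark runs report a few thousand merged reads from 20,000 pairs.

It does **not** emulate PCR amplification bias, chimeras, indel errors,
primer-site mismatches against real templates (an option plants exact
expansions only), or real *groEL* phylogenetic structure — species here
are equidistant from one ancestor. Passing tests therefore demonstrate
the pipeline's correctness and quantitative fidelity under controlled
conditions, not classification accuracy on real communities, which is
bounded by reference-database completeness and the genuinely confusable
species pairs flagged by the cross-alignment module.

The default mock community: nine species, one strain each, DNA masses
geometrically spaced over [0.01, 50] ng, genome lengths seeded uniform in
[1.8, 3.4] Mb (typical *Lactobacillus* genome sizes), depth 20,000 pairs,
substitution rate 0.5%. Unit tests run the same machinery at depths of a
few hundred reads; the benchmark experiments run at the full depth.

## Degenerate inputs and edge rules

- Sequences are normalized on ingestion: uppercase, U→T.
- A template shorter than a primer has no sites (empty result, not an
  error); an empty sequence set, all-zero mock masses, a zero-variance
  regression x, or fewer than 3 NJ taxa are contract errors.
- Alignment of disjoint sequences whose optimal placement shares no
  column yields identity 0.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical
  outputs.

## Known limitations

- Greedy clustering is O(uniques × centroids) alignments; adequate for
  amplicon-scale data, not for shotgun scale.
- Best-hit assignment has no lowest-common-ancestor fallback; a tie
  simply refuses to choose.
- The NJ tree and the identity-based distances are descriptive QC tools.
- No chimera detection or demultiplexing: inputs are assumed
  demultiplexed, and chimera rates of this marker are uncharacterized
  here.
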