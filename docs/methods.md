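# Methods

## Binding-site model

A guide RNA is modelled as a protospacer (5′→3′ DNA string, length
11, 15 or 20 nt) plus a PAM pattern (IUPAC, default `NGG`, SpCas9
convention). A binding site is a genomic interval, on either strand,
where the protospacer matches with at most *k* substitutions and the
immediately 3′-adjacent PAM matches its pattern exactly. Decisions
that the search pins down:

* **PAM orientation.** The PAM abuts the protospacer's 3′ end; on the
  minus strand protospacer+PAM are read on the reverse complement and
  reported in plus-strand coordinates over the protospacer bases only.
* **Genome `N`.** Matches nothing: it counts as a protospacer mismatch
  and fails every PAM position, including pattern `N` (which accepts
  only A/C/G/T). This is the conservative choice for assembly gaps.
* **No bulges.** Insertions/deletions are not modelled; the repeat
  arrays of interest are recovered by substitution-tolerant matching
  alone.
* **Overlaps.** Every genomic offset is scored independently. This
  matters for short-period tandem repeats (e.g. a 10-bp-period
  pericentromeric repeat), where a 20-nt guide matches at every period
  offset and the biologically meaningful count is the number of
  bindable positions, not the number of disjoint matches.
* **Cumulative tiers.** The site set at budget *k* is a superset of
  budget *k−1*; reported per-tier counts are cumulative, so they are
  non-decreasing in *k*.
* **Determinism.** Output is sorted by genome chromosome order, then
  start, then strand (`+` before `−`), so runs are byte-reproducible.

Trimming a 20-nt protospacer to 15 or 11 nt keeps the PAM-proximal
(3′) suffix — the only choice under which the shorter guide binds the
same PAM-adjacent positions.

The scanner is vectorised (per-position mismatch accumulation over
numpy byte arrays, O(L·n) per chromosome/strand); the test suite holds
it to exact agreement with a naive sliding-window oracle on random
genomes at budgets 0–2.

## Repeat discovery

Sites (exact matches only) are assigned to fixed 10-kb bins anchored
at coordinate 0 of each chromosome — the bin phase is a convention,
not data-driven — by their start coordinate. Maximal runs of adjacent
occupied bins form binding clusters; a guide's *target cluster* is the
cluster with the most sites (ties broken by genomic order, for
determinism). Three successive filters with strict thresholds follow:
some chromosome with > 500 sites, some cluster with > 500 sites, and
no non-target-chromosome cluster with > 40 sites. The thresholds
reflect the empirical finding that ~1,400 binding sites suffice to
nucleate an ectopic kinetochore while 44 do not, with > 500 chosen as
a permissive lower bound and > 40 as the specificity cap; all three
are parameters.

During genome-wide discovery, identical protospacer sequences are
collapsed to one query (a 600-copy array would otherwise yield 600
identical guides), and the protospacer enumeration itself serves as
each unique sequence's exact-match site list — an occurrence of a
protospacer *is* an exact site of that sequence, which turns the
all-guides-vs-genome search into a single grouping pass.

Target clusters of passing guides that share ≥ 1 bp merge
transitively into targetable repeats; abutting half-open intervals do
not merge. A repeat is *centromeric* if it shares ≥ 1 bp with a
centromere annotation or a CENP-A peak. The
pericentromeric/telomere-proximal subclass for noncentromeric repeats
has no canonical definition; the default rule (nearest feature by Mb
distance wins) is advisory and can be disabled. Distances are
edge-gap distances in Mb rounded to one decimal; telomeres are taken
as positions 0 and the chromosome length.

## Nonclonal CNA quantification

Inputs are per-cell integer copy-number states on a shared fixed-width
bin grid (default 500 kb; chromosome-terminal bins may be shorter).
The pipeline assumes the upstream caller's states are integer ploidy
levels and performs no re-segmentation below bin resolution.

* **Median reference.** Per bin, the median across control cells, with
  the *lower* median for even counts so states stay integer. This
  absorbs the clonal karyotype of heterogeneous lines (e.g.
  near-triploid HEK293T) into the baseline.
* **Relative segments.** Per cell, maximal runs of equal nonzero
  `state − median` within one chromosome. Reference plus deltas
  reconstructs the profile exactly (tested as a round trip).
* **Widespread-aneuploidy exclusion.** Cells whose altered-bin
  fraction strictly exceeds a threshold (default 0.5, configurable and
  logged) are excluded — such cells indicate a diverged karyotype
  rather than discrete induced events. The threshold is a run
  parameter; no canonical value exists.
* **Clonal events.** Control segments with the same chromosome and
  delta sign group when their reciprocal overlap is ≥ 50% of *both*
  lengths; events are connected components of that relation and must
  be supported by ≥ 4 distinct cells. Reciprocal overlap is the
  default denominator convention; one-sided variants
  (`overlap_mode="query"/"subject"`) are provided because the
  convention is not uniquely determined by the procedure's description.
  The support requirement is expressed as a cell count (`min_cells=4`)
  rather than a fraction, since a fraction is ambiguous across control
  sets of different size.
* **Masking.** A test segment is removed whole when a same-sign clonal
  event on its chromosome overlaps it at the same threshold; no
  partial trimming. Masking can alternatively compare against the raw
  supporting control segments (`against="segments"`) instead of the
  collapsed event hull — the hull is wider, so segment mode is the
  stricter matching of the two; both are provided.
* **Span and size classes.** Surviving segments spanning ≤ 1 Mb are
  dropped (this also removes isolated single-bin miscalls on the
  500-kb grid). Strict inequalities partition the rest into large
  (> 20 Mb) and small (< 20 Mb) CNAs; a segment of exactly 20 Mb falls
  in neither class, as the class definitions are strict on both sides.
* **Quantification.** Large CNAs are reported per chromosome as
  CNAs-per-cell; small CNAs are split into those overlapping the guide
  locus ± 0.5 Mb by ≥ 1 bp vs the remainder of the genome. Condition
  comparisons use a Pearson chi-squared (1 df, no continuity
  correction) on the 2×2 table [[CNAs_a, cells_a], [CNAs_b, cells_b]];
  a zero expected count raises an error rather than returning a
  meaningless statistic. The contingency construction (single
  chromosome vs pooled) is the caller's choice: the function takes
  counts, not segments.
* **Control composition.** Controls for a test condition should be all
  conditions in which the test guide was not used; the CLI takes an
  explicit control-condition list and echoes it to the log.

## Synthetic data

`simulate_repeat_genome` plants tandem arrays (unit = protospacer +
PAM, optional spacer, per-base divergence applied with the seeded
generator) into random background sequence at a stated GC fraction
(default 0.41, the human genome-wide average). The truth table's
exact-site count is computed by direct string scan of the constructed
array (both strands, overlaps included), independent of the search
implementation it is used to test.

`simulate_cell_population` composes, per cell: a base integer
karyotype, clonal CNAs (all cells), subclonal CNAs (independent
Bernoulli per cell), at most one induced segmental aneuploidy with
probability `event_rate` — its proximal breakpoint drawn uniformly on
bin boundaries between the guide locus and the centromere, the segment
running to the chromosome end on the locus side, mimicking breakage of
a pseudodicentric chromosome between its two attachment sites — and
per-bin ±1 miscall noise. Noise skips bins already altered by a
planted event so that every nonzero bin has exactly one labelled
cause in the truth table. Default study conditions used by the
acceptance script: 200 cells, six 100-Mb chromosomes, near-triploid
base, event rate 0.4 (matching the observed ~40% transfection
efficiency), noise 0.002 per bin.

What the generator does *not* emulate: GC- and mappability-driven
bin-level bias, correlated noise from amplification artefacts,
replication-timing structure, breakpoint microhomology, and multiple
induced events per cell (multiplicity is configurable but defaults to
one). Passing tests therefore demonstrate correctness of the
*post-calling* logic under an idealised caller, not robustness to raw
single-cell sequencing artefacts.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale: 100–400 kb synthetic
genomes for search/discovery (where the exhaustive oracle is exact and
affordable) and 200-cell populations on a 600-bin grid for the CNA
pipeline. Rate-recovery checks use a ±0.07 band around the planted
0.4 (≈2 binomial standard deviations at n=200) and ±0.02 for
zero-background chromosomes. Genome-scale discovery (3.1 Gb, three
guide lengths) uses the same code paths; only the grouping pass's
memory (one entry per PAM-adjacent window) is size-sensitive, and a
per-chromosome streaming run is the practical layout at that scale.

## Known limitations

* Guide-level reporting covers passing guides only; per-guide failure
  reasons are available via `apply_guide_filters` but the discovery
  driver does not tabulate the (very many) failing sequences.
* The clonal-event union hull can chain through intermediate segments
  (connected components), so an event's interval may exceed any single
  supporting segment; masking in `against="events"` mode inherits
  that width.
* Distances are reported to 0.1 Mb; sub-100-kb geometry near
  annotation edges is below the report's resolution.
* The chi-squared comparison treats cells as independent and CNA
  counts as Poisson-like; it is a screening statistic, not a
  mixed-model analysis.
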