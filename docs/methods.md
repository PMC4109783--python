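# Methods

## Restriction maps and qualification

A sequence is digested in silico by locating every occurrence of the
enzyme's recognition site (SwaI's palindromic ATTTAAAT by default,
cutting at offset 4) and taking consecutive differences of the cut
positions; overlapping occurrences all count, windows containing N
never match (an ambiguous stretch may or may not harbour a site, and
guessing would plant phantom cuts). Coordinates are 0-based half-open
internally; 1-based conversion happens only in GFF3/AGP emission.

A scaffold map *qualifies* for alignment when at least three internal
fragments (ends excluded) are ≥ 0.4 kb — below that size optical
measurement does not reliably resolve a fragment. In the filtered map
used for alignment, each sub-threshold internal fragment is merged into
its left neighbour, a deterministic tie-break that preserves total
span; end fragments are left untouched because they are already
truncated by the sequence boundary rather than by cuts.

Map resolution is total span over fragment count, in kbp — the average
distance between resolvable cuts.

## Alignment model

Optical fragment sizes carry multiplicative error (coefficient of
variation `sizing_cv`, default 0.03), some true cuts go unobserved
(neighbouring fragments merge) and spurious cuts appear. Alignment
therefore matches *blocks* — up to `max_merge = 4` consecutive
fragments a side — scored as a cut-match bonus (3.0) minus a Gaussian
sizing term on the block-sum difference, scaled by `sizing_cv · Σt`,
minus unit penalties per unmatched cut inside the block. The sizing
term is the log-likelihood of the size discrepancy under the
multiplicative error model, up to constants; penalties are fixed
charges rather than fitted rates, which keeps scores comparable across
map densities.

The dynamic program finds the best chain of blocks placing the scaffold
map within an optical contig (both orientations; ties broken toward
fewer blocks, then the smaller optical start, then forward). Scaffold
ends may remain unaligned: free where the alignment abuts an optical
contig end (the scaffold genuinely extends past the mapped region), at
`clip_penalty = 0.2` per fragment elsewhere. Interior clipping is
essential: each half of a chimeric scaffold aligns to the interior of a
different map contig, with the foreign half clipped. Unaligned tails
are reported as overhangs in base pairs.

Two score thresholds matter. An alignment is *reported* at
`min_score = 6`; it is *placement-grade* — usable as bridging evidence
— only if it is end-anchored (reaches within one fragment of an end of
either map), scores ≥ 9 and covers ≥ 70% of the scaffold's fragments.
The thresholds were calibrated on simulation by separating the score
distribution of true placements from the best wrong-map alignments
(spurious chains reach scores of ~8–13 but rarely cover a scaffold
densely); the two-tier design mirrors the practice of validating with
permissive alignments while bridging only with high-quality ones.

## Chimera detection

A scaffold is chimeric when *distinct parts* of it align to two or more
optical map contigs. Implementation: take the best alignment per map,
require at least one confident anchor (score ≥ 9, otherwise the
scaffold is simply unaligned), then admit alignments greedily by score
if each covers a contiguous run of ≥ 3 scaffold fragments not already
explained by stronger evidence. The contiguous-run requirement echoes
the three-fragment qualification rule; plain range disjointness is too
strict because alignments over-extend a fragment or two past a misjoin
junction, and plain map counting is too loose because spurious
secondary hits re-align fragments the primary alignment already covers.
Chimeric scaffolds are excluded from joining and pass through as
singletons; they are reported, not broken.

## Megascaffolding

Placement-grade alignments are filtered to end-anchored ones; a
scaffold aligning to several maps is assigned to the largest map among
those scoring within 3.0 of its best (map size arbitrates comparable
placements only — without the margin, a large map's marginal hit can
outrank a decisively better alignment). Each optical map with two or
more placements forms a bridge; placements are ordered by optical
position and neighbour gaps taken from optical coordinates.

Neighbours are joined greedily left to right when (1) the two facing
overhangs total ≤ 2 Mbp, (2) the gap estimate is < 2 Mbp, and (3) the
facing overhangs physically fit inside the gap plus a 10 kb sizing
slack — unaligned tails occupy the unmapped interval between aligned
regions, so tails longer than the gap would overlap the neighbour's
aligned sequence, the signature of a spurious tail such as the foreign
half of an undetected chimera. Gap estimates of zero or below (down to
a 50 kb overlap, beyond which the join is refused) become a flagged
100 bp sentinel gap, the common convention for inferred overlaps.
Megascaffolds serialise as AGP v2.1 (gap rows of type `map`, linkage
`no`) and gapped FASTA with reverse-complemented reverse components;
accounting reports scaffold counts and N50 before and after, which are
asserted non-increasing and non-decreasing respectively.

## QC metrics

* **Nxx** — smallest length L such that elements ≥ L hold ≥ x of total
  bases; contigs are derived by splitting scaffolds at N-runs ≥ 10 bp
  (configurable; registry convention, and "gap" is otherwise
  ill-defined).
* **Gene territories** — gene span ± 10 kb flank, clipped to the
  scaffold, strand-independent. A gap counts toward a territory when
  the intervals intersect; a gap spanning several territories counts
  once per territory.
* **Exon conservation** — exact 11-mer seeding (both strands) groups
  hits by diagonal; candidate windows are locally aligned with
  Biopython's PairwiseAligner (match 1, mismatch −1, gap open −2,
  extend −0.5). Identity is matches over aligned columns including
  gaps; coverage is aligned exon bases over exon length; conserved
  means identity > 0.86 AND coverage > 0.87, both strict. Identity
  carries the 0.86 threshold and length-coverage the 0.87 one.
* **Read summaries** — exact integer sums across platforms; fold
  coverage is total bases over an assumed genome size (1.23 Gbp
  default). Average sizes are reported both exact and rounded half
  away from zero, since published tables round inconsistently.
* **Percentages** — computed in decimal arithmetic with explicit
  round/truncate modes (e.g. 3,165/3,288 truncates to 96.25%).

## Simulator

The generator emulates the study conditions end to end:

* **Genome** — uniform random A/C/G/T with sites planted at
  exponential spacings. The planted rate is thinned by the background
  occurrence rate 4⁻⁸ so the *total* cut density is one per
  `mean_site_spacing` (14 kb default); background occurrences stay and
  the recorded truth is the realized cut list, so a digest recovers it
  exactly.
* **Optical maps** — the genome is split into `n_map_contigs`
  contiguous contigs with boundaries snapped to true cuts; interior
  cuts drop with probability 0.10, false cuts arrive as a Poisson
  process at 10⁻⁵ per bp, and each fragment is scaled by lognormal
  noise with CV 0.03 (mean 1). With all noise at zero the optical maps
  equal the in silico maps fragment for fragment.
* **Scaffolds** — Normal(75 kb, 15 kb) tiling with exponential 5 kb
  unsampled inter-scaffold gaps, random 50/50 orientation, Poisson
  internal N-gaps (10⁻⁵ per bp, exponential 2 kb lengths, sequence
  replaced so length is preserved). Defaults give ~120 scaffolds on
  the 10 Mb benchmark genome. A 5% fraction of the final set is
  chimeric: two scaffolds from different map contigs concatenated.
  Chimera parts are drawn from scaffolds with ≥ 9 resolvable
  fragments: a misjoin between stretches invisible to the optical map
  is undetectable by construction and outside the method's domain, so
  planting it would only measure the map's resolution limit, not the
  detector.
* **Annotation** — non-overlapping genes (2–15 kb, 1–10 exons of
  30–300 bp) placed uniformly, scaffold choice weighted by length.
* **Determinism** — every draw comes from one seeded NumPy PCG64
  generator; a seed reproduces the dataset exactly.

### Evaluation semantics

A predicted join (consecutive megascaffold components) is *correct*
when the two scaffolds' relevant true intervals on the bridge's map
contig are in genome order with their true orientations; joins need
not be immediate, since megascaffolding legitimately bridges across a
scaffold it could not place. Join *recall* is measured over true
adjacent pairs whose members were both placed on their true map —
i.e., recall of the bridging stage given the placements; alignment
placement success is asserted separately (≥ 90% of well-fragmented
scaffolds top-score on their true map). Chimera sensitivity is
detected over planted; a non-chimeric scaffold that genuinely spans a
map-contig boundary (≥ 10 kb on each side) truly is aligned to two
contigs, so flagging it is tallied separately from false positives.

### What the simulation does and does not show

The simulator exercises sizing error, missing/false cuts, orientation
recovery, partial alignments, chimeras and gap estimation — the
mechanics the method depends on. It does not emulate repeats,
GC-dependent digestion bias, segmental duplications, heterozygosity or
correlated sizing error along a molecule; real genomes will produce
more ambiguous placements than random sequence does, so simulated
precision/recall are upper bounds on real-data behaviour, useful mainly
for regression testing and threshold calibration. Problem sizes in the
test suite (10 Mb genome, 8 map contigs, ~120 scaffolds for the noise
benchmark; 5 Mb, 4 contigs for the noise-free identity check) are the
package's chosen desk-scale study conditions.

## Known limitations

* Under default noise a small scaffold occasionally aligns better to a
  wrong locus than to its own; across non-benchmark seeds join
  precision ranges ~0.85–1.0. The caps and the tail-fits-in-gap test
  remove most such joins but not all.
* Chimeras are detected, never broken; junction localisation is out of
  scope.
* A single enzyme per run; nicking enzymes and methylation sensitivity
  are unsupported.
* Alignment significance is score-thresholded, not p-valued; the
  thresholds are calibrated for ~14 kb maps and 3% sizing CV and should
  be re-calibrated for substantially different map densities.
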