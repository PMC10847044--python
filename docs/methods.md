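# Methods

## The inference problem

Multisegmented RNA viruses carry (nearly) identical sequences at the 5′
and 3′ ends of all genome segments on the coding strand.  FLDS library
construction preserves those physical ends: the dsRNA molecule is
fragmented, a known adapter (U2) is ligated to the 3′ end of both strands
of every fragment, and reads are taken from fragment ends.  Two
consequences drive the pipeline:

* every molecule copy contributes fragments whose outermost boundaries
  coincide with the true segment termini, so read alignments accumulate
  start/stop pileups at exactly those coordinates;
* a read that sequences through its fragment runs into the adapter, so
  adapter trimming restores the exact fragment sequence and terminal
  alignments are not smeared.

Segment termini are therefore *called*, not assembled, and complete
segments are grouped into virus genomes by terminal-sequence conservation
rather than sequence homology — which is what makes the approach work for
viruses with no detectable similarity to anything known.

## Stage models and parameters

### Adapter trimming (`preprocess`)

Semiglobal suffix-overlap matching: the read is cut at the leftmost
position where a prefix of U2 (`GACGTAAGAACGTCGCACCA`) or U2-comp
(`TGGTGCGACGTTCTTACGTC`; reads come from both cDNA strands) matches the
remainder of the read with overlap ≥ `min_overlap` (8 nt) and mismatch
rate ≤ `max_mismatch_rate` (0.1).  Trimming is iterated to a fixed point,
making it idempotent.  Reads < 50 nt after trimming are flagged and
excluded downstream.  Full Smith–Waterman is unnecessary because FLDS
adapters are 3′-anchored by construction.  A pigeonhole prescreen
(`str.find` on exact adapter blocks) accelerates the scan without
changing its result.  The quality filter defaults (mean Phred ≥ 20,
length ≥ 50) are conventional and configurable; the original trimming
pipeline's exact rules are unpublished, so this module documents its own
rules rather than claiming equivalence.

### Alignment and stop profiles (`align_pileup`)

Standard SAM is ingested with pysam (primary, mapped records only; SAM
1-based coordinates converted to 0-based half-open).  The built-in mapper
— exact 21-mer seeds, gapless extension, mismatch rate ≤ 5 %, multiple
seed offsets to tolerate errors — is intended for low-error synthetic
reads; real data should use an external aligner and the SAM path.
Multi-mapping reads are discarded rather than placed randomly, because
terminus calling is count-based and random placement could fabricate stop
signals.  Alignments are clipped at contig boundaries with the clip
recorded, so a read running off a segment end still registers a stop at
the end; clip-derived stops count only at contig boundaries.  Stop
profiles store per-position alignment starts, ends (at the exclusive
coordinate) and coverage; the conservation identity
Σ coverage = Σ aligned length is asserted on every profile.  Strand-aware
stop semantics are collapsed to contig coordinates because FLDS reads
derive from both strands of the duplex.

### Terminus calling and completeness (`segment_calling`)

A position within `end_window` (50 nt; the window quantifies "near the
contig end" and is configurable) of a boundary is a terminus iff

* stop count **strictly greater than** `min_stop_reads` (10), and
* dominance = stop count / local coverage ≥ `min_dominance` (0.2).

The dominance test supplements the absolute count to suppress chance
pileups under very high coverage; the count threshold alone is
scale-free and would fire on noise at 10,000×.  At most one call per
side: highest stop count, ties to the position nearest the boundary.
Internal stop pileups (possible subgenomic ends) stay visible in the
profile but never become termini.  Contigs with both termini are
complete; the sequence is trimmed to the called termini.  Status encodes
the missing end (`partial_3` = 3′ end missing).  Complete segments with
mean coverage > 1,000× (strict) are *major*.

### Genome binning (`genome_binning`)

Coding-strand orientation picks the strand whose three forward frames
carry the greater total maximal-ORF length (genetic code 11, ≥ 150 nt),
with the longest single ORF as tie-break; a segment with no ORFs either
way keeps its input orientation and is flagged low-confidence.

Terminal conservation is scored by global alignment
(match 2, mismatch −3, gap open −5, extend −2) of the first and last 30 nt
(`terminal_window`); identity = matches / alignment columns.  Two
segments link when **both** terminal identities ≥ `link_threshold`
(0.6); a 5′-only mode supports virus groups that conserve only the 5′
terminus.  The 0.6 default over a 30-nt window sits well above the
~0.4–0.55 identity that unrelated random termini reach under this
scoring, and well below the near-1.0 identity of true siblings;
it is echoed into the output metadata.  Single linkage reflects the
transitive nature of shared termini; chained merges are a documented
caveat.  Within a bin, members with whole-sequence identity ≥ 0.9
(edit-distance based, via edlib) collapse into one segment class;
distinct classes whose lengths differ < 10 % and whose ORF counts differ
≤ 1 are flagged alternative segments of one another — length and gene
content act as a guard, not a score.  Strain pairing is a greedy maximum
matching over same-sample, different-class pairs ordered by
|log₂ coverage ratio| (≤ `max_log2_ratio`, default 1.0); segments without
coverage are excluded with a warning, unpaired members are reported, and
ambiguous assignments are left unpaired rather than forced.  The terminal
alignment view is a center-star MSA (star = longest member) of the 5′ and
3′ windows with per-column modal-base conservation.

### Annotation (`annotation`)

ORFs: maximal open reading frames on the three forward frames of the
coding strand, starts ATG/GTG/TTG, ending at a stop codon (included in
the coordinates) or at the segment end (flagged `open_3p`); nested starts
are suppressed (longest ORF per stop).  `min_orf_len` = 150 nt (50
codons) is a conventional floor and configurable.  The SD scanner slides
the `AGGAGG` consensus over the upstream window and calls a hit when ≥
`sd_min_match` (4) consecutive bases match at a spacer of 4–14 nt before
the start codon; hits are labelled "SD-like" — this is a consensus
matcher, not a trained RBS model.  The RdRP scan reports all motif C
(`GDD`) and motif B (`SGxxxT`) occurrences, flags B "ordered" when a C
hit lies 10–60 residues downstream, and classifies motif-A candidates
(Asp 80–200 residues upstream of C) as canonical (partner Asp 4–5
residues downstream) or extended (12–14 residues) — the latter being the
unusual arrangement whose detection motivates the A-scan.  Motif-A
localisation is a sequence-window heuristic; structure-based placement is
out of scope.  The TMD flag is the classic Kyte–Doolittle criterion
(19-aa window, mean hydropathy ≥ 1.6), a deliberate lightweight heuristic
rather than an HMM topology predictor.  The bin member with an ordered
B–C pair is labelled the RdRP segment.

## The synthetic-data generator

`simulate_virome` draws, per virus, a 5′ and a 3′ terminal sequence
(25 nt default) by rejection sampling so that *ungapped* pairwise
identity between viruses stays ≤ 0.3 per side — gapped identity of random
termini is intrinsically ~0.4–0.55, so the dissimilarity contract is
defined positionally; the binning linkage threshold (0.6, gapped) is
validated separately on fixtures.  Segments (1.5–6 kb) are gene-dense and
polycistronic: ORF lengths take a Dirichlet split of the length budget
(floors 180 nt, 480 nt for the RdRP ORF so the planted A/B/C motifs fit
at realistic spacings), with random intergenic filler.  Each ORF is
preceded by an in-frame stop codon immediately upstream of its start, so
planted coordinates are exactly the maximal-ORF coordinates the caller
should report.  With probability `sd_fraction` (0.95) an ORF gets
`AGGAGG` at a uniform 4–14 nt spacer; for SD-free ORFs the upstream
window is resampled until no chance ≥ 4-base consensus run remains at a
valid spacer — otherwise roughly one in eight "SD-free" labels would be
wrong and recovery tests would measure label noise, not detector error.
One ORF per virus (on its first segment) encodes a protein carrying the
extended-motif-A RdRP signature.

`simulate_flds_reads` models library construction per molecule copy:
fragment lengths ~ Normal(1,500, 300) floored at the read length, cut
sequentially from the 5′ end; the remainder at the 3′ end becomes its own
terminal fragment when ≥ 50 nt (sub-minimum remainders merge into the
previous fragment).  Terminal fragments shorter than a read are the
reason adapters appear inside reads.  Both strands of each fragment yield
one read: strand sequence + U2, truncated to 300 nt, with i.i.d.
substitutions at `error_rate` (indels optional, default off — this keeps
the gapless built-in mapper adequate and the terminus signal crisp).
Copy number is set so that expected read coverage matches the requested
depth.  `terminal_capture_rate` (default 1.0) lets a fraction of molecule
ends lose their exact terminus, emulating imperfect end retention through
cDNA synthesis; `molecule_ranges` restricts a segment's molecule
population to a sub-interval, the mechanism behind the truncated-end
negative controls.  Per-segment depth jitters ×2^U(−0.3, 0.3) around the
virus depth, keeping same-strain segments within the pairing tolerance
while distinguishing strains at different abundances.

What the generator does **not** emulate: rRNA/host background reads,
chimeric fragments, PCR duplicates, coverage bias along the segment,
quality-score degradation, and ssRNA-library artefacts.  Passing
recovery tests therefore demonstrate correctness of the inference rules
under the declared generative model, not robustness to every failure mode
of real libraries; the SAM ingestion path exists precisely so real data
can bring its own aligner.

## Numerical and procedural choices

* All randomness flows through one `numpy.random.Generator` per entry
  point, seeded from `SimParams.seed`; identical parameters give
  byte-identical FASTQ/FASTA/TSV output.
* Clustering is order-invariant: segment ids are sorted before
  union-find, and the smaller root id wins merges.
* Dominance is capped at 1 by flooring local coverage at the stop count
  (a stop's own reads always cover the adjacent base).
* Degenerate inputs: empty truth sets produce valid empty fixtures;
  header-only tables; an empty alignment set gives an all-zero profile;
  single-member bins raise on the terminal-alignment view; segments
  shorter than the terminal window shrink the window and record it.
* Test and acceptance problem sizes — 5 viruses × 2–3 segments at 200×
  over 10 seeds for terminus recovery, 3 × 5-virus bipartite fixtures for
  binning, 100/1,000/1,000 random instances for the oracle-equivalence
  checks — were chosen to make the binomial noise on each recovery
  fraction small relative to its acceptance margin while keeping the full
  suite fast.

## Known limitations

* The built-in mapper is gapless and exact-seeded; indel-rich or
  high-error data must come through the SAM path.
* Single-linkage binning can chain distinct viruses that share termini
  with a common intermediate; the terminal alignment view is provided for
  manual inspection of exactly this case.
* Strain pairing is a heuristic matching; when several variants co-occur
  at similar abundance the assignment is genuinely ambiguous and members
  are left unpaired rather than forced (mirroring the underlying
  biology, where terminal similarity alone cannot resolve strains).
* The SD and TMD detectors are declared conventions, tuned for the
  simulator's planted signals; on real genomes a trained gene caller and
  a topology predictor will disagree in edge cases.
* ORF counts on real contigs include chance ORFs in non-coding regions;
  counting conventions (minimum length, open ends) materially affect
  per-segment ORF tallies.
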