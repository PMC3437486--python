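# Methods

`tusmine` re-implements, as a tested library plus analysis drivers, the
computational pipeline behind a legume transcriptome marker resource: a
transcript assembly (tentative unique sequences, TUSs) is cleaned and
classified, mined for simple sequence repeats (SSRs), profiled for
differential expression from fixed-length sequencing tags of two
genotypes, scanned for inter-genotype SNPs, and used to design
intron-spanning (ISR) and conserved-ortholog (COS) markers. Assembly
itself, spliced alignment and similarity searching are consumed as
standard files (FASTA, GFF3, 12-column tabular hits), not re-run.

## Post-assembly cleanup and TUS classes

Reads and TUSs are DNA over {A,C,G,T,N}; other ambiguity codes are
rejected rather than remapped because the SSR and k-mer machinery
assumes a 5-letter alphabet. Terminal poly-A (3') and poly-T (5') runs
of at least `min_run` = 8 nt are removed. A single interrupting base
may be crossed only when at least `10/max_mismatch_per10` further run
bases lie inward of it (default one mismatch per 10 nt), so an isolated
template base adjacent to a tail is never swallowed; trimming iterates
to a fixed point and is therefore idempotent. A sequence is dropped as
low-complexity when one base exceeds 80 % of its length.

TUS classes partition the assembly: `singleton` (one member read),
`high_confidence_singleton` (exactly two members and a depth profile
with zero standard deviation, i.e. both reads span the whole contig —
the only reading under which such a contig is informatically
indistinguishable from a singly sequenced low-expression gene), and
`contig` otherwise. The upstream assembler's preset
(`-p 95 -o 50 -g 3 -y 50 -t 1000`) is recorded for provenance only.

## SSR mining

Detection reports maximal, non-overlapping, perfect tandem repeats of
primitive 1–6-nt units, scanning left to right; at each position the
qualifying repeat with the greatest total tract length wins, with ties
to the shortest unit (so (AT)6 is reported, never the non-primitive
(ATAT)3). Repeat-count minima follow the canonical MISA profile
(mono 10, di 6, tri/tetra/penta/hexa 5). Units are reported exactly as
they occur — AG, GA, TC and CT are distinct — matching how the resource
tallies motifs; a canonical grouping (minimum over rotations and
reverse complement) exists for reporting but is never the default.
Adjacent repeats on one sequence separated by ≤ 100 nt are flagged
compound, transitively; members keep their identity so per-unit counts
are conserved. Class I means a tract of ≥ 20 nt (Temnykh convention;
the source resource uses "Class I" without definition).

Marker candidates must have unit length ≥ 2, a successful primer
design, and a predicted product ≥ 100 bp. The redundancy screen drops a
candidate when any hit against a prior marker source set has
E ≤ 1e-5, query coverage ≥ 30 % and identity > 90 % (identity strictly
greater). Polymorphism information content uses the Botstein formula
PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j², the quantity PowerMarker-style tools
report.

The detector is checked against an independent O(n²·6) brute-force
enumeration oracle on sequences up to 200 nt and must recall 100 % of
planted, isolated, perfect repeats.

## Tag mapping and digital expression

Tags are fixed-length (36 bp). The index stores every forward k-mer of
every TUS plus all half-length windows; a tag placed with ≤ 1 mismatch
matches at least one half exactly (pigeonhole), so candidate positions
come from two seed lookups and are verified directly. Zero-mismatch
placements beat one-mismatch placements; forward and reverse
orientations compete within a stratum, and every equal-best placement
is recorded with its multiplicity. Counting policies: `unique_only`
(default — heavy multi-mapping in the source data is judged an
assembler artifact), `all`, and `fractional` (1/n per placement, so
fractional counts sum to the number of mapped tags).

Counts are normalized per million mapped tags of each library
(CPM = x·10⁶/N). Fold change is log2(cpm₁/cpm₂), defined only when both
libraries detect the TUS; TUSs seen in one library only are classed
exclusive and excluded from fold binning. |log2fc| bins are [0,1),
[1,2), [2,3), [3,4] and (4,∞) — the boundary 4 falls in the
three-to-four-fold bin because the top bin is strictly "more than
four-fold".

Differential representation is scored with the log-likelihood
R-statistic: with pooled rate f̂ = (x₁+x₂)/(N₁+N₂),
R = Σⱼ xⱼ·ln(xⱼ/(Nⱼf̂)), taking 0·ln 0 = 0 (natural log, as the
statistic is defined; fold change stays log2). R = 0 iff the
proportions are equal; R is undefined when both counts are zero. The DE
set is the union {|log2fc| ≥ 2} ∪ {R > 6}, reported with
inclusion-exclusion accounting (|A|, |B|, |A∩B|, |A∪B|). Under an
equal-rate Poisson null with expected counts ≥ 5, the empirical
false-positive rate P(R > 6) is ≲ 0.1 %, comfortably under the 2 %
bound asserted in tests.

## Variant mining

Pileups accumulate base counts from uniquely placed tags per genotype.
The TUS consensus derives from genotype 1, so "allele frequency" is
operationalized as the non-consensus allele fraction among genotype-2
reads, and the depth filter refers to the same read set (the
frequency's denominator). At each position covered in genotype 1 and
with depth ≥ 3 in genotype 2, a non-consensus allele is binned into a
10-row frequency × 4-column depth matrix (rows <0.1, 0.10–0.19, …,
0.90–1.0 with 1.0 in the top row; columns 3–10, 11–100, 101–500, >500).
Candidates additionally require frequency > 0.1 and depth < 500; the
matrix deliberately keeps the below-threshold frequency row and the
above-ceiling depth column, mirroring how the resource tabulates all
binnable positions. Two overlapping confidence tiers are reported
independently: well-supported (frequency ≥ 0.9, depth ≥ 3) and
stringent high-confidence (frequency > 0.60, depth > 10); the tier
label resolves to the stringent one when both hold. Candidates are
written as VCF v4.2 with AF/DP/TIER in INFO.

Indels are out of scope in practice: the 0/1-mismatch ungapped mapper
cannot place a tag across an indel, so no indel candidate can arise,
although the candidate type and VCF writer accept them.

## Primer engine, ISR and COS markers

The primer picker is deterministic and exhaustive: candidate single
primers are every window of length 18–27 passing GC 30–70 %,
homopolymer ≤ 4 and Tm 57–63 °C (nearest-neighbor thermodynamics at
50 mM monovalent salt, 50 nM oligo — Biopython's `Tm_NN`); pairs must
flank the target, differ by ≤ 3 °C and give a product inside the
configured range. The best pair minimizes, lexicographically,
(|Tm_left−60| + |Tm_right−60|, |product − optimum|, left start, right
start), so results are reproducible and testable against a brute-force
all-pairs oracle. Failures carry stable reason codes.

Introns are inter-block genomic gaps of a spliced alignment within
[40, 5000] bp; smaller gaps are treated as alignment indels (the floor
is this package's choice — the source states only the 5000 maximum) and
larger gaps split the alignment without emitting an intron. Alignments
scoring under 50 % of a TUS's best are dropped before design.
Same-genome alignments separated by ≤ 1000 uncovered bp are grouped
transitively into transcribed units (order-invariant). ISR design
places each primer entirely within one exon, spanning ≥ 1 junction; the
genomic product equals the transcript product plus the spanned intron
lengths, an identity asserted exactly in tests.

The COS cascade filters queries through four stages: (1) a hit at
E ≤ 1e-30 in every one of six legume species; (2) identical best-hit
functional annotation across species, after case-folding, punctuation
stripping and removal of isoform/fragment suffixes; (3) removal of
putative paralogs — the source gives no method, so a query is flagged
when any single species shows ≥ 2 distinct subjects at E ≤ 1e-30 with
bitscore ≥ 0.9 × that species' best (documented as an interpretation);
(4) removal of queries matching a prior COS set at E ≤ 1e-5 with query
coverage ≥ 25 %. Per-stage counts are emitted and are monotone
non-increasing by construction. The generic similarity screen
(`filter_hits_cascade`) applies any subset of E-value, identity,
alignment-length and coverage thresholds; the genomic-survey-sequence
screen is this filter at E ≤ 1e-10, alignment ≥ 70 nt, identity ≥ 80 %.

## Synthetic data and what it shows

The generator emulates the study's inputs at desk scale: 500 TUSs
(log-normal lengths, mean ≈ 450 bp, clipped to 150–1200 bp, matching
the resource's reported averages), ~40 planted SSRs (one per host TUS,
flanks chosen so tracts are exact and non-extendable), 10 % of TUSs
with poly-A tails, 30 intron-bearing genes (2–4 exons, introns
80–2000 bp) plus linked/unlinked single-exon pairs around the 1000-bp
merge boundary, 60 homozygous planted substitutions, and two 100 000 ×
36-bp tag libraries with log-normal abundances (σ = 1), symmetric
planted log2 fold changes (±2.5, ±3, +1), a handful of
exclusive-to-one-library TUSs, and a 1 % uniform per-base error rate.
Ortholog hit tables are constructed directly with controlled E-values
and bitscores so the cascade's per-stage outcome is known exactly.

All randomness flows from one seed through one generator, so identical
configurations produce byte-identical files. The generator does not
model 454 homopolymer miscalls, quality-dependent errors, assembler
chimeras or multi-mapping gene families; passing tests therefore
demonstrate correctness of the computations under clean planted truth,
not robustness to those real-data artifacts. Library sizes (10⁵ rather
than ~10⁷) were chosen as the smallest scale at which per-position
depths (mean ≈ 15×) exercise every depth bin and the recovery bounds;
full-scale behaviour differs only in counting statistics.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive everywhere (the tabular-hit
convention). Allele-frequency rows use left-closed bands with 1.0 in
the top row. `select_de_set` treats undefined fold changes as
non-members of the fold set but still admits exclusive TUSs through the
R criterion. Empty inputs yield empty outputs (empty histogram, empty
DE set, header-only VCF); an unsorted VCF input is an error rather than
silently re-sorted. Trimming may empty a sequence; the empty record is
returned flagged and the caller decides whether to drop it.

## Known limitations

Multi-library (> 2) R-statistics, imperfect/approximate SSRs, gapped
tag alignment (hence indels), quality-aware trimming and primer
secondary-structure checks are not implemented. The well-supported and
stringent SNP tiers overlap by design; consumers needing disjoint
strata should use the membership predicates, not the single tier label.
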