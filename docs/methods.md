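# Methods

`sap` maps single-end sequencing reads onto a reference with a hash-seeded,
band-restricted Smith-Waterman aligner, calls SNPs with a Bayesian
three-genotype model and InDels with a summed-quality rule, and ships a
simulator + benchmark harness that emulates targeted (exon-capture style)
sequencing with known injected variants.  This note records the model, the
parameters that matter, and the places where the design was genuinely open.

## Mapper

**Seeding.** Each read of length n is cut into m pieces (default m = 7) of
k bp (default k = 15) at offsets s_i = round((i-1)(n-k)/(m-1)); the first
piece starts at 0 and the last ends at the read's end, so pieces overlap on
reads shorter than m*k.  Pieces are looked up in a k-mer index of the
reference: exactly in FastMap mode, with at most one mismatch in SlowMap
mode.  One-mismatch lookup uses the pigeonhole split (each half of the
piece queried exactly, the full window verified against the reference), so
it returns the exact Hamming-distance <= 1 hit set without enumerating the
45 one-mismatch neighbors.  Both strands are searched by additionally
querying the reverse complement of each piece; the index itself stores only
the forward strand, which halves memory at identical results.  Pieces
containing N never seed, and N never matches during scoring.

**Candidate loci.** A hit of piece i at reference position MP_i implies the
read starts at l_i = MP_i - s_i.  Hits on one reference/strand are sorted by
l_i and chain-merged while consecutive values differ by at most the cluster
window (default 30 bp; a larger InDel splits into two loci and the read maps
by its larger side).  Loci supported by fewer than two distinct pieces are
discarded; the rest are ranked by support, then by compactness, then by a
fixed coordinate order for determinism.

**Extension.** A colinear locus (l_min == l_max) is resolved by gapless
column-by-column comparison.  A spread locus indicates an InDel and is
resolved by the banded Smith-Waterman: the DP is computed only on diagonals
l_min - w <= (j - i) <= l_max + w (band margin w = 5 by default), giving
O(n * band) work; a cell counter exposes the bound in tests.  The alignment
is read-global and reference-local with affine gaps (match +1, mismatch -1,
gap open -2, extend -1; a gap of length g costs 2 + (g-1)).  Scoring
parameters are conventional and configurable; the acceptance rule below
depends only on the identity count, which insulates it from the score
scheme.  One refinement: when a colinear locus's gapless comparison either
fails acceptance or shows three or more mismatches inside a terminal 15 bp
window, the read is re-extended with the banded DP — mismatches piled at an
unanchored read end are the signature of an InDel the colinear seeds did
not see, and the gapless alignment would otherwise leak systematic
mismatches into the pileup.

**Acceptance and choice.** With L_map the number of identically aligned
bases, an alignment is kept only if S_map = L_map/n > 0.9 (strict).  Among
accepted candidates the reported placement maximizes the quality-weighted
identity (sum of 1 - P_s(q) over matching read positions divided by the sum
over all positions, P_s(q) = 10^(-q/10) clamped to 0.75); ties fall back to
the deterministic locus ranking.  SlowMap first tries exact seeding and
repeats the search with one-mismatch seeding only for reads that exact
seeding failed to place, which makes it a strict superset of FastMap.
Reads shorter than k are reported unmapped rather than erroring.

## Variant caller

**Pileup.** Accepted alignments are decomposed by CIGAR; M columns
contribute base + quality, insertions attach to the column of the preceding
base, deletions mark every deleted column.  Two hygiene rules keep
alignment artifacts out of the evidence: terminal mismatch *runs* of each
read are trimmed (a run of consecutive mismatches touching an aligned read
end is an unrepresented InDel or clip, not independent base evidence), and
SNP calling is suppressed within 5 bp of any column whose InDel evidence is
supported by two or more reads (gap placement next to an InDel is
ambiguous; this is the usual InDel-proximity mask).

**Genotype model.** At a site with reference base E, let b and b' be the two
most frequently observed bases (b' defaults to E, with count 0, when only
one base is observed; count ties prefer the reference base, then A<C<G<T).
Over the n reads showing b or b' (k of them b):

- P(D | <b,b'>) = C(n,k) (1/2)^n  — the binomial heterozygote, deliberately
  quality-blind;
- P(D | <x,x>)  = prod over those reads of (1-P_s) if the read shows x,
  else P_s/3 (the error is assumed uniform over the three wrong bases).

Priors follow the MAQ convention with r = 0.001: the reference homozygote
gets 1 - r - r^2, the heterozygote r, the non-reference homozygote r^2
(both homozygotes r^2 when neither b nor b' is the reference base).  The
posterior is computed in log space; a site whose maximum-posterior genotype
differs from <E,E> is a tentative SNP.

**Filters.**  A tentative SNP must pass both filters (flag-overridable):

- *depth*: site depth >= Cover/5 (inclusive), with Cover = total aligned
  read bases / reference positions with >= 1 aligned base;
- *score*: the posterior odds of the reference homozygote,
  P(<E,E>|D) / (1 - P(<E,E>|D)), at most 0.01 — i.e. variant posterior
  >= ~0.99, the conventional Q20 consensus-quality bar.  When E is not
  among {b, b'} the reference homozygote is still scored, as an explicit
  fourth hypothesis under which every evidence read is an error.

The score definition deserves a note, because the obvious alternative —
(P_1 + P_2)/P_max over the three genotype posteriors — fails structurally
on data whose true variants are homozygous: at a unanimously non-reference
site the posterior mass splits between <b,b> and <b,b'> until depth ~14
(their prior ratio is r, and the binomial ignores quality), so both SNP
genotypes together can carry ~100% of the posterior while neither
dominates, and the filter rejects a certain variant.  The reference-odds
form measures exactly what the filter is for — confidence that the site is
not reference — and, through the homozygote likelihoods, it is quality
aware: two low-quality strays cannot fake a variant, while one genuine
variant read plus ambiguity about zygosity cannot kill one.

**InDels.** Per read, an insertion event carries the mean PHRED of its
inserted bases; a deletion event carries the mean of the two read bases
flanking the deletion.  Events pool per anchor column (insertions) or per
maximal run of deleted columns (deletions).  A call is emitted when the
summed event quality exceeds half of the mean per-column base-quality sum
over the 10 columns on each side (InDel columns excluded).  The one-half
factor makes the rule a majority test on local quality mass: an event on
one haplotype of a diploid sample can pass, a one-read artifact cannot.
Requiring the full flank mass instead would make even a unanimously
supported homozygous InDel a coin flip (its statistic equals the comparator
in expectation).  Insertions report the most frequent inserted sequence
(a tie reports nothing); deletions report the modal per-read deleted span
within the run, because ragged alignments can stretch the raw run.

## Simulator

The generator emulates the benchmark recipe end to end and is the source of
every dataset the tests and the acceptance script use.

- **Variants**: each base independently becomes a SNP with probability
  2e-4 (alternative uniform over the other three bases) or an InDel anchor
  with probability 9e-5 (length uniform 1-5 bp, half insertions);
  overlapping events are re-drawn.  Truth is recorded in original
  coordinates, and re-applying it to the original reference reproduces the
  mutated sequence exactly (tested).  By default the single mutated copy is
  sequenced (every variant effectively homozygous), matching a recipe that
  mutates one reference copy; a `diploid-5050` model (half the variants
  heterozygous, reads drawn from two haplotypes) is available.
- **Capture targets**: the sequence is partitioned into contiguous regions
  with lognormal lengths (median 1000 bp, sigma 0.75, minimum 200 bp) —
  the scale of exon-capture target intervals.  Each region is cut into
  fragments of uniform length 300-1500 bp, clipped to the region, with
  Poisson counts; the Poisson mean is coverage * |region| / E[min(read
  length, fragment length, |region|)], so one single-end read per fragment
  realizes the requested read coverage.  Because reads come only from
  fragment ends, regions of certain sizes have interior stretches that no
  read can cover; this end-read geometry — not any tuned parameter — is
  what keeps detection coverage below 100% at high depth.
- **Reads**: one read per fragment from a uniformly chosen end (5' prefix,
  or reverse complement of the 3' suffix), clipped to the fragment.  Base
  qualities are drawn per base from a two-level profile, Q30 with
  probability 0.924 and Q6 with probability 0.076, chosen so the
  PHRED-implied mean error is exactly the configured 2%; errors are then
  generated per base at the quality-implied rate (substitution uniform over
  the wrong bases).  Qualities are therefore *calibrated*: errors
  concentrate on low-quality bases, as on a real instrument.  A constant
  quality model (flat Q, flat error rate) is available but mismatches what
  it advertises by construction; with it, coincident same-base errors at
  moderate depth forge high-confidence false SNPs, which no calibrated
  caller should be expected to survive.
- What the simulator does **not** emulate: platform-specific error
  profiles (homopolymer errors, InDel-dominant long-read errors), quality
  decay along the read, PCR duplicates, and any real exon annotation.
  Passing benchmarks on this generator therefore demonstrate the
  pipeline's behavior under idealized substitution-dominated noise, not
  performance on any particular instrument's data.

## Evaluation

Captured fraction = reads with an accepted alignment / all reads (placement
correctness is tested separately with error-free reads, >= 99% of which
must map to their exact origin).  Variant matching is allele-aware for
SNPs (position + alternative base) and, for InDels, requires the same type
and length within +/-2 bp after left-normalization of both call and truth.
Accuracy is TP/P, coverage TP/T, with TP + FP = P and TP + FN = T enforced
as invariants.

## Problem sizes and numerics

The benchmark grid in the test suite runs on a 250 kb synthetic reference
with two replicates per cell; the acceptance script uses 300 kb and three
replicates over the full {75, 150, 1000 bp} x {5x, 10x, 20x} grid.  At
these sizes a cell carries roughly 30-90 true SNPs and 10-30 true InDels,
so coverage/accuracy checks use tolerances that include the binomial
sampling error of those counts.  All randomness flows from
`numpy.random.default_rng` seeded per dataset; identical seeds give
byte-identical FASTQ/SAM/VCF/TSV outputs (tested).  Posterior arithmetic is
done in log space with a single max-shift before exponentiation; error
probabilities are clamped at 0.75 so a q=0 base stays a proper error
probability on a four-letter alphabet.

## Known limitations

- Single-end only; no paired-end flags, no split/chimeric alignments, and
  mapping quality is a constant placeholder rather than a calibrated value.
- The quality-blind binomial heterozygote is kept as specified; its cost is
  absorbed by the reference-odds score filter, but genotype *zygosity* (as
  opposed to variant presence) is unreliable near depth ~10-14 on
  homozygous data.
- InDels longer than the cluster window (30 bp) map by their larger side
  and are not called as variants; the caller targets small InDels (<= ~10
  bp) within the Smith-Waterman band.
- Hash indexing holds the reference and two half-length k-mer tables in
  memory (~30x the reference size); appropriate for exomes and microbial
  genomes, not whole mammalian genomes.
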