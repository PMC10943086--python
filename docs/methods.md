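# Methods

`ncgseek` models a searchable DNA data-storage system: plain text is
compressed into an oligo pool by non-collision grouping (NCG) coding, file
access is simulated through orthogonal PCR primer IDs, keyword search is
simulated as CRISPR-Cas12a collateral (trans-cleavage) fluorescence, and
reading back is simulated as Illumina-style paired-end sequencing with
Reed-Solomon (RS) protection. This note records the models, the defaults
that matter, and the design decisions taken where the scheme left room.

## Text preparation

Input text is normalized to printable ASCII with all whitespace runs
collapsed to single spaces. Each file is segmented into 12–16 character
pairs (24–32 characters, 84–112 nt of payload at 7 nt per pair) by greedy
word packing: words are appended until the 32-character cap would be
exceeded, and the segment is closed at the word boundary. Keeping words
uninterrupted is load-bearing for search — a query must always be contiguous
within a single oligo. Padding uses spaces only; because normalized text
never contains a double space, the decoder can collapse space runs and
recover the input byte-for-byte without per-segment padding metadata. A
word longer than 32 characters cannot be packed and is rejected. The 4-nt
(4-trit) segment index bounds a file at 81 segments (~2.6 KB per file);
larger files must be split upstream.

Each character pair becomes a 16-bit fragment (first character in the high
byte). Printable-ASCII fragments are never zero, which is what lets the
decoder flag a failed column lookup.

## Non-collision grouping

Distinct fragments are packed into groups whose members share no 1-bit at
any position, at most three members per group — a fourth pointer would leave
no base for the filler. The packer is greedy first-fit in first-occurrence
order: deterministic and reproducible, though not guaranteed minimal. With
a 6-trit group index the encoding volume is 3^6 = 729 groups; exceeding it
raises an error advising a second dictionary/reference pool. Pointer bases
traverse the cyclic order ACGT: member of rank *r* in group *g* gets base
(g + r) mod 4, the filler is the next base in the cycle. This produces the
characteristic repeats of ACGT and its shifted permutations down reference
columns, which is also what the palette repair below exploits.

A practical note on capacity: an all-lowercase corpus can never overflow
the volume, because any two lowercase-letter pairs share bits 0x2020/0x4040
and therefore collide, so the group count equals the distinct-pair count,
bounded by 27^2 = 729. Mixed-case or punctuated text creates the
multi-member groups.

## Strand construction

The dictionary is materialized as a 16 × V base matrix (row 0 = most
significant bit; column g = group g: pointer base where the member has a
1-bit, filler elsewhere) and sectioned row-wise into 80-nt pieces, giving
16 × ceil(V/80) reference strands — 144 whenever 640 < V ≤ 720. Columns
beyond V are padded with the cyclic filler of an empty virtual group.
Strand layouts (5'→3'):

    reference: primer(21) | ref index(4) | seg index(4) | payload(80) | RS(12) | primer(21)   = 142 nt
    data:      primer(21) | seg index(4) | units(84–112)              | RS(12) | primer(21)   = 142–170 nt

Group indices are written as base-3 digits under a rotating (Goldman-style)
base mapping: digit *d* selects the (d+1)-th base, in fixed order A<C<G<T,
among the three bases differing from the previously emitted base. Every
field (index or 7-nt data unit) is seeded as if preceded by 'T'. Per-field
seeding was chosen over threading the rotation across fields for two
reasons: a data unit then encodes identically regardless of context, which
is required for a fixed 21-nt crRNA spacer to match it; and a unit can never
start with 'T', so with intra-field rotation forbidding adjacent repeats no
'TTT' (hence no canonical TTTV PAM) can occur anywhere in a data payload,
including across unit junctions. The same 4-trit scheme encodes the 4-nt
reference/segment indices (capacity 81).

## Reed-Solomon layer

Every strand body (indices + payload, primers excluded) is chunked into
6-nt symbols — elements of GF(4096) under the 2-bit mapping A=00, C=01,
G=10, T=11, primitive polynomial x^12+x^6+x^4+x+1 — and two parity symbols
(12 nt) are appended. The code is a shortened generalized-position RS code:
symbol *i* sits at exponent E_i from a fixed list, and the parity checks are
Σ c_i α^{E_i} = 0 and Σ c_i α^{2E_i} = 0.

A plain distance-3 RS code corrects one symbol *or* detects two, but not
both: some two-symbol errors land within distance one of another codeword
and would be silently miscorrected. The target behavior here is stated at
base granularity — correct one erroneous base, detect two — and that is
achievable: the decoder only accepts corrections whose magnitude is a
single-base change (one 2-bit slot), and the position exponents
(0, 1, 3, 4, 6, 7, … — skipping e ≡ 2 mod 3, found by exhaustive pair
screening) admit no codeword whose three nonzero symbols are all
single-base magnitudes. The code's nucleotide-level minimum distance is
therefore ≥ 4: any single substituted base is corrected exactly, any two
substituted bases are corrected (same symbol is impossible to confuse) or
flagged, and silent miscorrection of ≤ 2 base errors is impossible — a
property verified exhaustively by test. The cost is that multi-base
corruption concentrated in one symbol is flagged rather than corrected;
read consensus upstream makes that case rare.

## Primer screening

File IDs are 21-nt primer target pairs drawn from uniformly random 21-mers
and filtered by: homopolymer runs ≤ 3; GC fraction in [0.40, 0.60];
nearest-neighbor melting temperature in [60, 65] °C (SantaLucia unified
parameters as implemented in Biopython `Tm_NN`, 50 mM Na+, 250 nM oligo —
conditions are a package default, stated here because the window is
meaningless without them); longest self-complementary stretch ≤ 10 as a
hairpin/homodimer proxy; Hamming distance ≥ 6 to every query spacer, its
reverse complement, and every 21-nt window of the Illumina overhang
adapters; then a greedy pairwise filter requiring Hamming ≥ 6 and
complementary stretch ≤ 10 between accepted primers. Dimer screening is a
longest-complementary-stretch rule rather than a free-energy fold: the
10-base rule *is* the operational criterion the design targets. About 8–10%
of random 21-mers survive the per-candidate screens, so a 2 000-candidate
run yields on the order of 200 orthogonal primers; the yield scales with
the candidate budget and is reported per stage in the screening log.

## Keyword search model

A query is a pair of 21-nt spacers: the first three data units of the
keyword starting at its first letter, and of the whitespace-prefixed
keyword. Dual spacers cover the two pairing phases a word can occupy. For
five-letter keywords the letter-phase spacer uses the keyword plus its
trailing space (valid in space-separated text); shorter keywords are
rejected. Matching is unit-aligned exact substring search over data
payloads — the biochemistry is simulated at sequence level, with
mismatch-tolerant recognition confined to the similarity scan.

The fluorescence readout is modeled as slope = k·f for frequency f ≤ 20,
and a·log10(f)+b for 20 < f ≤ 1000, with a and b fixed by continuity at
f = 20 and a calibration slope at f = 500 (default 60 units at k = 1; units
are arbitrary fluorescence/min — only ordering and ratios carry meaning, so
tests assert linearity, continuity and monotonicity, not absolute values).
Optional Gaussian noise (seeded) models replicate scatter. Classification
thresholds at the minimum slope over true-target files; non-targets at or
above the threshold count as misidentified, and the error rate divides
misidentifications by total searches. Ties are resolved against the
classifier (a non-target exactly at the threshold is an error), which makes
the degenerate all-equal case behave sensibly; with continuous noise the
choice is measure-zero.

The misidentification similarity scan aligns a spacer globally
(Needleman-Wunsch, gap 1 / mismatch 1 / match 0, computed with edlib)
against every 21-nt window of every strand, primers included, both
orientations, reporting windows under a penalty cutoff of 5 — the candidate
off-target sites behind false-positive searches.

## Sequencing simulation and recovery

Reads are 151-nt paired-end, substitution-only at 1% by default (the
dominant Illumina error mode at its commonly reported rate), with
per-strand Poisson depth. Recovery: mate 2 is reverse-complemented and
merged with mate 1 at the largest overlap ≥ 11 nt with ≤ 1 mismatch per 20
overlap bases; merged strands are demultiplexed on both primer targets
(≤ 2 total mismatches, ambiguity → unassigned); strands are bucketed by
parsed indices and majority-consensused per position; RS then cleans or
flags each consensus. Flagged reference strands get palette repair: a
payload cell whose base falls outside its column's palette — the contiguous
cyclic run of pointer bases plus filler inferred from RS-clean rows — is
replaced by palette candidates until the RS check passes. This exploits the
same ACGT-cycle structure that makes reference strands repeat-prone in the
first place. Index-call errors on single erroneous reads can fabricate
phantom strands; buckets with support below 5% of the best-supported bucket
are discarded. At 40× and 1% error the whole pipeline returns byte-identical
text across seeds; at 0% error it is lossless whenever every strand drew at
least one read.

Dropout analysis follows the subsampling protocol: species are unique
designed strands; reads are attributed to species by merged-strand
alignment (exact, else unique nearest same-length strand within 5%
mismatches); for each coverage in 5×..200× (step 5) a subsample of
coverage × species reads is drawn without replacement, 20 replicates × 3
repeats, after resampling the read set up to 200× if it is smaller than
needed. Dropout is the missed-species fraction; full access is dropout
zero. The minimum coverage for a dropout cutoff (default 1%) comes from a
2-parameter logistic in log-coverage, dropout = expit(a − b·ln c), solved
at the cutoff; the parameterization is a package choice, and recovery of a
known crossing is verified within 5% on synthetic curves.

## Synthetic corpora

The generator emulates the study input: a multi-file ASCII corpus of
space-separated words (default 40 files × 180 words, ~8 000 background
tokens, mirroring the 40-abstract scale) with keywords planted at exact
per-file counts, and an oligo-level frequency series in which strands carry
one, two or five keyword copies (frequencies 1–500, mixture fractions
configurable) for characterizing the slope model. Keywords are validated
against the vocabulary so no background token can fire a search probe;
tests rely on the planted counts being exactly recoverable. The generator
does not emulate synthesis yield variation, PCR amplification bias,
quality-score structure, or indels — conclusions from passing tests extend
to real data only where substitution-dominated errors and near-uniform
coverage hold. Test and acceptance runs use scaled-down corpora (2–3 files
of 30–60 words for round-trip sweeps; one 40 × 180 corpus for the
paper-scale check); the strand format, dictionary and pipeline are
identical at every scale.

## Density accounting

Coding potential divides input bits (8 per character of normalized text) by
payload-plus-index nucleotides; a payload-only variant is also reported, as
published figures are ambiguous about the denominator. Net information
density divides by every synthesized nucleotide, primers and parity
included.

## Known limitations

* The greedy packer and the greedy word segmentation are stated stand-ins
  for unpublished heuristics; dictionary sizes and strand counts for a
  given corpus are reproducible under this package but not guaranteed to
  match other implementations of the scheme.
* The RS generator/primitive polynomial is a package choice; parity bytes
  differ across implementations even though the correct/detect capability
  does not.
* Search matching is exact at unit boundaries; partial-degeneracy effects
  of Cas12a (mismatch tolerance near the PAM-distal end) appear only
  through the similarity scan, not in the counting model.
* fm-to-copies conversion and the slope model treat the reaction as
  well-mixed and unsaturated below f = 1000.
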