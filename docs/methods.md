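# Methods

## The signal model

Randomly fragmented sequencing libraries place fragment ends uniformly
along a DNA molecule, but a *natural* DNA terminus occurs exactly once per
packaged phage genome.  Significantly more reads therefore *start* at a
terminus than anywhere else.  The package quantifies this with, per strand
and position,

* **SPC** — starting-position coverage: reads whose first aligned base is
  at the position (reverse-strand starts are expressed as the top-strand
  position of the read's first base's complement, so they pile up at right
  termini);
* **COV** — read coverage per strand; with paired ends, **fragment
  coverage** counts every base between the two reads of a pair as covered;
* **τ = SPC / COV**, using fragment coverage as the denominator for paired
  data and strand read coverage for single-end data.

At a non-terminus position, if R reads start there on average, about R·F
fragments cover it (F = mean fragment size), so background τ ≈ 1/F — below
3·10⁻³ for typical Illumina inserts (300 < F < 800 bp).  At termini, τ
rises to a class-specific value:

| packaging class            | τ at terminus | geometry |
|----------------------------|---------------|----------|
| 3′ cohesive ends (cos)     | ≈ 1           | end repair resects the 3′ overhang; nothing covers a terminus without starting there |
| 5′ cohesive ends (cos)     | ≈ 0.5         | end repair fills 5′ overhangs, so fragments from the *opposite* terminus also cover the position |
| direct terminal repeat     | ≈ 0.5         | N molecules start at the repeat, N more cover its far edge; the repeat region shows ≈2× coverage |
| pac site (headful)         | ≈ 1/(1+C)     | N/C molecules start at the pac site out of ≈N covering it, C = genome copies per concatemer |
| headful without pac, Mu    | none          | circularly permuted / host-flanked molecules leave no start bias |

Two derived quantities: the signal size **T/R** (reads starting at the
terminus over the mean background start rate) is expected to equal F for a
fixed terminus — a markedly smaller value flags inefficient end capture
(e.g. poor adapter ligation at cohesive ends) or alternative termini — and
for pac phages the concatemer size is **C = 1/τ − 1 = F·R/T − 1**.

## Mapping

Only read *start positions* matter, so the internal mapper aligns the
first S bases of each read (default S = 20) by exact match against the
reference and its reverse complement.  Reads with no seed hit go to an
unmapped pool reused for host analysis; reads with more than one hit are
discarded from the profiles and tallied, because a wrong start corrupts
the peak signal.  The reference is treated as linear: reads spanning a
circular junction simply fail to map.  Proper pairs (unique, opposite
strands, forward mate leftmost, insert ≤ 2000 bp) yield fragments; improper
pairs still contribute their reads to SPC/COV.  Quality scores are ignored
(no quality-dependent step exists in the model).  There is no
mismatch-tolerant mode: the method targets clean phage re-sequencing data,
and the simulator is mutation-free by default.

## Calling significant termini

To be robust to uneven coverage (collapsed duplications, mis-assemblies),
the genome is first partitioned by a regression tree fitted to fragment
coverage (squared-error splits, max depth 4, minimum leaf 500 bp; both
config-exposed).  Within each segment a gamma null is fitted to the SPC
values at covered positions by the method of moments (shape = mean²/var,
scale = var/mean), excluding the top 0.1 % of values so genuine peaks do
not inflate the null; zero variance falls back to shape = mean, scale = 1,
and segments with fewer than 30 covered positions inherit the whole-genome
fit.  Per covered position the upper-tail gamma probability of the observed
SPC is adjusted across the strand (Benjamini–Hochberg by default,
Bonferroni selectable).  Positions with adjusted p < 0.01 are candidate
termini; candidates whose adjusted p is also below 1/G are merged when
within 20 bp of each other (both thresholds configurable; merging absorbs
terminases that cleave at several nearby positions).  A merged peak reports
the position of its highest member, the summed SPC, and τ recomputed with
the summed SPC.

Method of moments was chosen over maximum likelihood because it is
closed-form, deterministic, and — once trimmed — robust enough for a null
that only has to rank extreme outliers.  p-values are computed at covered
positions only; zero-coverage positions carry τ = 0 and are excluded from
background statistics.

## Classification rules

Peaks with τ > 0.1 drive the decision tree, applied in order:

1. **Multiple** — a strand with more than one significant peak and none
   above τ = 0.35 (e.g. a reference with the terminal repeat assembled at
   both ends).
2. **Both strands**: the distance between the top peaks separates cohesive
   ends from repeats at 20 bp (longest known cohesive overhang 19 nt,
   shortest known terminal repeat 131 bp).  The distance is evaluated
   *circularly*, because an assembler that opens the genome exactly at the
   cos site leaves the two peaks at opposite contig edges.  Within 20 bp:
   cos — 5′ if the forward peak precedes the reverse peak (going rightwards
   on the circle), 3′ otherwise.  Beyond 20 bp, with forward peak left of
   reverse and inter-peak fragment coverage at least 10 % above the rest of
   the genome: a direct terminal repeat (short/long split at 1 kb; the
   known short repeats are ~130–440 bp, the long ones >10 kb, so any
   boundary between is serviceable).  The genome average in the 10 % test
   excludes the inter-peak region itself, which would otherwise dilute the
   test.
3. **One strand**: headful packaging from a pac site; the peak strand is
   the packaging orientation and C = 1/τ − 1 (averaged with the F·R/T − 1
   form) estimates concatemer size.
4. **No peaks**: Mu-like vs headful-without-pac, decided by hybrid
   fragments (below); with no host genome supplied the call is unknown,
   with an advisory that a complete genome with no signal suggests T4-like
   packaging (protein-capped termini would also leave no signal).

τ thresholds are applied to merged-peak τ.  A cos/DTR call whose peaks
both sit below τ = 0.35 carries a note that unpackaged-DNA contamination
(or a novel mechanism) may be depressing τ.

The junction sequence is reported as the closed 1-based interval between
the two peak positions (wrapped around the origin when the termini sit at
opposite contig edges).  For 5′ cohesive ends this is exactly the shared
overhang; for 3′ ends the reads no longer contain the resected overhang,
so the interval — which brackets the overhang plus the two terminal
bases — is taken from the reference.

## Hybrid fragments, Mu-like phages, transduction

A phage fragmented into ~G/F pieces yields two pieces straddling a
phage/host junction when its termini are host DNA (Mu-like), and a
straddling fragment is only detectable if both sides are at least seed
length S, giving the corrected expectation **2(F − 2S)/G** (F replaced by
the read length for single-end data, where the two seed-length read ends
are classified instead of the two mates).  Observing at least half the
expectation calls Mu-like; a positive but lower rate is annotated headful;
zero hybrids means unknown.  Reads are assigned with phage priority — a
read mapping uniquely to the phage counts as phage even if the host carries
the prophage.  Mu termini are estimated as the 2.5th/97.5th percentiles of
the phage-side positions of hybrid fragments; short reads cannot size the
host flanks themselves.

The fraction of reads mapping only to the host is reported as a
generalized-transduction proxy (valid only for capsid preparations free of
host DNA contamination, which the report states).  Host-side hybrid
positions are binned (500 bp); a bin exceeding five times the uniform
expectation with at least 10 fragments flags a putative attachment site —
specialized transduction and prophage contamination are not
distinguishable from these data.

## The simulator

The generator produces the packaged molecules of each class directly (the
table above), then fragments and sequences them:

* **cos/DTR geometry.**  The reference is emitted rotated so the termini
  sit internally (default G/4), emulating assemblers that place the cos
  junction at an arbitrary position when contaminating circular DNA spans
  it.  A filled 5′ overhang appears as one extra terminal copy of the
  overhang (making 5′cos generatively a 12-bp terminal repeat, which is
  exactly why both share τ = 0.5); a resected 3′ overhang appears as a
  coverage gap.  A `duplicated_repeat` variant reproduces the
  repeat-at-both-contig-ends assembly failure.
* **Headful packaging** cuts concatemers of C genome copies processively
  into C headfuls of G·(1 + u) bases with per-headful overshoot
  u ~ Uniform(0.02, 0.10).  The overshoot is randomized per cut because a
  fixed value would place every second cut at the same genome offset and
  fabricate deterministic secondary termini; the processive-C model is what
  makes the 1/(1+C) expectation hold exactly.
* **Fragmentation** draws sizes ~ Normal(F = 400, sd = 60) truncated at
  the read length until they overshoot the molecule, then rescales them to
  an exact partition (≲2 % size distortion at ~100 fragments per molecule).
  Naive sequential chopping would leave a uniform-length runt at the right
  end whose frequent loss (runt < read length for ~¼ of molecules) biases
  τ at 5′cos/DTR right termini down to ~0.43; rescaling keeps both
  terminal fragments ordinary draws.
* **Reads**: 100 bp, constant quality, no sequencing errors by default
  (an optional uniform substitution rate exists); paired reads are the two
  fragment ends, single-end reads come from a random end of each fragment.
  Optional spike-ins: circular-DNA contamination (fragments drawn uniformly
  from the circular genome, filling the cos gap and doubling inter-terminus
  coverage), host-only fragments, and a transposase-library mode that
  discards terminal fragments (after which no termini are detectable, as
  with real tagmentation data).
* Mu molecules carry one short (40–60 bp) and one long (1.5–2.5 kb) host
  flank, drawn from random host positions, or adjacent to the insertion
  site when a prophage-carrying host is requested.

Everything is driven by one seed through independent per-stage
sub-streams; identical scenarios and seeds give identical libraries.  Each
read's true origin and strand are logged, which is what the mapping and
profile oracles in the test suite check against.

What the simulator does **not** emulate: sequencing errors and quality
profiles, PCR duplicates, GC/coverage bias, adapter read-through, real
terminase sequence preferences, or imperfect end repair.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
generative model, not robustness to every artifact of real libraries —
though the regression-tree segmentation and the trimmed gamma null are
precisely the components designed to absorb real-data unevenness.

## Problem sizes and numerical choices

The default verification conditions are a 40 kb genome, 10⁴ paired
fragments (~100× fragment coverage), F ~ Normal(400, 60), 100 bp reads;
the Mu check uses G = 36 kb, F = 485, a 150 kb host and 2·10⁴ fragments.
The unit suite runs reduced 20 kb / 5·10³-fragment libraries and samples
three seeds per packaging class; the null false-positive check runs twenty
20 kb seeded libraries.  Resolving *secondary* pac termini (two cut sites
6 bp apart) splits the start signal between the sites, so that check runs
deeper, at 2.5·10⁴ fragments (~250×), a depth routine for real phage
libraries.

Degenerate inputs: empty references and non-IUPAC characters are hard
errors; an all-zero coverage profile raises "no mapped reads"; τ at
zero-denominator positions is 0; peak ties are broken by higher merged SPC
then leftmost position; negative concatemer estimates are dropped with a
warning.

## Known limitations

* Exact-seed mapping cannot place reads across the reference's circular
  junction or inside duplicated repeats (multi-mapped reads are dropped),
  so a duplicated-repeat assembly yields *no* termini here rather than the
  spurious multiple termini a tolerant mapper produces.
* Re-running the pipeline on a reorganized DTR genome (repeat present at
  start and appended end) hits the same multi-mapping limit; the
  round-trip property holds for cos genomes.
* Single-end τ is harder to interpret (it can reach 1 for 5′cos and
  short-DTR phages when fragments outsize reads); every single-end call
  carries this caveat.
* Phages with protein-capped termini leave no signal by construction, and
  transposase (Nextera-style) libraries are unsuitable input.
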