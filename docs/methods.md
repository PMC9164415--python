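# Methods

## Frame translations and FrameAlign

A CDS of `n` codons is translated on its sense strand at offsets 0, 1 and 2,
giving the wild-type protein `WT` (`n` residues) and the frameshift
translations `FF` and `RF` (`n − 1` residues each; the trailing incomplete
codon is discarded). Offsets are the two possible outcomes of any ±1/±2
insertion or deletion: every such mutation puts the downstream sequence into
one of these two frames, so the pair (FF, RF) covers all frameshift cases.

Because the correspondence between frames is known exactly, alignment is
deterministic ("FrameAlign"): `WT` vs `FF` appends one terminal gap to `FF`;
`WT` vs `RF` prepends one gap to `RF`; `FF` vs `RF` needs none. Exactly two
gaps are placed per CDS, in contrast to general-purpose aligners, which
insert dozens of spurious gaps into frame translations and inflate the
similarity estimate. The three sequences cannot be aligned jointly in one
multiple alignment — the two WT-relative offsets are incompatible — hence
three pairwise alignments.

**Similarity.** A column is conserved iff neither symbol is a gap and the
substitution score of the residue pair is ≥ 0 in the active matrix.
Similarity is conserved columns / alignment length, so the single gap column
of each WT pair counts in the denominator (WT pairs divide by `n`, FF–RF by
`n − 1`). The 10-codon poly-A CDS pins both conventions: δ₁₂ = δ₁₃ = 9/10,
δ₂₃ = 1, δ = 0.9333…

**Shiftability** is δ = (δ₁₂ + δ₁₃ + δ₂₃)/3, in [0, 1].

## Scoring matrices and stops

Bundled matrices: BLOSUM62, PAM250 (Dayhoff), and GON250 — Gonnet's 250-PAM
matrix in the conventional ×10 integer scaling (identities A:24 … W:142).
"Deep" matrices are appropriate here because frameshift pairs have low
identity but moderate similarity. Any NCBI-format square matrix file can be
loaded by path; symmetry and completeness are validated.

Stops form a 21st residue class. The default `min_score` policy scores
('\*','\*') as +1 (a stop aligned to a stop is treated as synonymous) and
('\*', aa) as the matrix minimum over the 20×20 block, i.e. never conserved.
The alternative `matrix_star_row` policy uses the '\*' row shipped in the
file (BLOSUM62/PAM250 have one). Published per-substitution averages are
sensitive to this unstated convention; note that the *rank* of a
degeneracy-preserving code among random codes is provably independent of it,
because stop codons are fixed across the pool and contribute the same
constant to every code's FSS sum.

## Readthrough

Stop-codon readthrough follows natural suppressor tRNAs: TAG→S (supD; Q/supE
and Y/supF selectable), TAA→K (supG), TGA→W (supU). When enabled, the rules
replace **every** stop codon in every frame, including a terminal stop of
the native frame — the in-frame example driving this choice replaces a stop
that is the first codon of its frame, and uniform treatment keeps the three
frame translations symmetric.

`shiftability()` defaults to readthrough **on** (the frame translations of
real genes are displayed and aligned as readthrough translations). The
random-CDS reference statistics below are computed with readthrough **off**;
that is the convention under which the published baseline means are
reproduced, consistent with the observation that the similarity floor equals
the raw fraction of non-negative matrix entries. For sense-codon CDSs,
readthrough cannot change δ₁₂ at all: a stop in FF forces the overlapping WT
codon into {I, L, V, M}, and K/S/W score negative against all of these in
GON250. Both modes are exposed everywhere.

## Codon substitution families

Under a codon table, with scores from the active matrix:

* **RCS** (random): all 64 × 64 = 4096 ordered codon pairs;
* **ICS** (interchangeable): third-position changes, 64 × 4 = 256 including
  identity;
* **FCS** (frameshift): forward shift of codon `b₁b₂b₃` with incoming base
  `b` is `b₂b₃b`; reverse shift is `b b₁b₂`; 4 + 4 per codon, 512 total.

Classification: `unchanged` iff the codons are identical; `SYN` iff both
codons encode the same product (stop counts as its own class, so SYN
includes unchanged); otherwise `POS`/`NEG` by the sign of the score (zero
counts as NEG). Structural counts from exhaustive enumeration: FF and RF
columns are identical with 4 unchanged (the triplet monomers) and 14
synonymous; ICS has 64 unchanged and 192 synonymous. The RCS synonymous
count is 244 = Σ (class size)² including the 3×3 stop block; no reduction of
the stated definitions yields a smaller figure, so 244 is reported as-is.
Mean FSS exceeds mean RSS under all three bundled matrices — frameshift
substitutions are systematically milder than random ones — and this ordering
is asserted rather than the convention-sensitive averages themselves.

## Alternative genetic codes

* **Random codes** permute the 20 amino acids over the standard code's 20
  synonym classes (degeneracy and stop codons fixed). Default sampling is a
  uniform seeded permutation of the 20! space; a `proportional_swap` variant
  (transposition chain with selection probability proportional to an amino
  acid's codon count) is provided because the historical description of the
  sampling is ambiguous, but a symmetric transposition chain mixes to the
  same uniform distribution, so the default is the cleaner construction.
* **Compatible codes** apply independent base permutations (p₁, p₂, p₃) to
  the three codon positions, translating `b₁b₂b₃` as the standard code
  translates `p₁(b₁)p₂(b₂)p₃(b₃)`: 24³ = 13,824 codes, each preserving
  per-amino-acid codon counts; the wobble constraint (identity or A↔G at
  position 3) leaves 24 × 24 × 2 = 1,152.

Ranking: rank = 1 + #{codes with strictly greater FSS sum} (best rank on
ties, which are common in the discrete pools); percentile = rank / pool
size. Under GON250 the standard code ranks 481/13,824 = top 3.48 % of
compatible codes and in the top ~3 % of sampled random codes; under PAM250
it sits outside the top decile (~13–15 % depending on the PAM250 file
variant), so near-optimality is a GON250/BLOSUM62-supported conclusion, not
a matrix-independent one.

## Codon pairs

A pair `B₁…B₆` with flanking base `B₀` (forward) or `B₇` (reverse) shifts to
(`B₀B₁B₂`, `B₃B₄B₅`) or (`B₂B₃B₄`, `B₅B₆B₇`): 8 CPFSs per pair, 32,768
total. The CPFS score is the **sum** of the two residue substitution scores
(additive with single-codon FSS; a per-residue mean is available). Flank
bases are weighted equally; weighting by genomic base composition is not
implemented.

## Usage statistics

Codons are counted in-frame; codon pairs as adjacent in-frame pairs within a
record (never across records). Expectations follow the independence
construction: for pairs, E(a,b) = N_a N_b / N² × P with codon marginals N
and pair total P; for single codons, each amino acid's observed total is
spread uniformly over its synonym class (stops form their own class). Both
normalizations satisfy ΣE = ΣO. Each unit gets χ² = (O−E)²/E and an
over/under/absent status. The usage-weighted mean FSS weights each unit's
mean FSS over its 8 shifts by observed frequency; absent units carry zero
weight but are reported.

## Simulator

Random CDSs draw codons i.i.d. uniformly from the 61 sense codons
(codon-level, not base-level, uniformity — "random sense codons" is
codon-level language), so the native frame has no stops while shifted frames
contain hidden stops at the induced rate (≈ 4.7 %, close to the 3/64
uniform-base expectation). Default CDS length 500 codons (300 selectable);
reference batches use 10,000 CDSs (or 10,000 sets of three). Output is
deterministic given the seed (PCG64). The simulator emulates only codon
composition: no codon-usage bias, no dicodon correlation, no length
variation, no sequence evolution. Tests passing on it therefore validate
the machinery and the code-level floor, not genome-level usage effects.

## Reference statistics and problem sizes

The acceptance script computes, from scratch: the ICS synonymous count (192,
exact); mean shiftability of 10,000 random 500-codon CDSs (GON250,
readthrough off; ≈ 0.399 vs the published 0.394 ± 0.016 — the residual is
compatible with matrix-file rounding at the score-zero boundary); and mean
native-frame similarity of 10,000 independent triples (≈ 0.372 vs published
0.383; equals the closed-form expectation Σ p_a p_b 𝟙[s(a,b) ≥ 0] = 0.3722
to within Monte-Carlo error, which the tests check at 3 standard errors).
Full scale is used because the vectorized kernel makes 10,000 × 500-codon
batches a matter of seconds.

## Known limitations

* Genome-scale tables for real species require their RefSeq CDS sets, which
  are not bundled; the pipeline accepts any CDS FASTA.
* The absolute usage-weighted FSS scale depends on unstated conventions
  (sum-vs-mean over shifts, 61-vs-64 codon normalization, stop scoring); all
  are exposed as options, and only internally consistent comparisons are
  asserted.
* MSA/progressive-aligner similarity estimates are deliberately out of
  scope: FrameAlign exists precisely because gap-searching aligners
  overestimate frame similarity.
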