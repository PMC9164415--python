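# frameshift-kit

Tools for measuring how well protein-coding sequences — and the genetic code
itself — tolerate frameshift mutations.

A frameshift moves the ribosome's reading frame by ±1 base, replacing every
downstream codon with a *shifted* codon that overlaps the original in two
bases. Because the codon table places physicochemically similar amino acids
on similar codons, the shifted protein is often far more similar to the wild
type than a random sequence would be. This package quantifies that effect at
three levels:

1. **Gene level — shiftability (δ).** For a CDS of *n* codons, translate the
   sense strand in all three frames: the wild type `WT` (*n* residues) and
   the two frameshift translations `FF` (+1) and `RF` (+2), each *n* − 1
   residues after discarding the trailing incomplete codon. Because the
   frame relationship is known exactly, the three sequences are aligned with
   **fixed** gap placement (no gap search): one gap appended to `FF` against
   `WT`, one gap prepended to `RF` against `WT`, none between `FF` and `RF`.
   A column is *conserved* when its substitution score is ≥ 0 (GON250 by
   default; gap columns are never conserved), pairwise similarity δᵢⱼ is the
   conserved-column fraction, and

   δ = (δ₁₂ + δ₁₃ + δ₂₃) / 3.

2. **Code level — frameshift substitution scores (FSS).** Each codon has 4
   forward and 4 reverse shifted codons (64 × 8 = 512 frameshift
   substitutions, FCSs); their amino-acid substitution scores are FSSs, and
   the sum over all 512 measures a genetic code's frameshift tolerance. The
   standard code is ranked against degeneracy-preserving random codes
   (amino acids permuted over the 20 synonym classes, 20! possibilities)
   and against the 24³ = 13,824 *compatible* codes obtained by permuting
   the base alphabet independently at each codon position (1,152 under the
   wobble constraint). Codon-pair frameshift substitutions (4096 pairs × 8
   flank choices = 32,768 CPFSs) extend the same score to adjacent codon
   pairs.

3. **Genome level — usage-weighted FSS.** Codon and codon-pair usage is
   counted in-frame, compared with Gutman–Hatfield independence
   expectations (χ², over/under-representation), and the per-unit mean FSS
   is averaged with the observed usage as weights — over-use of
   frameshift-resistant codons raises a genome's expected shiftability.

A seeded simulator generates random CDSs of uniform sense codons (300 or
500 per CDS) for the reference baselines.

## Worked example

```python
>>> import frameshift_kit as fk
>>> r = fk.shiftability("ATGGCTGGTAAACGTGAAGATCTGTTCTAA")
>>> r
ShiftabilityResult(delta12=0.2, delta13=0.3, delta23=0.3333333333333333,
                   delta=0.27777777777777773, n=10, gap_total=2)
```

The 10-codon CDS keeps 2/10, 3/10 and 3.33/10 of its aligned columns
conserved in the three pairwise frame comparisons (the one gap per WT pair
counts in the denominator), giving shiftability δ ≈ 0.278: about 28 % of
residues would remain conserved under a frameshift. From the shell:

```sh
$ frameshift-kit simulate --sets 3 --codons 300 --seed 7 --out demo.fasta
wrote 9 records to demo.fasta
$ frameshift-kit shiftability --in demo.fasta --out delta.tsv --summary summary.tsv
9 records: mean delta 0.4089 (sd 0.0181)
$ frameshift-kit code-rank --pool compatible --matrix GON250
SGC sum FSS -3408; rank 481/13824 (3.48%)
```

Random sense-codon CDSs have mean δ ≈ 0.40 — the floor imposed by the code
alone — and the standard code's total FSS places it in the top 3.5 % of all
compatible alternative codes under GON250: the code is close to optimal for
frameshift tolerance, and real genes sit above the random floor.

Other subcommands: `code-stats` (substitution-class census for
random/frameshift/interchangeable substitutions), `code-rank --pool random
--count N --reps R` (sampled random-code ranking with per-repetition
percentiles), `cpfs` (all 32,768 codon-pair frameshift substitutions), and
`usage` (codon / codon-pair usage with χ² and usage-weighted FSS).

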