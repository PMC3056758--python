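# Methods

This note records the models implemented in `herd`, the defaults and why
they were chosen, the numerical and tie-breaking rules, and the known
limitations — in particular what the synthetic scenarios do and do not show
about full-size populations.

## Simulating linkage disequilibrium

Founder haplotypes are generated locus by locus along each chromosome on an
*underlying* biallelic scale where every allele has frequency 0.5:

1. the first underlying allele of a chromosome is Bernoulli(0.5);
2. each next locus copies the previous underlying allele, flipped when the
   pre-drawn linkage phase between the two loci is repulsion (phases are
   coupling/repulsion with probability 0.5 each, fixed per population);
3. with probability `1 - ld_decay` per step the block ends and the next
   underlying allele is drawn fresh;
4. one uniform `u` is drawn per block; at every locus of the block the
   *observed* allele is the major allele if `u > 2 * MAF(locus)`, otherwise
   the underlying allele.

Step 4 reproduces each marker's target frequency exactly: the underlying
allele is the minor one with probability 0.5, and it survives replacement
with probability `2 * MAF`, giving minor-allele frequency
`0.5 * 2 * MAF = MAF`.  The block process gives squared genotype
correlations that decay approximately geometrically with the number of
intervening loci, an autoregressive analogue of observed LD decay.  With
the default `ld_decay = 0.998` blocks average 500 loci.

The published sentence describing the replacement rule is garbled (it
compares the minor allele frequency with twice itself); the rule above is
the reading that is self-consistent, uses exactly two uniform draws per
allele, and hits the stated frequencies.  This is flagged here because it is
an interpretation, not a transcription.

Recombination in the gene-drop is Haldane: crossover count per chromosome
Poisson(length in Morgans), positions uniform, no interference, QTL loci
inherited exactly like markers.  There is no mutation and no selection
during the pedigree generations.

## QTL effects and phenotypes

QTL positions are drawn uniformly among within-chromosome marker intervals
and sit strictly between markers.  Effects are heavy-tailed: for standard
normal `s`, the allele substitution effect is `a = s * 2**(|s| - 2)`,
rescaled so `sum_j 2 p_j q_j a_j^2 = sigma_a^2`.

The source prints this transform as `2^abs(s - 2)`, which evaluated
literally is strictly positive, is *smallest* near `s = 2`, and produces a
one-sided effect distribution — contradicting both "heavy tails" and the
reported share of variance from the largest locus.  The sign-preserving
reading above is symmetric, genuinely heavy-tailed, and with 10,000 QTL puts
2–4% of the additive variance on the largest locus (the reported range);
the literal reading puts ~1% there.  The sign-preserving form is therefore
used, and this remains the one deliberate departure from the printed text.

Deregressed observations are `y_i = TBV_i + e_i` with
`Var(e_i) = sigma_a^2 (1/REL_prog - 1)`.  Proven bulls draw REL_prog from
U(0.85, 0.99) (progeny-test information), cows from U(0.25, 0.40) (a few own
records at moderate heritability); young bulls and heifers carry no record.
Genotyping artifacts are i.i.d. per entry: missing with probability 1.00%,
then a uniformly chosen *different* code with probability 0.02%.

## The scaled study population

The full-size design — 33,414 genotyped Holsteins, 86,465 ancestors,
500,000 markers — is not desk-computable, so the package ships a scaled
scenario used by the tests and the acceptance script:

* genome: 3 chromosomes x 2,000 markers.  The chromosome length is
  0.12 Morgans so that the *marker density* (16,667 markers per Morgan) of
  the full design is preserved.  This matters more than chromosome count:
  both the LD between adjacent markers and the recombination rate per
  500-marker segment (0.03 M) then match the full-size design.  With
  1-Morgan chromosomes the same marker count would put eight times more
  recombination inside every segment and no pedigree structure can then
  reproduce realistic haplotype sharing.
* cohorts: 540 proven bulls, 840 young bulls, 260 cows, 360 heifers
  (the full design's 27:42:13:18 proportions at ~2,000 genotyped animals),
  under 8 ancestral generations of 25 males and 200 females with
  Zipf-weighted sire use.  These sizes were calibrated so that the
  population's per-segment haplotype statistics match the published ones:
  roughly 24 copies per distinct true segment haplotype and a most-frequent
  haplotype carrying ~10–15% of all slots.  The haplotype-sharing structure,
  not calendar depth, is what the algorithm exploits.
* mixed density: every genotyped sire with >= 10 genotyped progeny plus
  randomly chosen young bulls up to 10% of genotyped animals keep the full
  panel; everyone else keeps every 10th marker.

What passing tests on this scenario show: that the combined
population/pedigree haplotyper recovers masked genotypes and parental
origins under realistic LD, pedigree depth and panel mixing, at rates
consistent with the full-scale study.  What they do not show: behaviour
under real-chip error structure (artifacts here are i.i.d.), under map
errors or misplaced markers, for multi-breed data, on sex chromosomes, or
the absolute reliabilities attainable with 16x more reference animals —
phase and paternal-origin error rates in particular shrink with reference
size, and the scaled scenario runs 1–3 points of paternal accuracy below
the full-scale report.

## Haplotyping: rules beyond the published outline

The published algorithm is an outline; these concrete rules fill its gaps.

* Matching and storage.  A genotype matches a stored entry when no
  homozygous locus conflicts with a known entry allele.  Mutual imputation
  writes only *homozygous-genotype evidence* into shared entries; phase
  inferences (the complement's `2 - h` alleles at observed heterozygotes)
  stay with the animal or in freshly appended entries.  One coincidental
  match therefore cannot corrupt a frequent haplotype — a rule that proved
  decisive for phase accuracy.
* Complement search starts at the first-match index (inclusive), so a fully
  homozygous genotype reuses its own entry rather than duplicating it.
* The library is re-sorted by assignment count (stable, first-discovered
  first on ties) after every iteration; unreferenced entries are dropped.
* Iteration schedule (6 rounds): population on the densest genotypes,
  population on all, two pedigree-guided rounds (sire then dam candidate
  entries, else grandparents', tried before any scan — a candidate pair
  whose complement also matches the other parent orients the animal), two
  pedigree-only rounds.
* Pedigree-only refits rebuild each gamete as the parent's haplotypes with
  at most one switch point, the leftmost point with fewest conflicts.
  Conflicts with the animal's own homozygous loci are hard (at most one is
  tolerated, and only against a genotyped parent — it is then treated as a
  genotyping error and resolved in favour of the more frequent haplotype,
  correcting the stored genotype so the no-conflict invariant survives);
  disagreements with phase inferences from the other haplotype are soft and
  only break ties.  Orientation is chosen to minimize conflicts
  lexicographically — genotyped parents decide, vote-assembled ancestors
  only break ties.  A fit is rejected when the parent pair covers less than
  80% of the tested loci.
* Non-genotyped ancestors are assembled per segment from their children's
  gametes: oriented children vote (weight 2) with the gamete received from
  that parent, unoriented children vote once for each candidate; the two
  top entries become the ancestor's pair, requiring at least two voting
  children.  No crossover stitching is attempted against assembled pairs.
* After the last iteration a final orientation pass re-decides
  parent-of-origin against the converged library, recovering orientations
  fixed early under incomplete information.
* Monotone-improvement safeguard: a pass keeps an animal's previous
  assignment when the new one resolves strictly fewer alleles (and the old
  pair is still genotype-consistent), so the unknown-allele fraction never
  increases across iterations.
* Calling: imputed dosage is the sum of the two haplotype alleles; with one
  known allele the other is replaced by the population allele frequency
  (provenance "half-filled", counting one half toward the call rate); with
  none, by twice the frequency.  Observed codes are never overwritten
  except by the single-locus conflict rule.

## Genomic evaluation

Mixed-model equations for `y = Xb + Zu + p + e` are solved by Gauss–Seidel
with residual updating in the order mean, markers (index order), polygenic
block; deterministic throughout.  Defaults and rationale:

* per-marker prior variance `(1 - poly) sigma_a^2 / sum_j 2 p_j q_j`, the
  standard normalization; base frequencies default to half the mean observed
  dosage;
* `poly` = 0.10 at 50K-scale density, 0 at 500K (denser panels trace more
  of the QTL variance); the polygenic block uses Henderson's
  relationship-inverse rules ignoring inbreeding over genotyped animals and
  all their ancestors;
* nonlinear prior: each round, marker j's prior variance is multiplied by
  `curvature ** (min(|u_j|/sd(u), 5) - 2)`; the cap prevents overflow and
  the exponent offset leaves a 2-SD effect unshrunk relative to the linear
  model.  Curvature 1.0 reproduces SNP-BLUP bit for bit.  The exact
  re-weighting rule of the lineage of programs this follows is not public;
  this one is an interpretation and is isolated in `nonlinear_scale` so it
  can be swapped.
* convergence is tracked as `var(GEBV_t - GEBV_{t-1}) / var(GEBV_t)`;
  iteration stops at 1e-6 or `n_iterations` (default 150); ten consecutive
  rises above 1e-2 abort with diagnostics.
* imputed fractional dosages (half- and frequency-filled) enter Z as they
  are.

The iterative solution matches a direct dense solve of the same equations to
1e-6 relative tolerance on systems up to 200 equations (tested with and
without the polygenic block).

## Reliability approximation

All formulas are closed-form (see README).  Defaults: `k = 15`; solved
polygenic fractions 1% (500K), 3.4% (50K), 30% (3K) are exposed as
`reliability.DEFAULT_POLY`, never hard-coded into calculations.  Two
documented printing quirks: the worked chain gives DE_max = 75.0 from the
rounded inputs `.825/.99` where 74.8 was printed from unrounded values (both
accepted); and the projection helper `project_reliability` composes
DE_max -> REL_max -> DE_gen -> REL_tot with no parent-average add-back — it
projects trends over reference size and density and deliberately does not
chase any particular published projection curve, whose exact chain is
underdetermined.

## Numerical conventions

Marker indices are 0-based internally and 1-based in files; segment ranges
are half-open; all randomness flows from one root seed through named child
streams, and identical seeds reproduce identical outputs bit for bit.
Genotype files use `0/1/2` with `5` for missing; haplotype files use `0/2`
with `1` for unknown.

## Problem sizes used by tests and the acceptance script

The suite runs the scaled scenario once per density design (~2,000 genotyped
animals, 6,000 markers), evaluation experiments on 400-marker/200-QTL
populations with five trait replicates drawn on one genotype set, and
generator calibration on 500 x 10,000 matrices — sizes chosen so that every
claim is tested with real Monte-Carlo error bars while the whole suite stays
interactive.
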