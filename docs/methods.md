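# Methods

## Data model

A `Panel` holds one `Haplotype` per male sample plus a population label, over
an ordered list of `LocusSpec`s. Alleles are repeat counts stored as floats;
microvariant alleles keep one decimal digit restricted to .1/.2/.3 (ISFG
nomenclature), and every locus's allele multiset is canonically sorted
ascending — input order of DYS385a/b-style copies carries no meaning.

Quality flags are per locus, per sample:

- **missing** — no call (table tokens "", "-", "N", "null", case-insensitive,
  configurable). The sample is dropped from that locus's spectrum and from
  haplotype-level statistics over any subset containing the locus.
- **copy-number anomaly** — observed copy count contradicts the locus
  specification (e.g. two alleles at a single-copy locus). The observed
  alleles are retained and still participate in whole-haplotype identity
  (a duplicated pattern is identifying information), but the sample is
  excluded from that locus's allele spectrum and from Rst distances, where
  no defined copy pairing exists. Variable-copy loci (DYF387S1, DYS527,
  DYF404S1) accept any count ≥ 1 without a flag.

DYS389II is taken exactly as reported; no subtraction of DYS389I is applied.

## Forensic statistics

All frequencies come from direct counting. Gene diversity uses Nei's
unbiased form `n/(n−1)·(1 − Σ pᵢ²)`; it is undefined for n < 2 and the API
raises rather than returning a sentinel. Haplotype diversity is the same
statistic on the whole-haplotype spectrum, the match probability is
`Σ pᵢ²`, and discrimination capacity is `k/n` (the formula `k/Σ(pᵢ·n)`
sometimes printed in reports reduces to this identically, since
`Σ pᵢ·n = n`).

Multi-copy loci expose two spectra: *pooled* (each copy counted separately,
n = samples × copies) and *combination* (sorted multiset per sample,
n = samples). The per-locus GD of a multi-copy locus is reported on the
combination spectrum, matching the convention of reporting one GD for
"DYS385a/b" jointly. Because published allele totals are ambiguous about
which convention they use, the report emits distinct-allele totals under
both.

Reporting precision is 4 decimals. The API always returns full precision;
the helpers `round_half_up` and `round_toward_zero` exist because published
tables are not consistent about rounding — a haplotype diversity of
0.99995 appears as 0.9999 (truncation) while a match probability of
0.00255 appears as 0.0026 (half-up) — and reproducing a printed value
requires saying which rule is in force.

## AMOVA and Rst

The molecular distance between two haplotypes is
`δ² = Σ_loci Σ_copies (a − b)²` with copies paired in ascending order;
microvariants contribute their literal decimal values (no repeat-equivalence
table is assumed). Pairs with unequal copy counts at a variable-copy locus
skip that locus for that pair, and the skip is logged.

For populations p = 1…P with sizes n_p (N total), the sums of squared
deviations are computed from pairwise distances:

    SSD_total  = (1/N) Σ_{i<j over all} δ²ij
    SSD_within = Σ_p (1/n_p) Σ_{i<j in p} δ²ij
    SSD_among  = SSD_total − SSD_within

with MS_among = SSD_among/(P−1), MS_within = SSD_within/(N−P),
n_c = (N − Σ n_p²/N)/(P−1), σ²ₐ = (MS_among − MS_within)/n_c,
σ²_w = MS_within, and Rst = σ²ₐ/(σ²ₐ+σ²_w). A panel with no molecular
variance at all yields Rst = 0 with a degenerate flag. Raw (possibly
negative) Rst is reported alongside the value clamped to [0, 1]; only the
clamped value enters distance matrices, since MDS and NJ require
non-negative inputs.

Complete-case analysis per locus set: samples flagged at any selected locus
are dropped before distances are computed, avoiding per-pair
renormalization. The default subset for cross-population comparison is the
Yfiler-Plus panel (25 locus names, 27 amplicons counting DYS385a/b and
DYF387S1 per copy); whether multi-copy loci enter the comparison is
selectable (`include_multicopy`, default True, i.e. they are included via
sorted pairing).

Significance: individuals are permuted across the two population labels
with group sizes preserved; `p = (1 + #{Rst_perm ≥ Rst_obs})/(n_perm + 1)`,
bounded below by 1/(n_perm+1). The pairwise-distance matrix is computed
once and reused across permutations. The comparison uses a 1e−12 tolerance
so that permutations tying the observed statistic count as at least as
extreme.

When every sample shows its nominal copy count at every locus (always true
for simulated panels) distances are computed through a vectorized Gram
identity `δ²ij = |xᵢ|² + |xⱼ|² − 2 xᵢ·xⱼ` on the copy-expanded allele
matrix, clipped at zero; otherwise an explicit per-pair loop handles locus
skipping.

## Ordination and trees

**Classical MDS** (Torgerson): square the distances, double-center
`B = −½ J D² J`, take the eigendecomposition, and scale the top `dims`
positive-eigenvalue eigenvectors by √λ. Rst values are used directly as
distances — no Rst/(1−Rst) or other transformation — because that is how
such matrices are conventionally plotted. Negative eigenvalues (non-
Euclidean input) are excluded from coordinates but reported in the full
spectrum; `goodness` is the captured fraction of positive-eigenvalue mass.
Axis sign is fixed so the largest-magnitude loading on each axis is
positive, making plots reproducible across runs and machines.

**Neighbor joining** (Saitou–Nei): repeatedly join the pair minimizing
`Q(i,j) = (m−2)d_ij − Σ_k d_ik − Σ_k d_jk`; branch lengths from the
standard three-point formulas; the final three lineages close onto one
internal node. Ties in Q are broken by the lowest (row, column) index pair,
and negative branch lengths are clamped to zero without redistributing
length — both choices are arbitrary where the literature is silent, so they
are fixed and documented rather than left to implementation accident.
NJ is exact on additive matrices, which the test suite exploits: a random
tree with positive branch lengths is reconstructed from its path-length
matrix to 1e−9. Two taxa yield the degenerate single-edge tree.

These two components are implemented here rather than delegated so that the
tie-break/sign/clamping conventions above hold exactly; independent
implementations (scikit-bio's PCoA and NJ, dendropy's Newick parser) serve
as cross-check oracles in the test suite only.

## The simulator

`simulate_panel` is a forward-time haploid Wright–Fisher model under the
single-step stepwise mutation model: each generation all N haplotypes
choose parents uniformly at random, and each allele copy mutates with its
locus's per-copy rate by ±1 repeat with equal probability, reflecting at
one repeat (a 1 stepping down becomes 2). Multi-copy loci are simulated as
linked, independently mutating copies.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `pop_size` N | 100 | haploid effective size; large enough for Rst in the empirically observed 0.01–0.5 range at the split times below, small enough to simulate thousands of generations quickly |
| `mutation_rate` | 0.002 /copy/generation | the canonical order of magnitude for Y-STR loci; rapidly mutating loci can be given higher per-locus rates |
| `sample_size` | 50 per population | typical reference-population scale relative to N |
| `split_generations` | 100 | a star split; a tuple gives per-population branch lengths |
| burn-in | 4N generations | from a monomorphic founder (allele 14), long enough to approach mutation–drift equilibrium before the split |
| founder allele | 14 repeats | the modal repeat count of common forensic Y-STRs |

One `SeedSequence` per run spawns per-population child streams, so panels
are byte-identical for a fixed seed and earlier populations are unaffected
by adding later ones.

What the generator emulates: haploid transmission without recombination,
stepwise repeat-count evolution, drift, divergence by isolation. What it
does not: multi-step or asymmetric mutations, microvariant creation,
migration, selection, population growth, genotyping error. Passing tests
therefore demonstrate correctness of the statistics and the qualitative
population-genetic behaviour (diversity rising with Nμ, Rst rising with
split time), not calibration against any real population's parameters.

`sample_from_spectra` bypasses evolution entirely: in exact mode the
returned panel's haplotype spectrum equals the input spectrum by
construction (used to rebuild the published 392-singleton/4-doubleton,
n = 400 spectrum); multinomial mode draws with replacement from the
spectrum's frequencies. `distinct_haplotype_keys` enumerates guaranteed-
distinct haplotypes by writing an index in mixed radix across allele slots,
with each copy of a multi-copy locus in a disjoint allele range so sorting
cannot collapse two indices.

## Problem sizes in the test suite

Oracle-equivalence checks run at exhaustive-loop scale (N ≤ 12 for AMOVA,
4–12 leaves for NJ). The divergence-monotonicity check uses N = 100,
μ = 0.002, all 36 loci, 50 replicates per split time T ∈ {20, 100, 500} —
replicate-averaged mean Rst is strictly increasing, and at these sizes the
whole check runs in seconds thanks to the vectorized generation step. Null
calibration uses duplicated populations (observed Rst at the bottom of the
permutation distribution) and 199-permutation p-values; a separate property
test checks approximate uniformity of null p-values (KS distance < 0.1 over
200 random label splits).

## Known limitations

- Haplotype-frequency confidence intervals, YHRD-style frequency surveying
  and mutation-rate estimation are out of scope.
- The AMOVA is two-level only (no region/group hierarchy).
- The reader auto-detects tab vs comma delimiters from the header row;
  exotic quoting inside comma-separated multi-copy cells should use TSV.
- Whether a published 27-locus Rst included the multi-copy loci is kit- and
  tool-dependent; both behaviours are available but results will differ.
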