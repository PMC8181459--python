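# Methods

## Data model

A haplotype is one male's joint allele profile over the panel loci; the
Y chromosome recombines with nothing, so the profile is inherited — and
analyzed — as a single block. Allele designations are repeat counts with
optional microvariant suffixes (19.1 = 19 repeats + 1 base). They are
stored exactly as integer tenths of a repeat, so `19.1` can never print
as `19.099999…` and microvariants are distinct alleles for identity
purposes. The default panel is PowerPlex Y23: 21 single-copy loci plus
DYS385a/b, which is reported in one column as an unordered pair and
stored sorted ascending, so `(17,13)` and `(13,17)` are the same call.
DYS389II is used exactly as typed (no subtraction of DYS389I): any
recoding would change haplotype identity. Missing calls (blank or `0`
on input) exclude a haplotype from haplotype-level statistics but not
from per-locus statistics at loci where it has calls.

## Forensic statistics

Per locus, gene diversity is the unbiased estimator
GD = n/(n−1)·(1−Σᵢpᵢ²) over observed allele frequencies. For DYS385a/b
the default counting unit is the canonical sorted pair (one GD value for
the combined locus); a per-value mode is also exposed because published
allele counts for multi-copy loci are ambiguous between the two
conventions, and the per-locus report carries both counts.

All haplotype-level statistics are functions of the occurrence spectrum
{m → c_m} (c_m distinct haplotypes observed m times; n = Σ m·c_m,
k = Σ c_m):

- match probability MP = Σ c_m (m/n)²
- haplotype diversity HD = n/(n−1)·(1−MP)
- discrimination capacity DC = k/n
- unique-haplotype fraction FUH = c₁/k

Frequencies are exact rationals internally (`fractions.Fraction`) and
floats only on output, so the integer identities DC·n = k and
FUH·k = c₁ hold exactly and HD/MP agree to the last bit. A documented
caveat: published HD values sometimes disagree with n/(n−1)(1−MP)
evaluated on the occurrence spectrum printed beside them (e.g. 0.9994
printed where the spectrum gives 0.99893). This package always follows
the formula; the test suite asserts the formula-consistent values.

## AMOVA and R_ST

The inter-individual distance is the stepwise-mutation-model kernel:
the sum over distance loci of squared repeat-count differences.
DYS385a/b is excluded by default because an unordered pair has no copy
orthology (inclusion is togglable; when included, pairs are compared
sorted-elementwise and skipped if copy numbers differ). Microvariants
enter at face numeric value (19.1 − 19 = 0.1) by default, with a
truncate-to-integer alternative. Missing loci are dropped pair by pair
without rescaling; the deletion count is logged.

One-level AMOVA in distance form: SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ,
SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²ᵢⱼ, SS_among by difference;
df_among = G−1, df_within = N−G; σ²_w = MS_within,
σ²_a = (MS_among − MS_within)/n₀ with n₀ = (N − Σn_g²/N)/(G−1); and
R_ST = σ²_a/(σ²_a+σ²_w). Negative estimates are reported raw and floored
at 0 only where a non-negative dissimilarity is required (MDS/NJ input).
Permutation p-values shuffle individuals between the two populations and
use the add-one estimator p = (1+#{Φ\* ≥ Φ})/(1+B); default B = 9,999,
seed mandatory. Because the permutation distribution is discrete and can
tie with the observed statistic, these p-values are conservative
(super-uniform) under the null — the calibration test checks the
one-sided (anti-conservative) Kolmogorov–Smirnov statistic for exactly
that reason.

## Ordination

Rows are populations, columns the union of observed (locus, allele)
identifiers, zero-filled where unobserved; within a fully observed locus
block each row sums to 1. PCA is a column-centered (not
variance-scaled) SVD — frequencies already share a scale. MDS is
classical/metric (Torgerson): double-center −½d², embed with the top-k
non-negative eigenpairs; deterministic, no random starts. Negative
eigenvalue mass (possible for the Manhattan metric, which need not be
Euclidean-embeddable) is recorded on the result, never silently
dropped; for Euclidean inputs it is 0 and classical scaling coincides
with PCA up to per-axis sign. Axis signs follow a fixed convention —
largest-magnitude loading (PCA) or coordinate (MDS) positive — so
outputs are platform-stable.

## Neighbor joining

Standard Saitou–Nei agglomeration over Q(i,j) = (r−2)d(i,j) − Σd(i,·) −
Σd(j,·) with rate-corrected branch lengths and the closed-form
resolution of the final three nodes. Ties in Q are broken by the lowest
(i,j) index pair in the current label order, so trees are bit-stable.
Negative branch lengths are clamped to 0 with the total deficit recorded
on the tree; on additive matrices the deficit is 0 and the generating
tree is recovered exactly. Trees are left unrooted (the root node is
the final trifurcation).

## Haplogroup prediction

Y haplogroups are SNP-defined lineages; STR profiles are predictive of
them because lineages share recent founders. The classifier is
k-nearest neighbors (default k = 5) on the squared repeat-count
distance with DYS385a/b excluded: the k closest references vote, the
majority label wins with confidence = vote fraction, and queries below
`min_confidence` (default 0.6) are reported `unassigned`. Ties break by
smaller mean distance, then lexicographic label, making predictions
deterministic and independent of panel row order. This is an explicit,
auditable design choice of this package — production forensic
prediction services use large proprietary Y-SNP/STR databases whose
algorithms are not published — so absolute agreement with any particular
service's output is out of scope.

## Synthetic data

The simulator is deliberately simpler than a coalescent: a star
phylogeny of populations, each founder evolving independently from the
ancestral haplotype (all loci at 14 repeats by default) for its
divergence time, and each individual evolving from its founder for a
within-population depth (default 50 generations). Per generation and
locus a mutation occurs with probability μ (default 0.002, a typical
Y-STR per-meiosis rate) and moves the repeat count ±1 with equal
probability, reflecting at allele 1 (a down-step from 1 lands on 2).
Implementation draws the Binomial(t, μ) mutation count per lineage and
applies the steps sequentially, which is distribution-identical to the
per-generation walk and verified against a naive step-by-step oracle by
a chi-square test. Under this model the expected squared allele-size
difference between two populations split t generations ago is 2tμ,
which is the calibration target. Reference-panel generation places
founders ≥ a requested squared distance apart (one dedicated locus
shifted by ⌈√(sep/2)⌉ per haplogroup) and perturbs members with
Poisson(μt) mutations per locus.

What the simulator does *not* emulate: genealogical structure within
populations (everyone is an independent line from the founder), locus-
specific mutation rates, multi-step mutations, allele-range constraints,
null alleles, and any Y-SNP information. Tests passing on these data
therefore validate the *statistics* — the estimators, the permutation
machinery, the tree and ordination algebra — not demographic realism.

Exact-spectrum table generation encodes each distinct haplotype's index
as base-10 digits across the single-copy loci on top of seeded random
base alleles, guaranteeing distinctness; composing it with the spectrum
extractor is the identity, which is what makes published spectrum-level
results checkable without the deposited genotypes.

## Problem sizes and numerical conventions

The test suite runs the AMOVA-vs-oracle battery at 200 random tables of
N ≤ 12, the permutation-null calibration at 2,000 splits of a 16-sample
population with B = 199, NJ consistency at 100 random additive matrices
of 4–10 taxa, SMM calibration at 3,000 replicate loci per divergence
level (within 3 Monte-Carlo standard errors of 2tμ), and haplogroup
recovery at 500 references / 200 queries; these sizes give stable
verdicts at fixed seeds while keeping the default run fast. Oracle
equivalences are asserted at 1e-12 (AMOVA) and 1e-9 (NJ, MDS
reconstruction). Reported tables round to 4 decimals at the
presentation layer only.

## Known limitations

- Haplotype-level statistics silently exclude incomplete haplotypes;
  with much missing data the per-locus and haplotype-level n differ.
- R_ST assumes the SMM distance kernel; published values computed by
  external services with unstated kernels or locus sets will differ.
- The permutation test is two-group; hierarchical AMOVA with regional
  groupings is not implemented.
- Classical MDS on strongly non-Euclidean distances discards the
  negative spectrum (reported, but the embedding is then lossy).
- k-NN prediction quality is entirely bounded by the reference panel's
  coverage; confidence is a vote fraction, not a calibrated probability.
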