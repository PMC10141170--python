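# Methods

## The model

The package analyzes supplementation experiments on pooled fecal
communities grown in defined medium: one unsupplemented control and a set
of glycan-supplemented conditions, each with 4–6 technical replicates
sequenced over the 16S rRNA V3–V4 region. The pipeline starts *after*
denoising: its inputs are an ASV × sample count table, ASV-vs-reference
alignment hits, a reference taxonomy, a copy-number table, and genome
annotations. Read-level processing (quality filtering, chimera removal)
is upstream and out of scope.

### Multi-taxonomy assignment

For one ASV, let *M* be its best alignment identity (a fraction). The
admissible set is every reference with identity strictly greater than
*t* = *M* − (1 − *M*)/4, plus always the *M*-achieving reference(s).
The window width (1 − *M*)/4 encodes that a weaker best match deserves a
wider candidate set; at *M* = 1 the window closes and a perfect match is
unambiguous. Three deliberate choices:

- **Strictness.** The inequality is strict except for the maximum itself,
  which is always a member — the assignment must be non-empty and contain
  the best hit.
- **Rounding.** Identities are compared after rounding to 6 decimals.
  Tabular identity columns carry 2–3 decimals; without rounding, float
  noise could split genuine ties.
- **Naming.** Member species labels are de-duplicated, sorted
  lexicographically and joined with `/`. Sorting is not biologically
  meaningful; it makes multi-names deterministic so set operations on
  phylotype names are well defined downstream.

ASV counts are added whole to exactly one phylotype (the shared label at
the collapse rank, or the `/`-joined multi-name on disagreement); counts
are never fractionally split, so collapse conserves column sums exactly.
ASVs without hits collapse into `unclassified`, which is retained in
abundance tables and excluded from phenotype prediction. No global
identity floor is applied.

### Copy-number correction

A reference table of (lineage, copy number) records is averaged at every
rank. A phylotype's estimate is the mean at its most specific indexed
rank, walking species → domain, then a global mean; a multi-taxon
assignment takes the unweighted mean over members (they are equally
plausible under the admission rule). Correction happens at the phylotype
level *after* collapse, because the phylotype is the analysis unit of all
downstream statistics; correcting per-ASV first would give the same
result for single-member assignments and differ only through multi-member
averaging, which operates on the same member set either way.

### Community phenotype index

Genome annotations are binarized (a CAZyme family scores 1 iff the genome
encodes ≥ 1 member enzyme; pathway calls are already 0/1) into the binary
phenotype matrix (BPM). A phylotype's phenotype value is the unweighted
mean of BPM rows over all genomes of all its members, so strain-variable
traits take fractional values. The CPI of a sample is Σₜ *a*ₜ·*v*ₜ with
abundances renormalized over *mapped* phylotypes; the mapped fraction is
reported per sample. Treating unmapped taxa as phenotype-negative would
bias every CPI downward, which is why they are dropped with
renormalization instead. For binary taxon values the CPI equals the
summed relative abundance of phenotype-positive taxa, so "producer
representation" and CPI coincide in that regime.

### Modulation scoring and inference

Zero counts are replaced by a pseudocount of 0.5 (half a read,
configurable) before relative conversion, so fold ratios always exist;
affected phylotypes are flagged. A phylotype is *increased* when the
ratio of mean relative abundances (treatment/control) is ≥ 5 and
*reduced* when ≤ 1/5 — bounds inclusive, a determinism choice for ratios
landing exactly on the cut-off. Replicate means (not pooled counts) enter
the ratio. Ratios computed through pseudocounts should be read with
caution, as very low counts dominate them.

The exact Mann–Whitney test ranks the pooled replicates with mid-ranks
for ties and enumerates every C(n₁+n₂, n₁) assignment of ranks to the
first group; the two-sided p is min(1, 2·min(P(U ≤ u), P(U ≥ u))) under
this exact distribution. Its resolution floor, 2/C(n₁+n₂, n₁), is 0.002
at 6 vs 6 and 0.008 at 5 vs 5 — the most frequently attained values in
small complete-separation designs. Groups larger than 10 fall back to the
normal approximation with a logged notice. Student's t (pooled variance)
and the chi-squared test (no continuity correction) are provided for
CPI-style and frequency comparisons. **No multiple-testing correction is
applied by default** (α = 0.05), matching the hypothesis-driven small-n
design; an optional Benjamini–Hochberg switch exists but is off.

Shannon diversity uses the natural log by default (base 2 available);
Bray–Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); PCoA is classical scaling (delegated to
scikit-bio), returning axes with positive eigenvalues and variance
fractions.

### f-scores

For responder sets A, B (taxa with p < α and increased means vs the same
control — the increased direction only, by default): o = |A∩B|,
s = |A| + |B|, f = 100·o/s, undefined (reported missing, not 0) when
s = 0. f is bounded by 50, attained only for identical non-empty sets.
Taxa are matched across treatments by exact phylotype display name,
multi-names included. Prebiotic–herb profiles summarize, per prebiotic
(mucin included on the prebiotic side), the herbs with f strictly above
10: count, mean and range.

## Synthetic data: what it emulates, and what it does not

The generator plays the role of the reference databases and the
sequencing run. Reference lineages are organized into genera with
genus-correlated phenotype content: each genus draws a carriage
probability from Beta(c·p, c·(1−p)) around the target prevalence p
(concentration c = 8), its species draw Bernoulli from it, so related
taxa share traits while marginal prevalence matches the target. Positive
families get 1 + Poisson(2) enzymes; 16S copy numbers are uniform
integers in [1, 15], the known biological range, chosen to stress the
renormalization path.

Hit tables plant one ASV per reference: best identity M ~ U(0.95, 1.00)
at 3 decimals, and (with the configured ambiguity rate, default 0.2) 1–3
decoys strictly inside the admission window plus decoys strictly below
it. Identities are placed by integer milli-arithmetic so the planted
membership survives rounding exactly; when the window holds no 3-decimal
point (M near 1) the ASV stays unambiguous.

Experiments draw baseline relative abundances log-normal(0, σ = 1.5) —
a skewed community dominated by a few taxa — apply planted per-taxon fold
changes per condition, renormalize, and sample each technical replicate
as an independent multinomial at the configured depth. Replicates share
one composition (technical noise only); Dirichlet overdispersion is
available for biological-replicate scenarios but off by default.

Default study conditions: 120 species in 30 genera, 6 replicates per
condition, depth 10⁵ reads (the experimental regime is 4–6 replicates at
~1.3 × 10⁵ reads). Planted responders are drawn from taxa with baseline
relative abundance in [1e-3, 5e-3]: expected counts of 100–500 reads make
a 10-fold shift unambiguous at this depth, while the planted mass stays
small enough that compositional dilution cannot push a true 10-fold
effect below the five-fold cut-off (worst-case dilution ≈ 1.7×). When the
band holds too few taxa the selection falls back to the nearest taxa by
log-distance.

**What passing tests do not show about real data:** the generator has no
sequencing error, chimeras or contamination; identity values are planted,
not computed from sequences; phenotype annotations are internally
consistent by construction (no annotation error); and technical
replicates are genuinely exchangeable, which real library preparation
only approximates. Recovery and calibration results are statements about
the statistical machinery under the stated noise model, not about
database quality or wet-lab artifacts.

## Numerical choices

- Relative abundances renormalize to column sums of 1 within 1e-9.
- PCoA keeps eigenvalues > 1e-10; round-trip accuracy on Euclidean
  matrices is 1e-8.
- Tie handling in the exact test uses mid-ranks; tail comparisons use an
  absolute guard of 1e-9 on U.
- p-values are stored at full precision; summary displays round to 3
  decimals.
- Degenerate inputs fail loudly: all-zero samples, empty hit sets,
  unresolvable reference ids, asymmetric distance matrices and
  zero-expected-count contingency tables are errors, not warnings. The
  one exception: a t-test on two identical constant vectors returns
  p = 1 (no evidence) rather than failing on zero variance.

## Problem sizes

The test suite and acceptance checks run at desk scale, chosen as the
smallest sizes at which every claim is still meaningfully exercised:
recovery and calibration use 20 seeds × 120 phylotypes with full
enumeration tests per phylotype; the oracle-equivalence sweep covers all
group sizes up to 7 against a brute-force permutation oracle; formula
conformance samples 10⁴ random set pairs. The accession-bound headline
numbers of the original experiments (hundreds of phylotypes from ~10⁵-read
libraries against pinned external databases) require the deposited raw
data and are intentionally not reproduced here.

## Known limitations

- The admission rule's behavior when *all* hits are poor is governed only
  by the window; there is no global identity floor.
- Pseudocount-driven fold ratios for rare taxa are sensitive to the
  pseudo value (0.5 by default, configurable).
- The exact test's conservatism under heavy ties (rare taxa with many
  zero counts) lowers its effective size below α; null calibration holds
  in the abundant regime the default generator produces.
- Copy-number estimation ignores phylogenetic placement
  (no hidden-state prediction); unknown lineages get coarse rank or
  global means.
- `prebiotic_herb_profile` assumes the class labels of the packaged
  treatment roster; user-supplied metadata must use the same classes.
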