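# Methods

This note records the models, conventions and design choices behind
`tagdge`, in the order the pipeline runs them.

## Reference digestion

A canonical tag is the `CATG` anchor plus the 17 nt immediately downstream,
taken at the **3′-most** NlaIII site of a transcript that still has a
complete, N-free 17-nt window. The 3′-most convention follows the chemistry:
3′ fragments are bead-captured after NlaIII digestion, so the MmeI-released
tag abuts the last `CATG` before the poly(A) tail. Sites whose window
contains `N` are skipped in favour of the next site upstream.

The mapping index is built over **both strands by default** (`strand_mode=
"both"`): tag libraries of this family are not strand-resolved, and a
reference built from assembled unigenes of unknown orientation roughly
doubles its distinct tag count when antisense tags are included, which
matches the tag-to-unigene ratios reported for real references of this
assay. `sense` mode is available for strandedness experiments. Tags shared
by more than one gene stay in the index, flagged ambiguous. Coordinates are
0-based on the oriented strand.

## Tag QC

Per distinct tag, in order: tags containing `N` → low-quality; exact match
to a configured adaptor 21-mer → adaptor-only; any other structural defect
(wrong length, missing anchor) → counted with the low-quality class; library
copy number 1 → singleton; the rest is the clean library. The four category
totals partition the raw total exactly, and filtering is idempotent.
Adaptor detection is exact string match (configurable input set); it is
checked before the structural test because adaptor-only reads never carry a
`CATG` anchor and would otherwise vanish into the low-quality class.
Singleton removal is per-library. Report percentages are rounded half-up to
two decimals; copy-based rows are relative to the clean total, distinct-tag
rows to the distinct clean count, gene rows to the reference gene count.

## Mapping

Exact index lookup first; an exact hit shared by several genes is final
(ambiguous), never rescued through mismatch neighbours — an error-tolerant
match must not override a perfect observation. A tag with no exact hit is
compared via its 51 single-substitution neighbours of the variable region;
the `CATG` anchor is held fixed because anchor-corrupted tags were already
removed at QC. The union of neighbour gene sets decides unique / ambiguous /
unknown. A tag hitting the sense and antisense tags of the same gene is
unique to that gene and counted once. TPM uses the **clean-tag total** as
denominator (the assay's convention); a mapped-tag denominator is available
behind a flag at the model level by passing the mapped total instead.

## Exact test and calling

With `r = N2/N1`, the conditional `p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1))`
is the negative-binomial `NB(x+1, N1/(N1+N2))` pmf. The two-sided p-value is

```
p = min(1, 2 · min(F(y), 1 − F(y))),   F = inclusive lower CDF
```

This convention was chosen because it is **exactly symmetric** under
exchanging the libraries, `(x, N1) ↔ (y, N2)` (via the incomplete-beta
identity `F_{x,r}(y) = 1 − F_{y,1/r}(x)`), returns exactly 1 for `x = y`
with equal totals, and is monotone in `|y − x|`. The alternative that
includes the observed point in both tails is not exactly symmetric and was
rejected. Numerically, whichever tail is smaller is summed directly in log
space (log-gamma terms, chunked until a whole chunk is negligible at
relative 1e-18); the small tail is never formed as `1 − big`, so tiny
p-values keep full relative accuracy. Agreement with a term-wise summation
oracle is ≤ 4e-13 over counts 0–200 and totals 1e5–5e6.

Multiple testing uses Benjamini–Hochberg step-up (delegated to statsmodels
behind `bh_fdr`). Default thresholds: FDR ≤ 0.001 and |log₂ ratio| ≥ 1
(2-fold). The fold-change floor is exposed (`min_abs_log2`) because the
literature of this assay family states it both as "log2 foldchange ≥ 2" and
as a bound on |log₂ ratio|; 1.0 (2-fold) is the default as the reading
consistent with the per-gene DE tables of such studies. Zero TPM is
replaced by 0.001 **only** when forming ratios; the test itself uses the
raw counts, and genes absent from one library are tested with count 0.

## Abundance categories and trend groups

Categories are left-closed: rare [0, 5), low [5, 50), moderate [50, 100),
high [100, ∞); the published "TPM > 5–50" style notation is ambiguous at
the boundaries, so a fixed half-open convention was adopted. Five-stage
profiles (floored at 0.001) are classified by ordered rules: amplitude
(max/min) < 4 → constitutive, unless the profile drifts steadily (Spearman
|rho| ≥ 0.6 against the stage index *and* endpoints differing ≥ 2-fold in
the same direction), in which case it falls through to the trend rules; a
unique stage-3 maximum ≥ 1.3× both endpoints → low-high-low; rho ≥ 0.6 or
a maximal last stage ≥ 2× the first → up; mirrored → down; otherwise
unclassified. The monotone-escape clause on the constitutive rule exists
because shallow but perfectly steady drifts (e.g. a 2.1-fold strictly
increasing profile) are trends, not constitutive expression. All four
thresholds were calibrated once against the bundled 39-profile reference
panel and frozen; the panel's plasma-membrane ATPase row (14-fold range,
labelled constitutive) is irreconcilable with any amplitude-based rule and
is the single accepted mismatch (38/39).

## Pathway enrichment

For `N` annotated background genes, `n` annotated DEGs, `M` genes in a
pathway and `m` DEGs among them, `P = P(X ≥ m)` for hypergeometric X
(scipy's survival function behind `upper_tail_pvalue`; exact rational
enumeration is the test oracle, agreeing to < 1e-15 for all instances with
N ≤ 30). Significance is flagged at raw P ≤ 0.05, the convention of this
assay family; a BH column is emitted alongside but does not drive the flag.
Genes in several pathways count in each; DEGs without annotation are
dropped with a logged count.

## Saturation

Subsampling is **nested**: one random permutation of the clean-tag stream
per replicate, evaluated as prefixes, so each replicate's detected-gene
curve is non-decreasing by construction. Ambiguous and unknown tags occupy
stream positions (depth is tags sequenced, not tags mapped) but cannot
detect a gene. On a uniform toy library (G genes × t copies), the expected
curve has the closed form `G·(1 − C(T−t, d)/C(T, d))`; the simulated mean
matches it within Monte-Carlo error, which the validation suite checks with
a family-wise 99% confidence band using the theoretical (independence-bound)
standard error, since the sample variance degenerates near the endpoints.

## The simulator: what it does and does not emulate

`SimulationConfig` defaults describe a deep five-stage fruit-development
experiment: 90,227 genes, uniform lengths 150–900 bp (mean ≈ 0.5 kb,
matching typical unigene assemblies), GC 0.45, five stages, log-normal
abundances (σ = 1.5 in natural log, a typical transcriptome dynamic range),
5% of genes changing 2–16-fold between adjacent stages, 6 million raw tags
per library, 0.2% per-base substitution error, 0.5% N-artifact and 0.2%
adaptor-artifact tags. Error and artifact rates are plausible for the
sequencing technology of this assay generation, not fitted to any dataset —
no per-library error estimates exist to fit to.

Faithful by construction: exact stream depth (artifacts replace positions,
so QC partitions a fixed total); substitution errors i.i.d. over all 21
positions including the anchor (errors do not respect the anchor, and
anchor hits exercise the QC low-quality path); DE genes drawn as an
exact-size subset so planted counts are reproducible; fold changes applied
to the previous stage then renormalised (abundances are compositional, so
large planted changes slightly shift every other gene — the recorded truth
keeps non-DE log-fold-changes at 0, and the validation scenarios tolerate
the resulting small compositional bias).

Not emulated: read-level FASTQ/quality scores, PCR duplication, isoforms,
overdispersion beyond the planted fold changes (counts are multinomial
given abundances, i.e. Poisson-like). Passing tests therefore demonstrate
correctness of the bookkeeping and the statistics under the assay's own
sampling model, not robustness to biological replicate variance — the
exact test inherits that limitation by design.

`simulate_annotation` produces a random GMT-style gene→pathway map (120
pathways over 60% of genes) so enrichment can run end-to-end on synthetic
data; it carries no biological structure.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: the full 201×201
count grid at nine total-pairs for the exact-test oracle; two-stage
simulations of 2,000 genes at 1–2 million tags per library (three seeds for
the null scenario, one for planted recovery — sizes at which the planted
effects are unambiguous while a full run stays under a minute); a 300-gene
index with 1,000 mixed queries for the mapping oracle; every hypergeometric
instance with N ≤ 30; and 200 replicates of the uniform saturation toy.

## Known limitations

* The exact test assumes Poisson sampling within a library; with biological
  replicates a dispersion-based model (negative-binomial GLM) is more
  appropriate and deliberately out of scope.
* Ambiguous tags are discarded rather than apportioned; genes whose
  canonical tags are all shared are invisible to quantification.
* The trend classifier is a fixed rule set for five-stage profiles only;
  it is a reporting convention, not a time-course model.
* `percent` uses half-up decimal rounding to reproduce two-decimal report
  tables; it is for reporting, not computation.
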