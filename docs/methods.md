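# Methods

`uraburden` tests whether ultra-rare coding variants pile up in individual
genes or in functionally related gene-sets within a case-only sequencing
cohort — no parental genomes, no matched controls.  This note records the
statistical model, the defaults and why they were chosen, the behaviour of
the synthetic-data generator, and the numerical decisions a maintainer
would want to know about.

## Ultra-rare variant definition and filter cascade

An *ultra-rare* variant is a cohort singleton (allele observed in exactly
one subject) that is absent from all three population references (1000
Genomes, ExAC, gnomAD).  A missing frequency annotation and a literal 0
are both treated as "absent".  The rationale: such variants are strongly
enriched in recent, often de novo, mutations, which licenses the use of de
novo mutation-probability models below.

The cascade applies, in order:

1. **Ultra-rare selection** — cohort allele count 1 and absence from every
   reference.
2. **Call quality** — remove calls with DP ≤ 10; heterozygous calls with
   alternate-read fraction < 0.3 or GQ < 99; homozygous calls with
   alternate-read fraction < 0.8 or GQ ≤ 25.  The het genotype-quality rule
   keeps only calls at the common GQ cap of 99: a rule that removed GQ ≤ 99
   would remove every capped het call, so the threshold is interpreted as
   "anything below the cap is suspect".  All four thresholds are
   configurable (`QCThresholds`).
3. **Frameshift-indel collapse** (truncating class only) — when a subject
   carries two or more frameshift indels in one gene, the signed sizes
   (insertions positive, deletions negative) are summed; if the total is a
   multiple of 3 the reading frame is restored and all are removed,
   otherwise a single representative is kept.  The representative is the
   record with the smallest (chrom, pos) — any deterministic choice works,
   since the final per-gene count only asks whether the subject carries at
   least one.  An `absolute` size convention is available
   (`size_mode="absolute"`) for pipelines that treat cumulative size
   unsigned.
4. **Principal transcript** — only effects on the gene's principal isoform
   (APPRIS-style map) are retained; genes without a mapped principal
   transcript are dropped and counted in the log.
5. **Splice-insertion rescue** (truncating only) — an insertion labelled as
   hitting a canonical splice dinucleotide is only truncating if the
   alternate allele no longer encodes the canonical motif.  The local
   alternate sequence is reconstructed by splicing the inserted bases into
   an annotated reference context window (±10 bp around the dinucleotide)
   and the canonical GT (donor) / AG (acceptor), reverse-complemented on
   the minus strand, is looked up at the annotated offset.  A flagged
   record without annotation is conservatively retained as truncating.
6. **Per-gene-per-subject cap** — at most one qualifying variant per gene
   per subject, so a gene's count equals its number of distinct carrier
   subjects.  This is what makes the binomial model below coherent: each
   subject is one Bernoulli trial per gene.

Every filter only removes or reclassifies records, so stage counts are
non-increasing and each filter is idempotent.

## Rescaled mutation probabilities and the gene burden test

Per-gene, per-generation de novo mutation probabilities P_exp,g (as
distributed with sequence-context mutation models, separately for
loss-of-function and missense classes) are rescaled by a single global
scaling factor chosen so that expected and observed totals match over the
gene universe G (all genes with a defined probability):

    SF = N_obs / (N_S · Σ_{g∈G} P_exp,g)

where N_obs is the total number of ultra-rare variants of the class and
N_S the number of subjects.  Any systematic factor — diploidy, ascertainment,
pipeline differences — is absorbed into SF, so the probabilities are used
exactly as supplied (no ×2 diploid correction).  The per-gene carrier
probability is P_success,g = P_exp,g · SF, clamped at 1 with a warning for
pathological inputs.  By construction Σ_g P_success,g · N_S = N_obs exactly
(`RescaledModel.check_conservation`).

Each gene is then tested one-sided: with k observed carriers,

    p = P(X ≥ k),  X ~ Binomial(N_S, P_success,g),

and a gene with no carriers gets p = 1.

**Constrained universes.**  A second analysis restricts G to genes under
negative selection: gnomAD observed/expected < 0.35 for truncating, < 0.75
for missense variants (strict inequalities; genes missing from the
constraint table are excluded).  SF is recomputed within the restricted
universe, and by default N_obs is also restricted to variants in universe
genes (`n_obs_scope="universe"`), which keeps the conservation identity
within the analysis; `"all"` reproduces the alternative reading.

**Multiple testing.**  BH-FDR is computed per variant class over m = |G|
(genes without observations enter as p = 1, or can be omitted — at top
ranks the two are identical since p·m dominates); Bonferroni multiplies by
the joint universe size of both classes.  Subject-subset analyses (e.g. a
diagnosis subgroup) re-run the whole chain including corrections.

## Exact-test enrichments

Three analyses share the 2×2 machinery (`fisher_exact`):

- **Reference-singleton comparison**: cohort ultra-rare variants in a gene
  vs elsewhere, against reference-database singletons in the same gene vs
  elsewhere; the universe is restricted to genes with at least one
  truncating and one missense reference singleton (avoiding masked genes);
  two-sided, BH across tested genes.
- **Protein-region enrichment**: cohort vs reference variant positions
  inside vs outside a named amino-acid interval; one-sided greater.
- **Residue-class enrichment**: membership is a set of positions (e.g.
  disulfide-bond cysteines); one-sided greater.

The two-sided p-value uses the minimum-likelihood rule (sum of all
hypergeometric table probabilities no larger than the observed table's),
not mid-p or doubling.  The reported odds ratio is the conditional
maximum-likelihood estimate under the noncentral hypergeometric model
(+∞ when an off-diagonal cell is 0 with a positive diagonal); the sample
estimate ad/bc is also emitted for transparency.  Both are cross-checked
in the tests against full-table enumeration and a dense grid search of the
conditional likelihood.

## Gene-set burden, clustering and resampling FDR

A gene-set's carrier probability is Σ over member genes of P_success,g
(clamped at 1) and its observed count is the number of subjects carrying
≥ 1 qualifying variant anywhere in the set (one variant per set per
subject).  Sets are tested only if, after intersection with the
probability universe, they contain more than 5 and fewer than 100 genes —
small sets lack power, large sets are overly general, can be dragged to
significance by one concentrated gene, and violate the one-variant-per-
subject approximation; in constrained mode a set must also retain at
least two constrained genes.

Curated collections overlap heavily, so significant sets are de-correlated
by **greedy step-down clustering**: repeatedly select the most significant
remaining set (ties broken lexicographically by name for determinism) and
absorb every remaining set whose Jaccard similarity with it exceeds 0.5.
Similarity is computed on the sets' *ultra-rare variant content* — the
(gene, subject) indicator entries of member genes — not on gene lists, so
two sets only cluster when they share observed signal.  This makes the
clustering data-dependent by design.

The surviving representatives get a **resampling-based FDR**: the observed
variants are redistributed over the universe by a multinomial with
probabilities ∝ P_success,g, preserving the total count exactly; each
resampled variant lands on a uniformly random subject, and duplicate
(gene, subject) draws are retained as multiplicity and only capped at test
time.  Each of the (default 1000) iterations re-runs the full gene-set
test plus greedy selection (`perm_selection="fixed"` skips the
re-clustering for comparison).  At each representative's p-value threshold,

    FDR_p = mean_i(N_selected sets with p ≤ threshold in iteration i) / N_real,

clamped to [0, 1] and monotonized by a cumulative minimum from the least
to the most significant threshold, so reported q-values never decrease as
the threshold weakens.

## Power

Prospective power for a single gene uses the one-sample proportion test
with Cohen's arcsine effect size h = 2·asin(√p1) − 2·asin(√p0), where p0
is the rescaled null carrier probability and p1 the alternative (e.g. an
observed carrier fraction): power = Φ(h√n − z_{1−α}), inverted for the
required sample size and verified by integer search.  α defaults to 0.05
divided by the joint Bonferroni universe size.  The approximation is
validated against Monte Carlo power of the arcsine-stabilized statistic
under exact binomial sampling; agreement is within 0.02 for n ≥ 200
provided n·p0 is not so small that binomial discreteness dominates (for
carrier probabilities of a few per mille, discreteness alone moves the
rejection boundary by more than that band — exact binomial calculations
should be preferred there).

## Synthetic data: what it emulates and what it does not

The generator draws per-gene probabilities log-uniformly over
[1e-7, 1e-4] per class — the dynamic range of published per-gene de novo
tables — and distributes the stated per-class variant totals (defaults:
231 subjects, 642 truncating and 3293 missense ultra-rare variants, the
scale of the motivating cohort) multinomially over genes, with uniform
subject assignment.  Burden is injected as extra *distinct* carriers of a
named gene; filter violations (low DP, low alt fraction, reference-
frequency hits, non-principal transcripts, frame-restoring indel pairs)
are planted at configurable rates.  Ground-truth labels are returned in a
side channel, never written into the variant table.

What it does **not** model: sequence context (all synthetic variants are
point alleles at arbitrary positions), linkage and relatedness, batch and
pipeline artifacts, per-gene annotation error, or realistic genotype-
quality distributions (clean records are uniformly high quality).  A
passing synthetic suite therefore demonstrates that the statistics are
computed correctly and are calibrated under the stated multinomial null —
not that real cohorts are free of the artifacts the surrounding checks
(reference-singleton comparison, comparison cohorts, QQ inspection) are
designed to catch.

Problem sizes in the test suite and in `scripts/acceptance.py` were chosen
as the smallest that make the stochastic assertions stable: 300–500 gene
universes, 200 null or injected replicates, 1000 resampling iterations,
100k Monte-Carlo power draws.

## Numerical and design notes

- Binomial tails via `scipy.stats.binom.sf`; validated to 1e-12 relative
  against exact tail summation on n ≤ 50 grids.
- The BH step-up supports a test count m larger than the number of
  supplied p-values so unobserved genes can enter corrections implicitly.
- The recovery benchmark injects 7 carriers into a gene with a typical low
  truncating probability (~1e-6): the scientifically interesting regime is
  a large observed count against a small expectation; injecting into a
  high-probability gene (expected carriers already ≈ 5–9 in a cohort of
  231) is a different, intrinsically underpowered question.
- Degenerate inputs fail loudly: empty constrained universes, zero
  observed totals, all-zero contingency tables, gene-sets empty after
  universe intersection, and enrichment tables with an empty in-class
  margin all raise.
- Coordinates are 1-based VCF-style; indels are used as given (no
  re-normalization or left-alignment).
- All randomness flows through `numpy.random.Generator` objects or
  explicit seeds; identical seeds give byte-identical outputs.
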