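# Methods

## Data model and functionality classes

One record per sequencing read: a functionality class, V/D/J gene calls, CDR
amino-acid sequences, the CDR3 nucleotide sequence and the full read.
Functionality tokens from annotation pipelines are normalized by
case-insensitive prefix match onto four classes — `productive`,
`unproductive`, `unknown`, `no_result` — with unrecognized tokens mapped to
`unknown` under a logged warning (pipelines append free-text parentheticals
to these tokens, so exact matching would misclassify). `no_result` reads
(no alignment found) carry no annotation-derived fields and are excluded from
every clonality and diversity computation; they appear only in the
functionality summary.

Which of the remaining classes enter clonotype counting is a property of the
`ClonotypeDefinition` (default: all three; `productive_only()` restricts to
productive reads, the usual convention in repertoire studies). Keys are
compared by exact string identity after upper-casing and whitespace
stripping; `*` (stop) and `X` are legal CDR3 characters because out-of-frame
junctions translate with stops. Ties in every sorted table break by
descending count then ascending key, so all outputs are deterministic.

## Rarefaction

`rarefy` draws, for each grid point `n`, `replicates` (default 5) independent
subsamples of size `n` without replacement from the `N` clonotype keys and
averages the distinct-key counts. Sampling is without replacement because the
estimand is "how many clonotypes would I have seen at depth n of this
sample", not a draw from an infinite population; this makes the exact
expectation hypergeometric:

    E[c_unique(n)] = Σ_i [ 1 − C(N−N_i, n) / C(N, n) ]

for clonotype abundances `N_i`. `expected_unique` evaluates this in log space
(`gammaln`) and serves as the independent oracle for the sampler in the test
suite (200-replicate means agree within a fraction of a percent). The default
grid is {0, 1000, 2000, …} plus `N` itself; `n = 0` anchors the model at the
origin and `N` pins the most informative, least noisy point.

## The saturation-plus-error model

    div_mod(n) = a·(1 − exp(−b·n)) + k·n,  a, b, k ≥ 0

assumes (i) a fixed pool of `a` true clonotypes sampled at a single effective
rate `b`, and (ii) read errors that convert a constant fraction `k` of reads
into spurious unique clonotypes. Assumption (i) is deliberately coarse: a
real abundance distribution is a mixture of discovery rates, and when the
sample contains genuinely rare clonotypes still being discovered at full
depth, their residual discovery is linear-like and is absorbed into `k`. That
is real diversity, not read error — so `k` is only interpretable as an error
fraction when the sample saturates (see *What the simulations show* below).

Units: `n` and `N` count reads carrying a key; `a` counts clonotypes; `b` is
per sequence; `k` is dimensionless (clonotypes per read).

## Fitting by evolution strategy

The objective is the unweighted sum of squared residuals between `div_mod`
and the replicate-mean curve (replicate variances are not used as weights;
the means are what the model describes). The optimizer is an elitist
(μ+λ) = (10+50) evolution strategy, 500 generations:

- genome: `a` on a linear scale, `b` and `k` on a natural-log scale (they
  span orders of magnitude and must stay positive); `a` is reflected at 0,
  log-parameters floored at ln(1e−12);
- per-parameter step sizes, self-adapted by log-normal perturbation with
  learning rate τ = 1/√(2·3); no recombination — the problem has 3 dimensions;
- initialization: a₀ = div_calc(N) (the observed plateau), b₀ = 3/N (the
  saturating basin), k₀ = the terminal slope of the curve; the unmutated
  start is kept as a parent, so with elitist selection the final objective
  can never exceed the initial one and the per-generation best objective is
  non-increasing — both are asserted in tests;
- all randomness flows from a single user-supplied seed; identical seeds give
  bit-identical fits.

Degenerate inputs behave sanely: a flat-zero curve fits to `a ≈ 0`, `k ≈ 0`
with objective ≈ 0; fewer than 4 grid points (3 free parameters) is rejected.

On noiseless model-generated curves the fit recovers `a` to machine-level
precision (measured ≪ 1% relative error); under 1% multiplicative Gaussian
noise the median error in `a` over 20 seeds stays below 1%.

## Synthetic repertoires

The generator emulates a multiplex-PCR amplicon run of one locus: a fixed
pool of distinct CDR3 amino-acid keys (lengths uniform on 8–16 aa) with
random V-(D)-J assignments from the bundled germline reference; multinomial
read sampling over a clonal abundance distribution (default: geometric with
ratio 0.995, giving the skewed, slowly saturating curves typical of real
samples; uniform and lognormal alternatives); a functionality mix (default
0.828 / 0.104 / 0.005 / 0.063 — proportions typical of a heavy-chain run);
and a per-read error: with probability `error_rate` one random CDR3 position
is substituted, usually creating a spurious unique clonotype — the minimal
mechanism behind the model's `k·n` term.

What it does **not** emulate: real junctional sequence statistics (CDR3
nucleotide sequences are random codon-length strings, not reverse
translations; flanking read sequence is random per clonotype), realistic
V(D)J recombination (no junctional insertions/deletions), platform-specific
error profiles (no indels, no quality correlation), or primer-induced
amplification bias. Passing tests therefore demonstrate the estimators'
correctness under the stated sampling model, not robustness to every artifact
of real libraries.

What the simulations show: at 100,000 reads from 1,000 clonotypes with a
0.1% error rate, the fitted `a` lands within ~11% of truth under geometric
abundances; under uniform (saturating) abundances with no errors the fitted
`k` collapses to ~1e−7 and with 0.1% errors it recovers ~0.001. Under the
geometric default with no errors, `k` settles near 1e−3: rare clonotypes
(expected ~3 reads each) are still being discovered at full depth and the
single-exponential model absorbs that residual discovery into the linear
term. This is the documented limitation of assumption (i), and it is why the
error-isolation checks use a saturating sample.

## Design choices on open points

- **Summary dialect.** Annotation portals emit many files with drifting
  headers; the package defines one canonical tab-separated dialect with
  remappable column names (`SummaryDialect`) rather than hard-coding any
  vendor's headers. The README documents a typical mapping.
- **FASTA split/merge** is byte-preserving (headers and line wrapping kept
  verbatim) so that merging chunks reproduces the source exactly; library
  FASTA parsers normalize wrapping and would break that guarantee.
- **Reverse primers** are searched as reverse complements by default because
  annotated reads are reported in V→J orientation; `--literal` disables this.
  IUPAC degenerate codes in a primer match any compatible read base; a
  read-side ambiguity code is matched only by `N` in the primer. The per-
  primer denominator is all searched reads, with reads lacking any
  forward/reverse hit reported separately. The `v_region` search field is
  defined as the read prefix ending where the CDR3 nucleotide sequence
  begins (falling back to the whole read), since summary tables carry no
  dedicated V-region column.
- **Ambiguous gene calls** (comma-separated alternatives) resolve to the
  first listed, the annotation pipeline's highest-scoring hit.
- **Germline reference.** A curated, versioned subset of human TRB and IGH
  gene/allele names ships with the package for spectrum mapping and
  simulation; users can load their own full tables (`GermlineReference.
  from_tsv`). Observed genes missing from the reference are warned about and
  kept under an explicit "unknown" section, never dropped. Spectrum axes sort
  in natural numeric order (TRBV2 < TRBV6-4 < TRBV12-3) so exports align
  across samples.
- **Threshold filtering** of combination matrices keeps the original total as
  denominator so surviving frequencies remain fractions of the sample.
- **Comparer colors** are assigned by a deterministic hash of the key, so a
  clonotype matched across any number of reports always renders identically.
  Default top-c is 20. Comparers match on exact key identity only (no V-gene
  qualifier on CDR3 keys).
- **Frequency scales.** Clonotype tables and comparison reports use
  percentages (0–100) at full precision, formatted only at export; all other
  tables use fractions (0–1).

## Problem sizes

The bundled tests and the acceptance script run simulations at up to 100,000
reads / 1,000 clonotypes, rarefaction grids of ~100 points × 5 replicates,
200-replicate oracle comparisons at 2,000 reads, and a 1.2-million-record
FASTA split — sizes chosen to exercise run-scale behavior while completing in
seconds on a single CPU.

## Known limitations

- The diversity estimate is a point estimate; no confidence interval is
  computed.
- Alternative diversity indices (Shannon, Simpson, Chao1) are out of scope.
- Primer matching is exact (degenerate-code-aware) substring search; no
  mismatch tolerance.
- The fitted `a`/`k` decomposition degrades when the abundance distribution
  has a heavy tail of never-saturating clonotypes (see above).
- Only human gene nomenclature ships with the package.
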