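# Methods

## Coordinate model

A promoter window of length `L` anchored at a transcription start site (TSS)
covers TSS-relative positions −L…−1; the base at −1 is immediately 5′ of the
TSS and the TSS base itself is excluded. Genomic coordinates at the API
boundary are 1-based inclusive (NCBI style); internally everything is
0-based half-open, with `index = rel + L`. On the + strand the window is the
genomic interval `[tss − L, tss − 1]`; on the − strand it is the reverse
complement of `[tss + 1, tss + L]`, so the extracted sequence always reads
5′→3′ toward the TSS. Whether a published "−3 kb promoter" includes the TSS
base itself is convention-dependent; we fix the TSS-excluded convention,
which can introduce a ±1 offset against coordinates produced under the other
convention. A feature's TSS-relative position is that of its 5′-most base on
the + strand of the window.

Input sequences are uppercased, U→T, and IUPAC ambiguity codes other than N
are collapsed to N at load: the scanners define behaviour only over
{A,C,G,T,N}, and a conservative N (match nothing) is the safest reading of
masked or ambiguous sequence.

## PWM scoring

Position frequency matrices are parsed from the raw JASPAR dialect (labelled
rows, brackets optional, any row order). Counts become corrected
frequencies with a background-distributed pseudocount,

    f_bj = (n_bj + κ·p_b) / (N_j + κ),   w_bj = log2(f_bj / p_b),

with κ = 0.8 and uniform `p` by default. These constants are not dictated by
the scientific question — any standard PFM→PWM recipe works here — and the
min–max **relative score**

    rel(s) = (s − s_min) / (s_max − s_min),

where `s_min`/`s_max` are the sums of per-column weight extrema, is
invariant to the log base and only weakly sensitive to κ. The
high-confidence filter is `rel ≥ τ` with τ = 0.85 inclusive. No per-site
p-values are computed: the relative-score threshold is the sole PWM filter,
and a matrix whose best and worst words score identically (uninformative at
every column) is rejected at build time.

Both strands are scanned by default (D-box-like sites are not palindromic);
a − strand hit is scored on the reverse complement of the window but
reported at the + strand 5′-most base, and `matched` always carries the
+ strand substring, so every hit can be verified against the promoter
sequence directly. Windows containing N are skipped (with the skip disabled,
N scores the column minimum). All overlapping hits are reported; a greedy
non-overlap pruner (highest relative score, ties to the 5′-most hit, then
+ strand) is available but off by default, since any deduplication policy is
a reporting choice rather than part of the scoring model.

## Consensus families

Six bundled families: canonical E-box `CACGTG`, degenerate E-box `CANNTG`,
D-box `TTATGYAA`, CRE `TGACGTCA`, Pdp1 `ATTTAT/ATAAAT`, PER-repeat
`CATAC/GTATG`. Matching is positional-set membership (a pattern N admits
{A,C,G,T}; a sequence N matches nothing), implemented as overlapping-match
regular expressions. The default is + strand reporting — the Pdp1 and
PER-repeat alternative pairs are mutual reverse complements, so those
families are orientation-closed even in + only mode — with both-strand
scanning as an explicit option. Because every `CACGTG` is also a `CANNTG`,
degenerate E-box hits co-located with canonical ones are removed by default;
counts would otherwise double-count every canonical site.

## Enrichment test

Observed per-family counts (scanner conventions included: strand mode and
E-box dedup apply identically to observed and null counts) are compared to
counts in `n` background sequences of the same length. The null model is a
zero- or first-order Markov chain with add-pseudocount smoothing (default
pseudocount 1), fitted by default to the query promoter itself; a
user-supplied promoter set can replace resampling (each supplied sequence
contributes one null count and `n` becomes the set size). The empirical
one-sided p-value is

    p = (1 + #{null ≥ observed}) / (1 + n),

never zero by construction; depletion uses `#{null ≤ observed}`. Correction
across the tested families (all configured consensus families plus each
supplied PWM) is Benjamini–Hochberg by default, Bonferroni optionally, via
statsmodels. Defaults: n = 999, α = 0.05.

**Calibration caveat.** Motif counts are small integers, so the empirical
p-value is discrete and the test is conservative: with a null mean of ~1.46
Pdp1 cores per 3 kb (uniform background, + strand), the largest attainable
rejection region below 0.05 has true mass ≈ 0.02, and measured type-I rates
over replicated experiments sit at 0.015–0.03 rather than 0.05. This is the
standard behaviour of add-one permutation p-values on discrete statistics,
not an implementation artefact; power on promoters carrying five planted
cores is ≈ 1.0 regardless.

## Synthetic data

The generator emulates the study conditions the analysis assumes: 3 kb
promoters from a zero- or first-order Markov background (uniform base
composition by default — the composition under which the closed-form
expectations like 2·2995·4⁻⁶ ≈ 1.46 Pdp1 cores per window hold; an AT-rich
honeybee-like composition can be supplied as a fitted model), optionally
purged of all six families' cores by local resampling, with exact cores or
PWM-sampled words planted at fixed TSS-relative positions. Planting into a
purged background can create new matches spanning plant/background
junctions, so fixture construction finishes with a plant-aware purge that
resamples only non-planted bases; the emitted truth table therefore lists
exactly the family-core matches present. `ammtr_layout()` encodes the twelve
positions printed for the *AmMTR* promoter (Pdp1 −820/−357/−102, degenerate
E-boxes −2762/−1580/−1383, canonical E-box −1334, CRE −93, D-boxes
−2701/−2498/−457/−132); degenerate E-box plants use `CAGTTG` so the
canonical and degenerate families stay disjoint in fixtures. Generation is a
pure function of (seed, parameters).

What passing on synthetic fixtures does **not** show: real promoters are not
Markovian (CpG effects, repeats, composition gradients), real sites diverge
from consensus cores, and real TSS annotations carry uncertainty; recovery
of planted exact cores demonstrates correctness of the machinery, not field
performance of the motif definitions.

## Numerical and design choices

- PWM scanning is vectorised by summing 5×w weight-matrix lookups over
  shifted slices; the N row is −∞ (skip) or the column minimum. Scanner
  equivalence with exhaustive per-window enumeration is tested to 1e−9.
- The batch null-counting path shares this machinery and additionally ORs
  alternative patterns per family before counting, so a window matching two
  alternatives counts once, exactly as in the scanner.
- The threshold comparison is inclusive (≥ τ); the batch path allows a
  1e−12 absolute slack when translating τ to a raw-score cutoff to avoid
  float-rounding asymmetry against the scanner.
- Replicated-experiment seeds derive from `numpy.random.SeedSequence`
  spawn keys, so replicates are independent streams and every result is
  reproducible from one integer.
- Degenerate inputs fail loudly: empty FASTA, all-zero PFM columns, PWMs
  with `s_min == s_max`, plants out of bounds or overlapping, purge
  non-convergence (pathological background models).
- Problem sizes used by the shipped checks — 3 kb windows, 100 random
  scanner instances, 200 replicates × 999 resamples for calibration and
  power — were chosen as the smallest sizes at which the binomial/Poisson
  sanity expectations are sharp enough to be meaningful.

## Known limitations

- No mismatch-tolerant consensus matching and no information-content or
  dinucleotide-corrected PWM variants.
- No automatic TSS discovery; the TSS coordinate is user-supplied.
- No analytic (Poisson/compound-Poisson) p-value approximations; the
  resampling test is the only enrichment route.
- First-order purging resamples offending windows conditional on the left
  flank only, which leaves a slight dinucleotide discontinuity at the right
  window edge; for purged fixtures this is immaterial, for background-model
  inference it would not be.
- Real JASPAR matrices are not bundled (they are versioned upstream);
  fixtures use toy PFMs.
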