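# Methods

## The experimental system being modelled

The package models a deliberately simple library preparation: a pool of
single-copy DNA amplicons, each carrying two 20-nt random barcodes flanking
the 46-nt PhiC31 AttL constant region, plus a 15-nt varietal tag (a UMI)
ligated before amplification. The pool is PCR-amplified for `k` cycles
(default 25) and sequenced as fully overlapping 101-nt paired-end reads.
Because every input molecule is unique (4^40 possible barcode pairs) and
single-copy, any structure in the read-count-vs-rank profile beyond a flat
plateau must have been created by PCR or sequencing.

Two barcode classes, BC1 and BC2, carry complementary purine/pyrimidine
(R = A/G, Y = C/T) anchor patterns parsed directly from the template
strings: per 20-nt barcode, three dinucleotide anchors and one singleton
anchor (seven constrained positions). Parsing the templates, rather than
hard-coding positions, is treated as ground truth; the design is sometimes
summarised as "six positions" per barcode, which matches the count of
dinucleotide anchors per barcode pair side but not the per-barcode
constrained-position count — the parsed layout is authoritative here.
A third class, BC3, uses S = G/C codes (12 S + 8 N per barcode, expected GC
content 0.80) and carries no R/Y anchors; it exists to probe GC bias and is
excluded from switch analyses.

## Stochastic amplification

PCR is a Galton–Watson branching process: each molecule duplicates each
cycle with probability `P_amp`, so `n(j+1) = n(j) + Binomial(n(j), P_amp)`.
For a single founder the exact copy-number distribution is computed by the
binomial updating recursion — the distribution after one more cycle is the
mixture over current states `n` of `n + Binomial(n, P_amp)`. This is
mathematically identical to multiplying by the Markov updating matrix whose
`i`-th column is a shifted binomial, but is evaluated as per-state
shifted-binomial accumulation with each binomial row truncated at ±12
standard deviations (truncated mass < 1e-30 per row, far below the 1e-12
normalisation tolerance). The exact stage is limited to 15 cycles
(support 2^15).

Beyond 15 cycles each point mass at `n` is propagated to a Gaussian with
mean `n(1 + P_amp)` and standard deviation `sqrt(n · P_amp (1 − P_amp))`,
integrated over the bins of a fresh 2^14-bin grid spanning the reachable
range (CDF differences, not density sampling, so narrow Gaussians are
binned exactly), and renormalised; the grid is rebuilt each cycle.
Guards: the mean of the extended distribution must stay within 0.5% of
`(1 + P_amp)^j` and its variance within 5% of the branching-process closed
form `σ² m^(j−1)(m^j − 1)/(m − 1)` with `m = 1 + P_amp`,
`σ² = P_amp(1 − P_amp)`. `P_amp = 1` degenerates to a delta at `2^j` and is
special-cased. Sampling final copy numbers uses the exact PDF up to 15
cycles and per-founder rounded Gaussian increments after that (floored at
the current count so counts never decrease).

Mode analysis uses strict local maxima with a 1e-12 probability floor
(suppressing numerical ripple); plateaus resolve to the smallest copy
number of the flat stretch.

`P_amp` is fitted by simulation: for each candidate, `N0` founders are
amplified and Poisson-sequenced at a rate matched to the observed plateau
read sum, both profiles sorted, and the squared Pearson correlation of the
read counts computed over the common top-N. Correlation is computed on raw
(linear) read counts: the plateau and shoulder heights carry the `P_amp`
signature, and linear scoring proved markedly more stable across simulation
replicates than log-space scoring, which inflates tail noise. The score is
averaged over 3 simulation replicates per candidate; exact ties (e.g. a
perfectly flat observed profile, where no candidate correlates) resolve to
the largest candidate, the one with the least spread.

## GC bias

Because each input is single-copy, plateau abundances estimate per-sequence
PCR efficiencies. Abundances are normalised to the mean of the sequences
with GC in [0.50, 0.55), which is assigned the reference efficiency 1.9,
giving `c_x = (m_x · 1.9^25)^(1/25)`. Efficiencies are averaged in GC bins
of width 0.05 (left-closed, right-open; GC = 1.0 joins the last bin) and
regressed on GC content by ordinary least squares with a t-based 95% CI.
The regression uses per-sequence efficiencies by default (more data); a
per-bin flag exists, since which variant the original analysis used is not
stated. The GC-biased forward simulation draws GC ~ Binomial(40, 0.5)/40
per input, grows each deterministically as `c_bin^25` (missing bins inherit
the nearest populated bin) and Poisson-samples reads.

## Template switching

Switching is modelled as a bimolecular collision: the expected number of new
chimeras on cycle `j` is `S_j = s0 · N_j²`, each then amplifying like any
other molecule, giving `Q_m = Σ_j S_j c^(m−j)` switched molecules after `m`
cycles, approximated by the closed form `s0 N0² c^(2m+1)/(c−1)`
(`s0 N0² 2^(2m+1)` at `c = 2`; the closed form is the large-`m` upper
envelope of the exact sum, which it matches to 0.01% by `m = 25`).
Detection relies on the anchor classes: a BC1–BC2 or BC2–BC1 pair cannot
exist in the input and must be a chimera; under an even class mix this sees
exactly half of all switches (within-class chimeras are invisible), so the
estimator doubles the between-class rate:
`s0 = 2 · J_k / (N0 · c^(k+1))`, with `J_k` the ratio of detected-chimera
reads to input-class reads. `N0` defaults to the plateau row count.
Barcodes with any anchor matching neither class are left unclassified and
take no part in the ratio.

## Polymerase errors

A per-molecule per-cycle error probability `e` relates to the
per-nucleotide rate over the 40 barcode positions as
`e = 1 − (1 − p_nt)^40`; both the exact inversion and the `e/40`
linearisation are reported (printed rates in the source analyses match the
linearisation). With faithful molecules growing as `R_j = N0 c^j` and new
errors `E_j = e R_{j−1}` per cycle, the erroneous molecules accumulate to
`Z_k = N0 e k c^(k−1)` and the erroneous read fraction is `F_k = k e / c`.

`F_k` is measured as the reads of non-plateau sequences at Hamming
distance 1 from the plateau over plateau reads. Sequencing errors are
suppressed twice: consensus merging of the overlapping read pairs (a
disagreement at equal quality fails the pair outright), and Poisson
resampling of read counts with λ = 0.1, which removes low-read rows while
leaving the ratio `F_k` invariant in expectation. Rows with fewer than 3
reads are reported separately as ambiguous (a recurring Q30 sequencing
error at three reads has probability ~4e-8 per molecule). Minimum Hamming
distances are computed exactly (4-bit one-hot packing, XOR + popcount), and
an independent detector counts mixed (RY/YR) dinucleotide anchors, which
cannot occur in the input pool.

## Combined simulation and the synthetic experiment generator

The study-condition generator (`pipeline.simulate_experiment`) reproduces
the analysed conditions: 2900–5000 single-copy inputs (default 5000; the
acceptance-scale runs use 2900, the size of the reference plateau),
25 cycles, `P_amp = 0.9`, `p_nt = 2.7e-5`, `s0 = 2.6e-15`, mean plateau
depth 5000 reads per input. Inputs draw final copy numbers from the
(extended) copy-number PDF; error and chimera cohorts are born per cycle at
their expected rates (`e N_{j−1}` and `s0 N_j²` with `N_j = N0(1+P_amp)^j`),
realised as Poisson draws by default (`deterministic_events` reproduces the
pure-expectation scheme), and each new sequence draws its final count from
the PDF of the remaining cycles. Event sequences are real: errors are a
uniform single substitution of a uniformly chosen input parent; chimeras
cross the first barcode of one parent with the second barcode of another.

Late cohorts are enormous (tens of millions of single-copy molecules) but
almost never sequenced, so rows are materialised only if observed: per
cohort the observation probability `E[1 − exp(−λ n)]` is computed from the
copy-number PDF, the number of observed rows is binomial, their copy
numbers are drawn from the read-weighted PDF, and reads from a
zero-truncated Poisson. This is distributionally exact for the observed
table and keeps the run at ~1e5 rows.

What the generator does not emulate: errors on top of error/chimera
sequences (each new sequence is assumed unique and final), indels,
transition/transversion structure, instrument-specific quality profiles,
PCR plateau-phase resource depletion, and oligo synthesis errors. Passing
tests therefore demonstrate internal consistency of model and estimators
under the stated generative assumptions, not robustness to every artefact
of real libraries.

## Preprocessing

Reads fully span the 101-nt amplicon, so paired-end merging is a
position-wise full-overlap consensus (general overlap aligners solve a
harder problem and are not bit-reproducible here): reverse-complement R2,
compare per position, resolve disagreements toward the higher-quality base,
fail the pair on a quality tie or on more than 10 disagreements. Passing
consensus reads must match the AttL constant region exactly — one mismatch
rejects the read. Varietal tags are counted by exact match; tags differing
by a sequencing error are not clustered. Conservation is enforced:
reads in = merged-and-passed + merge failures + AttL failures.

## Rank profiles and scaling

Profiles sort by descending read count with lexicographic tie-break (bit
reproducibility). Cross-run alignment fits x/y scale factors by minimising
the mean squared difference of log10 read counts at the reference's integer
ranks, with linear interpolation of the scaled profile over log10 rank —
counts span four orders of magnitude, so linear-space least squares would
be dominated by the plateau (a linear-space flag exists; the original
choice of error space is not recorded). A 33×33 log-spaced grid search is
refined by Nelder–Mead; ties (flat profiles) resolve to scale 1. Windows on
the scaled rank axis default to plateau (0, 2900] and shoulder+tail
(2900, 10000], scaled proportionally when the input pool size differs
from 2900.

## Bootstrap uniformity test

The positions (scaled ranks) of detected switches or anchor errors are
resampled with replacement (as many draws as observations, default 1e5
replicates); each replicate's statistic is the median distance from the
window centre. Under a uniform null the median distance is a quarter of the
window width; the p-value is the two-sided tail weight of that null value
under the bootstrap distribution, clamped to [1/reps, 1] (a result at the
clamp is "0 at the resolution of the replicate count"). Whether the
original analysis was one- or two-sided is not recorded; a one-sided flag
is provided. Null calibration (uniform positions) holds the nominal 5%
rejection rate.

## Numerical and design choices

* All randomness flows through numpy Generators; pipeline stages derive
  their streams from one master seed and a stage label (CRC32-mixed), so a
  run is byte-reproducible.
* Exact-PDF normalisation is enforced to |Σp − 1| < 1e-12 per cycle;
  single-founder distributions have zero mass at zero copies.
* The full-resolution molecule-level simulator (`simulate_full_pcr`) tracks
  per-sequence counts and warns when `s0 · N_j` leaves the rare-event
  regime (`s0 ≪ 1/N_j`) instead of failing.
* Efficiency values outside [1, 2] are reported, not clamped.
* Default problem sizes (2900 inputs, depth 5000, 1000–10000 bootstrap
  replicates in the pipeline) keep a full run around a minute while leaving
  every estimator's sampling error well inside its stated tolerance.

## Known limitations

* The Gaussian extension underestimates fine structure of the far lower
  tail at 25 cycles; only means, variances and mode positions are
  guaranteed by the guards.
* `estimate_s0` inherits the closed-form approximation of the switch load
  (no `1/(c−1)` geometric correction), an upward bias of ~11% at `c = 1.9`
  — well inside the factor-of-two accuracy claimed for the estimator.
* The anchor detector sees only substitutions that hit a dinucleotide
  anchor and flip its purine/pyrimidine class (6 of 40 positions, 2/3 of
  substitutions), so it underestimates absolute error counts; it is used
  for position structure, not rates.
* Distinct-tag counts are exact-match based; at very high depth, tag
  sequencing errors that survive consensus merging inflate them slightly.
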