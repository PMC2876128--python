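# Methods

## The model

`crpcna` labels each SNP marker of an ordered log2-ratio track with an
integer copy number. The score of a labeling **y** for observations
**x** is

    psi(y, x) = sum_t [ f_TP(y_{t-1}, y_t; d_t) + f_LE(x_{t-m+1..t+m-1}, y_t) ]

and the conditional distribution is `p(y|x) = exp(psi) / Z(x)` with
`Z(x)` the sum of `exp(psi)` over all `K^T` labelings. The transition
term is omitted at the first marker (equivalently, a uniform prior over
states). Although the local evidence reads a window of observations,
it is a fixed per-locus function of **x**, so the model factorises as a
chain over hidden states and exact inference costs `O(T K^2)` after an
`O(T K P)` evidence pass (`P` = number of patterns) — the same
asymptotic cost as an HMM.

### Transition potential

Adjacent markers at genomic distance `d` megabases are coupled through
Haldane's map function:

    theta(d) = 0.5 * (1 - exp(-2 * rho * d))

`theta` is the probability that the copy-number state changes between
the two markers; the potential is `log(1 - theta)` for staying and
`log(theta / (K - 1))` for a change, splitting the change mass
uniformly over the other states (the model carries no prior about the
magnitude of a jump). Rows of the exponentiated potential sum to one.

Parameters: `rho` (default 0.01 Morgan/Mb, the 1 cM/Mb genome-average
convention) and `theta_floor` (default 1e-10), which keeps
`log(theta)` finite at `d = 0`; `theta` is also capped just below 0.5
so the stay term stays finite. `d` comes from marker bp positions,
`d_t = (pos[t] - pos[t-1]) / 1e6`. Chromosomes are decoded
independently; no transition spans a chromosome boundary.

### Local evidence

A copy-number call is only believable when supported by a run of at
least `m` markers (default `m = 4`; the window then spans
`2m - 1 = 7` markers). Every hypothesis about which neighbours share
the center's state is a contiguous run of length >= m containing the
center: there are `m(m+1)/2` of them (10 for m = 4), enumerated by
`enumerate_patterns`.

Each pattern's support for state `y` is the *mean* Gaussian
log-likelihood of its observations under `y` — the log of the
geometric mean of the per-observation likelihoods. Rescaling by
pattern cardinality is what makes 4-observation and 7-observation runs
comparable: on a window of constant value every pattern scores
identically, which is the invariant the tests pin down. The local
evidence is the maximum over patterns. Near chromosome ends a pattern
is intersected with the offsets that exist (the center always exists);
no padding values are fabricated.

Raising `m` suppresses more noise but misses shorter aberrations;
`m = 1` reduces the evidence to a plain per-marker likelihood and the
model to a distance-aware HMM.

### Emissions

`p(x_t | y_t = i) = N(x_t; mu_i, sigma_i)` in log2-ratio units.
Defaults for the 5-state space {0,1,2,3,4}: `mu = {-2.0, -0.45, 0,
0.38, 0.8}`, `sigma = 0.25`. The one- and three-copy means are
empirical SNP-array monosomy/trisomy values — array compression pulls
them far below the naive `log2(1/2)` and `log2(3/2)`. **The zero- and
four-copy means are extrapolations** beyond anything calibrated and
should be refitted whenever labelled regions exist. A 3-state
loss/normal/gain configuration with `mu = [-0.27, 0, 0.27]`,
`sigma = 0.1` suits array-CGH-style tracks.

`fit_emission_params` estimates `(mu_i, sigma_i)` per state from
labelled markers (sample mean, n-1 sd), keeping fallback values for
absent states. A state with exactly one labelled marker errors
(undefined sd); fitted means out of copy-number order warn but do not
error, since small labelled sets are noisy.

### Inference outputs

Viterbi gives the best path; ties in the argmax are broken toward the
state closest to the normal copy number, deterministically. The
forward recursion gives `log Z(x)` and the normalized best-path
probability `exp(max_y delta_T(y) - log Z)`; forward-backward gives
per-locus posteriors over states (rows sum to 1 within 1e-9). All
recursions run in log space with shifted log-sum-exp; tracks of 10^6
markers decode without underflow. Maximal constant-state runs become
segments carrying the mean posterior of their assigned state; segments
shorter than `m` are flagged, not removed, and a reporting filter can
reassign aberrant segments with mean posterior below a threshold back
to normal.

## Feature extraction

From a marker x sample table of normalized intensities: (1) each
sample is linearly rescaled so its autosomal mean equals a common
target (default 1000); (2) for a test sample, each candidate
reference is scored by the standard deviation over markers of
`log2(test/reference)` — flatter is better under the assumption that
references are two-copy almost everywhere — and the `m_refs` (default
3) best are kept; (3) the track is `log2(test_i / mean_i(selected
references))`, split per chromosome. The sd-of-log-ratio criterion is
scale-blind (a reference at exactly twice the test also scores 0),
which is precisely why mean-normalization precedes selection; the
selection statistic and `m_refs` are this package's choices, recorded
in output metadata, since only the best-fit concept is standard.
PCR-fragment/GC corrections and ploidy-informed baselines used by
array-vendor pipelines are out of scope.

## Synthetic benchmarks

Both generators work directly at log2-ratio level, which keeps the
full validation self-contained and seconds-fast; they do not emulate
probe-level artefacts (cross-hybridisation, GC/fragment-length trends,
wave artefacts, genotype-dependent intensity), so passing them shows
correct sequence inference under the stated noise model, not
robustness to everything a real array does.

* **Sequence design**: 100 sequences x 300 points per SNR level; four
  gain regions of 5, 10, 20, 40 markers (75 aberrant points), mean
  shift 0.4, placed in random order with >= 5-marker gaps; noise
  `N(0, sigma)` everywhere with `sigma = 0.4 / SNR`, ladder
  {2, 1.3, 1}; markers every 10 kb.
* **Array design**: 22 autosomes x 500 markers (a desk-scale stand-in
  for ~11k markers/chromosome on a 500K array; lengths in markers are
  as stated, so region geometry is preserved), marker spacing uniform
  2–20 kb; one aberrant region per autosome, length uniform in
  [4, 100] markers; geometry and marker map drawn once per seed and
  shared by all samples. For each of 3 named references and SNR in
  {5, 2, 1.25}, one deletion sample (regions at the one-copy mean
  -0.45) and one amplification sample (three-copy mean 0.38): 18
  samples. Noise `sigma = |aberrant mean| / SNR` on every probe —
  the log2-ratio analogue of intensity-proportional noise at the
  stated SNR, recorded in the manifest.

One global seed expands to per-sample child seeds
(`SeedSequence(seed, spawn_key)`), so datasets are bit-reproducible
and parallelisable.

## Evaluation

Binary aberrant/normal detection at two granularities (copy-number
values are ignored for detection):

    sr = TP/(TP+FN)   sp = TP/(TP+FP)          (marker level)
    rr = detected/truth regions                (>=1 marker suffices)
    rp = true predicted/predicted regions      (>=1 overlapping marker)
    hr = sr*rr        hp = sp*rp        f = 2*hp*hr/(hp+hr)

Predicted regions are maximal runs of aberrant markers. Degenerate
0/0 denominators score 1 when the call set is vacuously perfect (no
errors of the relevant kind, e.g. empty truth and empty calls) and 0
otherwise; `f = 0` when `hp + hr = 0`. The hybrid/f definitions were
reverse-engineered from the published per-sample benchmark tables; the
straight products `hr = sr*rr`, `hp = sp*rp` reproduce every cell of
the HMM table within 0.001, while the companion detector table follows
crossed products (`hr ≈ sp*rr`, `hp ≈ sr*rp`) — the two tables are
mutually inconsistent, and this package implements the straight-product
convention and documents (and tests) the discrepancy rather than
resolving it.

## Benchmark protocol and problem sizes

`run_array_benchmark` simulates replicate array designs, fits
emissions per sample from the simulator's truth labels (standing in
for known monosomy/trisomy regions), decodes every chromosome with
`m = 4`, and pools the seven metrics per sample. The acceptance
script reports the mean f-score at SNR 5 over 10 replicate seeds
(60 sample evaluations, 22 x 500 markers each); the test suite
additionally checks that mean f is non-increasing over the ladder
{5, 2, 1.25}. `run_sequence_benchmark` does the same on the sequence
design with the generating 3-state model (means {-0.4, 0, 0.4}, the
known sigma) rather than fitted parameters.

## Numerical choices and edge cases

* All DP in log space; local evidence computed from one cumulative sum
  of the (T, K) log-likelihood table per pattern.
* Viterbi ties: preference permutation ordered by |copy - normal|,
  then copy value; fully deterministic.
* `T = 1` degenerates correctly: probability is the softmax of local
  evidence, best entry.
* Non-finite observations are rejected with the offending marker
  named; positions must be strictly increasing per chromosome.
* Coordinates: marker indices are 0-based half-open; BED output is
  0-based half-open bp (a segment ends at its last marker's position
  + 1); probe tables carry 1-based-style positions as given.

## Known limitations

* No modelling of B-allele frequency, genotype information, or
  normal-cell contamination; tumor-fraction dilution shrinks the
  effective mean shifts and must be absorbed by refitting emissions.
* The transition model treats all state changes alike; known
  recombination or aberration hotspots are not encoded.
* Emission defaults for 0 and 4 copies are extrapolated; calls in
  those states should be treated as "strong loss/gain" rather than
  calibrated copy numbers.
* The simulators' Gaussian, locus-independent noise is idealised;
  real tracks show autocorrelated waves and outlier-heavy tails.
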