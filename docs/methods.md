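# Methods

## Signal model and methylation score

Nanopore event levels (mean current, pA) depend on the 6-mer in the
pore, so class-conditional models are trained per 6-mer containing a
GpC dinucleotide (a G immediately followed by C; each C of overlapping
GpCs such as `GCGC` is its own site). The unmethylated model is a
single Gaussian fitted by the sample mean and the unbiased (n-1)
variance of pooled negative-control events; a 6-mer with fewer than two
events or with standard deviation under `eps = 1e-3` pA is left
untrained. The methylated model is a two-component Gaussian mixture
`rho N(mu1, sigma1^2) + (1 - rho) N(mu2, sigma2^2)` — two components
because exogenous methylation is not perfectly efficient, so the
positive control contains a minority of unmethylated molecules. It is
fitted by EM (at least 20 events; initial means at the 75th/25th
percentiles with a shared variance, tolerance 1e-6 on the observed-data
log-likelihood, at most 500 iterations; on variance collapse below
`eps`, up to 3 restarts with jittered means seeded from the run seed).
Components are ordered `mu1 >= mu2` for determinism. The EM ascent
property (non-decreasing log-likelihood) is asserted in tests, and the
fit is cross-checked against scikit-learn's `GaussianMixture` on
synthetic draws.

The *discrimination* of a 6-mer is one minus the overlap area of the
two densities, integrated by the trapezoid rule on 4001 points spanning
`[min(mu) - 6 max(sigma), max(mu) + 6 max(sigma)]` and clipped to
[0, 1]. For each GpC site on each molecule, the six covering 6-mers are
enumerated in molecule orientation (reverse-complement context for
reverse-strand molecules; forward- and reverse-aligned molecules are
trained and scored as separate groups throughout); candidates with more
than one GpC, with more than 10 aligned event levels on that molecule,
or without a trained model are excluded, and the survivor with maximal
discrimination wins (ties to the leftmost 6-mer start). The methylation
score is the flat-prior posterior `s = prod f_P / (prod f_P + prod
f_N)` over the events aligned to the chosen 6-mer, computed in log
space; any event with `log f_P` or `log f_N` below -10 (natural log —
the base is a package choice) is dropped first, and a site whose events
are all dropped is FILTERED and invisible downstream.

## Nucleosome-phasing dynamic program

Per-base states are `L` (linker) and `N_1..N_147` (position within a
147-bp nucleosome), with transitions `N_m -> N_{m+1}`, `N_147 -> L`,
`L -> {L, N_1}`. A GpC base with score `s` emits `q_P(s)` under `L` and
`q_N(s)` under any `N_m`; all other bases carry a dummy score and emit
a factor of one. `q_N`/`q_P` are Gaussian KDEs of control-score
samples with R's `bw.nrd0` bandwidth (0.9 min(sd, IQR/1.34) n^(-1/5);
hand-rolled because scipy's "silverman" factor is a different formula),
tabulated on 512 grid points over [-0.05, 1.05] and floored at 1e-8 so
logs stay finite; scores are evaluated by linear interpolation on the
grid. Simulated benchmarks use the simulator's exact parametric class
densities on the same grid.

Decoding is Viterbi over an `l x 148` matrix in natural-log space. The
path may start and end mid-nucleosome; such boundary-truncated calls
are emitted with truncation flags (droppable via `complete_only`). One
printed variant of the linker-column recursion would enter `L` from
`N_146`; the implementation follows the transition rules (`L` entered
from `L` or `N_147`). Ties are broken deterministically: the final
state prefers `L`, then lower nucleosome index, and backtracking
prefers `L` over `N_147` — equivalently, among maximum-likelihood paths
the decoder returns the one minimising the reversed state sequence
lexicographically. A molecule with no called GpC site has all paths at
likelihood 1 and returns the all-linker path with log-likelihood 0 by
convention.

Two independent oracles guard the decoder. `exhaustive_decode`
literally enumerates every transition-valid path (parameterised by
nucleosome start coordinates) with the same tie order; it is O(l^3)-ish
and used on molecules up to ~200 bp. `brute_force_decode` is an
exhaustive segmental search — prefix-optimal values for "ends in
linker" and "nucleosome ends here" with a running maximum, then a
backward greedy reconstruction implementing the same
reversed-lexicographic tie order — usable to 600 bp in O(l). Because
the three algorithms accumulate the same log terms in different orders,
log-likelihood equality is asserted at 1e-9 and path identity exactly;
the oracle treats value differences below 1e-9 as ties for the same
reason.

## Accessibility rules

Single-molecule accessible regions: consecutive called GpC sites both
scoring > 0.5 (strict) and less than 100 bp apart are linked; chains are
merged transitively; a chain is kept when the distance between its
flanking C positions is at least 100 bp, with score the median of its
site scores. Bulk peaks apply the identical chaining to per-site
methylated fractions `r_i` (fraction of covering molecules with score
> 0.5; sites require coverage >= 5 molecules by default) with threshold
`1.5 r_bar`, where `r_bar` is the mean ratio over covered sites of that
strand group; peaks are called per strand and an intersection operation
yields strand-concordant peaks. The promoter of a gene is the peak with
the longest overlap of the "-500, +100" window around the TSS (oriented
by gene strand; a strand-naive switch exists), ties to the peak nearest
the TSS, falling back to the window itself. A molecule fully covering
the promoter is "open" iff the median GpC score inside is strictly
greater than 0.5; molecules with no called site there are NO_CALL and
excluded from the openness fraction. Differential accessibility is the
difference of openness fractions between two conditions.

## Downstream metrics

* **Positioning heterogeneity**: distances from the TSS to the +1
  nucleosome (center downstream of and closest to the TSS; a center
  exactly at the TSS counts as downstream) are collected across
  molecules, the largest `floor(0.1 n)` are discarded, and the unbiased
  SD of the rest is reported (>= 10 molecules required).
* **Spacing uniformity**: mean over all unordered pairs of |d_i - d_j|
  of the linker lengths inside the -500..+100 window on one molecule
  (>= 2 linkers; linkers partially overlapping the window are clipped to
  it by default, with a switch to keep full lengths), averaged over
  molecules per gene.
* **Combinatorial patterns**: molecules with an open/closed status at
  every listed promoter are tabulated into pattern strings; `2^k`
  patterns are possible for `k` genes and counts conserve molecules.
* **Score autocorrelation**: all within-molecule site pairs are binned
  by distance (10-bp bins, default max 400 bp); per bin the Pearson
  correlation is computed over the order-symmetrised pooled pairs. Raw
  scores are used rather than binarized status. Bins under 100 pairs or
  with (near-)zero variance are missing.
* **Openness clustering**: per-molecule binary occupancy vectors over a
  fully covered window are averaged into 10-bp features and clustered
  by k-means (k = 3 default, 20 restarts, seeded); labels are
  re-ordered so cluster 0 is the most closed.

## Simulator

A molecule (default 3000 bp) is built left to right starting with a
linker: each linker length is drawn from `N(nu1, gamma1^2)` with
probability `tau` and `N(nu2, gamma2^2)` otherwise (defaults nu1 = 15,
gamma1 = 5, gamma2 = 10, tau = 0.1 — the study's design, with nu2 the
swept coverage knob), rounded to an integer and truncated below at 0
(so adjacent nucleosomes can abut), followed by a 147-bp nucleosome;
the final nucleosome is clipped at the molecule end and the clipped
remnant is part of the ground truth. The printed mixture weighting is
kept as stated even though it makes the long-linker component dominant
(coverage spans ~0.20-0.91 across the nu2 sweep). GpC sites are
independent per-base Bernoulli draws (default frequency 0.0375, the
yeast genome's GpC density; 0 is allowed and yields a site-less
molecule).

Class-conditional methylation scores default to a mirrored Beta pair:
protected (nucleosome) sites draw from Beta(1.354, 2.708) and exposed
(linker) sites from Beta(2.708, 1.354). The single free parameter of
this family (the concentration, at fixed mirrored means 1/3 and 2/3)
was solved by bisection on the exact AUC integral so that the
two-class separation AUC is 0.860, anchoring the synthetic noise to the
method's measured 5mC-detection AUC on real control data;
`calibrate_beta_auc` reproduces the calibration. Scores can instead be
drawn from tabulated `ScoreDensity` grids. A separate event-level
generator (`make_synthetic_kmer_models` + `simulate_event_levels`)
drives the signal-model stage end to end with synthetic per-6-mer
Gaussians whose methylated component is shifted by a configurable
delta.

Decoder accuracy is the fraction of bases whose predicted
in-nucleosome indicator matches the truth. The accuracy grid decodes
each simulated molecule against the exact simulator densities and
averages over replicates per (GpC frequency, nu2) cell; the package's
benchmark runs use 200 replicates per cell (the printed design used
1000; 200 gives a cell SE of ~0.005, ample for the grid's contrasts).

### What the simulator does and does not emulate

It emulates the study's molecule geometry, site density, and a
score-noise level calibrated to the reported detection AUC. It does
not emulate raw squiggles, base-calling or alignment errors, coverage
bias, strand asymmetries, or correlated scoring errors along a read —
so passing benchmarks demonstrate the decoder's statistical behaviour
under the stated noise model, not end-to-end performance on real runs.
Two consequences are documented in tests rather than hidden:

* The coverage formula `147 / (147 + E[linker])` is the
  renewal-process asymptotic; on 3-kb molecules the trailing partial
  period biases realized coverage low by up to ~0.02, so the
  formula-consistency checks run on 50-100-kb molecules where the bias
  is negligible, and a separate test pins the direction of the
  short-molecule bias.
* The periodicity check simulates linkers with mean 25 bp and SD 25 bp
  (mean +- SD reading). With a much smaller SD the array is nearly
  crystalline and the correlation harmonic at twice the repeat ties
  the ~172-bp fundamental statistically, making "the global maximum is
  the repeat length" ill-posed; realistic linker variability produces
  the decaying oscillation seen in footprinting data, with the maximum
  at 170-190 bp.

## Known limitations

* With AUC-0.86-calibrated class scores, the decoder's mean per-base
  accuracy at 3.75% GpC frequency spans roughly 0.78-0.83 across the
  coverage sweep — the high-coverage cells (nu2 = 15-100, short
  linkers that often contain no GpC site) sit just below 0.80. Several
  alternative score families at the same AUC (a logit-normal posterior
  channel, Betas with other means) behave the same, so this band
  appears to be a property of the noise level, not of the chosen
  family.
* `r_bar` for bulk peaks is computed per strand group (a joint switch
  exists); the per-site coverage threshold of 5 molecules is a package
  default.
* The pooled nucleosome track is a plain per-base coverage counter
  (optionally normalized by molecule coverage); no Gaussian-smoothing
  peak caller is layered on top of it.
* Tie-breaking, truncation handling, and the zero-site convention are
  package decisions where the underlying recursion is silent; they are
  pinned by the oracle-equivalence tests.
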