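# Methods

## SILAC phosphosite model and normalization

A quantified phosphosite is a row keyed by (protein accession, 1-based
position) carrying per-replicate log₂(H/L) ratios, where the heavy channel
is the high Cyclin A condition, so positive log₂ H/L means more
phosphorylation when Cyclin A is present.  Two normalizations precede any
filtering:

* **Median centring** (`median_center`): the median of each replicate's
  log₂ H/L distribution is subtracted, absorbing the 1:1 mixing error of
  the heavy/light lysates.  Per-replicate centring is the default because
  each replicate is mixed independently; a pooled mode exists for tables
  whose replicates were exported pre-scaled together.  After centring the
  per-replicate median is zero — exactly so for odd site counts.
* **Protein-abundance correction** (`correct_protein_abundance`): where a
  protein-level log₂ H/L is available, it is subtracted from every
  replicate ratio of that protein's sites, leaving the
  phosphorylation-specific change.  Sites without a protein ratio pass
  through unchanged and are flagged, not dropped: discarding them would
  silently bias the screen toward well-quantified proteins.

Duplicate rows for one site (several peptide forms covering the same
residue) are collapsed by averaging replicate ratios before any counting,
so "unique phosphorylation sites" is well defined.

## Kinase consensus motifs

Motifs are position-offset residue classes over the 15-mer window centred
on the phosphosite (index 7): minimal Cdk1 = S/T with P at +1; optimal
Cdk1 additionally requires K or R at +2 **or** +3 (either position
suffices — the disjunctive reading of "+2/+3"); Aurora B = R/K at −2 with
−1 unconstrained; Plk1 = D/E at −2 with −1 unconstrained.  All four rules
demand S/T at the centre, so phosphotyrosine sites never match.  Windows
truncated by a protein terminus are padded with `X`, which belongs to no
residue class; a motif reaching past the terminus therefore fails rather
than matching vacuously.  Motif annotation is a pure sequence computation
and is invariant under every ratio transformation, which the tests assert.

## The filter cascade

Per motif, three nested tiers: (1) quantified sites matching the motif;
(2) additionally mean log₂ H/L ≥ 1, i.e. at least two-fold more
phosphorylated with high Cyclin A — the threshold is signed, not absolute,
because the screen asks for substrates *activated* by Cyclin A/Cdk1;
(3) additionally p < 0.1 from a two-tailed t-test.  "Reproducibly
quantified" means ≥ 2 replicate measurements and non-zero replicate
variance, the minimum for a t statistic; sites failing that have undefined
p and cannot reach tier 3.  When the input table already carries p-values
(deposited exports), they are used verbatim; otherwise the default is a
one-sample test of the mean log₂ ratio against 0, with a Welch
unequal-variance two-sample mode against a user-supplied reference vector
as an alternative.  An optional user-supplied gene list intersects tiers 2
and 3 with proteins of known mitotic function; no such list is bundled
because its composition is a curation decision, not a computation.

Calibration: the p-filter's nominal behaviour is checked on effect-free
synthetic tables with the fold tier disabled (threshold −∞).  Conditioning
on mean ≥ 1 first would select extreme means and inflate the apparent
pass rate far above the nominal level on a null table, which is a property
of the cascade's tier ordering, not a defect of the test.

## Network clustering

Candidate complexes are grown on the weighted interaction network by
greedy cohesiveness optimisation.  The cohesiveness of a member set V is
w_in(V) / (w_in(V) + w_bound(V) + penalty), with w_in the summed internal
edge weights and w_bound the summed boundary weights.  `cohesiveness()`
takes the additive penalty term directly; during growth the penalty term
scales with cluster size (rate × |V|, default rate 2), the form that makes
the greedy stop: with a size-independent term, converting a boundary edge
to an internal one never decreases the score, so every pendant neighbour
would be absorbed and clusters would dilate to whole components.  Growth
seeds each unclaimed node in descending weighted-degree order and applies
the single add/remove move that most increases cohesiveness until locally
optimal, with lexicographic node-id tie-breaks for determinism.  Clusters
below 3 members or below weighted density 0.3 are discarded; pairs with
overlap |A∩B|²/(|A||B|) ≥ 0.8 are merged transitively.  STRING-style
integer scores (0–1000) are rescaled by 1/1000 on read; duplicate edges
keep the maximum weight; self-loops are dropped with a warning.

## FDAPA turnover model

Each cell's trace is corrected as
corrected(t) = (intensity − background) / bleach_factor, then normalized
to the first post-activation frame.  The bleach factor is the
whole-spindle reference normalized to its own t₀ (default when a reference
exists), an exponential e^(−ct) with a user constant, or 1.  The corrected
decay is fit by bounded least squares to A₁·e^(−k₁t) + A₂·e^(−k₂t) with
amplitudes in [0, 1.5] and rates in [10⁻⁵, 1] s⁻¹; the model is written as
decay with positive rates since fluorescence dissipates.  The reported
labels always satisfy k₁ > k₂ (fast = free microtubules, slow = k-MTs),
enforced by a post-hoc swap.  Because the biexponential least-squares
surface is multimodal, fitting is multi-start: the first start is a
deterministic log-linear fit of the tail (slow component) followed by a
log-linear fit of the early residual (fast component); the remaining
starts (default 20 total) apply seeded log-normal jitter to it.  A later
start must beat the incumbent by a small absolute margin so the
deterministic start wins ties; this resolves the amplitude-split
degeneracy when the data are effectively single-exponential (k₁ ≈ k₂).
A₁ + A₂ = 1 can be imposed (`constrain_sum`) but is off by default:
normalization makes the sum ≈ 1 and the free form absorbs noise at t₀.
Half-lives are ln 2 / k.  Group comparisons use an unpaired two-tailed
Welch t-test on per-cell statistics (default: slow half-life); cells with
non-converged fits or r² < 0.8 are excluded and reported by id.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng` (PCG64); a fixed seed
reproduces outputs bit-for-bit across platforms.

* **SILAC tables**: defaults emulate the screen's design — 2000 sites on
  ~670 proteins, 4 replicates, 40% of sites carrying the minimal Cdk1
  motif, 10% of motif sites spiked with a true mean effect of +1.5 log₂
  (~three-fold, the scale of the reported substrate responses), replicate
  noise σ = 0.3 log₂ units (Gaussian in log space, the standard model for
  SILAC ratio noise), a +0.2 log₂ mixing shift, and 5% missing
  measurements (missing completely at random — the simplest testable
  mechanism).  The real dataset's replicate variance and missingness are
  not published; these values are a realistic design point, not estimates.
  Non-motif windows exclude P at +1 by construction so the motif tier
  separates cleanly; other motif occurrences (Aurora/Plk1 at −2, basic
  residues at +2/+3) arise at background frequency.  Truth labels
  (`is_spiked`) are emitted for benchmarking and never consumed — a test
  drops the column and asserts identical cascade output.  Protein-level
  ratios are emitted as already centred (no mixing shift); an optional
  `protein_sd` adds protein-abundance variation that the correction step
  removes.
* **FDAPA traces**: intensity(t) = bleach(t)·[background + I₀·(a_fast·
  e^(−k_fast t) + (1−a_fast)·e^(−k_slow t))] + Gaussian noise, sampled
  every 15 s over 4 min (17 frames), with bleach(t) = e^(−bleach_rate·t)
  applied multiplicatively (the simplest photobleaching model consistent
  with a correction by division).  Defaults: 70% fast signal with 15 s
  half-life, slow half-lives of a few minutes, I₀ = 1000 a.u., noise σ 10
  a.u. (1% of I₀), background 100 a.u.  Each cell also gets a paired
  contralateral background trace and a whole-spindle bleach reference so
  every correction mode is exercisable.  Cell-to-cell parameter
  variability is not modelled: per-cell spread comes from measurement
  noise only, so group comparisons on synthetic data are a best case.
* **Toy networks**: planted clusters connect internal pairs with
  probability p_in and everything else with p_out; weights are uniform on
  [0.5, 1.0] so no edge is vanishingly light.

What passing on synthetic data does not show: real phosphoproteomes have
correlated replicates, intensity-dependent variance, non-random
missingness, and peptides spanning multiple sites; real photoactivation
data have cell-to-cell kinetic heterogeneity, drift, and registration
error.  The generators validate the machinery and its statistical
calibration, not the biology of any particular dataset.

## Numerical and design notes

* t-tests delegate to scipy (`ttest_1samp`, `ttest_ind(equal_var=False)`);
  the vectorised cascade path computes the identical statistic from
  per-row moments and is tested row-by-row against the scalar path and an
  independent textbook-CDF oracle.
* Zero-variance replicate sets yield an undefined p (NaN), a signal, not
  an exception — such sites simply never pass the significance tier.
* Degenerate inputs: empty tables produce zero-count reports; an empty
  network yields no clusters; traces need ≥ 5 strictly increasing
  timepoints; corrected t₀ intensity ≤ 0 marks a trace unusable.
* Problem sizes in the tests and the acceptance script (2000-site tables,
  50 null tables of 400 sites, 100 noisy traces, 50-node networks) were
  chosen as the smallest designs at which the calibration and recovery
  checks are statistically meaningful.
* Pipelines write a `manifest.json` (config, seed, package version,
  SHA-256 input checksums, output list) sufficient to reproduce any run;
  reruns are byte-identical and inputs are never mutated.
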