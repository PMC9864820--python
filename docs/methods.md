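# Methods

This note documents the models and numerical choices behind the pipeline:
what the simulator emulates, how each analysis stage is defined, which
parameters matter, and what passing tests do and do not demonstrate.

## 1. The synthetic venom model

No public raw data exists for the kind of intact-protein venom survey this
package implements, so validation rests on simulation with known ground
truth. The generator's defaults are the study conditions under which the
pipeline is tested; they are chosen once, from field-typical values, and the
test suite treats them as fixed.

### Toxin panel

A clade is `n_genera × species_per_genus × samples_per_species` individual
venoms (default 2 × 2 × 2 = 8). Toxins exist at three levels of sharing:

* **genus-shared** (default 12 per genus) — present in every sample of the
  genus, each sample's copy subject to dropout (default probability 0.1);
* **species-unique** (default 6 per species) — present in every sample of
  one species, subject to the same dropout;
* **sample-unique** (default 2 per sample) — present in exactly one sample,
  never dropped (they are defined by being observed in that sample).

Every sample therefore carries ~20 toxins. Neutral masses are drawn from a
four-component mixture echoing elapid venom composition: <5 kDa peptides
(weight 0.04, N(3200, 700) truncated to [1.5, 5) kDa), 5–9 kDa
three-finger-toxin/Kunitz range (0.57, N(6800, 900)), 13–15 kDa
phospholipase A2 range (0.36, N(13900, 550)), >15 kDa large components
(0.03, N(22000, 4000) truncated to [15, 40] kDa). The weights follow the
pooled per-bin isoform proportions reported for taipan and brown-snake
venoms; the 9–13 kDa gap is intentionally empty. Per-toxin base intensities
are log-uniform over 10^3.3–10^5.3 (arbitrary units); per-sample
multipliers are log-normal with `abundance_log10_sd = 0.5`, putting the
2.5–97.5 percentile fold-range near the ~100-fold abundance variation such
surveys report.

### Instrument model

Each run covers a `gradient_minutes = 20` acquisition scanned every 4 s
(300 spectra), m/z 500–5500. This is a deliberate desk-scale reduction of a
typical 40-min, 1-Hz acquisition (2400 spectra); both are configuration
fields, not constants. Retention-time centers are uniform over the eluting
portion of the gradient (12.5–85%, mirroring a 5–34 min window on a 40-min
program); no mass–RT correlation is imposed. Peak shape is Gaussian with
`rt_sigma_minutes = 0.25`.

A toxin of mass M ionizes at charges within ±3 of the denatured-protein
heuristic `z ≈ M/1200`, clipped to the m/z window; envelope weights are a
discretized Gaussian over z with sd 1.5 charges. Each (toxin, charge)
contributes one centroid per in-window scan at `(M + z·m_p)/z` with
Gaussian m/z jitter (sd 0.01) and multiplicative log-normal intensity noise
(sd 5%). Chemical noise is a Poisson number of centroids per spectrum
(mean 20), uniform in m/z, exponential in intensity (scale 50).

**Not simulated:** isotopic fine structure (one centroid per charge, since
the downstream identity rule works at 1 Da, far above isotope spacing),
adducts, in-source decay, UV traces, detector saturation, RT drift between
runs. Consequences: the pipeline performs no deisotoping and is not
validated against isotope-resolved data, and cross-run RT alignment is
assumed unnecessary (consistent with an identity rule that simply requires
"the same retention time").

Determinism: all draws derive from `numpy.random.default_rng` seeded by
`(config.seed, sample index)`, so a given sample's run is bit-identical
regardless of generation order.

## 2. Deconvolution

* **Elution windows.** Apexes are local TIC maxima ≥ `min_snr ×
  median(TIC)`; bounds extend to the half-apex crossings, truncated at the
  TIC minimum between adjacent apexes. `min_snr` defaults to 1.5: the TIC
  median is dominated by the chemical-noise baseline, and an apex is
  baseline *plus* signal, so demanding 3× the median would require signal
  twice the entire baseline and bury minor toxins. Because venoms co-elute
  densely, the complementary gaps between detected windows are averaged as
  well (piecewise whole-run coverage); otherwise toxins sitting in TIC
  valleys would never be seen.
* **Averaging.** In-window centroids are merged by single-linkage in m/z at
  `mz_merge_tol = 0.02` (≈2× the m/z jitter sd; a wider 0.05 blends
  co-eluting charge-state centroids that a QTOF resolves, creating orphan
  artifacts). Merged intensity is the mean over in-window spectra with
  absent scans counting as zero, so averaging does not inflate single-scan
  spikes.
* **Charge assignment.** Every (peak, z) pair for z ∈ [1, 30] proposes
  `M = z·(mz − m_p)`. Windows of proposals agreeing within
  `mass_cluster_tol = 0.1` Da (flat, mirroring the flat 1 Da identity rule)
  are scored by (distinct charges, summed intensity) and accepted greedily,
  each peak consumed once. Masses above 5 kDa need ≥2 charges; below,
  a single charge suffices (small peptides often show one). Ties break to
  the lower mass — this also resolves harmonics, since the same peaks
  support mass kM at charges kz with *identical* score. Scores use exactly
  rounded summation (`math.fsum`) so identical member sets tie exactly.
  After an envelope at M is accepted, remaining peaks with any proposal
  within 1 Da of M are consumed too (ownership sweep): jitter can push one
  charge state just outside the cluster tolerance, and such an orphan would
  otherwise re-emerge as a spurious low-mass single-charge envelope.
* **EIC refinement and ranking.** Each envelope's abundance is the apex of
  the EIC (±0.05 m/z) at its highest-intensity charge state; the apex is
  hill-climbed to the local maximum over the whole run so an envelope found
  in a peak's tail still reports the true elution apex. Records must be
  chromatographic (≥3 consecutive scans at half-apex; chemical-noise spikes
  span one scan). Pooled records are deduplicated under the 1 Da + 0.5 min
  identity rule (keeping the more intense), and an "EIC-channel shadow" —
  a record whose best-charge m/z rides a channel of a better-supported
  co-eluting record — is suppressed in favour of the interpretation with
  more charge states. The top `n_top = 12` by apex intensity are kept
  (the conventional 10–15 band; configurable 1–50).

## 3. Cross-sample screening

Per-run toxins pool into a database without merging (provenance preserved).
Features are formed by complete-linkage agglomerative clustering with the
clique condition: a merge is allowed only while **all** pairwise mass
differences ≤ 1 Da **and** all pairwise RT differences ≤ `rt_tol` (0.5 min —
small against the gradient; the rule's "same retention time" is otherwise
unquantified). The clique reading follows the wording "within 1 Da from
*each other*"; single-linkage chaining would let 6783.0 and 6784.4 share a
feature via an intermediate. Merge order is ascending scaled Chebyshev
distance `max(Δm/1 Da, ΔRT/rt_tol)` with deterministic ties (lower mass,
then earlier RT); consensus mass and RT are intensity-weighted means.

Screening re-extracts, per feature and per recorded charge state, an EIC at
the implied m/z. Present ⇔ the best apex within `rt_tol` of the consensus
RT reaches `detection_snr = 3` × the run-local noise floor (median non-zero
off-window EIC value; an absolute floor of 1 intensity unit when the
off-window trace is silent) *and* the apex centroid re-deconvolves to
within 1 Da of the consensus mass. Confirmation is deliberately restricted
to recorded charge states rather than a fresh full deconvolution. Absent
calls carry intensity 0, making presence monotone in the threshold.

## 4. Matrix, bins, transforms, ordination

Matrix rows are features ordered by ascending mass (ties by RT); columns
are samples ordered genus → species → locality → id. Mass bins are
[0, 5000), [5000, 9000], (9000, 13000), [13000, 15000], (15000, ∞) Da; the
explicit 9–13 kDa "unclassified" bin surfaces the range the conventional
taxonomy omits instead of silently widening a neighbour.

The default intensity transform is `log10p`: v → log10(1 + v/floor) with
floor the smallest non-zero matrix value. It compresses ~100-fold spreads
while mapping absence to exactly 0 in a scale-free way; `raw` and `binary`
are alternatives. PCA is a plain SVD of the (centred, by default unscaled)
samples × features matrix: centring is the minimal PCA requirement, the log
transform already stabilizes variance, and unit scaling would promote
noise-only features. The sign convention (largest-magnitude loading of each
component positive) makes output platform-stable. Cluster separation is the
mean between-group minus mean within-group pairwise Euclidean distance over
the first two score dimensions; positive means separated. MS ion intensity
is not absolute quantification, so all abundance statements are relative —
hence presence/absence plus relative-intensity heatmaps rather than
concentration estimates, and numeric (not image) heatmap export.

## 5. Validation design and limitations

Every stage is tested against independent oracles: closed-form m/z ↔ mass
identities, hand-traced worked examples of averaging and the identity rule,
brute-force enumeration for greedy envelope selection, exhaustive partition
search (factorized over single-linkage components) for feature merging,
scikit-learn as a cross-check for PCA, and end-to-end parameter recovery on
20 seeded replicates of the default simulation (pooled recall of each
sample's true top-12 toxins, feature false-discovery proportion,
presence-call accuracy, mean absolute mass error, and the sign of the
species-separation statistic).

The oracle-equivalence comparisons for merging use replicate-structured
random sets (tight groups, well separated relative to the tolerances), the
geometry cross-run replicates actually produce; on adversarial chain
geometries a greedy agglomeration and a global maximal-merge search can
legitimately differ, and the hand-traced chain example pins the greedy
behaviour there.

Passing these tests shows the pipeline recovers a *known* panel under the
stated noise model. It does not show robustness to phenomena the simulator
omits — isotope structure, RT drift, saturation, co-eluting isobars below
the 1 Da rule — and the identity rule itself cannot distinguish isoforms
closer than 1 Da at the same RT. The per-run "most abundant" cut also means
a toxin present everywhere but never abundant anywhere is invisible by
design, exactly as in the manual workflow this reproduces.
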