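# Methods

## Problem and scope

In medication-resistant focal epilepsy, surgery aims to remove the
tissue that generates seizures while staying as small as possible.
`frnetsim` operates downstream of HFO detection: its inputs are, per
patient, an SEEG contact table (MNI coordinates, shaft membership,
seizure-onset-zone and resection flags), a catalog of detected HFO
events (onset time, category, peak frequency), and recording metadata.
From these it computes resection-referenced fast-ripple (FR) metrics,
classifies post-operative seizure freedom, and simulates alternative
surgeries (spherical virtual resections) and alternative RNS
stimulation-lead placements.  Raw iEEG, HFO detection, and imaging
co-registration are out of scope.

## Event families

The driving event family, written FR>350, is: fast ripples on
oscillations with peak frequency > 350 Hz, plus *all* fast ripples on
spikes (200–600 Hz).  Ripples on spikes (RonS) and on oscillations
(RonO, both 80–200 Hz) and the broader all-FR family enter only
descriptive resection ratios.  Event-count resection ratios divide the
family's events on resected contacts by the family total; the SOZ
resection ratio is contact-count based.  A family with zero events
yields an undefined (`None`) ratio, never a silent 0/0.  RNS
"stimulation ratios" are the same formulas evaluated on the stimulated
contact set.

## Mutual information between event trains

Temporal coupling between FR>350-generating contacts is the mutual
information (bits) between their onset-time trains.  The default
estimator represents each event of train *a* (after the first) by a
2-D point: its preceding inter-event interval, paired with the
preceding interval of the nearest event in train *b*.  MI of this
sample is estimated by Darbellay–Vajda adaptive partitioning: a cell of
the plane is split at the marginal medians of its points whenever a
chi-square test (3 df, α = 0.05) rejects uniformity over the four
quadrants, and cells below 6 points are never split.  The estimate is
the average of the two directions, which makes symmetry exact.

The aligned-interval representation was chosen after rejecting a
latency-based pairing (own interval vs. nearest-event latency): for a
train against an exact copy of itself the latency is ~0 everywhere but
statistically *independent* of the interval, so a latency pairing
estimates zero MI precisely where coupling is strongest.  With aligned
intervals, an exact copy approaches the interval entropy (~4.6 bits in
calibration runs), 0.8-probability copies with 20 ms jitter give ~1.5
bits, and independent Poisson pairs average < 0.001 bits (n = 100
pairs, 2/min, 60 min).  The calibration (minimum cell 6, α = 0.05) was
fixed once from those runs.  A fixed-width binned estimator (1 s bins,
plug-in MI with Miller–Madow correction) is available as
`MIOptions(estimator="binned")`; both estimators pass the same
independence and coupling tests.

MI is clamped at 0; trains with fewer than 2 events get MI 0.

## Networks and the four factors

The MI network has one node per FR>350-generating contact and edge
lengths 1/MI (no edge where MI = 0).  The rate–distance graph is the
complete graph over the same nodes with edge weights
mean(rate_i, rate_j) × Euclidean distance (mm); weights act directly as
path lengths, and shortest paths may route through intermediate nodes.

* **Local efficiency (LE)** of a node: efficiency of the subgraph
  induced by its neighbors, on weights normalized by the global
  maximum (so a complete equal-weight graph has LE 1); nodes with
  fewer than two neighbors have LE 0.
* **Characteristic path length**: mean shortest-path length over
  ordered pairs; unreachable pairs are excluded from the mean and
  counted separately.
* **Global efficiency**: mean inverse shortest-path length over
  ordered pairs, 0 for unreachable pairs, computed on *raw* 1/MI
  lengths so a direct edge contributes its MI.  (Normalizing here
  would make a two-node graph's efficiency always 1 regardless of
  coupling strength; keeping raw lengths preserves that a stimulated
  subnetwork of weakly coupled sites scores low.)
* **Graph radius**: minimum over nodes of the maximum shortest-path
  distance; a single node has radius 0.

The four outcome factors for a resected set R:

1. **FR RR** — FR>350 event resection ratio.
2. **Spatial FRnet** — sqrt(max(0, radius(all FR nodes) −
   radius(FR nodes in R))) on the rate–distance graph.  Negative
   differences are clamped before the square root; resecting every FR
   node gives exactly 0.  A resection containing no FR node leaves the
   resected-only radius at 0.
3. **Temporal FRnet-A** — characteristic path length of the MI
   subgraph induced on R, divided by that of the whole network.
   Undefined (flagged) when the resected subgraph has under two nodes
   or no finite pair.
4. **Temporal FRnet-B** — mean LE over evaluated nodes with LE > 0.
   The evaluated set defaults to the *unresected* nodes
   (`frnet_b_scope="unresected"`): the virtual simulator must respond
   to what a growing resection leaves behind, and a full resection
   then lands on the degenerate convention 1.0, consistent with the
   full-resection anchor.  `scope="all"` is available as a config
   switch.

Unavailable components are carried as `None` plus a flag and imputed at
the training-set feature mean (z-score 0) inside the classifier.

## Outcome classification

`FROutcomeClassifier` is a scikit-learn estimator: z-score
normalization fitted on the training rows, RBF SVM with C = 1 and
kernel coefficient fixed at 1/(number of factors) = 0.25 on the scaled
features (`kernel_scale="auto"` delegates to sklearn's variance-scaled
rule instead).  The positive class is seizure free; a decision value of
exactly 0 is labelled not seizure free, the conservative convention
that keeps a virtual resection growing.  Leave-one-out cross-validation
refits normalization and SVM per fold; folds whose training rows cannot
support a fit (single label or constant features) predict the fold
majority.  Note that leave-one-out on a balanced cohort is
pessimistically biased for uninformative features (each fold trains
tilted against the held-out class), so chance-level feature sets score
somewhat *below* 0.5.  Models serialize to a JSON sidecar holding the
training matrix and hyperparameters; reload refits, which is exact
because the solver is deterministic.

## Virtual resection simulator

Candidates are MI-network nodes with FR>350 rate > 1/min ordered by
ascending LE (ties: higher rate, then contact id), followed by the
remaining FR-generating nodes by descending rate.  The sphere is
centered on the first candidate (center never moves), starts at 10 mm,
and for each later candidate outside the current sphere grows to
max(previous, distance-to-center + 10 mm buffer).  Membership is a
closed ball; contacts contralateral to the center are excluded, so a
contralateral candidate is consumed without changing the set and
without an SVM query, as is any candidate already inside the sphere.
After every change of the resected set the four factors, SOZ RR and
RonS RR are recomputed and the SVM queried; the run stops at the first
seizure-free label, else when the resected set spans three distinct
lobe labels (non-seizure-free designation), else when candidates run
out.  Unsampled space never contributes.  Contact-level agreement with
the actual resection is summarized by a confusion table over all of the
patient's contacts, with percent_r ≡ sensitivity and
novel_r = FP/(TP+FP).

## RNS simulation

The stimulated set is every SEEG contact strictly within 15 mm of any
of the eight RNS contacts (monopolar-field range at 1–3 mA).  Metrics:
SOZ stimulation ratio (contact counts), FR stimulation ratio (event
counts), and the RNS temporal FRnet — global efficiency of the MI
subgraph induced on the stimulated nodes plus their first-degree MI
neighbors; low values indicate stimulation of autonomous FR sites.
Virtual placement puts a four-contact lead along the shaft holding the
highest-rate FR>350 contact, as a contiguous window of shaft positions
(i−1 … i+2) around it, clipped at shaft ends; shafts with fewer than
four contacts are padded with the spatially nearest other contacts.
The second lead repeats the construction in the opposite hemisphere
(bilateral implants) or on a different shaft (unilateral).

## Cohort statistics

Kruskal–Wallis (tie-corrected, chi-square p) is delegated to scipy with
the all-identical degenerate case (H = 0, p = 1) handled first.  The
Wilcoxon signed-rank test drops zero differences, uses midranks for
ties, and computes the exact two-sided p (doubled one-sided tail,
capped at 1) by enumerating all 2^n sign assignments for n ≤ 15; a
tie-corrected normal approximation takes over above that.  Autonomy
clustering runs k-means (k = 2 by default, fixed seed, 10 restarts) on
z-scored (log natural FR rate, LE) points; the autonomous cluster is
the one with lower mean LE.  Trial power uses the closed-form two-sided
unpooled-variance Z-test, Φ(|Δ|/SE − z_{1−α/2}) + Φ(−|Δ|/SE −
z_{1−α/2}); enrollment inflation is ceil(n/(1 − dropout)).

## Synthetic cohorts

The generator plants the structure the analysis assumes.  Linear
shafts (8–16 per patient, 7–15 contacts at 5 mm spacing) enter a
brain-sized box from the lateral surfaces; hemispheres follow the sign
of x and lobes a fixed geometric partition — enough anatomy for the
three-lobe rule, not a cortical model.  A spatially clustered
*autonomous core* (3–6 contacts) emits independent Poisson FR>350
trains at 2–10/min (65% fRonO above 350 Hz, 35% fRonS); a surrounding
*halo* (6–12 contacts) copies two shared latent 1/min trains with
probability 0.7 and 20 ms Gaussian jitter (≈0.7/min each, high
pairwise MI); background RonS/RonO run at 0.3/min everywhere.  The
actual resection is a 15–25 mm sphere at the core centroid; in the
displaced arm (alternating patients in a cohort) the center is shifted
beyond its own radius in a random direction, which reliably leaves
core contacts in place.  The ground-truth label is seizure free iff
every core contact is resected; an optional label-flip probability
(default 0) probes classifier robustness.  Recording length defaults
to 30 min, the middle of the 10–60 min analysis window.

What passing tests show — and do not show.  The cohort is separable by
construction: resections that miss the high-rate autonomous core
depress the FR RR and inflate the spatial FRnet, so the SVM's
leave-one-out accuracy on the reference seed (~0.94) exceeds what
heterogeneous clinical cohorts yield.  The generator omits
nonstationary rates, propagation delays, detector false positives,
electrode artifacts and real anatomy; results on it validate the
pipeline's mechanics and the recoverability of planted structure, not
clinical performance.

## Numerical conventions

Distances are Euclidean in MNI mm throughout; no voxel indexing.
Shortest paths use Dijkstra on dense matrices with ∞ for missing
edges; zero-weight rate–distance edges (both rates 0) are kept as
explicit zero-length edges.  All ratios are in [0, 1] or `None`;
degenerate cases prefer explicit flags over silent sentinels.  Every
simulation is deterministic given its inputs; all randomness flows
through numpy `SeedSequence` spawning.

## Reproduction script

`scripts/acceptance.py` recomputes, from scratch: the exact signed-rank
comparison of the nine published virtual/actual resection radii and the
published-column cohort means (bundled reference tables); the trial
power (80.2%) and enrollment (200/167) numbers; and the synthetic
pipeline quantities (LOOCV accuracy, unresected-autonomous-count
Kruskal–Wallis p, virtual seizure-free fraction, full-resection factor
anchors) at n = 18 patients — a size that exercises every stage while
keeping the whole script under a minute.
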