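# Methods

This note documents the models and numerical choices behind `leaftrack`:
what is computed, under which assumptions, with which defaults, and what
the synthetic validation does and does not demonstrate.

## Problem setting

The input is one plant's time-series of 3D segmentations ("snapshots"),
typically ~43 dates at a 24 h frequency. Each snapshot holds a stem
polyline and a set of segmented leaves; each leaf carries an insertion
height *h* (mm), a blade length *l* (mm), an azimuth *α* ∈ [−π, π]
(horizontal plane, radians, wrapped), a 3D midrib polyline, and a
ligulated/growing status. Coordinates are millimetres, right-handed,
z vertical. Time is carried on two parallel axes — calendar days and
thermal time in day₂₀°C — and thermal time is always an input, never
computed, since its definition depends on the platform's temperature
records.

The goal is a time-consistent botanical rank per leaf observation. The
difficulty is that the per-date bottom-to-top order of ligulated leaves
drifts over time (senescence removes basal leaves; segmentation misses
leaves or adds artefacts), and growing whorl leaves have no topological
order at all.

## Stem-series preprocessing

* **Stem height** is the highest collar detection over all side views.
  A date with no detection has, by definition, no ligulated leaf; its
  raw height is 0 and the smoothing step reconciles it with the series.
  If collar detections are absent from the input entirely, a provided
  per-date stem height (or, failing that, the stem polyline's top) is
  used instead.
* **Smoothing**: a centred 3-point rolling median removes isolated
  spikes, then isotonic (non-decreasing, least-squares) regression
  enforces monotone growth. A series that is already non-decreasing is
  returned unchanged. The estimator is a package choice: the upstream
  description requires only that the series be smoothed and corrected.
* **Abnormal snapshots**: the median stem joins the per-z-bin (default
  20 mm) coordinate-wise median (x, y) of all stem polyline points of
  the series. Any snapshot whose stem lies more than 100 mm from the
  median stem in directed Hausdorff distance is discarded from all
  downstream stages. The distance is computed on vertices after
  densifying both polylines to ≤ 10 mm spacing, bounding the
  vertex-only error; the median stem is built once (no re-iteration
  after discarding).
* **Classification**: a leaf is ligulated iff its insertion height is
  ≤ the smoothed stem height (a collar exactly at the tip counts as
  ligulated); the ligulated sequence is sorted by increasing insertion
  height.

## End-gap-weighted pairwise alignment

Feature vector v = [cos α, sin α, w_h·h, w_l·l] with w_h = 0.03 mm⁻¹ and
w_l = 0.004 mm⁻¹ scaling the two metric features against the unit-norm
azimuth components. Match cost: Euclidean distance c_vv. Gap penalty:
g = w_gap·c̄_adj with w_gap = 3; c̄_adj is the mean c_vv over
topologically adjacent leaf pairs, estimated per plant from its own
series (an override, e.g. 4.23, can pin a fleet-wide value). Terminal
gaps cost w_tml·g with w_tml = 0.2.

A gap column is *terminal* iff it lies in the maximal gap run touching
the start or end of its own aligned sequence. In the dynamic program
this is realised by charging w_tml·g for gap moves taken in the first or
last row/column of the DP matrix; per-move charging is provably
identical to per-column counting for every lattice path, so the DP
optimum, the cost re-evaluated from the returned columns, and the
brute-force enumeration oracle used in the tests agree exactly. Gaps
are charged linearly (no affine opening cost), matching the global cost

    C = (n − n_tml)·g + n_tml·w_tml·g + Σ_{i∈I} c_vv(v_i, v′_i).

Traceback ties are broken match > gap-in-second > gap-in-first, making
the output deterministic.

One property of plain Needleman-Wunsch does **not** carry over: with
end-gap weighting, appending an identical element to both sequences can
*increase* the optimal cost (a formerly terminal gap may become
interior). The test suite asserts the conditional form instead (when the
previous optimum ends in a match, the cost cannot rise).

## Progressive multiple alignment and rank assignment

Sequences are folded into a profile in ascending temporal order. The
sequence-profile cost of matching v′ against a column is the mean of
c_vv over the column's k non-gap members — gaps do not dilute the mean.
Terminal-gap weighting applies unchanged (same DP machinery). Inserting
a gap into the profile inserts an all-gap entry for all previously
processed snapshots; an empty sequence contributes an all-gap row.

After the final profile, interior columns are pruned when
n_k < (n_{k−1} + n_{k+1})/4, evaluated in a single pass on the original
occupancy counts of the immediate original neighbours; the first and
last columns are exempt. Leaves of pruned columns stay unassigned.
Surviving columns are numbered 1..K bottom-to-top; if the true first
leaf is never segmented, all reported ranks shift by one relative to
botany — an accepted failure mode of rank-1 segmentation.

Isolation of an artefact in its own sparse column is optimal only when
the artefact has roughly ≥ w_gap leaves both below and above it;
artefacts near the sequence ends can instead displace the short end of
the sequence through cheap terminal columns. Combined with the first/
last pruning exemption this is the pipeline's main catastrophic-failure
channel: a surviving spurious column shifts every rank beyond it.

## Backward tracking of growing leaves

Midribs are resampled to n = 20 points equally spaced in arc length
(endpoints preserved); the trajectory distance is the index-wise sum of
Euclidean distances. Ranks are processed in ascending order; each chain
starts at the rank's first ligulated observation and steps backwards
date by date, at each date adopting the nearest remaining unassigned
growing leaf and removing it from the pool (the query is always the most
recently associated midrib). Dates with an empty pool are skipped; the
chain stops when no earlier snapshot retains any growing leaf, or at the
first snapshot. Lower ranks win contested observations. No distance
cutoff is applied by default; `max_backtrack_distance` exists as an
optional guard, off by default.

The greedy chain is deliberately simple and is fragile to a missing
observation when other whorl leaves are present at that date: the forced
adoption of a neighbour diverges the chain permanently, because a leaf's
own one-day-earlier observation is always closer than any cross-leaf
match. This fragility is inherent to the per-date greedy and is visible
in the noisy-regime accuracies.

## Traits

* **Rank profiles** x_pf(r): median of a variable over a rank's
  ligulated observations within 20 day₂₀°C of its ligulation (= the time
  of its first ligulated observation, the classification boundary).
* **Visible leaf stage**: r_vis(t) is the maximum rank observed at t;
  t_med(r) the median of {t : r_vis(t) = r} (midpoint convention for
  even counts); t_vis(r) = (t_med(r−1) + t_med(r))/2, omitted for ranks
  never maximal. n_vis(t) linearly interpolates the (t_vis(r), r) knots
  and is clamped (not extrapolated) outside their support.
* **Ligulated leaf stage**: t_lig(r) is the earliest time the smoothed
  stem height reaches h_pf(r − offset), with linear interpolation
  between height samples; n_lig(t) = max{r : t_lig(r) ≤ t} is integer
  and piecewise constant. The rank offset defaults to 1 — keying leaf
  r's ligulation to the collar height of leaf r−1, as the stage
  definition is printed — and can be set to 0 via
  `lig_stage_rank_offset` if the off-by-one is considered a typo.
* **Leaf growth**: the time-ordered lengths of a rank's observations
  strictly before its ligulation time.

## Synthetic plant generator

The generator emulates the acquisition regime the pipeline targets, with
defaults fixed as the study conditions: 16 leaves, 43 daily time points,
phyllochron 2 d, ligulation lag 8 d (3-5 leaves growing simultaneously
mid-season), logistic stem growth to ~1.9 m, bell-shaped length profile
(~300-1000 mm), alternating ±π/2 azimuth with 0.1 rad jitter, senescence
dropping basal leaves from day 30 at 0.3 leaves/day. A collar fixes
100 mm below the stem tip at ligulation — the whorl of still-rolled
leaves extends well above the highest collar — and growing leaves insert
at the whorl top. Midribs are a smooth two-parameter arc family whose
droop increases with age and freezes at ligulation, so day-to-day
displacement is small against inter-leaf separation. Thermal time is
emitted at 1 day₂₀°C per day (constant-temperature greenhouse
assumption; configurable).

Corruption, per snapshot and independently: with probability
`p_missing_leaf` (default regime 0.03) one uniformly chosen leaf is
missed; with probability `p_artefact_leaf` (0.05) one ear-like artefact
(length 80-200 mm, random azimuth, inserted among the collars above the
5th — snapshots with fewer than five collars host none) is added; h, l
and α receive zero-mean Gaussian noise of sd = `feature_noise_sd` ×
feature scale (scales 500 mm, 800 mm, π rad). Midrib polylines are
carried unchanged — the noise models feature-extraction error, not
geometry error.

What passing tests show — and do not. The simulator provides exact
ground truth, bottom-up emergence, and feature stationarity after
ligulation; real data additionally contain correlated segmentation
errors, non-stationary features (leaf bending over time), irregular
acquisition gaps, and collar-detection noise, none of which are
emulated. Synthetic accuracies therefore validate the algorithmic
machinery, not field performance.

## Numerical choices and degenerate inputs

* All pipeline stages are deterministic for fixed input and parameters;
  the only randomness lives in the simulator, driven by one seed.
* Ties: equal-cost traceback prefers matches (see above); equal
  insertion heights keep input order in sorting; equal trajectory
  distances adopt the first candidate.
* Single-snapshot series: ranks are the topological order 1..n; growth
  curves are empty; no gap-penalty estimate is needed (it is computed
  lazily, only when two sequences must actually be aligned).
* A series whose sequences never contain two adjacent ligulated leaves
  cannot estimate c̄_adj and is rejected with an explicit error (use the
  override to proceed).
* Zero-length (degenerate) midribs are rejected at resampling.
* Serialization uses plain JSON (exact for doubles via repr round-trip)
  and flat CSV for trait tables.

## Known limitations

* The greedy backward tracker cascades on missing whorl observations
  (see above); a global assignment across dates would be more robust but
  is out of scope by design.
* The first/last pruning exemption lets a spurious bottom or top column
  survive and shift all ranks; rare but catastrophic when it occurs.
* c̄_adj estimated per plant differs from a fleet-wide constant; both
  are supported, and the choice changes the gap penalty scale.
* The median stem is not re-estimated after discarding outlier
  snapshots (single pass).
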