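# Methods

This note documents the models behind `strokenet`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Domain model

Hospitals are points on a projected planar map in km; no geodesy is
performed. A hospital is a *hub* iff its care level is SC or SU; hubs hold
≥ 1 monitored bed and TSRH spokes hold none. Travel distances default to
Euclidean on the planar coordinates; a user-supplied distance matrix
(e.g. road distances, which may be asymmetric) replaces them everywhere —
nothing in the pipeline assumes symmetry or the triangle inequality.

Catchments map each population zone to the hospital with the smallest
Euclidean centroid distance, ties broken by lexicographically smallest
hospital id so the mapping is reproducible across platforms.

## Performance criteria

For network *n* with spokes *P_n* and hubs *S_n*:

- `C1_n = (1/|P_n|) Σ_{p∈P_n} min_{s∈S_n} d(p, s)` — undefined (reported
  as missing, never an error) when the network has no spokes, because
  clustering legitimately produces hub-only networks; an error when it has
  spokes but no hub, which a valid design cannot contain.
- `C2_n` = summed catchment population of **all** member hospitals
  (spokes included — spoke catchments are served by the network's hubs
  after transfer) divided by the hub count.
- `C3_n = |S_n| / |P_n|`, missing when there are no spokes.

Summary C1 is weighted by **member counts** by default. A hub-count
weighting is available behind `weight_mode="hubs"`; member-count weighting
is the default because it is the convention the criteria tables in this
line of work actually follow, whatever their footnotes say. Reported cells
are rounded half-up to 2 decimals; internal computation keeps full
precision, and derived comparison lines (differences, percent reductions)
are computed from the rounded table values, matching how a reader would
derive them from the printed table.

## Hub assignment

The 0/1 program assigns each independent hub to exactly one network,
minimizing the summed average distance to the receiving network's current
members. Membership sets and member counts are **not** updated as hubs are
assigned — assignments are simultaneous, by a literal reading of the
model. Because the objective decomposes per hub, the exact optimum is the
per-hub argmin of the assignment cost; this greedy is the default engine,
and the explicit MILP (scipy's HiGHS backend) is retained purely as a
fidelity cross-check. Ties between networks with equal cost go to the
lexicographically first network id and are logged.

## Clustering redesign

K-means with squared-Euclidean distance, Lloyd's algorithm, random-point
initialization, max 300 iterations, relative tolerance 1e-6 (scikit-learn's
`KMeans` with `init="random"`, `n_init=1`). Restart sub-seeds are spawned
from the run seed, so a run is reproducible as a whole. Hospital planar
coordinates are the only features — no population weighting — because the
aim is spatially contiguous service territories.

Filtering: partitions with an empty cluster are excluded; partitions with a
hub-less cluster are *also* excluded, because C1 is undefined there; the
two counts are tracked separately. Survivors are deduplicated by canonical
form (clusters renamed in order of first appearance over the sorted
hospital-id list), scored by member-weighted C1, and the minimum wins with
ties broken by canonical order.

## Flow simulation

**Arrivals.** Homogeneous Poisson per catchment at
`population/100,000 × incidence × ischemic_fraction` per year. Defaults:
incidence 420/100k/yr, ischemic fraction 0.82. This is the minimal
assumption consistent with "stochastic arrivals"; an optional sinusoidal
annual modulation (`seasonal_amplitude`, thinning-based) exists but is off
by default. Patients originate at their catchment hospital's location; a
hub admitting its own catchment's patient counts as a nearest admission at
0 km.

**Patient classes.** MT-eligibility is i.i.d. Bernoulli with
`mt_fraction = 0.075`, the midpoint of the reported 5–10% range; with the
default incidence this reproduces the familiar ≈ 26 MT-eligible strokes per
100,000 after rounding. MT patients may only be admitted at an SC.

**Routing.** The cascade scans the patient's own-network eligible hubs in
ascending distance (ties by id): first with a free bed wins — nearest ⇒
`ADMITTED_NEAREST`, later ⇒ `DIVERTED`. If none, all other-network
eligible hubs in ascending distance: first free ⇒
`REJECTED_TO_OTHER_NETWORK` (the receiving hub's bed **is** consumed). If
none anywhere: `NOT_TREATED`. Routing is a pure function of the occupancy
state; bed seize/release happens in the event loop. Unassigned hubs are
modelled as singleton networks: they cannot divert internally but can
receive rejected patients. A consequence worth knowing: an MT patient whose
network has no SC is always cross-network rejected, even with unlimited
beds — so "zero rejections in the uncapacitated limit" holds only for
designs in which every network contains an SC.

**Stays and measurement.** Admitted patients hold one monitored bed for a
triangular(5.8, 11.3, 16.7)-day stay (mean 11.27 d), then leave the system.
The warm-up is fixed at 60 days ("two months") and excluded from metrics;
the measured horizon is 365 days. Utilization is the time-weighted average
of occupied/total beds per network over the measurement window (patients
admitted during warm-up still occupy beds into the window; stays censored
at the window edge).

**Replications and CRN.** Replication *r* uses seed `base_seed + r`. The
demand stream (times, origins, classes, stays) is generated from region,
config and seed alone — never from the design — so two designs under the
same seed face bit-identical demand (common random numbers). Aggregation
reports mean and std (ddof = 1) across replications per network, with
independent hubs pooled into one reporting group. Overall rows weight by
hub counts, except the travel distance, which is total diverted/rejected km
over their count. The diversion proportion's denominator is all patients
originating in the network by default; `diversion_denominator=
"network_admissions"` switches to within-network admissions. Networks with
fewer than two hubs cannot divert and report a missing value.

The event engine is a binary-heap calendar (arrivals pre-sorted, departures
heap-managed, departures processed before arrivals at equal timestamps);
one full-year replication of the default 97-hospital region (~52,000
patients) runs in about half a second, which sets the problem sizes used in
the test suite (tens to hundreds of replications).

## Validation statistics

Simulator output is binned into 30.4-day months from the end of warm-up
(trailing partial bin dropped): arrival counts, and utilization percent per
bin. Observed-vs-simulated series are compared with a two-sided t-test of
H0: equal means at α = 0.05. Pooled, Welch and paired variants are all
implemented; **Welch is the default** because the equal-variance assumption
buys nothing here and the variant used in the published validation tables
of this literature is generally not identifiable from the printed
statistics. Two identical constant series are a defined limit (t = 0,
p = 1), not an error.

## Synthetic regions

`bavaria_like_spec()` encodes the study conditions of a large federal
system: 97 hospitals, 58 hubs of which 13 SC-level, 5 networks plus 14
independent hubs, 13 M inhabitants on 350×300 km, 4–22 monitored beds per
hub. `generate_region`:

- places hospitals by a clustered spatial process (60% near ≥3 urban
  centers with 18 km scatter, the rest uniform);
- draws hub/SC status uniformly at random among hospitals/hubs, beds
  uniform over the bed range (per-site bed counts are not published; the
  uniform draw is a modelling choice);
- creates 3 zones per hospital with lognormal(σ = 1.2) sizes — σ chosen to
  give the strong urban/rural contrast that drives the spread of C2;
- forms "historically grown" networks by seeding one well-separated SC per
  network, attaching every hospital to its nearest seed, then detaching the
  stroke units farthest from their seed as independent hubs (seeds are
  never detached, so every network keeps a hub).

Zone populations are stored as float inhabitant counts of the form
`share × total / 2^20` with integer shares apportioned by largest
remainder (each zone ≥ 1 share). Because the denominator is a power of
two, these are dyadic rationals: floating point sums them exactly in any
grouping (Σ zone populations equals the requested total bit-exactly, as
does any catchment regrouping) and doubling the total doubles every zone
bit-exactly. No integer apportionment has both properties.

What the generator does **not** emulate: real road travel distances (the
spatial texture is Euclidean), true postcode geometries, empirically
calibrated per-site bed counts, seasonal or demographic structure in
demand. Consequently, passing tests demonstrate the correctness of the
algorithms under controlled conditions, not agreement with any particular
real region's published tables — those depend on proprietary road
distances, registry coordinates and census populations.

One property of the default conditions deserves emphasis: at incidence 420,
ischemic fraction 0.82 and an 11.3-day mean stay, 13 M inhabitants generate
an offered load of ≈ 1,380 monitored beds, while 58 hubs with 4–22 beds
supply ≈ 750. The default synthetic region is therefore demand-saturated —
region-wide simulations show near-100% utilization and heavy rejection.
That is the arithmetic of the stated inputs, not a bug; studies of routing
behaviour at realistic 60–85% utilizations should size capacities with
`size_beds(annual_arrivals, los_mean, target_utilization)` =
`ceil(λ·LOS/365/ρ)`, the M/G/c offered-load rule, which the test suite
verifies lands within ±10 points of target on a single-hub system.

## Numerical conventions and limitations

- All RNGs are numpy `default_rng`; every public entry point takes an
  explicit seed; identical seeds give bit-identical outputs.
- Ties (catchments, routing candidates, assignment costs, cluster
  selection) always break lexicographically — determinism over elegance.
- Reported tables round half-up to 2 decimals; populations to integers.
- The simulator does not model ambulance dispatch, time windows,
  thrombolysis decisions, outcomes, or costs; distances are km, never
  minutes.
- The optimizer is distance-only, as specified — no capacity or population
  balancing. The clustering is likewise unweighted; balanced or capacitated
  territory design is out of scope.
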