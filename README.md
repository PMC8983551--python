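# strokenet

Analysis toolkit for **hub-and-spoke stroke-care networks**: score a regional
network design, fold unaffiliated stroke units into existing networks
optimally, propose geographic redesigns by clustering, and stress-test any
design with a capacity-constrained discrete-event simulation of patient flow.

It is written for health-services and operations researchers studying
regional stroke systems — collections of **stroke centers (SC)** and
**stroke units (SU)** acting as hubs with monitored beds, and
telemedicine-assisted stroke-ready hospitals (**TSRH**) acting as spokes
that stabilize patients and transfer them to a hub.

## The model

A region is a set of hospitals (planar km coordinates, care level, monitored
beds), population zones (centroid + inhabitants), and a travel-distance
matrix (Euclidean by default; supply road distances if you have them). Each
zone belongs to the catchment of its nearest hospital. A **network design**
partitions hospitals into named networks; independent hubs carry the
`UNASSIGNED` label.

Designs are scored by three criteria:

- **C1** — mean distance from each spoke *p* to its nearest hub *s* within
  the network: `C1_n = mean_p min_s d(p, s)` (km);
- **C2** — inhabitants served per hub: total catchment population of all
  member hospitals divided by the hub count;
- **C3** — hub-to-spoke ratio `|hubs| / |spokes|`.

Summary rows report the member-count-weighted average C1.

**Hub assignment.** Each independent hub *a* joins exactly one network *n*,
minimizing `Σ_n Σ_a x_{a,n} · Σ_{b∈Bⁿ} d(a,b) / h_n` with
`Σ_n x_{a,n} = 1`, x binary. The objective is separable, so the per-hub
argmin is exact; an explicit 0/1 program (`scipy.optimize.milp`) is kept as
a cross-check.

**Redesign.** K-means (Lloyd's, random-point init, 100 restarts) on
hospital coordinates proposes k spatially compact networks; degenerate
partitions (empty or hub-less clusters) are discarded, survivors are
deduplicated up to relabeling and ranked by weighted C1.

**Simulation.** Ischemic strokes arise per catchment as Poisson arrivals at
`population/100,000 × incidence × ischemic fraction` per year (defaults
420 /100k/yr and 0.82). A fraction (default 0.075) needs mechanical
thrombectomy and can only go to an SC. The routing cascade: nearest free
own-network hub → next-nearest own-network hub (*diversion*) → closest free
hub in another network (*rejection*) → *non-treatment*. Admitted patients
hold one monitored bed for a triangular(5.8, 11.3, 16.7)-day stay.
Replications share demand streams across designs (common random numbers).

## Worked example

```python
import strokenet as sn

region, design = sn.generate_region(sn.bavaria_like_spec(seed=1))
sn.assign_catchments(region)

before = sn.criteria_report(design, region)
prob = sn.AssignmentProblem.from_design(design, region.distances)
mapping, _ = sn.assign_independent_hubs(prob)
after = sn.criteria_report(sn.apply_assignment(design, mapping), region)

run = sn.run_kmeans_designs(region, k=5, restarts=100, seed=1)
k5 = sn.criteria_report(sn.select_best_design(run), region)
```

On the default synthetic region (97 hospitals, 58 hubs, 5 networks plus 14
independent hubs, 13 M inhabitants) this prints:

```
== current design ==
NET1: members=30 hubs=16 C1= 18.23 km  C2=196,024  C3=1.14
NET2: members= 4 hubs= 2 C1= 60.78 km  C2=119,812  C3=1.00
NET3: members=27 hubs=14 C1= 18.25 km  C2=224,415  C3=1.08
NET4: members= 3 hubs= 1 C1= 43.96 km  C2=534,269  C3=0.50
NET5: members=19 hubs=11 C1= 25.81 km  C2=259,720  C3=1.38
member-weighted C1 = 22.95 km

== after assigning the 14 independent hubs ==
member-weighted C1 = 20.57 km (reduction 2.38 km)

== K-means redesign, k=5 (44 unique valid partitions) ==
member-weighted C1 = 18.99 km
```

Reading this: the historically grown design leaves two small networks with
long spoke-to-hub distances (NET2, NET4) and one hub carrying a 534 k
catchment; absorbing the independent hubs shaves 2.38 km off the average
transfer, and a clean geographic re-partition shaves a further 1.6 km.

Capacity planning uses the offered-load sizing rule: a catchment of 100,000
people generates 344.4 ischemic strokes/year, and
`size_beds(344.4, 11.27, 0.75)` → 15 monitored beds, which the simulator
confirms runs at 68% utilization (std 2.5% across 50 replications).
Note that the full synthetic region under the default incidence and
length-of-stay is demand-saturated — far more offered load than its 4–22
beds per hub can carry — so region-wide simulations report utilization near
100% with large rejection counts unless capacities are re-sized with
`size_beds`; see `docs/methods.md`.

The same pipeline is scriptable from a shell via the `strokenet` console
command (`synth`, `assign`, `cluster`, `simulate`, `validate`, `report`);
each subcommand reads/writes the plain CSV/JSON formats documented in the
module docstrings.

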