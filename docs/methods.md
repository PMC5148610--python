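# Methods

`oplconn` quantifies the connectivity between photoreceptors and bipolar
cells (BCs) in the mouse outer plexiform layer (OPL) from skeletonised
EM-style reconstructions: contact-point tables between BC dendrites and
photoreceptor terminals, per-cell skeletons, and terminal geometry.
Because the volume it was designed around is not shippable at package
scale, every stage is exercised against a synthetic OPL generator that
plants known ground truth; this note documents the model behind each
stage, the defaults and their rationale, and what the synthetic tests
do and do not establish about real data.

## Coordinate conventions

All coordinates are µm. The optical axis of every simulated terminal is
the global +z axis, pointing from the pedicle base toward the pedicle
top. The pedicle base (where ribbon synapses sit and BC dendrites
arrive) lies near z = 0; BC somata sit near z = −8 and the inner
plexiform layer (IPL), where BC axons stratify, at z ≈ −40 to −55.
Simulated pedicles are axis-aligned; the data model carries an explicit
unit axis vector per pedicle so tilted real data fit the same code
path.

## Contact sets and geometric features

All contact points between one BC and one terminal form a *contact
set*, the classification unit. Per set we extract:

| feature | definition | unit |
|---|---|---|
| a | total contact area, summed over points | µm² |
| b | eccentricity: min planar distance of a point to the terminal centre, ⊥ to the axis | µm |
| c | contact height of the min-eccentricity point above the base, / height | – |
| d | along-dendrite distance to the nearest branch point | µm |
| e | along-dendrite distance to the nearest dendritic tip | µm |
| f | smallest acute angle between the local dendrite direction and the axis | rad |
| g | number of contact points in the set | – |
| h | (rods, OFF-CBC only) Euclidean distance to the nearest synaptic RBC contact on the same spherule | µm |

Numerical choices where the definitions are silent:

* ties for "minimal eccentricity" break to the smallest axial
  coordinate (the point nearest the base);
* the local dendrite direction is a central difference across the node
  when it has both a parent and a child, otherwise the single incident
  edge; the first child is used when several exist;
* a tree without a branch point uses the root for feature d;
* rod contacts reuse the pedicle frame with the spherule centre, the
  global optical axis, base at the sphere bottom and height = diameter.

Features are invariant under rigid translation, and b, c under rotation
about the terminal axis (tested).

## Contact classification

An RBF-kernel C-SVM decides synaptic vs. non-synaptic per contact set,
separately for five groups: OFF-CBC/cone, ON-CBC/cone, RBC/cone,
OFF-CBC/rod (features a–g plus h) and RBC/rod. Features are
standardised inside each leave-one-out (LOO) fold only (scaler inside
the CV pipeline), so no held-out information leaks into the scaler.
Hyperparameters are chosen by LOO accuracy on a fixed logarithmic grid,
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1, 10}; classes are not
reweighted, so the reported false-positive/-negative rates are raw.
CBCX sets are excluded from ON-CBC training because their contacts are
atypical (mostly non-invaginating tip contacts). Training-set sizes in
the pipeline mirror the labelled pools of the source analysis (50
OFF-CBC, 108 ON-CBC and 67 RBC cone sets; 100 RBC and 97 OFF-CBC rod
sets). Because OFF-CBC rod synapses sit next to the invaginating RBC
dendrites, feature h is computed from the *predicted* synaptic RBC–rod
sets, and rods without any RBC contact are excluded from the OFF-CBC
rod analysis (their count is reported).

## S-cone identification

CBC9 selectively targets S-cones, so classified CBC9–cone contact sets
carry the spectral information. A cone with ≥ 1 invaginating
(synaptic) CBC9 set is a candidate. The strict rule labels a candidate
S iff it has ≥ 2 invaginating contact sites AND these come either from
two different CBC9s, or from a single CBC9 with at least one
contacting branch terminating at the cone; single-site candidates are
M, as are non-candidates. The liberal rule labels every candidate S.

Two operationalisations were open:

* "invaginating contacts" are counted as contact *sites* (points), not
  sets — grouping admits exactly one set per (CBC9, cone) pair, so
  "two contacts from a single CBC9" can only refer to sites within one
  set;
* "branch ending at the cone" means the set's distance-to-tip feature
  (e) falls below 1 µm (configurable) — a judgment made visually in
  manual workflows;
* "in reach" (the denominator of S-cone fractions) means the cone
  centre lies inside the projected convex hull of ≥ 1 CBC9.

The packaged worked example encodes the canonical published contact
configuration: 48 CBC9–cone sets over 43 cones, 29 cones peripheral-
only, 8 single-site candidates, 5 candidates with two sites from two
CBC9s and 1 candidate with two sites from one terminating CBC9 — giving
14 candidates, 6 strict S (4.8% of the 124 in-reach cones) and 14
liberal S (11.3%). An exact one-sided upper-tail binomial test
(P(X ≥ k | n, p₀), p₀ = 0.05) quantifies the plausibility of an S
fraction; a two-sided variant is exposed behind a flag.

## CBC5 subtyping

Type 5 CBCs split into 5T/5O/5I by axonal stratification depth in the
IPL. Raw depths are normalised against the two starburst amacrine cell
(SAC/ChAT) bands: per (x, y) grid cell (default 10 × 8 over the field)
the depth histogram (0.5 µm bins) of the SAC point cloud is peaked; the
modal bin (argmax; ties resolve to the lower bin) is refined by the
median of points within ±2 bins, which is robust to band tilt across
the cell; empty cells are nearest-neighbour filled; a bivariate cubic
B-spline is fitted through the grid of peaks. Depths are then mapped
affinely per column so the ON band → 0 and the OFF band → 1
(extrapolated linearly outside). Fit accuracy is below the depth-bin
height over the interpolation-supported interior; at the extreme field
border the spline extrapolates and the error can reach ~1 µm (~0.1
corrected depth for a 10 µm band gap), which leaves the subtype
separation of ~0.2 intact.

Per cell, corrected depths of the axonal points are histogrammed (50
bins over [−0.5, 1.5], length-weighted when skeletons are supplied) and
unit-normalised. Profiles are mean-centred, reduced to the first three
principal components, and clustered by a 3-component full-covariance
Gaussian mixture (20 seeded restarts, best likelihood kept, covariance
ridge 1e-6). Because each subtype should approximately tile the
retina, assignments are refined by greedy descent over single-cell
shifts and pairwise swaps minimising

L = λ₁ Σᵢ (xᵢ − μ_cᵢ)ᵀ Σ_cᵢ⁻¹ (xᵢ − μ_cᵢ)
  + λ₂ Σ_{i≠j} δ(cᵢ,cⱼ) O_ij,OPL / Σᵢ A_i,OPL
  + λ₂ Σ_{i≠j} δ(cᵢ,cⱼ) O_ij,IPL / Σᵢ A_i,IPL

with O the pairwise intersection areas of the projected convex hulls
and A the hull areas. Design decisions:

* the Mahalanobis form uses the inverse covariance; a literal variant
  without the inverse (which would reward, not penalise, tight
  clusters along low-variance directions) is available behind
  `use_inverse_covariance=False`;
* overlap sums count ordered pairs (i, j) and (j, i) and exclude i = j;
* λ₁ = 1 and λ₂ = n_cells by default, balancing the per-cell distance
  sum against the field-level overlap ratios; both configurable;
* the best strictly-decreasing move is applied per iteration, so the
  cost sequence is strictly decreasing until a local minimum.

Clusters are named 5T/5O/5I by ascending mean profile-peak depth.

## Connectivity statistics

The dendritic field is the convex hull of the skeleton's nodes
(soma/trunk excluded) projected along the optical axis; a cone is in
the field when its centre lies inside or on the hull. Hull coverage of
a type is Σ hull areas / union area; cone coverage is Σ per-cell
in-field counts / cones in the union of fields. Convergence (cones per
BC, by spectral class) and divergence (BCs per cone, by type) are
restricted to complete cones, with an optional inset margin excluding
border cells; incomplete cones are excluded and flagged. Contact
distances (soma to contacted cone, planar) are summarised per type by
Gaussian KDEs (Silverman bandwidth by default); the normalised variant
divides by the equivalent hull radius √(A/π). Rod connectivity reports
rods per RBC, the 0/1/2/>2 histogram of RBC partners per rod, and rods
per OFF-CBC type restricted to rods with ≥ 1 synaptic RBC contact. The
two-group RBC comparison (rod-only vs. rod+cone) reports group sizes,
rod-count and hull-area distributions and bootstrap CIs of the group
difference. All intervals are seeded percentile bootstrap CIs over
case resampling (default 95%, ≥ 100 resamples enforced). Mixed-model
or rank-sum hypothesis tests are not re-implemented; the module
exports the tidy per-cell contingency tables (e.g. invaginating vs.
tip contacts per ON-CBC type, thresholds: height > 0.15 and
eccentricity within the pedicle radius ⇒ invaginating) for external
fitting.

## Synthetic OPL generator

The generator emulates the statistical structure the analysis assumes,
with every parameter a config field and all randomness derived from
one seed through fixed stage-indexed streams (fixed config ⇒
byte-identical output).

* **Cone mosaic** — jittered hexagonal lattice with a 5 µm hard
  exclusion radius, clipped to a 114 × 80 µm field at 17.9 pedicles /
  1000 µm² (≈ 163 pedicles); S labels drawn at 5%; pedicle radius
  3.0 ± 0.25 µm, height 2.0 ± 0.15 µm, base near z = 0.
* **Rod field** — 380 spherules / 1000 µm² over the left half of the
  field (≈ 1730 rods), mirroring a half-field reconstruction.
* **BC mosaics** — per-type counts, mean OPL hull areas and coverage
  factors follow the published type table. Trees grow by a vertical
  trunk, 4–6 primary dendrites and recursive bifurcation (probability
  0.35/step, depth ≤ 3, segments 1.2–2.8 µm), then are rescaled in xy
  so each cell's hull matches its drawn target area (SD = 15% of the
  mean). The mosaic spread is calibrated by bisection on the realised
  hull union so the coverage factor hits its target (typically to
  < 1%).
* **Wiring** — OFF types contact each in-field cone with probability
  0.70 via basal geometry; standard ON types with 0.70 (5T/5O/8: 0.45)
  via invaginating geometry; CBCX contacts 20% of in-field cones,
  invaginating with probability 3/19 and otherwise via small basal-like
  tip contacts; CBC9 makes invaginating, branch-terminating contacts
  with every covered S-cone (2–3 sites per pair, matching the ~32/14
  sites-per-cone ratio of the source counts) plus rare single M-cone
  contacts (rate 0.04); 75% of RBCs contact 1 + Poisson(0.8) nearest
  in-field cones; each rod receives 0/1/2 invaginating contacts from
  distinct nearest RBCs with probabilities (0.02, 0.54, 0.44), only
  RBCs with somata inside the rod region participating — at the default
  densities this yields ≈ 35 rods per RBC; CBC3A/3B/4 receive
  Poisson(5/10/5) basal rod contacts placed next to the rod's RBC
  contact, CBC1/2 almost none (0.3/0.5).
* **Contact geometry** — synaptic contacts terminate dendritic twigs
  appended to the arbor (tip distance 0), invaginating twigs axial,
  basal twigs oblique. Class-conditional distributions: invaginating
  eccentricity U(0.05, 0.50)·R, height U(0.15, 0.60); basal U(0.05,
  0.55)·R, U(0.00, 0.18); peripheral (spurious) contacts attach to
  passing mid-arbor nodes at eccentricity U(0.55, 1.40)·R and height
  U(0.10, 1.10), placed on 35% of unwired in-reach pairs (6% for
  rods). Areas are log-normal (medians 0.20 / 0.10 / 0.05 / 0.04 µm²
  for invaginating / basal / tip / peripheral, σ = 0.5–0.6). The
  ranges overlap slightly, so the classes are separable but not
  trivially so (a threshold on eccentricity alone reaches ~0.97, the
  SVM ~0.99 on large pools and ~0.9–1.0 at the source-analysis training
  sizes). The spatial statistics of peripheral contacts are
  conventions, not inferences from data.
* **SAC bands / CBC5 axons** — two sinusoidally warped surfaces
  (amplitude 1.5 µm, wavelengths 70/55 µm) at z = −52 (ON) and −42
  (OFF), ON below OFF everywhere; 4000 cloud points per band with
  0.3 µm depth noise. CBC5 subtypes are planted at corrected depths
  0.35 / 0.55 / 0.75 with per-cell profile SD 0.06 ("moderate
  overlap": ±1.7σ spacing between neighbouring subtypes), 150 axonal
  points per cell distributed over the configured IPL hull area.

### What the generator does not emulate

Real membrane morphology, voxel-level contact detection, horizontal
cells, amacrine interneurons beyond the SAC band surfaces, opsin
co-expression gradients, and any spatial correlation structure of
spurious contacts. Tests passing on this generator establish that the
implementation recovers *planted* structure under the stated
statistical assumptions; they do not certify accuracy on real EM data,
whose label noise and geometry are richer.

## Problem sizes and determinism

Default study-scale runs use the full 114 × 80 µm field (≈ 163 cones,
≈ 1730 rods, 558 BCs, ≈ 4300 contact sets); the CBC5 analysis uses the
planted 22/22/25 population. These sizes keep a full pipeline run in
the low minutes on one CPU while matching the source reconstruction's
scale. Every stochastic stage takes an explicit seed; the pipeline
derives all stage seeds from one run seed and records config, seed and
file hashes in a manifest.

## Known limitations

* The per-group SVM scores depend on the generator's class overlap;
  the published per-table error rates are properties of manual labels
  on real data and are deliberately not targeted.
* The SAC surface fit is extrapolated outside the outermost grid-cell
  centres; fields much smaller than ~10 grid cells per side need a
  coarser grid.
* The shift/swap refinement is a greedy local search; it repairs
  isolated tiling violations but is not a global optimiser.
* Hull-based coverage ignores dendritic gaps inside the hull; for
  sparse arbors (CBCX) the hull overstates the sampled area, as it
  does in hull-based analyses of real data.
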