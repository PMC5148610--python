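# oplconn

Connectivity analysis of photoreceptor → bipolar cell contacts in the
mouse outer plexiform layer (OPL).

In the mouse retina, two spectral cone types (S and M) and rods feed 14
bipolar cell (BC) types through stereotyped synapses: ON-type cone
bipolar cells (CBCs) and rod bipolar cells (RBCs) make *invaginating*
contacts reaching into the presynaptic terminal, OFF-CBCs make *basal*
contacts at the terminal base, and dendrites passing a terminal leave
*peripheral* touches that are not synapses. Given skeleton
reconstructions, terminal geometry and a membrane contact-point table —
the outputs of a dense EM reconstruction — `oplconn` answers the
wiring questions of outer-retina connectomics:

* **Contact classification** — all contact points of one (BC, terminal)
  pair form a *contact set* described by seven geometric features
  (contact area *a*, eccentricity *b*, contact height *c*,
  along-dendrite distances to branch point *d* and tip *e*, dendrite /
  optical-axis angle *f*, point count *g*; plus the distance *h* to the
  nearest synaptic RBC contact for rod contacts of OFF-CBCs). An
  RBF-kernel C-SVM per biological group (OFF-CBC / ON-CBC / RBC ×
  cone / rod) decides synaptic vs. non-synaptic, with hyperparameters
  chosen by leave-one-out cross-validation.
* **S-cone identification** — CBC9 selectively contacts S-cones, so
  classified CBC9–cone sets yield spectral labels. Strict rule: S iff
  ≥ 2 invaginating contact sites from two different CBC9s, or from one
  CBC9 with a branch terminating at the cone. Liberal rule: S iff ≥ 1
  invaginating contact. An exact upper-tail binomial test
  P(X ≥ k | n, p₀ = 0.05) gauges an S fraction against the canonical
  ~5% share.
* **CBC5 subtyping** — axonal depth profiles, corrected by mapping the
  two starburst-amacrine (ChAT) band surfaces (bivariate cubic
  B-spline fits) to the parallel planes 0 and 1, are reduced by PCA to
  three components, clustered by a 3-component Gaussian mixture, and
  refined by a greedy shift/swap heuristic minimising
  `L = λ₁ Σᵢ (xᵢ−μ_cᵢ)ᵀ Σ_cᵢ⁻¹ (xᵢ−μ_cᵢ) + λ₂ Σ_{i≠j} δ(cᵢ,cⱼ) O_ij / Σᵢ Aᵢ`
  (convex-hull overlap terms for both OPL and IPL), labelling the
  clusters 5T/5O/5I by stratification depth.
* **Connectivity statistics** — convergence (cones per BC, by spectral
  class), divergence (BCs per cone, by type), cones-in-field vs.
  contacted fractions, hull and cone-counting coverage factors,
  soma-to-contact distance KDEs, rod↔RBC/OFF-CBC connectivity and the
  rod-only vs. rod+cone RBC comparison — all with seeded percentile
  bootstrap confidence intervals.
* **Synthetic OPL generator** — a first-class, fully ground-truthed
  simulator of the outer retina (cone/rod mosaics, per-type BC mosaics
  with configured hull areas and coverage factors, wiring rules per
  type, contact geometry per class, SAC bands, CBC5 subtypes) so that
  every stage is testable end-to-end without the original volume.

## Worked example

The packaged worked example encodes the canonical CBC9–cone contact
configuration of the reconstruction this analysis was designed around:
48 contact sets over 43 cones, of which 29 cones carry only peripheral
contacts.

```python
>>> from oplconn.scones import worked_example_summary
>>> import json; print(json.dumps(worked_example_summary(), indent=2))
{
  "n_sets": 48,
  "n_candidates": 14,
  "n_strict_S": 6,
  "n_liberal_S": 14,
  "strict_fraction_pct": 4.8,
  "liberal_fraction_pct": 11.3,
  "binomial_p_liberal": 0.0037442797538365887
}
```

Removing the 29 peripheral-only cones leaves 14 candidates with
invaginating CBC9 contacts; the strict rule keeps 6 S-cones — 4.8% of
the 124 cones within reach of a CBC9, matching the 3–5% S-cone share
reported for the mouse retina — while the liberal rule (any
invaginating contact) would claim 11.3%, which the exact binomial test
rejects against a 5% null (p ≈ 0.0037).

CBC5 subtyping on a synthetic population with planted subtypes
(22/22/25 cells):

```python
>>> import oplconn as oc
>>> ds = oc.generate_dataset(oc.OplSimConfig(seed=1),
...                          bc_types=["CBC5T", "CBC5O", "CBC5I"])
>>> res = oc.run_cbc5_typing(ds, seed=1)
>>> sorted(res["labels"].values()).count("5T")
22
```

which recovers the planted subtype of every cell (agreement 1.0 at this
seed; ≥ 0.9 adjusted Rand index across seeds), with the refinement cost
never increasing.

A full pipeline run (simulate → features → classify → S-cones → CBC5 →
connectivity) from the shell:

```bash
oplconn run --out run1 --seed 1
oplconn report --run-dir run1 --out run1/report
```

writes the dataset (SWC skeletons + CSV tables + manifest), per-set
features and predictions, cross-validation reports, S-cone labels,
CBC5 assignments and the connectivity tables with bootstrap CIs.

## Layout

```
src/oplconn/
  geometry.py      data model + contact features
  synthetic.py     ground-truthed OPL generator
  classify.py      per-group RBF-SVM classification
  scones.py        S-cone rules + binomial test + worked example
  cbc5.py          SAC surfaces, depth profiles, PCA/GMM, refinement
  connectivity.py  convergence/divergence, coverage, KDEs, bootstrap
  io.py            SWC + CSV + manifest round-tripping
  pipeline.py      stage orchestration
  cli.py           command-line interface (`oplconn`)
docs/methods.md    models, defaults, design decisions, limitations
```
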