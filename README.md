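# refltriage

Triage of merged diffraction intensities before phasing. The pipeline

1. reads a merged reflection file (MTZ or a plain-text dialect), converting
   amplitudes to intensities when needed and screening for data that have
   already been through a Bayesian posterior-intensity treatment;
2. refines and applies a point-group-constrained anisotropic scale tensor
   (BFGS maximization of a Wilson likelihood, with a restraint at low
   resolution);
3. searches the Patterson map of the normalized intensities for
   translational noncrystallographic symmetry (TNCS), proposing candidate
   orders and translations — the no-TNCS hypothesis is always retained;
4. refines a TNCS expected-intensity-factor model per candidate order
   (translation, effective molecular radius, r.m.s. displacement,
   resolution-dependent scattering fraction and, for order 2, the rotation
   between the related copies, started from five angular states);
5. runs a local-pair L-test for twinning on the fully corrected normalized
   intensities under each TNCS hypothesis;
6. expands the data to every proper subgroup of the point group on branches
   where twinning is indicated (untwinned branches keep the parent
   symmetry);
7. records every decision as a node in a directed acyclic graph of
   hypotheses; each leaf is a phasing-ready corrected dataset written in
   both formats.

A synthetic-data module generates datasets with known anisotropy, TNCS
(order, translation, scatter, scattering fraction), twin fraction and
noise for testing and calibration.

## Command line

```sh
# simulate a pathological preset (tetragonal merge, sevenfold TNCS, twinning)
refltriage simulate 4n3e --out sim/ --seed 5

# or with explicit parameters (JSON)
refltriage simulate '{"laue": "2", "n_atoms": 50, "d_min": 2.5}' --out sim/

# run the triage pipeline
refltriage run sim/simulated.tsv --out triage/ -v

# resume a previous run (reuses nodes whose content-derived ids match)
refltriage run sim/simulated.tsv --out triage/ --resume triage/dag.json

# inspect the hypothesis DAG
refltriage dag show triage/dag.json
refltriage dag show triage/dag.json --dot > dag.dot
```

Key `run` options: `--dmin/--dmax` (resolution window), `--bins`
(normalization bins), `--patterson-threshold`, `--max-tncs-order`,
`--twin-p` (twin verdict threshold), `--threads` (advisory; results are
independent of the degree), `--seed`, `-v/-vv`.

Outputs per run: `dag.json`, `dag.dot`, `run.log`, and per-leaf datasets
`<node-id>.tsv` / `<node-id>.mtz` with provenance recorded in the file
headers.

## Text dialect

```
# cell = 45.0 45.0 77.0 90.0 90.0 90.0
# laue = 422
# columns = H K L I SIGI
1	2	3	140.5	4.2
```

Amplitude columns (`F`/`SIGF`) are accepted and converted with I = F²,
sigI = 2·F·sigF.

## Package layout

| module | contents |
| --- | --- |
| `reflection_data` | unit cell, dataset model, MTZ/text I/O |
| `symmetry` | point groups, epsilon/centricity, subgroup enumeration, expansion |
| `intensity_stats` | binning, mean-intensity curve, second moments, outliers, posterior intensities |
| `anisotropy` | constrained tensor basis, Wilson likelihood, BFGS refinement |
| `tncs` | Patterson search, order inference, expected-intensity factors, refinement |
| `twinning` | L-test pair selection, statistics, reference curves, p-values |
| `dag` | hypothesis DAG, topological sort, shortest path, (de)serialization, DOT |
| `simulate` | structural and distribution-level synthetic data with ground truth |
| `pipeline` / `cli` | orchestration, resume, configuration, command line |
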