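# castates

Mechanistic characterization of single-cell calcium signaling states.

`castates` fits a four-variable, 17-parameter ODE model of ATP-induced
calcium release to single-cell fluorescence traces with likelihood-free
Bayesian inference (ABC-SMC rejection sampling), checks that independent
sampling runs agree via a nearest-neighbor run-identity test, measures
between-cell differences as the KL divergence of posterior particle
ensembles, and clusters cells into functional states with
average-linkage hierarchy and a medoid-based Calinski–Harabasz
criterion. A synthetic-data generator with known ground truth (three
parameter regimes differing in IP3R feedback constants, measurement
noise, and a high-frequency nuisance component) makes the whole pipeline
testable end to end without microscopy data.

## Layout

| module | role |
| --- | --- |
| `castates.model` | ODE right-hand side, rest state, stiff integration; frozen parameter order and reference table |
| `castates.preprocess` | fluorescence→calcium calibration, reflective-boundary zero-phase low-pass filter, noise-floor threshold, trajectory features |
| `castates.fitting` | goodness-of-fit score (value + first-derivative SSE), ABC rejection sampling, sequential Monte Carlo loop |
| `castates.convergence` | dual-run nearest-neighbor chi-square convergence test (exact permutation-null variance) |
| `castates.ensemble_analysis` | pairwise ensemble KL distances, hierarchical clustering, cluster-count selection, cluster characterization |
| `castates.synthetic` | ground-truth population generator (regimes, noise, rendering) |
| `castates.io` / `castates.pipeline` / `castates.cli` | text-format readers/writers, orchestration, `castates` CLI |
| `castates.sbml` | SBML export plus an independent generic SBML integrator (validation path) |

## CLI

```sh
# simulate the reference transient
castates simulate --atp 10 --t-on 60 --duration 660 --dt 2

# generate a 12-cell three-regime synthetic population
castates synth --n-cells 12 --seed 1 --out-prefix scratch/pop

# extract the six trajectory features per cell
castates features scratch/pop_traces.tsv scratch/pop_meta.json

# full pipeline: preprocess, dual ABC-SMC fit, convergence filter,
# KL distances, clustering, characterization, attrition summary
castates run scratch/pop_traces.tsv scratch/pop_meta.json \
    --out-dir scratch/run1 --seed 1 --n-particles 200

# individual stages
castates fit scratch/pop_traces.tsv scratch/pop_meta.json \
    --cell cell0000 --out-dir scratch/fits --seed 1
castates converge scratch/fits/cell0000_run1.csv scratch/fits/cell0000_run2.csv
castates cluster scratch/fits/*_run1.csv
```

Input traces are delimited text (rows = cells, columns = time points)
with a JSON sidecar holding `dt`, `stim_index`, optional `cell_ids` and
per-cell `calibration` triplets `[Kd, Fmin, Fmax]`. All outputs
(ensembles, distance matrix, cluster labels, convergence reports,
attrition summary) are plain CSV/JSON.

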