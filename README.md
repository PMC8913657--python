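# stemfit

Fractional-order equivalent-circuit modeling of plant-tissue impedance
spectra, with metaheuristic parameter extraction.

The package implements five circuit models of bio-impedance — the
single- and double-dispersion Cole models, the fractional-order
double-shell model, and two plant-stem models (a six-branch stem model
and a simplified three-branch variant) — and fits them to impedance
spectra by minimizing the sum of per-frequency complex relative errors
with one of four population metaheuristics (water cycle, flower
pollination, cuckoo search, chicken swarm). A synthetic-spectrum
generator makes every stage testable without measured data.

Every model has **two independent evaluation routes**: the rational
closed-form expression, and a circuit-topology oracle that combines
element impedances/admittances recursively. The two agree to better than
1e-9 relative over the full frequency grid, which is the package's core
self-check.

## Library quick start

```python
import stemfit as sf

# simulate a noisy spectrum from a published cole parameter set
params = sf.get_preset("cole", "marjoram5")
grid = sf.make_grid(100.0, 100_000.0, 80)            # 241 points
noisy = sf.simulate_spectrum("cole", params, grid,
                             sf.NoiseModel(sigma_rel=0.01, seed=7))

# fit it back
config = sf.OptimizerConfig("wca", n_agents=60, n_iterations=300,
                            n_runs=5, seed=1)
fit = sf.fit_model(noisy, "cole", config)
print(fit.params.as_dict(), fit.best_objective, fit.max_error_percent)
```

Model parameters and their search bounds live in `sf.MODEL_SPECS`;
`sf.oracle_impedance(model_id, params, grid)` evaluates the independent
topology route; `sf.compare_models(...)` fits several models to one
spectrum and ranks them by maximum per-frequency error.

## Command line

```sh
# simulate: 241-row CSV with header freq_hz,z_real_ohm,z_imag_ohm
stemfit simulate --model cole --preset marjoram5 \
    --fmin 100 --fmax 100000 --ppd 80 --noise 0.01 --out spec.csv

# fit one model (defaults are the full 60 x 1800 x 100 protocol;
# jobs above 1e9 model evaluations require --yes)
stemfit fit --input spec.csv --model cole --optimizer wca \
    --agents 60 --iters 300 --runs 5 --seed 1 --out-prefix out/cole

# fit all five models and rank them
stemfit compare --input spec.csv --agents 30 --iters 300 --runs 5 \
    --seed 1 --out-prefix out/cmp
```

`fit` writes a `key = value` result document, a per-frequency error-curve
CSV, and one convergence CSV per run. A `--config file` provides defaults
for any flag (same `key = value` format). Exit codes: 0 ok, 1 usage
error, 2 data error.

## Tests and acceptance

```sh
python -m pytest -q                          # full suite, ~1-2 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria (dual-route
oracle equivalence, analytic frequency limits, passivity, objective
identities, cole parameter recovery, optimizer sanity on the 4-D sphere,
a model-ranking echo on synthetic stem spectra, and grid arithmetic).
The acceptance script re-runs the fast criteria from scratch and writes
the (empty — no offline-recomputable published targets exist) report
JSON.
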