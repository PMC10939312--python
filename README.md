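# expsup — forward modeling of expectation suppression

Expectation suppression is the attenuation of visual responses to expected
compared with unexpected stimuli. Two mechanistic accounts make opposite
neural-level predictions: *dampening* holds that neurons tuned **toward** the
expected stimulus are suppressed most (reducing redundancy), *sharpening*
that neurons tuned **away** from it are (sharpening the population code).
Both can produce similar voxel-level fMRI effects, so voxel-level results
alone cannot settle the question.

`expsup` is a forward-modeling toolkit for this inference problem, aimed at
cognitive neuroscientists analyzing trial-wise fMRI pattern data. It

* simulates populations of feature-tuned neurons on 1-D feature spaces
  (circular orientation space with von Mises tuning; linear shape-complexity
  or similarity spaces with Gaussian tuning),
* applies six candidate expectation modulations — {gain, tuning} × {local,
  remote, global}, with suppression magnitude *a*, distance scale *b* and
  tuning width σ:

      gain:    f_i(j) = c(i, j) · g(x_j; μ_i, σ)
      tuning:  f_i(j) = g(x_j; μ_i, c(i, j) · σ)

      c_local  = min(1, a + |d/b| (1 − a))
      c_remote = max(a, 1 − |d/b| (1 − a))
      c_global = a

* enforces three biological-plausibility criteria on every parameterization
  (feature-space coverage, a floor on modulated responses, population
  selectivity),
* forms simulated voxels by limited random sampling of the populations and
  calibrates additive Gaussian noise against a target decoding accuracy,
* computes seven fMRI outcome metrics (mean amplitude modulation; within-
  and between-class correlations; classification performance BC − WC;
  amplitude modulation by amplitude and by selectivity; image-preference
  suppression), and
* identifies the best-fitting neural modulation by sign matching and a
  grand-median-scaled, reliability-weighted MSE over a parameter grid
  (7820 combinations per family by default), with bootstrap CIs and a
  model-recovery control.

It also builds and validates the stimulus feature spaces themselves (Gabor
orientation energy, shape-complexity PCA, 1-D MDS of similarity judgments,
RSA with partial Spearman correlations and Mantel tests).

See `docs/methods.md` for the model conventions, parameter defaults, and
numerical choices.

## Worked example: the model-recovery control

Generate pseudo-empirical data from a known dampening model (local gain,
a = 0.6, b = 0.5, σ = 0.5) for 10 participants × 2 repetitions with
noise calibrated to 50% decoding accuracy, then fit all six model families
on a reduced grid and ask which wins:

```bash
expsup recover --model '{"op_class":"gain","distance":"local","a":0.6,"b":0.5}' \
               --sigma 0.5 --participants 10 --repetitions 2 --seed 7
```

prints

```json
{
  "truth_family": "local gain",
  "truth_params": {"a": 0.6, "b": 0.5, "sigma": 0.5},
  "noise_sd": 35.0,
  "winner": "local gain",
  "recovered": true,
  "winner_params": {"a": 0.6, "b": 0.5, "sigma": 0.5},
  "param_error": {"a": 0.0, "b": 0.0, "sigma": 0.0}
}
```

`noise_sd` is the calibrated Gaussian noise (in units where the maximal
clean voxel response is ≈ 100), `winner` the family with the smallest
weighted MSE, and `winner_params` its best grid point — here the generating
model is recovered exactly, parameters included.

The same machinery is available as a library:

```python
from expsup import ModulationModel, GroundTruthSpec, RunConfig, run_recovery
from expsup.pipeline import desk_grid

truth = GroundTruthSpec(
    model=ModulationModel("gain", "local", a=0.6, b=0.5),
    sigma=0.5, noise_sd=0.0, n_participants=10, n_repetitions=2,
    master_seed=7, n_voxels=300,
)
report = run_recovery(truth, RunConfig(grid=desk_grid(), n_participants=10,
                                       n_repetitions=2, master_seed=7))
print(report["winner"], report["recovered"])
```

Other CLI subcommands: `expsup report` (plausibility rejection rates per
family over the full grid), `expsup simulate` (write ground-truth datasets
as CSV), `expsup metrics` (the seven outcome metrics for one dataset),
`expsup fit` (fit the families to an empirical slope summary),
`expsup featurespace` (model RDMs from stimulus positions).

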