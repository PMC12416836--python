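# Plug-in single-cell model contract

The population engine is model-agnostic.  Any single-cell model can drive a
lineage-resolved simulation as long as it satisfies the contract below; the
built-in minimal cycle model is simply one registered implementation.

## What a model must provide

A model is a pair of callables (a *loader* and a *runner*), registered under
a name or referenced in a config as `"package.module:function"` strings.

### Loader

```python
loader(params) -> (ModelSpecs, kwargs_default)
```

* `ModelSpecs` declares:
  * `species_all` — ordered, unique species names; column order of every
    state vector and trajectory matrix,
  * `cc_marker` — name of the division-marker species.  Peaks of this
    species' trajectory are the division events,
  * `death_marker` — name of the cleaved death-marker species, or `None`
    (a model without one cannot die),
  * `progress_markers` — ordered names of at least one cycle-marker species
    used for fractional cycle-progress estimation.
* `kwargs_default` — keyword arguments forwarded verbatim to the runner
  (step sizes, model parameters, ...).

### Runner

```python
runner(state, duration_h, rng, **kwargs_default) -> Trajectory
```

* `state` — 1-D array in `species_all` order (the cell's birth state),
* `duration_h` — remaining simulation time in hours (> 0),
* `rng` — a `numpy.random.Generator`; all of the model's randomness must
  flow from it so that runs are reproducible,
* returns a `Trajectory` whose `times` start at 0 (birth-relative), sampled
  on a uniform grid, with `states` of shape `(len(times), len(species_all))`.

A runner may additionally provide a vectorized form

```python
runner_batch(states, durations_h, rng, **kwargs_default) -> list[Trajectory]
```

over `(n_cells, n_species)` state blocks; the engine prefers it when present
(this is what makes hundreds of cells per generation cheap) and otherwise
loops the per-cell runner with per-cell derived random streams.

## Registration

```python
from lineagesim.registry import register_model
register_model("my_model", loader, runner, runner_batch=None)
```

or in a simulation config:

```json
{"model": {"load_model": "my_pkg.my_model:load", "run_model": "my_pkg.my_model:run"}}
```

## What the engine does with it

1. Calls the loader once, validates the specs before any simulation.
2. Runs every living cell of a generation for its remaining time.
3. Detects the first `cc_marker` peak (division) and the first
   `death_marker` crossing of the death threshold (death); the earlier
   event wins, a tie counts as death.
4. On division, hands the state at the division time to both daughters
   (symmetric by default; a `divider` hook may transform the pair, e.g.
   binomial partitioning of molecule counts).
5. Repeats until a generation produces no divisions.
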