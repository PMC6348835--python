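# Configuration files

Both CLI commands that accept `--config` read YAML or JSON with the fields
below; command-line flags override nothing in the file (they are separate
options).

## `emaord simulate --config design.yaml`

Mirrors `emaord.simulate.CohortDesign` plus the generative family:

```yaml
n_patients: 130          # J >= 1; default 130
obs_per_patient: 18      # int, per-patient list, or omit for the
                         # reference split (116 x 18 + 14 x 17 = 2326)
n_categories: 10         # C >= 2
family: heterogeneous_cumulative   # or any of the four model names,
                                   # or "cumulative"/"stereotype"
slope_means: [0.4, -0.3, 0.2, 0.3, 0.2]   # population slopes, item order:
                                          # mood, worry, sleep,
                                          # enjoyed_activities, social_contact
heterogeneity_sd: 1.0    # per-slope between-patient SD (0 = homogeneous)
predictor_marginals:     # optional per-item score distributions over 1..C
  mood: [0.0, 0.0, 0.1, 0.1, 0.2, 0.2, 0.2, 0.1, 0.05, 0.05]
```

The `--seed` flag controls all randomness; the design file carries no seed
of its own.

## Sampler and prior settings

`MCMCConfig` and `PriorConfig` are constructed field-for-field from the
same names used in the API:

| field | default | meaning |
| --- | --- | --- |
| `chains` | 4 | independent HMC chains |
| `total_iterations` | 60000 | iterations per chain |
| `post_warmup_iterations` | 30000 | iterations kept before thinning |
| `thin` | 20 | store every k-th post-warmup draw |
| `seed` | 0 | master seed (per-chain seeds are spawned from it) |
| `desk_profile` | false | switch to the reduced 4 x 2000 preset |
| `max_leapfrog` | 32 | upper bound of the jittered leapfrog count |
| `target_accept` | 0.8 | dual-averaging acceptance target |
| `slope_prior_means` | (1, -1, 1, 1, 1) | prior means of delta |
| `prior_variance` | 100 | sigma^2 of all normal priors |
| `dirichlet_concentration` | 1 | symmetric Dirichlet A for gamma |

On the command line, `--desk-profile` selects the reduced preset and
`--seed` sets the master seed; `emaord evaluate` additionally takes
`--models` (comma-separated subset of `homogeneous_cumulative`,
`heterogeneous_cumulative`, `homogeneous_stereotype`,
`heterogeneous_stereotype`), `--folds`, and `--select-by`
(waic | dic | rmse | mae).
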