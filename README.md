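# coopnorms

Dynamics of conditional-cooperation norms coupled to community membership.

The package implements two linked models:

1. **Threshold dynamic** (`coopnorms.threshold`) — norm sensitivities are
   normally distributed on the probability scale with CDF `F`; the
   cooperation frequency follows `dp/dt = F(p) - p`. Depending on the
   mean and variance this is bistable (*coordination* regime: stable low
   and high cooperation) or monostable (*cooperation* regime: a single
   low-cooperation state). The module finds all fixed points, classifies
   the regime, computes the naive belief (the high-cooperation fixed
   point of a bistable reference distribution) and the critical variance
   at which bistability is lost.

2. **Community model** (`coopnorms.community`, `coopnorms.equilibria`,
   `coopnorms.bifurcation`) — a fixed population splits into susceptible
   outsiders `S`, insiders `I` and discouraged outsiders `D`. Insiders
   are naive (believing the advertised cooperation level `p_tilde`) or
   savvy (fraction `y`, cooperating at frequency `p`); the gap between
   belief and reality drives learning and disillusioned leaving:

   ```
   dS/dt = phi*D - iota*S*I/K
   dI/dt = iota*S*I/K - omega*gap*y*I
   dy/dt = lam*gap*(1-y) - omega*gap*y*(1-y) - (iota*S/K)*y
   dp/dt = F(p_bar) - p        with p_bar = y*p + (1-y)*F(p_tilde),
                                    gap   = p_tilde - p_bar
   ```

   The toolkit provides closed-form mixed equilibria (savvy fraction
   `y* = lam/(lam+omega)`, reproduction ratio
   `R = iota/(omega*gap*y*)`, population split `S* = K/R`, ...), numerical
   Jacobian stability, crash/invasion analysis at the empty-community
   boundary, parameter scans with fold refinement, regime diagrams over
   the threshold variance, and limit-cycle / bursting classification of
   long-run trajectories. A raw five-compartment formulation is included
   as an independent oracle for the reduced four-variable system.

## CLI

The `coopnorms` entry point reads a TOML config and writes CSV/JSON
artifacts (floats at 17 significant digits; runs are deterministic given
the config and, for random initial conditions, the seed):

```sh
coopnorms simulate   --config run.toml --out-dir out   # trajectory.csv
coopnorms equilibria --config run.toml --out-dir out   # equilibria.json
coopnorms scan       --config run.toml --out-dir out   # scan.csv + folds.json
coopnorms regime     --config run.toml --out-dir out   # regime.json
coopnorms cycles     --config run.toml --out-dir out   # cycles.json
```

A minimal config:

```toml
command = "equilibria"

[model]
mu = 0.7        # threshold-distribution mean
sigma2 = 0.04   # threshold-distribution variance
p_tilde = "auto"  # naive belief; "auto" = high root of the reference map

[rates]
inflow = 1.0
learning = 1.0
outflow = 0.5
phi = 1.0       # resusceptibility of discouraged outsiders
```

Unset keys fall back to logged defaults; the CLI subcommand overrides the
config's `command` key.

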