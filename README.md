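# episwitch

Stochastic modelling of a self-regulating transcription factor under
bivalent chromatin (H3K4me3/H3K27me3) regulation, for computational
biologists studying epigenetically driven cell-state heterogeneity and for
in-silico screening of epigenetic-drug combinations.

Bivalent ("poised") promoters carry both an activating mark (H3K4me3,
written by MLL2, erased by KDM5) and a repressive one (H3K27me3, written by
EZH2, erased by UTX/KDM6). `episwitch` implements a reduced three-variable
model of a monomeric TF coupled to these marks,

    dx/dtau        = B_x(x, q_A, q_I) - D_x(x, q_A, q_I)
    eps2 dq_A/dtau = B_A(x, q_A) - D_A(x, q_A)
    eps2 dq_I/dtau = B_I(x, q_I) - D_I(x, q_I)

together with the finite-size (WKB) stationary law of the slow variable,

    phi_x(x) ∝ exp(-Omega_T U(x, Omega_T)),
    U = -S + [log<B_x> + log<D_x>]/(2 Omega_T),  S = ∫_0^x log(<B_x>/<D_x>) ds.

On top of this core the package provides:

* quasi-steady-state mark curves, the TF response curve
  `R(x) = rho (1 + C1 h(x))` and its effective Hill cooperativity;
* exact (Gillespie) stochastic simulation of the reduced master equation,
  with histogram/bimodality analysis and system-size scans;
* deterministic slow–fast integration, equilibrium surfaces over parameter
  planes and Monte-Carlo basin-of-attraction estimates (`P_off`);
* parameter ensembles: uniform-prior sampling, a mark-monostability
  acceptance filter, landscape-topography classification into
  low/high-expression, bistable and noise-induced-bistable sub-ensembles,
  with per-parameter-set summaries (barriers, mark averages,
  enzyme-activity proxies, methylation status);
* perturbation ("therapy") screens: multiplicative dose protocols on the
  enzyme kinetics, re-classification of the bistable sub-ensemble, and the
  KS / correlation statistics used to choose targets.

See `docs/methods.md` for the model, the numerical choices and the shipped
(synthetic, non-canonical) calibration.

## Worked example

```python
import numpy as np
from episwitch import reference_params, compute_landscape
from episwitch.model import effective_hill
from episwitch.ssa import SSAConfig, gillespie_run
from episwitch.meanfield import estimate_Poff

p = reference_params("BISTABLE")          # frozen bistable exemplar
L = compute_landscape(p)                  # QSS -> S, U, phi_x -> label
print("label:", L.class_label)
print("equilibria (S' roots):", np.round(L.roots_Sprime, 4))
print("phi_x modes:", np.round(L.modes, 4))
print("barriers dU0=%.4f dU1=%.4f" % (L.dU0, L.dU1))
print("n_eff=%.2f" % effective_hill(p, L.qss).n_eff)

traj = gillespie_run(p, SSAConfig(t_max=20000.0, seed=7, burn_in=1000.0,
                                  record_stride=0.1))
x = traj.x[traj.times >= 1000.0]
print("time below the saddle: %.3f" % (x < L.roots_Sprime[1]).mean())

est = estimate_Poff(p, n_samples=500, seed=3)
print("P_off = %.3f +/- %.3f" % (est.P_off, est.ci_halfwidth))
```

prints

```
label: BISTABLE
equilibria (S' roots): [0.1953 0.331  0.6442]
phi_x modes: [0.1773 0.6319]
barriers dU0=0.0061 dU1=0.0076
n_eff=2.50
time below the saddle: 0.625
P_off = 0.424 +/- 0.043
```

The parameter set is bistable: the deterministic system has stable
equilibria at TF concentrations 0.195 and 0.644 separated by a saddle at
0.331, and the stationary density `phi_x` is bimodal with shallow barriers
(`Omega_T dU ~ 1`, so a simulated cell flips between the low- and
high-expression states, spending ~62% of its time below the saddle). The
effective cooperativity `n_eff = 2.5 > 1` is entirely feedback-generated
(the TF itself is monomeric), and a random initial condition ends in the
OFF state with probability `P_off ~ 0.42`.

A command-line surface mirrors the library
(`episwitch landscape|simulate|basins|ensemble|therapy`, YAML configs, CSV
/ JSON outputs with a reproducibility manifest), e.g.

```bash
episwitch ensemble --config config.yaml --n-accepted 500 --out ens/
episwitch therapy  --config config.yaml --ensemble ens/ --out screen/
```

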