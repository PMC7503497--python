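# evbkit

A desk-scale, two-state empirical valence bond (EVB) free-energy pipeline:

* **Core energetics** — two diabatic force fields (Morse bonds that swap
  between the states, harmonic terms, Buckingham nonbonded terms, Coulomb,
  positional tethers) coupled by a constant off-diagonal element `h_ij`;
  the adiabatic ground state is the lower eigenvalue of the 2×2 EVB
  Hamiltonian.  Convention: the mapping potential is
  `e_m = λ·e1 + (1−λ)·e2`, so **λ = 1 is the pure reactant state** and
  λ = 0 the pure product state.
* **Synthetic systems** — a donor/hydride/acceptor triad coupled to a
  harmonic bath whose per-oscillator tether displacements realize a
  requested reorganization energy exactly, plus a 1-D harmonic surrogate
  (Marcus limit) with closed forms for every quantity the estimator
  produces.
* **Sampling** — BAOAB Langevin dynamics on each mapping potential;
  the default protocol equilibrates at λ = 0.5 and walks both branches
  outward over 51 windows in independent replicas.  The force kernel is
  numba-jitted when numba is available and falls back to pure Python with
  bitwise-identical results (noise is pre-drawn from numpy PCG64 streams).
* **FEP/US estimator** — Zwanzig exponential averaging between adjacent
  windows (forward and reverse retained; hysteresis reported), umbrella
  binning on the energy-gap coordinate `X = e1 − e2`, reweighting onto the
  ground state, and barrier extraction with between-replica standard
  errors.
* **Calibration** — damped alternating secant fit of `(h_ij, α)` (the
  product-state shift) to reference activation and reaction free
  energies, with common-random-number sub-seeds; fitted parameters can be
  transferred to perturbed "environment" variants.
* **TST arithmetic** — Eyring rate/barrier conversions, ΔΔG from rate
  pairs, catalytic orders of magnitude; bundled reference energetics and
  measured inactivation rate constants for the two reference inhibitors.

## CLI

```sh
evbkit simulate  --config run.toml --out out/       # window TSVs + manifest
evbkit profile   --windows out/windows --h-ij 20 --out prof/
evbkit calibrate --config run.toml --target rasagiline --out cal.json
evbkit rates     --k1 0.99/min --k2 0.0533/min
evbkit fixtures  --out fixtures/                    # deterministic test data
```

Config files are TOML (JSON accepted).  A minimal example:

```toml
seed = 1

[toy]                      # omit and set system_path = "..." to load a
reorganization = 40.0      # serialized system instead

[schedule]
windows = 51
n_steps = 10000            # 10 ps per window at dt = 1 fs
replicas = 3
```

Exit codes: 0 success, 2 validation error, 3 numerical failure, 4 I/O.
Every command is a pure function of (config, seed): repeated runs are
byte-identical.

## File formats

* window energies: `win_<λindex>_rep<k>.tsv` — columns
  `frame  lambda  eps1_kcal  eps2_kcal`, `#`-prefixed metadata header;
* profile: TSV with `X_center_kcal  dG_kcal  n_samples  se_kcal`;
* systems, manifests, calibration results: JSON.

Units throughout: kcal/mol, Å, amu, fs, K; R = 1.987204×10⁻³ kcal/(mol·K).
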