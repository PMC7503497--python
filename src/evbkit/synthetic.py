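"""Synthetic reacting systems and analytically tractable surrogates.

Two generators are provided:

* :func:`build_toy_system` — a desk-scale donor/hydride/acceptor triad
  (Morse bonds that swap between the states, Buckingham nonbonded terms on
  the reacting atoms, a flat-bottom donor–acceptor restraint) coupled to a
  harmonic bath whose per-oscillator tether centers differ between the two
  states so as to realize a requested reorganization energy exactly.

* :class:`HarmonicSurrogate` — two 1-D parabolic diabats with shared
  curvature, for which every quantity of the free-energy machinery has a
  closed form (Marcus limit); window ensembles are drawn from the exact
  Gaussian stationary distribution, with no integrator error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import R_KCAL
from .core import DiabaticState, EVBSystem, Particle
from .errors import IOFailure, ValidationError
from .sampling import WindowSample, _lam_key, _window_seed

#: Seed under which the bundled test fixtures are regenerated.
FIXTURE_SEED = 20200826


# ------------------------------------------------------------------ toy

@dataclass
class ToySpec:
    """Parameters of the synthetic reacting system.

    ``reorganization`` is the target bath reorganization energy (kcal/mol),
    realized exactly as sum(1/2 * k_bath * d_i^2) over oscillator tether
    displacements.  ``alpha`` is the calibratable product-state shift and
    ``h_ij`` the constant coupling.
    """

    ch_morse: tuple = (100.0, 2.0, 1.09)  # (D, b, r0) donor-H bond, state 1
    nh_morse: tuple = (105.0, 2.2, 1.01)  # acceptor-H bond, state 2
    da_restraint: tuple = (5.0, 3.0)  # flat-bottom (k, onset) on donor-acceptor
    position_restraint_k: float = 0.5  # shared tether on donor & acceptor
    buck_hn: tuple = (2000.0, 3.5, 20.0)  # H..N in state 1
    buck_ch: tuple = (2500.0, 3.5, 20.0)  # C..H in state 2
    buck_cn: tuple = (30000.0, 3.8, 150.0)  # C..N in both states
    product_charges: tuple = (0.3, 0.0, -0.3)  # (C, H, N) in state 2
    reactant_charges: tuple = (0.0, 0.0, 0.0)
    donor_acceptor_distance: float = 2.9  # Å, initial geometry
    n_bath: int = 10
    k_bath: float = 2.0  # kcal/mol/Å^2
    bath_mass: float = 2.0  # amu (light effective solvent mode)
    reorganization: float = 40.0  # kcal/mol
    alpha: float = 0.0
    h_ij: float = 0.0
    temperature_default: float = 300.0
    seed: int = FIXTURE_SEED

    def __post_init__(self):
        if self.n_bath < 1:
            raise ValidationError(f"n_bath must be >= 1, got {self.n_bath}")
        if not self.k_bath > 0:
            raise ValidationError(f"k_bath must be > 0, got {self.k_bath}")
        if self.reorganization < 0:
            raise ValidationError(
                f"reorganization energy must be >= 0, got "
                f"{self.reorganization}")

    def bath_displacements(self) -> np.ndarray:
        """Per-oscillator tether displacement vectors between the states,
        scaled so the realized reorganization energy matches exactly."""
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(self.seed)))
        vecs = rng.normal(size=(self.n_bath, 3))
        mags = 0.5 + rng.random(self.n_bath)  # uneven but bounded
        vecs = vecs / np.linalg.norm(vecs, axis=1)[:, None] * mags[:, None]
        ssq = 0.5 * self.k_bath * float(np.sum(vecs * vecs))
        if ssq == 0.0:
            raise ValidationError("degenerate bath displacement draw")
        return vecs * math.sqrt(self.reorganization / ssq)


def realized_reorganization(spec: ToySpec) -> float:
    d = spec.bath_displacements()
    return 0.5 * spec.k_bath * float(np.sum(d * d))


def build_toy_system(spec: ToySpec) -> EVBSystem:
    """Assemble the triad + bath EVBSystem from a ToySpec.

    State 1 bonds donor-H (C–H), state 2 bonds H-acceptor (N–H); bath
    tether centers are displaced between the states to realize the
    requested reorganization energy.  Deterministic for a fixed spec.
    """
    C, H, N = 0, 1, 2
    n = 3 + spec.n_bath
    particles = [
        Particle("C", 12.011, "donor-C"),
        Particle("H", 1.008, "hydride-H"),
        Particle("N", 14.007, "acceptor-N"),
    ] + [Particle(f"B{i}", spec.bath_mass, "bath") for i in range(spec.n_bath)]

    r_da = spec.donor_acceptor_distance
    coords = np.zeros((n, 3))
    coords[H] = (spec.ch_morse[2], 0.0, 0.0)
    coords[N] = (r_da, 0.0, 0.0)
    base = np.zeros((spec.n_bath, 3))
    base[:, 1] = 5.0 + 2.0 * np.arange(spec.n_bath)
    disp = spec.bath_displacements()
    coords[3:] = base

    def charges(triad):
        q = np.zeros(n)
        q[:3] = triad
        return q if np.any(q) else None

    state1 = DiabaticState(
        morse_terms=[(C, H, *spec.ch_morse)],
        buckingham_terms=[(H, N, *spec.buck_hn), (C, N, *spec.buck_cn)],
        charges=charges(spec.reactant_charges),
        shift=0.0,
        tethers=[(3 + i, spec.k_bath, *base[i]) for i in range(spec.n_bath)],
    )
    state2 = DiabaticState(
        morse_terms=[(H, N, *spec.nh_morse)],
        buckingham_terms=[(C, H, *spec.buck_ch), (C, N, *spec.buck_cn)],
        charges=charges(spec.product_charges),
        shift=float(spec.alpha),
        tethers=[(3 + i, spec.k_bath, *(base[i] + disp[i]))
                 for i in range(spec.n_bath)],
    )
    k_da, onset = spec.da_restraint
    # weak positional restraints on the whole reacting region (H tethered
    # at the midpoint of its two bonded positions): keeps the hydride from
    # escaping to infinity after a violent window start while biasing
    # either bonded state by well under 0.1 kcal/mol
    h_anchor = 0.5 * (np.array([spec.ch_morse[2], 0.0, 0.0])
                      + np.array([r_da - spec.nh_morse[2], 0.0, 0.0]))
    return EVBSystem(
        state1=state1,
        state2=state2,
        h_ij=float(spec.h_ij),
        particles=particles,
        temperature_default=spec.temperature_default,
        restraint_bonds=[(C, N, k_da, onset)],
        restraint_tethers=[
            (C, spec.position_restraint_k, *coords[C]),
            (N, spec.position_restraint_k, *coords[N]),
            (H, spec.position_restraint_k, *h_anchor),
        ],
        initial_coords=coords,
    )


# ------------------------------------------------------------- surrogate

@dataclass
class HarmonicSurrogate:
    """Two parabolic diabats with shared curvature on a single coordinate.

    e1(x) = k/2 x^2,  e2(x) = k/2 (x-d)^2 + dg0.  The implied
    reorganization energy is k/2 d^2 and, at h_ij = 0, the diabatic
    crossing height is (reorganization + dg0)^2 / (4 * reorganization).
    """

    k: float = 2.0  # kcal/mol per unit^2
    d: float = math.sqrt(40.0)  # minima separation
    dg0: float = 0.0  # product minus reactant free energy, kcal/mol
    h_ij: float = 0.0

    def __post_init__(self):
        if not (self.k > 0 and self.d > 0):
            raise ValidationError("surrogate requires k > 0 and d > 0")
        if self.h_ij < 0:
            raise ValidationError(f"h_ij must be >= 0, got {self.h_ij}")

    @classmethod
    def from_reorganization(cls, reorganization: float, dg0: float = 0.0,
                            h_ij: float = 0.0, k: float = 2.0):
        if not reorganization > 0:
            raise ValidationError(
                f"reorganization must be > 0, got {reorganization}")
        return cls(k=k, d=math.sqrt(2.0 * reorganization / k),
                   dg0=dg0, h_ij=h_ij)

    @property
    def reorganization(self) -> float:
        return 0.5 * self.k * self.d * self.d

    def diabats(self, x):
        x = np.asarray(x, dtype=float)
        e1 = 0.5 * self.k * x * x
        e2 = 0.5 * self.k * (x - self.d) ** 2 + self.dg0
        return e1, e2

    def gap(self, x):
        e1, e2 = self.diabats(x)
        return e1 - e2

    def marcus_barrier(self) -> float:
        """Diabatic crossing height (Lambda + dg0)^2 / (4 Lambda)."""
        lam = self.reorganization
        return (lam + self.dg0) ** 2 / (4.0 * lam)

    def crossing_x(self) -> float:
        # e1(x) = e2(x)
        return (self.reorganization + self.dg0) / (self.k * self.d)

    def window_mean(self, lam: float) -> float:
        """Minimum of the mapping potential e_m = lam*e1 + (1-lam)*e2."""
        return (1.0 - lam) * self.d

    def window_gap_variance(self, temperature: float) -> float:
        """Closed-form variance of the gap X under any mapping window:
        (k d)^2 * RT / k = 2 * reorganization * RT."""
        return 2.0 * self.reorganization * R_KCAL * temperature

    def exact_mapping_free_energy(self, lam) -> np.ndarray:
        """Exact dG(lambda) relative to the reactant window (lam = 1):
        Lambda*lam*(1-lam) + (1-lam)*dg0 (curvature terms cancel)."""
        lam = np.asarray(lam, dtype=float)
        out = self.reorganization * lam * (1.0 - lam) + (1.0 - lam) * self.dg0
        return float(out) if out.ndim == 0 else out


def surrogate_window_samples(s: HarmonicSurrogate, lambdas, n_per_window: int,
                             temperature: float, seed: int = 0,
                             replicas: int = 1):
    """Draw exact Gaussian window ensembles on each mapping potential.

    For every lambda the coordinate is sampled from the exact stationary
    distribution N(window_mean, RT/k) of e_m — no integrator error — and
    per-frame (e1, e2) are evaluated from the drawn coordinate.
    """
    if n_per_window < 1:
        raise ValidationError("n_per_window must be >= 1")
    if not temperature > 0:
        raise ValidationError(f"temperature must be > 0, got {temperature}")
    sigma = math.sqrt(R_KCAL * temperature / s.k)
    out = []
    for rep in range(replicas):
        for lam in lambdas:
            lam = float(lam)
            if not 0.0 <= lam <= 1.0:
                raise ValidationError(f"lambda {lam} outside [0, 1]")
            rng = np.random.Generator(np.random.PCG64(
                _window_seed(seed, rep, _lam_key(lam))))
            x = rng.normal(s.window_mean(lam), sigma, size=n_per_window)
            e1, e2 = s.diabats(x)
            out.append(WindowSample(
                lam=lam, eps1=e1, eps2=e2, n_equil=0,
                temperature=temperature, dt=0.0, seed=int(seed), replica=rep))
    return out


# ------------------------------------------------------------- window I/O

_TSV_HEADER = "frame\tlambda\teps1_kcal\teps2_kcal"


def write_window_tsv(sample: WindowSample, path) -> None:
    """Write one window's energies in the tab-separated dialect."""
    path = Path(path)
    lines = [
        f"# temperature_k={sample.temperature!r}",
        f"# dt_fs={sample.dt!r}",
        f"# seed={sample.seed}",
        f"# replica={sample.replica}",
        f"# n_equil={sample.n_equil}",
        _TSV_HEADER,
    ]
    for i, (e1, e2) in enumerate(zip(sample.eps1, sample.eps2)):
        lines.append(f"{i}\t{sample.lam:.10g}\t{e1:.12g}\t{e2:.12g}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as err:
        raise IOFailure(f"cannot write window file {path}: {err}") from err


def read_window_tsv(path) -> WindowSample:
    """Read a window-energy file; raises IOFailure with file/line context
    on malformed rows."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as err:
        raise IOFailure(f"cannot read window file {path}: {err}") from err
    meta = {"temperature_k": 300.0, "dt_fs": 0.0, "seed": -1,
            "replica": 0, "n_equil": 0}
    lam = None
    e1s, e2s = [], []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = float(val) if "." in val or "e" in val \
                    else int(val)
            continue
        if not header_seen:
            if line != _TSV_HEADER:
                raise IOFailure(
                    f"{path}:{lineno}: expected header {_TSV_HEADER!r}, "
                    f"got {line!r}")
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise IOFailure(
                f"{path}:{lineno}: expected 4 tab-separated fields, "
                f"got {len(parts)}")
        try:
            row_lam = float(parts[1])
            e1s.append(float(parts[2]))
            e2s.append(float(parts[3]))
        except ValueError as err:
            raise IOFailure(f"{path}:{lineno}: {err}") from err
        if lam is None:
            lam = row_lam
        elif row_lam != lam:
            raise IOFailure(
                f"{path}:{lineno}: inconsistent lambda {row_lam} != {lam}")
    if not header_seen or not e1s:
        raise IOFailure(f"{path}: no data rows found")
    return WindowSample(
        lam=lam, eps1=np.array(e1s), eps2=np.array(e2s),
        n_equil=int(meta["n_equil"]), temperature=float(meta["temperature_k"]),
        dt=float(meta["dt_fs"]), seed=int(meta["seed"]),
        replica=int(meta["replica"]))


def window_filename(lam_index: int, replica: int) -> str:
    return f"win_{lam_index:03d}_rep{replica}.tsv"


def write_fixture(obj, path) -> list:
    """Write a system config (JSON) or window ensembles (TSV directory).

    For a list of WindowSample, one file per (lambda, replica) named
    ``win_<lambda index>_rep<k>.tsv`` is emitted under ``path``; the list
    of written paths is returned.  An empty sample list is an error.
    """
    path = Path(path)
    if isinstance(obj, EVBSystem):
        try:
            path.parent.mkdir(parents=True, exist_ok=True)
            obj.save(path)
        except OSError as err:
            raise IOFailure(f"cannot write system file {path}: {err}") from err
        return [path]
    samples = list(obj)
    if not samples:
        raise ValidationError("refusing to write an empty fixture")
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise IOFailure(f"cannot create directory {path}: {err}") from err
    lams = sorted({s.lam for s in samples})
    written = []
    for s in samples:
        fname = path / window_filename(lams.index(s.lam), s.replica)
        write_window_tsv(s, fname)
        written.append(fname)
    return written


def read_windows(directory) -> list:
    """Read every win_*.tsv under a directory."""
    directory = Path(directory)
    files = sorted(directory.glob("win_*.tsv"))
    if not files:
        raise IOFailure(f"no window files (win_*.tsv) found in {directory}")
    return [read_window_tsv(f) for f in files]
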