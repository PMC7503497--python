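"""Thermal sampling on mapping potentials via Langevin dynamics.

Windows are propagated with a BAOAB splitting on the mapping surface
e_m = lam*e1 + (1-lam)*e2.  The per-step kernel is numba-jitted when numba
is importable and falls back to pure Python otherwise (identical numerics:
all random numbers are pre-drawn with numpy Generators outside the
kernel).

Default protocol mirrors the reference procedure at desk scale: 51 mapping
steps, bidirectional walk started from an equilibration at lam = 0.5,
independent replicas; window length and replica count are scaled down and
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ACC_FROM_FORCE, COULOMB_KCAL, MV2_TO_KCAL, R_KCAL
from .core import EVBSystem
from .errors import IntegrationInstabilityError, ValidationError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


ENERGY_DIVERGENCE_LIMIT = 1.0e6  # kcal/mol


# ------------------------------------------------------------- packing

def pack_state(state, shared_bonds, shared_tethers, n_particles):
    """Flatten one diabatic state (+ shared restraints) into a tuple of
    arrays consumed by the force kernel."""
    morse = np.array(state.morse_terms, dtype=float).reshape(-1, 5)
    hb = [t for t in state.harmonic_terms if len(t) == 4]
    ang = [t for t in state.harmonic_terms if len(t) == 5]
    hb = np.array(hb, dtype=float).reshape(-1, 4)
    ang = np.array(ang, dtype=float).reshape(-1, 5)
    bk = np.array(state.buckingham_terms, dtype=float).reshape(-1, 5)

    cl_i, cl_j, cl_qq = [], [], []
    if state.charges is not None:
        q = np.asarray(state.charges, dtype=float)
        nz = np.nonzero(q)[0]
        for a in range(len(nz)):
            for b in range(a + 1, len(nz)):
                cl_i.append(nz[a])
                cl_j.append(nz[b])
                cl_qq.append(COULOMB_KCAL * q[nz[a]] * q[nz[b]])

    te = list(state.tethers) + list(shared_tethers)
    te = np.array(te, dtype=float).reshape(-1, 5)
    fb = np.array(list(shared_bonds), dtype=float).reshape(-1, 4)

    return (
        morse[:, 0].astype(np.int64), morse[:, 1].astype(np.int64),
        morse[:, 2].copy(), morse[:, 3].copy(), morse[:, 4].copy(),
        hb[:, 0].astype(np.int64), hb[:, 1].astype(np.int64),
        hb[:, 2].copy(), hb[:, 3].copy(),
        ang[:, 0].astype(np.int64), ang[:, 1].astype(np.int64),
        ang[:, 2].astype(np.int64), ang[:, 3].copy(), ang[:, 4].copy(),
        bk[:, 0].astype(np.int64), bk[:, 1].astype(np.int64),
        bk[:, 2].copy(), bk[:, 3].copy(), bk[:, 4].copy(),
        np.array(cl_i, dtype=np.int64), np.array(cl_j, dtype=np.int64),
        np.array(cl_qq, dtype=float),
        te[:, 0].astype(np.int64), te[:, 1].copy(), te[:, 2:5].copy(),
        fb[:, 0].astype(np.int64), fb[:, 1].astype(np.int64),
        fb[:, 2].copy(), fb[:, 3].copy(),
        float(state.shift),
    )


def pack_system(system: EVBSystem):
    n = system.n_particles
    p1 = pack_state(system.state1, system.restraint_bonds,
                    system.restraint_tethers, n)
    p2 = pack_state(system.state2, system.restraint_bonds,
                    system.restraint_tethers, n)
    return p1, p2


# ------------------------------------------------------------- kernel

@njit(cache=True)
def _energy_forces(x, p, f):
    """Energy and forces for one packed state; f is overwritten."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = p[29]
    # Morse bonds: D*(1-exp(-b*(r-r0)))^2 - D
    for t in range(p[0].shape[0]):
        i = p[0][t]; j = p[1][t]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        ex = math.exp(-p[3][t] * (r - p[4][t]))
        om = 1.0 - ex
        e += p[2][t] * om * om - p[2][t]
        dedr = 2.0 * p[2][t] * p[3][t] * ex * om
        g = -dedr / r
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    # harmonic bonds: 0.5*k*(r-r0)^2
    for t in range(p[5].shape[0]):
        i = p[5][t]; j = p[6][t]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - p[8][t]
        e += 0.5 * p[7][t] * dr * dr
        g = -p[7][t] * dr / r
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    # harmonic angles: 0.5*k*(theta-theta0)^2, vertex p[10]
    for t in range(p[9].shape[0]):
        i = p[9][t]; j = p[10][t]; kc = p[11][t]
        ax = x[i, 0] - x[j, 0]; ay = x[i, 1] - x[j, 1]; az = x[i, 2] - x[j, 2]
        bx = x[kc, 0] - x[j, 0]; by = x[kc, 1] - x[j, 1]; bz = x[kc, 2] - x[j, 2]
        ra = math.sqrt(ax * ax + ay * ay + az * az)
        rb = math.sqrt(bx * bx + by * by + bz * bz)
        cosv = (ax * bx + ay * by + az * bz) / (ra * rb)
        if cosv > 1.0:
            cosv = 1.0
        if cosv < -1.0:
            cosv = -1.0
        th = math.acos(cosv)
        dth = th - p[13][t]
        e += 0.5 * p[12][t] * dth * dth
        sinv = math.sqrt(max(1.0 - cosv * cosv, 1.0e-12))
        coef = p[12][t] * dth / sinv
        fix = coef * (cosv * ax / ra - bx / rb) / ra
        fiy = coef * (cosv * ay / ra - by / rb) / ra
        fiz = coef * (cosv * az / ra - bz / rb) / ra
        fkx = coef * (cosv * bx / rb - ax / ra) / rb
        fky = coef * (cosv * by / rb - ay / ra) / rb
        fkz = coef * (cosv * bz / rb - az / ra) / rb
        f[i, 0] += fix; f[i, 1] += fiy; f[i, 2] += fiz
        f[kc, 0] += fkx; f[kc, 1] += fky; f[kc, 2] += fkz
        f[j, 0] -= fix + fkx; f[j, 1] -= fiy + fky; f[j, 2] -= fiz + fkz
    # Buckingham: A*exp(-B*r) - C/r^6
    for t in range(p[14].shape[0]):
        i = p[14][t]; j = p[15][t]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        ea = p[16][t] * math.exp(-p[17][t] * r)
        r6 = r ** 6
        e += ea - p[18][t] / r6
        dedr = -p[17][t] * ea + 6.0 * p[18][t] / (r6 * r)
        g = -dedr / r
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    # Coulomb: qq/r (prefactor folded into qq)
    for t in range(p[19].shape[0]):
        i = p[19][t]; j = p[20][t]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += p[21][t] / r
        g = p[21][t] / (r * r * r)
        f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
        f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    # positional tethers: 0.5*k*|x-x0|^2
    for t in range(p[22].shape[0]):
        i = p[22][t]
        dx = x[i, 0] - p[24][t, 0]
        dy = x[i, 1] - p[24][t, 1]
        dz = x[i, 2] - p[24][t, 2]
        e += 0.5 * p[23][t] * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= p[23][t] * dx
        f[i, 1] -= p[23][t] * dy
        f[i, 2] -= p[23][t] * dz
    # flat-bottom distance restraints: 0.5*k*max(r-r_onset, 0)^2
    for t in range(p[25].shape[0]):
        i = p[25][t]; j = p[26][t]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > p[28][t]:
            dr = r - p[28][t]
            e += 0.5 * p[27][t] * dr * dr
            g = -p[27][t] * dr / r
            f[i, 0] += g * dx; f[i, 1] += g * dy; f[i, 2] += g * dz
            f[j, 0] -= g * dx; f[j, 1] -= g * dy; f[j, 2] -= g * dz
    return e


@njit(cache=True)
def _run_window(x, v, inv_mass_acc, sigma_v, mobile, lam, dt, c1, c2,
                n_steps, stride, normals, p1, p2, e1_out, e2_out):
    """BAOAB propagation on the mapping surface.

    Returns -1 on success or the 0-based step index at which the mapping
    energy diverged.  ``inv_mass_acc`` is ACC_FROM_FORCE/m per particle,
    ``sigma_v`` the Maxwell-Boltzmann velocity scale per particle.
    """
    n = x.shape[0]
    f1 = np.zeros((n, 3))
    f2 = np.zeros((n, 3))
    _energy_forces(x, p1, f1)
    _energy_forces(x, p2, f2)
    a = np.zeros((n, 3))
    for i in range(n):
        if mobile[i]:
            for d in range(3):
                a[i, d] = (lam * f1[i, d] + (1.0 - lam) * f2[i, d]) \
                    * inv_mass_acc[i]
    rec = 0
    half = 0.5 * dt
    for step in range(n_steps):
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    v[i, d] += half * a[i, d]
                    x[i, d] += half * v[i, d]
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * sigma_v[i] * normals[step, i, d]
                    x[i, d] += half * v[i, d]
        e1 = _energy_forces(x, p1, f1)
        e2 = _energy_forces(x, p2, f2)
        em = lam * e1 + (1.0 - lam) * e2
        if not (em > -ENERGY_DIVERGENCE_LIMIT and em < ENERGY_DIVERGENCE_LIMIT):
            return step
        for i in range(n):
            if mobile[i]:
                for d in range(3):
                    a[i, d] = (lam * f1[i, d] + (1.0 - lam) * f2[i, d]) \
                        * inv_mass_acc[i]
                    v[i, d] += half * a[i, d]
        if (step + 1) % stride == 0:
            e1_out[rec] = e1
            e2_out[rec] = e2
            rec += 1
    return -1


# ------------------------------------------------------------- data types

@dataclass
class WindowSample:
    """Per-window ensemble of diabatic energy pairs (post-equilibration)."""

    lam: float
    eps1: np.ndarray  # kcal/mol
    eps2: np.ndarray
    n_equil: int  # discarded equilibration steps
    temperature: float
    dt: float
    seed: int
    replica: int = 0
    final_coords: np.ndarray | None = None

    def __post_init__(self):
        self.eps1 = np.asarray(self.eps1, dtype=float)
        self.eps2 = np.asarray(self.eps2, dtype=float)
        if self.eps1.size == 0:
            raise ValidationError("window has no frames after equilibration")
        if not (np.all(np.isfinite(self.eps1)) and np.all(np.isfinite(self.eps2))):
            raise ValidationError("window contains non-finite energies")

    @property
    def frames(self) -> np.ndarray:
        return np.column_stack([self.eps1, self.eps2])

    @property
    def gap(self) -> np.ndarray:
        """Energy-gap reaction coordinate X = eps1 - eps2."""
        return self.eps1 - self.eps2

    def mapping_energies(self, lam=None) -> np.ndarray:
        l = self.lam if lam is None else lam
        return l * self.eps1 + (1.0 - l) * self.eps2


@dataclass
class Schedule:
    """Lambda schedule and per-window sampling settings."""

    lambdas: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 51))
    direction: str = "bidirectional"  # bidirectional | monotone
    replicas: int = 3
    n_steps: int = 10_000
    dt: float = 1.0  # fs
    temperature: float | None = None  # None -> system default
    friction: float = 1.0e-3  # 1/fs (= 1 ps^-1)
    stride: int = 10
    equil_fraction: float = 0.2
    n_equil_init: int | None = None  # initial lam=0.5 equilibration steps

    def __post_init__(self):
        self.lambdas = np.asarray(sorted(self.lambdas), dtype=float)
        if len(np.unique(self.lambdas)) != len(self.lambdas):
            raise ValidationError("lambda values must be unique")
        if self.lambdas[0] != 0.0 or self.lambdas[-1] != 1.0:
            raise ValidationError("lambda schedule must include 0 and 1")
        if np.any(self.lambdas < 0.0) or np.any(self.lambdas > 1.0):
            raise ValidationError("lambda values must lie in [0, 1]")
        if self.direction not in ("bidirectional", "monotone"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.replicas < 1 or self.n_steps < 1:
            raise ValidationError("replicas and n_steps must be >= 1")

    @property
    def n_windows(self) -> int:
        return len(self.lambdas)

    def digest(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "direction": self.direction,
            "replicas": self.replicas,
            "n_steps": self.n_steps,
            "dt_fs": self.dt,
            "friction_per_fs": self.friction,
            "stride": self.stride,
            "equil_fraction": self.equil_fraction,
        }


# ------------------------------------------------------------- drivers

def _window_seed(master: int, replica: int, key: int) -> np.random.SeedSequence:
    # spawn_key-based derivation: adding windows never perturbs others
    return np.random.SeedSequence(entropy=int(master),
                                  spawn_key=(int(replica), int(key)))


def _lam_key(lam: float) -> int:
    return int(round(float(lam) * 1_000_000_000))


def sample_window(system: EVBSystem, lam, n_steps, dt=1.0, temperature=None,
                  friction=1.0e-3, seed=0, x0=None, stride=10,
                  equil_fraction=0.2, replica=0):
    """Propagate one lambda window and return its post-equilibration
    (eps1, eps2) ensemble.

    Identical seeds give bitwise-identical output (all noise is pre-drawn
    from a numpy PCG64 stream).  Raises IntegrationInstabilityError if the
    mapping energy diverges.
    """
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must lie in [0,1], got {lam}")
    if dt <= 0 or n_steps < 1:
        raise ValidationError("dt and n_steps must be positive")
    T = float(system.temperature_default if temperature is None else temperature)
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")

    n = system.n_particles
    if x0 is None:
        if system.initial_coords is None:
            raise ValidationError("system has no initial coordinates")
        x0 = system.initial_coords
    x = np.array(x0, dtype=float).reshape(n, 3).copy()

    rng = np.random.Generator(np.random.PCG64(
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))))
    masses = system.masses
    mobile = np.array([not getattr(p, "frozen", False) for p in system.particles])
    kbt = R_KCAL * T
    sigma_v = np.sqrt(kbt / (masses * MV2_TO_KCAL))
    v = rng.normal(size=(n, 3)) * sigma_v[:, None]
    v[~mobile] = 0.0
    normals = rng.normal(size=(int(n_steps), n, 3))

    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    inv_mass_acc = ACC_FROM_FORCE / masses
    p1, p2 = pack_system(system)
    n_rec = int(n_steps) // int(stride)
    e1_out = np.empty(n_rec)
    e2_out = np.empty(n_rec)

    status = _run_window(x, v, inv_mass_acc, sigma_v, mobile, lam, float(dt),
                         c1, c2, int(n_steps), int(stride), normals,
                         p1, p2, e1_out, e2_out)
    if status >= 0:
        raise IntegrationInstabilityError(
            f"mapping energy diverged (|e_m| > {ENERGY_DIVERGENCE_LIMIT:g} "
            f"kcal/mol) at lambda={lam} step={status}", lam=lam, step=status)

    n_equil = int(round(equil_fraction * n_steps))
    skip = n_equil // int(stride)
    return WindowSample(lam=lam, eps1=e1_out[skip:], eps2=e2_out[skip:],
                        n_equil=n_equil, temperature=T, dt=dt,
                        seed=-1 if isinstance(seed, np.random.SeedSequence)
                        else int(seed),
                        replica=replica, final_coords=x)


def run_protocol(system: EVBSystem, schedule: Schedule, seed=0):
    """Run the full window protocol and return one WindowSample per
    (lambda, replica).

    Bidirectional mode first equilibrates at lam = 0.5, then walks each
    branch outward, reusing each window's final configuration as the next
    window's start.  Monotone mode chains windows from lam = 0 to 1.
    """
    samples = []
    lams = schedule.lambdas
    for rep in range(schedule.replicas):
        def _one(lam, x_start):
            ss = _window_seed(seed, rep, _lam_key(lam))
            return sample_window(
                system, lam, schedule.n_steps, dt=schedule.dt,
                temperature=schedule.temperature, friction=schedule.friction,
                seed=ss, x0=x_start, stride=schedule.stride,
                equil_fraction=schedule.equil_fraction, replica=rep)

        if schedule.direction == "monotone":
            x = system.initial_coords
            for lam in lams:
                try:
                    ws = _one(lam, x)
                except IntegrationInstabilityError as err:
                    raise IntegrationInstabilityError(
                        f"replica {rep}: {err}", lam=err.lam, step=err.step
                    ) from err
                samples.append(ws)
                x = ws.final_coords
        else:
            n_eq = schedule.n_equil_init or schedule.n_steps
            ss = _window_seed(seed, rep, 2_000_000_000)
            eq = sample_window(
                system, 0.5, n_eq, dt=schedule.dt,
                temperature=schedule.temperature, friction=schedule.friction,
                seed=ss, x0=system.initial_coords, stride=schedule.stride,
                equil_fraction=schedule.equil_fraction, replica=rep)
            x_mid = eq.final_coords
            up = [l for l in lams if l >= 0.5]
            down = [l for l in lams if l < 0.5][::-1]
            for branch in (up, down):
                x = x_mid
                for lam in branch:
                    try:
                        ws = _one(lam, x)
                    except IntegrationInstabilityError as err:
                        raise IntegrationInstabilityError(
                            f"replica {rep}: {err}", lam=err.lam, step=err.step
                        ) from err
                    samples.append(ws)
                    x = ws.final_coords
    return samples
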