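"""Two-state EVB energetics.

A reacting system is described by two diabatic force fields (reactant-like
state 1 with the donor C–H bond, product-like state 2 with the acceptor
N–H bond) coupled by a constant off-diagonal element ``h_ij``.  The
adiabatic ground state is the lowest eigenvalue of the 2x2 Hamiltonian

    | e1    h_ij |
    | h_ij  e2   |

Energies are kcal/mol, lengths Å, charges elementary units.  Harmonic and
flat-bottom terms use the E = 1/2 k (r - r0)^2 convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import COULOMB_KCAL
from .errors import InvalidConfigurationError, ShapeError, ValidationError

REACTING_ROLES = ("donor-C", "hydride-H", "acceptor-N")


@dataclass
class Particle:
    label: str
    mass: float  # amu
    role: str = "bath"  # donor-C | hydride-H | acceptor-N | bath
    frozen: bool = False  # immobile during dynamics (diagnostic use)


@dataclass
class DiabaticState:
    """One valence state's potential energy function.

    ``harmonic_terms`` entries are either bonds ``(i, j, k, r0)`` or angles
    ``(i, j, k_idx, k, theta0)`` with ``j`` the vertex and ``theta0`` in
    radians.  ``tethers`` are isotropic positional restraints
    ``(i, k, x0, y0, z0)`` standing in for an environment anchored
    differently in the two states.
    """

    morse_terms: list = field(default_factory=list)  # (i, j, D, b, r0)
    harmonic_terms: list = field(default_factory=list)
    buckingham_terms: list = field(default_factory=list)  # (i, j, A, B, C)
    charges: np.ndarray | None = None
    shift: float = 0.0
    tethers: list = field(default_factory=list)

    def validate(self, n_particles: int) -> None:
        for i, j, D, b, r0 in self.morse_terms:
            if not (D > 0 and b > 0 and r0 > 0):
                raise ValidationError(
                    f"Morse term ({i},{j}) requires D, b, r0 > 0; got "
                    f"D={D}, b={b}, r0={r0}"
                )
            _check_index(i, j, n=n_particles)
        for term in self.harmonic_terms:
            if len(term) not in (4, 5):
                raise ValidationError(
                    f"harmonic term must be a (i,j,k,r0) bond or "
                    f"(i,j,k_idx,k,theta0) angle; got {term!r}"
                )
            _check_index(*term[: len(term) - 2], n=n_particles)
        for i, j, *_ in self.buckingham_terms:
            _check_index(i, j, n=n_particles)
        if self.charges is not None and len(self.charges) != n_particles:
            raise ShapeError(
                f"charges length {len(self.charges)} != particle count "
                f"{n_particles}"
            )

    def with_shift(self, shift: float) -> "DiabaticState":
        return replace(self, shift=float(shift))


def _check_index(*idx, n):
    for i in idx:
        if not (0 <= int(i) < n):
            raise ValidationError(f"particle index {i} out of range [0, {n})")


@dataclass
class EVBSystem:
    """Two diabatic states, their coupling, and the particle roster.

    ``restraint_bonds`` are flat-bottom distance restraints
    ``(i, j, k, r_onset)`` (zero below ``r_onset``) applied identically in
    both states; ``restraint_tethers`` are shared positional restraints.
    Shared terms cancel in the energy gap but contribute to both diabatic
    energies.
    """

    state1: DiabaticState
    state2: DiabaticState
    h_ij: float
    particles: list
    temperature_default: float = 300.0
    restraint_bonds: list = field(default_factory=list)
    restraint_tethers: list = field(default_factory=list)
    initial_coords: np.ndarray | None = None

    def __post_init__(self):
        if self.initial_coords is not None:
            self.initial_coords = np.asarray(self.initial_coords, dtype=float)
        for st in (self.state1, self.state2):
            if st.charges is not None:
                st.charges = np.asarray(st.charges, dtype=float)
        self.validate()

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.particles], dtype=float)

    def validate(self) -> None:
        if not np.isfinite(self.h_ij) or self.h_ij < 0:
            raise ValidationError(f"h_ij must be >= 0, got {self.h_ij}")
        for role in REACTING_ROLES:
            count = sum(1 for p in self.particles if p.role == role)
            if count != 1:
                raise ValidationError(
                    f"role {role!r} must appear exactly once, found {count}"
                )
        n = self.n_particles
        self.state1.validate(n)
        self.state2.validate(n)
        if self.initial_coords is not None and self.initial_coords.shape != (n, 3):
            raise ShapeError(
                f"initial_coords shape {self.initial_coords.shape} != ({n}, 3)"
            )

    def role_index(self, role: str) -> int:
        for i, p in enumerate(self.particles):
            if p.role == role:
                return i
        raise KeyError(role)

    def with_parameters(self, h_ij=None, alpha=None) -> "EVBSystem":
        """Copy with overwritten coupling and/or product-state shift."""
        sys2 = replace(
            self,
            h_ij=float(h_ij) if h_ij is not None else self.h_ij,
            state2=(
                self.state2.with_shift(alpha) if alpha is not None else self.state2
            ),
        )
        return sys2

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        def state_dict(st):
            return {
                "morse_terms": [
                    [int(t[0]), int(t[1])] + [float(x) for x in t[2:]]
                    for t in st.morse_terms
                ],
                "harmonic_terms": [
                    [int(x) for x in t[: len(t) - 2]]
                    + [float(x) for x in t[len(t) - 2:]]
                    for t in st.harmonic_terms
                ],
                "buckingham_terms": [
                    [int(t[0]), int(t[1])] + [float(x) for x in t[2:]]
                    for t in st.buckingham_terms
                ],
                "charges": None
                if st.charges is None
                else [float(q) for q in st.charges],
                "shift": float(st.shift),
                "tethers": [
                    [int(t[0])] + [float(x) for x in t[1:]] for t in st.tethers
                ],
            }

        return {
            "format": "evbkit-system-v1",
            "particles": [
                {"label": p.label, "mass": float(p.mass), "role": p.role,
                 "frozen": bool(p.frozen)}
                for p in self.particles
            ],
            "h_ij": float(self.h_ij),
            "temperature_default": float(self.temperature_default),
            "state1": state_dict(self.state1),
            "state2": state_dict(self.state2),
            "restraint_bonds": [
                [int(t[0]), int(t[1]), float(t[2]), float(t[3])]
                for t in self.restraint_bonds
            ],
            "restraint_tethers": [
                [int(t[0])] + [float(x) for x in t[1:]]
                for t in self.restraint_tethers
            ],
            "initial_coords": None
            if self.initial_coords is None
            else self.initial_coords.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EVBSystem":
        def state(sd):
            return DiabaticState(
                morse_terms=[tuple(t) for t in sd["morse_terms"]],
                harmonic_terms=[tuple(t) for t in sd["harmonic_terms"]],
                buckingham_terms=[tuple(t) for t in sd["buckingham_terms"]],
                charges=None
                if sd.get("charges") is None
                else np.asarray(sd["charges"], dtype=float),
                shift=float(sd.get("shift", 0.0)),
                tethers=[tuple(t) for t in sd.get("tethers", [])],
            )

        return cls(
            state1=state(d["state1"]),
            state2=state(d["state2"]),
            h_ij=float(d["h_ij"]),
            particles=[
                Particle(p["label"], float(p["mass"]), p.get("role", "bath"),
                         bool(p.get("frozen", False)))
                for p in d["particles"]
            ],
            temperature_default=float(d.get("temperature_default", 300.0)),
            restraint_bonds=[tuple(t) for t in d.get("restraint_bonds", [])],
            restraint_tethers=[tuple(t) for t in d.get("restraint_tethers", [])],
            initial_coords=None
            if d.get("initial_coords") is None
            else np.asarray(d["initial_coords"], dtype=float),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "EVBSystem":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------ energies


def _pair_distances(coords, idx_i, idx_j):
    d = coords[..., idx_i, :] - coords[..., idx_j, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def _state_energy(state: DiabaticState, coords: np.ndarray) -> np.ndarray:
    e = np.zeros(coords.shape[:-2])
    for i, j, D, b, r0 in state.morse_terms:
        r = _pair_distances(coords, int(i), int(j))
        x = 1.0 - np.exp(-b * (r - r0))
        e = e + D * x * x - D
    for term in state.harmonic_terms:
        if len(term) == 4:
            i, j, k, r0 = term
            r = _pair_distances(coords, int(i), int(j))
            e = e + 0.5 * k * (r - r0) ** 2
        else:
            i, j, kc, k, th0 = term
            v1 = coords[..., int(i), :] - coords[..., int(j), :]
            v2 = coords[..., int(kc), :] - coords[..., int(j), :]
            cosv = np.sum(v1 * v2, axis=-1) / (
                np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
            )
            theta = np.arccos(np.clip(cosv, -1.0, 1.0))
            e = e + 0.5 * k * (theta - th0) ** 2
    for i, j, A, B, C in state.buckingham_terms:
        r = _pair_distances(coords, int(i), int(j))
        e = e + A * np.exp(-B * r) - C / r**6
    if state.charges is not None:
        q = np.asarray(state.charges, dtype=float)
        nz = np.nonzero(q)[0]
        for a in range(len(nz)):
            for bix in range(a + 1, len(nz)):
                i, j = nz[a], nz[bix]
                r = _pair_distances(coords, int(i), int(j))
                e = e + COULOMB_KCAL * q[i] * q[j] / r
    for i, k, x0, y0, z0 in state.tethers:
        d = coords[..., int(i), :] - np.array([x0, y0, z0])
        e = e + 0.5 * k * np.sum(d * d, axis=-1)
    return e + state.shift


def _shared_restraint_energy(system: EVBSystem, coords: np.ndarray) -> np.ndarray:
    e = np.zeros(coords.shape[:-2])
    for i, j, k, r_onset in system.restraint_bonds:
        r = _pair_distances(coords, int(i), int(j))
        excess = np.maximum(r - r_onset, 0.0)
        e = e + 0.5 * k * excess * excess
    for i, k, x0, y0, z0 in system.restraint_tethers:
        d = coords[..., int(i), :] - np.array([x0, y0, z0])
        e = e + 0.5 * k * np.sum(d * d, axis=-1)
    return e


def diabatic_energies(system: EVBSystem, coords) -> tuple:
    """Evaluate (e1, e2) for one configuration or a batch.

    ``coords`` has shape (n, 3) or (..., n, 3); returns scalars or arrays
    with the leading batch shape.  Shared restraints count toward both
    states.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2:] != (system.n_particles, 3):
        raise ShapeError(
            f"coords shape {coords.shape} incompatible with "
            f"{system.n_particles} particles"
        )
    if not np.all(np.isfinite(coords)):
        raise InvalidConfigurationError("non-finite coordinates")
    shared = _shared_restraint_energy(system, coords)
    e1 = _state_energy(system.state1, coords) + shared
    e2 = _state_energy(system.state2, coords) + shared
    if coords.ndim == 2:
        return float(e1), float(e2)
    return e1, e2


def mapping_energy(e1, e2, lam):
    """Mapping potential e_m = lam*e1 + (1-lam)*e2.

    lam = 1 is the pure reactant state, lam = 0 the pure product state.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0.0) or np.any(lam > 1.0):
        raise ValidationError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * np.asarray(e1, dtype=float) + (1.0 - lam) * np.asarray(
        e2, dtype=float
    )
    return float(out) if out.ndim == 0 else out


def ground_state_energy(e1, e2, h_ij):
    """Lowest eigenvalue of the 2x2 EVB Hamiltonian.

    E_g = (e1+e2)/2 - sqrt((e1-e2)^2 + 4 h_ij^2)/2, which equals
    min(e1, e2) when h_ij = 0 and never exceeds it.
    """
    if np.any(np.asarray(h_ij) < 0.0):
        raise ValidationError(f"h_ij must be >= 0, got {h_ij}")
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    out = 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * h_ij**2)
    return float(out) if out.ndim == 0 else out
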