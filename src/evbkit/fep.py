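"""FEP/US free-energy estimator.

Stage 1 (FEP): Zwanzig exponential averaging between adjacent mapping
windows gives the mapping free energies dG(lambda_m), anchored to zero at
the reactant endpoint (lambda = 1).  Stage 2 (US): each window's frames
are binned on the gap coordinate X = eps1 - eps2 and reweighted from the
mapping surface onto the adiabatic ground state,

    dg(X_b) = dG(lambda_m) - RT * ln < 1_b * exp(-beta (E_g - e_m)) >_m,

then combined across windows by sample-count weighting.  Standard errors
come from between-replica scatter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .constants import R_KCAL
from .core import EVBSystem, ground_state_energy
from .errors import (CoverageError, IOFailure, NoBarrierError,
                     ValidationError)
from .sampling import Schedule, run_protocol

DEFAULT_BIN_WIDTH = 2.0  # kcal/mol
DEFAULT_MIN_COUNT = 20


# ----------------------------------------------------------- FEP stage

@dataclass
class MappingFreeEnergy:
    """Cumulative mapping free energies along the window ladder.

    ``lambdas`` runs from the reactant endpoint (1) to the product
    endpoint (0); ``dg`` is the mean of forward and reverse Zwanzig
    evaluations, both of which are retained for hysteresis reporting.
    """

    lambdas: np.ndarray
    dg: np.ndarray
    dg_forward: np.ndarray
    dg_reverse: np.ndarray
    temperature: float

    @property
    def hysteresis(self) -> float:
        """|forward - reverse| cumulative dG at the product endpoint."""
        return float(abs(self.dg_forward[-1] - self.dg_reverse[-1]))

    def lookup(self, lam: float) -> float:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        if abs(self.lambdas[idx] - lam) > 1e-12:
            raise ValidationError(f"lambda {lam} not in mapping ladder")
        return float(self.dg[idx])


def _group_by_lambda(samples):
    groups = {}
    for s in samples:
        groups.setdefault(round(float(s.lam), 12), []).append(s)
    # reactant (lam = 1) first
    return dict(sorted(groups.items(), key=lambda kv: -kv[0]))


def _logmeanexp(a):
    return logsumexp(a) - np.log(len(a))


def zwanzig_increments(samples, temperature: float) -> MappingFreeEnergy:
    """Cumulative FEP free energies over the lambda ladder.

    Pools replicas within each window.  Overflow-safe via log-sum-exp.
    """
    groups = _group_by_lambda(samples)
    if len(groups) < 2:
        raise ValidationError(
            f"need at least 2 distinct lambda windows, got {len(groups)}")
    beta = 1.0 / (R_KCAL * temperature)
    lams = list(groups.keys())
    gaps = {lam: np.concatenate([s.gap for s in groups[lam]]) for lam in lams}
    fwd = [0.0]
    rev = [0.0]
    for m in range(len(lams) - 1):
        lam_m, lam_n = lams[m], lams[m + 1]
        dlam = lam_n - lam_m  # negative: walking from reactants to products
        # e_n - e_m = (lam_n - lam_m) * X
        inc_f = -(1.0 / beta) * _logmeanexp(-beta * dlam * gaps[lam_m])
        inc_r = +(1.0 / beta) * _logmeanexp(+beta * dlam * gaps[lam_n])
        fwd.append(fwd[-1] + inc_f)
        rev.append(rev[-1] + inc_r)
    fwd = np.array(fwd)
    rev = np.array(rev)
    return MappingFreeEnergy(
        lambdas=np.array(lams), dg=0.5 * (fwd + rev),
        dg_forward=fwd, dg_reverse=rev, temperature=float(temperature))


# ------------------------------------------------------------ US stage

@dataclass
class FreeEnergyProfile:
    """Binned ground-state free energy along the gap coordinate."""

    x_centers: np.ndarray  # kcal/mol
    dg: np.ndarray  # kcal/mol, reactant minimum gauged to 0
    counts: np.ndarray
    se: np.ndarray  # between-replica scatter; nan where < 2 replicas
    metadata: dict = field(default_factory=dict)
    replica_profiles: list = field(default_factory=list, repr=False)

    def to_tsv(self, path) -> None:
        lines = [f"# {json.dumps(self.metadata, sort_keys=True)}",
                 "X_center_kcal\tdG_kcal\tn_samples\tse_kcal"]
        for x, g, n, s in zip(self.x_centers, self.dg, self.counts, self.se):
            lines.append(f"{x:.6f}\t{g:.8f}\t{int(n)}\t{s:.8f}")
        try:
            Path(path).write_text("\n".join(lines) + "\n")
        except OSError as err:
            raise IOFailure(f"cannot write profile {path}: {err}") from err

    @classmethod
    def from_tsv(cls, path) -> "FreeEnergyProfile":
        try:
            text = Path(path).read_text()
        except OSError as err:
            raise IOFailure(f"cannot read profile {path}: {err}") from err
        meta = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    meta = json.loads(line[1:].strip())
                except json.JSONDecodeError:
                    pass
                continue
            if line.startswith("X_center"):
                continue
            x, g, n, s = line.split("\t")
            rows.append((float(x), float(g), float(n), float(s)))
        arr = np.array(rows)
        return cls(x_centers=arr[:, 0], dg=arr[:, 1], counts=arr[:, 2],
                   se=arr[:, 3], metadata=meta)


@dataclass
class BarrierSummary:
    """Activation and reaction free energies read from a profile."""

    dg_activation: float  # kcal/mol, TS max minus reactant min
    dg_reaction: float  # kcal/mol, product min minus reactant min
    x_reactant: float
    x_ts: float
    x_product: float
    se_activation: float = float("nan")
    se_reaction: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "dg_activation_kcal": self.dg_activation,
            "dg_reaction_kcal": self.dg_reaction,
            "x_reactant_kcal": self.x_reactant,
            "x_ts_kcal": self.x_ts,
            "x_product_kcal": self.x_product,
            "se_activation_kcal": self.se_activation,
            "se_reaction_kcal": self.se_reaction,
        }


def _check_coverage(samples):
    groups = _group_by_lambda(samples)
    lams = list(groups.keys())
    ranges = {}
    for lam in lams:
        g = np.concatenate([s.gap for s in groups[lam]])
        ranges[lam] = (g.min(), g.max())
    for a, b in zip(lams, lams[1:]):
        lo = max(ranges[a][0], ranges[b][0])
        hi = min(ranges[a][1], ranges[b][1])
        if lo > hi:
            raise CoverageError(
                f"windows lambda={a:g} and lambda={b:g} do not overlap on "
                f"the gap coordinate (ranges {ranges[a]} vs {ranges[b]})")


def _assemble_profile_values(samples, mapping, h_ij, temperature, edges):
    beta = 1.0 / (R_KCAL * temperature)
    nbins = len(edges) - 1
    num = np.zeros(nbins)
    weight = np.zeros(nbins)
    groups = _group_by_lambda(samples)
    for lam, ss in groups.items():
        gap = np.concatenate([s.gap for s in ss])
        e1 = np.concatenate([s.eps1 for s in ss])
        e2 = np.concatenate([s.eps2 for s in ss])
        n_m = len(gap)
        eg = ground_state_energy(e1, e2, h_ij)
        em = lam * e1 + (1.0 - lam) * e2
        log_w = -beta * (eg - em)
        dg_m = mapping.lookup(lam)
        idx = np.digitize(gap, edges) - 1
        inside = (idx >= 0) & (idx < nbins)
        for b in np.unique(idx[inside]):
            sel = idx == b
            val = dg_m - (1.0 / beta) * (logsumexp(log_w[sel]) - np.log(n_m))
            n_b = int(np.sum(sel))
            num[b] += n_b * val
            weight[b] += n_b
    dg = np.full(nbins, np.nan)
    ok = weight > 0
    dg[ok] = num[ok] / weight[ok]
    return dg, weight


def us_assemble(samples, mapping: MappingFreeEnergy, h_ij: float,
                temperature: float, bin_width: float = DEFAULT_BIN_WIDTH,
                min_count: int = DEFAULT_MIN_COUNT,
                metadata: dict | None = None) -> FreeEnergyProfile:
    """Umbrella stage: bin on X = eps1 - eps2 and reweight onto the ground
    state; bins below ``min_count`` pooled samples are omitted and the
    reactant-side minimum is gauged to zero."""
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be > 0, got {bin_width}")
    if h_ij < 0:
        raise ValidationError(f"h_ij must be >= 0, got {h_ij}")
    _check_coverage(samples)
    all_gaps = np.concatenate([s.gap for s in samples])
    # bins centered on integer multiples of bin_width, so X = 0 (the
    # symmetric diabatic crossing) falls on a bin center, not an edge
    lo = (np.floor(all_gaps.min() / bin_width) - 0.5) * bin_width
    hi = (np.ceil(all_gaps.max() / bin_width) + 0.5) * bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    dg, counts = _assemble_profile_values(samples, mapping, h_ij,
                                          temperature, edges)
    keep = counts >= max(min_count, 1)
    if not np.any(keep):
        raise CoverageError("no bin reaches the minimum sample count")

    # per-replica profiles on the same grid for scatter-based errors
    replicas = sorted({s.replica for s in samples})
    rep_profiles = []
    if len(replicas) > 1:
        for rep in replicas:
            sub = [s for s in samples if s.replica == rep]
            try:
                map_r = zwanzig_increments(sub, temperature)
                dg_r, cnt_r = _assemble_profile_values(
                    sub, map_r, h_ij, temperature, edges)
            except (ValidationError, CoverageError):
                continue
            rep_profiles.append((dg_r, cnt_r))

    x_out = centers[keep]
    dg_out = dg[keep]
    cnt_out = counts[keep]

    se = np.full(len(x_out), np.nan)
    rep_kept = []
    if rep_profiles:
        # gauge each replica the same way before taking scatter
        mat = np.full((len(rep_profiles), len(x_out)), np.nan)
        for r, (dg_r, cnt_r) in enumerate(rep_profiles):
            v = dg_r[keep]
            mat[r] = v
        # align replicas on their mean over commonly covered bins
        common = np.all(np.isfinite(mat), axis=0)
        if np.any(common):
            mat = mat - mat[:, common].mean(axis=1)[:, None] \
                + dg_out[common].mean()
        nrep = np.sum(np.isfinite(mat), axis=0)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(mat, axis=0, ddof=1)
        se = np.where(nrep >= 2, sd / np.sqrt(np.maximum(nrep, 1)), np.nan)
        rep_kept = [mat[r] for r in range(len(rep_profiles))]

    meta = dict(metadata or {})
    meta.update({
        "h_ij_kcal": float(h_ij),
        "temperature_k": float(temperature),
        "bin_width_kcal": float(bin_width),
        "min_count": int(min_count),
        "hysteresis_kcal": mapping.hysteresis,
    })
    profile = FreeEnergyProfile(
        x_centers=x_out, dg=dg_out, counts=cnt_out, se=se, metadata=meta,
        replica_profiles=rep_kept)
    _gauge_to_reactant(profile)
    return profile


def _locate_stationary_points(dg):
    """Return (i_react, i_ts, i_prod) bin indices via the most prominent
    interior maximum, or raise NoBarrierError."""
    n = len(dg)
    if n < 3:
        raise NoBarrierError("profile has fewer than 3 bins")
    best, best_prom = None, 0.0
    for j in range(1, n - 1):
        left = np.min(dg[:j])
        right = np.min(dg[j + 1:])
        prom = min(dg[j] - left, dg[j] - right)
        if prom > best_prom:
            best, best_prom = j, prom
    if best is None or best_prom <= 0.0:
        raise NoBarrierError(
            "profile has no interior maximum between two minima")
    i_react = int(np.argmin(dg[:best]))
    i_prod = best + 1 + int(np.argmin(dg[best + 1:]))
    return i_react, best, i_prod


def _gauge_to_reactant(profile: FreeEnergyProfile) -> None:
    try:
        i_react, _, _ = _locate_stationary_points(profile.dg)
        offset = profile.dg[i_react]
    except NoBarrierError:
        offset = float(np.min(profile.dg))
    profile.dg = profile.dg - offset
    profile.replica_profiles = [r - offset for r in profile.replica_profiles]


def extract_barriers(profile: FreeEnergyProfile) -> BarrierSummary:
    """Locate reactant/TS/product bins and report dG_activation (TS minus
    reactant) and dG_reaction (product minus reactant), with replica-
    scatter errors when per-replica profiles are available."""
    i_r, i_ts, i_p = _locate_stationary_points(profile.dg)
    dg_act = float(profile.dg[i_ts] - profile.dg[i_r])
    dg_rxn = float(profile.dg[i_p] - profile.dg[i_r])

    se_act = se_rxn = float("nan")
    rep_acts, rep_rxns = [], []
    for rep in profile.replica_profiles:
        if not (np.isfinite(rep[i_r]) and np.isfinite(rep[i_ts])
                and np.isfinite(rep[i_p])):
            continue
        # same stationary bins as the pooled profile: scatter measures
        # replica-to-replica variation of the same observable
        rep_acts.append(float(rep[i_ts] - rep[i_r]))
        rep_rxns.append(float(rep[i_p] - rep[i_r]))
    if len(rep_acts) >= 2:
        se_act = float(np.std(rep_acts, ddof=1) / np.sqrt(len(rep_acts)))
        se_rxn = float(np.std(rep_rxns, ddof=1) / np.sqrt(len(rep_rxns)))

    return BarrierSummary(
        dg_activation=dg_act, dg_reaction=dg_rxn,
        x_reactant=float(profile.x_centers[i_r]),
        x_ts=float(profile.x_centers[i_ts]),
        x_product=float(profile.x_centers[i_p]),
        se_activation=se_act, se_reaction=se_rxn)


def schedule_digest(schedule: Schedule, seed) -> str:
    payload = json.dumps({**schedule.digest(), "seed": int(seed)},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def profile_pipeline(system: EVBSystem, schedule: Schedule, seed=0,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     min_count: int = DEFAULT_MIN_COUNT):
    """Sample the protocol, run FEP/US, and extract barriers.

    Single entry point used by calibration and the CLI; returns
    (FreeEnergyProfile, BarrierSummary).
    """
    samples = run_protocol(system, schedule, seed=seed)
    T = schedule.temperature or system.temperature_default
    mapping = zwanzig_increments(samples, T)
    profile = us_assemble(
        samples, mapping, system.h_ij, T, bin_width=bin_width,
        min_count=min_count,
        metadata={"schedule_digest": schedule_digest(schedule, seed),
                  "seed": int(seed)})
    summary = extract_barriers(profile)
    return profile, summary
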