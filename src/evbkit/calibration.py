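"""Fit the two free EVB parameters (h_ij, alpha) to reference energetics.

The product-state shift alpha controls the reaction free energy with
near-unit sensitivity; the coupling h_ij lowers the barrier monotonically.
A damped alternating secant scheme updates alpha first, then h_ij, each
cycle.  All profile evaluations within one fit share a common derived
sub-seed (common random numbers), so secant differences are not drowned
in sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EVBSystem
from .errors import InfeasibleTargetError, ValidationError
from .fep import profile_pipeline
from .sampling import Schedule


@dataclass
class CalibrationTarget:
    """Reference activation and reaction free energies to reproduce."""

    dg_activation: float  # kcal/mol
    dg_reaction: float  # kcal/mol
    tolerance: float = 0.3  # kcal/mol, per observable
    label: str = ""

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ValidationError(
                f"tolerance must be > 0, got {self.tolerance}")
        if self.dg_activation < max(0.0, self.dg_reaction):
            raise ValidationError(
                f"target requires dg_activation >= max(0, dg_reaction); "
                f"got {self.dg_activation} vs {self.dg_reaction}")


@dataclass
class CalibrationResult:
    h_ij: float
    alpha: float
    dg_activation: float
    dg_reaction: float
    se_activation: float
    se_reaction: float
    iterations: int
    converged: bool
    seed: int
    target: CalibrationTarget | None = None
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "h_ij_kcal": self.h_ij,
            "alpha_kcal": self.alpha,
            "dg_activation_kcal": self.dg_activation,
            "dg_reaction_kcal": self.dg_reaction,
            "se_activation_kcal": self.se_activation,
            "se_reaction_kcal": self.se_reaction,
            "iterations": self.iterations,
            "converged": self.converged,
            "seed": self.seed,
            "target": None if self.target is None else {
                "dg_activation_kcal": self.target.dg_activation,
                "dg_reaction_kcal": self.target.dg_reaction,
                "tolerance_kcal": self.target.tolerance,
                "label": self.target.label,
            },
            "trace": self.trace,
        }


def calibrate(system: EVBSystem, target: CalibrationTarget,
              schedule: Schedule | None = None, seed: int = 0,
              max_iter: int = 30, damping: float = 0.8,
              bin_width: float = 2.0, min_count: int = 20,
              n_eval_seeds: int = 1) -> CalibrationResult:
    """Fit (h_ij, alpha) so the FEP/US profile reproduces the target.

    ``n_eval_seeds > 1`` averages each objective evaluation over that many
    common-random-number sub-seed streams, trading runtime for a smaller
    stochastic offset of the fitted optimum.  Raises
    InfeasibleTargetError when the target barrier exceeds the h_ij = 0
    barrier (h_ij can only lower it).  Reaching max_iter without meeting
    the tolerance returns converged = False rather than raising.
    """
    schedule = schedule or Schedule()
    eval_seeds = [int(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(777 + k,)).generate_state(1)[0])
        for k in range(max(1, int(n_eval_seeds)))]

    trace = []

    def evaluate(h, a):
        sysi = system.with_parameters(h_ij=h, alpha=a)
        summs = [profile_pipeline(sysi, schedule, seed=es,
                                  bin_width=bin_width,
                                  min_count=min_count)[1]
                 for es in eval_seeds]
        summ = summs[0]
        if len(summs) > 1:
            import dataclasses
            summ = dataclasses.replace(
                summ,
                dg_activation=float(np.mean([s.dg_activation for s in summs])),
                dg_reaction=float(np.mean([s.dg_reaction for s in summs])))
        trace.append({"h_ij": float(h), "alpha": float(a),
                      "dg_activation": summ.dg_activation,
                      "dg_reaction": summ.dg_reaction})
        return summ

    # warm-start alpha via its near-unit dG_R sensitivity, then check
    # feasibility of the barrier target at h_ij = 0
    alpha = float(system.state2.shift)
    s0 = evaluate(0.0, alpha)
    alpha = alpha + (target.dg_reaction - s0.dg_reaction)
    s0 = evaluate(0.0, alpha)
    if s0.dg_activation < target.dg_activation - target.tolerance:
        raise InfeasibleTargetError(
            f"target barrier {target.dg_activation} kcal/mol exceeds the "
            f"h_ij=0 barrier {s0.dg_activation:.2f} kcal/mol; the coupling "
            "can only lower the barrier")

    h_prev, f_prev = 0.0, s0.dg_activation - target.dg_activation
    h = max(0.5, 0.8 * f_prev)  # initial probe: barrier drops roughly by h
    summ = s0
    h_last, alpha_last = 0.0, alpha
    converged = abs(f_prev) <= target.tolerance and \
        abs(s0.dg_reaction - target.dg_reaction) <= target.tolerance
    it = 0
    while not converged and it < max_iter:
        it += 1
        summ = evaluate(h, alpha)
        h_last, alpha_last = h, alpha
        res_act = summ.dg_activation - target.dg_activation
        res_rxn = summ.dg_reaction - target.dg_reaction
        if abs(res_act) <= target.tolerance and \
                abs(res_rxn) <= target.tolerance:
            converged = True
            break
        # inner update: alpha against dG_R (sensitivity ~ 1)
        alpha = alpha - damping * res_rxn
        # outer update: damped secant on h_ij against dG_activation
        if abs(res_act - f_prev) > 1e-9 and h != h_prev:
            h_next = h - res_act * (h - h_prev) / (res_act - f_prev)
        else:
            h_next = h + (2.0 if res_act > 0 else -2.0)
        h_prev, f_prev = h, res_act
        h = float(np.clip(h + damping * (h_next - h), 0.0,
                          10.0 * max(target.dg_activation, 1.0)))

    return CalibrationResult(
        h_ij=float(h_last),
        alpha=float(alpha_last),
        dg_activation=summ.dg_activation,
        dg_reaction=summ.dg_reaction,
        se_activation=summ.se_activation,
        se_reaction=summ.se_reaction,
        iterations=it,
        converged=bool(converged),
        seed=int(seed),
        target=target,
        trace=trace)


def transfer_parameters(result: CalibrationResult,
                        other: EVBSystem) -> EVBSystem:
    """Apply fitted (h_ij, alpha) to another system, leaving everything
    else untouched.  Refuses unconverged results."""
    if not result.converged:
        raise ValidationError(
            "refusing to transfer parameters from an unconverged "
            "calibration result")
    return other.with_parameters(h_ij=result.h_ij, alpha=result.alpha)
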