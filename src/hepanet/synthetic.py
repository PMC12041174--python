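"""Seedable synthetic patients: geometry, truth resistances, noisy measurements.

Replaces the unavailable CT segmentations and intraoperative flow probes.
Each patient is a ground-truth network whose outlet resistances were tuned
so noise-free baseline flows fall in the cohort's observed ranges
(CHA 140-340, GDA 15-70 ml/min, PHA = CHA - GDA), plus "measured" flows for
all three scenarios with multiplicative probe noise.

Two deliberate realism features:

* A hepatic-arterial-buffer-response gain acts on the *truth* network in
  post-clamp scenarios (drawn uniform 0.05-0.35), so synthetic "real"
  post-clamp PHA flows systematically exceed the physics-only prediction —
  the regularity observed clinically. The default analysis pipeline predicts
  with gain 0, making the under-prediction (and hence the safety property of
  the predicted minimum) testable.
* The celiac-stenosis variant develops its stenosis on a vascular bed tuned
  to normal antegrade flows; the resulting baseline GDA reversal is an
  emergent solve, not an inserted number.

Noise model: multiplicative Gaussian with sd = v/1.96 truncated at three
standard deviations, so ~95% of draws fall within the probe's stated margin
v (default 0.12, inside the device's 10-15% band).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import FlowMeasurement, calibrate_outlets
from .errors import GenerationFailedError, HepanetError
from .network import (
    ArterialNetwork,
    DEFAULT_OUTLET_RESISTANCES,
    Variant,
    build_template,
)
from .scenarios import run_scenario
from .solver import BASELINE, CLAMP_CHA, CLAMP_GDA, SCENARIOS, FlowSolution

__all__ = ["SyntheticPatient", "generate_patient", "generate_cohort", "observed_network"]

#: Branches measured per scenario, mirroring the intraoperative protocol:
#: baseline measures PHA, CHA and GDA; each clamp scenario measures PHA plus
#: the still-open branch.
MEASURED_BRANCHES = {
    BASELINE: ("CHA", "GDA", "PHA"),
    CLAMP_GDA: ("CHA", "PHA"),
    CLAMP_CHA: ("GDA", "PHA"),
}

_MAX_RETRIES = 5


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    truth_network: ArterialNetwork
    measurements: tuple[FlowMeasurement, ...]
    truth_flows: dict[str, FlowSolution]  # scenario -> noise-free solution
    seed: int
    habr_gain_true: float


def _noise_factor(rng: np.random.Generator, variability: float) -> float:
    if variability == 0.0:
        return 1.0
    sd = variability / 1.96
    for _ in range(100):
        z = rng.standard_normal()
        if abs(z) <= 3.0:
            return 1.0 + sd * z
    return 1.0  # pragma: no cover - 3-sigma rejection virtually never exhausts


def generate_patient(
    variant: Variant | str,
    seed: int,
    noise_variability: float = 0.12,
    habr_gain_true: float | None = None,
    *,
    patient_id: str | None = None,
) -> SyntheticPatient:
    """Generate one reproducible synthetic patient for a given anatomy variant.

    ``habr_gain_true`` defaults to a uniform draw on [0.05, 0.35]; pass 0 for
    a physics-only patient. Raises :class:`GenerationFailedError` if the
    internal ground-truth calibration rejects every retry (practically
    unreachable for the documented parameter ranges).
    """
    variant = Variant(variant)
    if not 0.0 <= noise_variability <= 0.2:
        raise ValueError("noise_variability must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    last_error: Exception | None = None
    for _ in range(_MAX_RETRIES):
        try:
            return _generate(
                variant, seed, rng, noise_variability, habr_gain_true, patient_id
            )
        except HepanetError as exc:
            last_error = exc
    raise GenerationFailedError(seed, detail=str(last_error))


def _generate(variant, seed, rng, noise_variability, habr_gain_true, patient_id):
    # Geometry jitter: per-segment radius +-10%, length +-15% around the
    # template (documented override bounds).
    base = build_template(
        Variant.MICHELS_I
        if variant is Variant.CELIAC_STENOSIS
        else variant
    )
    overrides = {
        s.id: {
            "radius": s.radius * rng.uniform(0.90, 1.10),
            "length": s.length * rng.uniform(0.85, 1.15),
        }
        for s in base.segments
    }
    net = build_template(base.variant, overrides)

    # Baseline flow targets in the cohort's ranges (ml/min).
    cha = rng.uniform(140.0, 340.0)
    gda = rng.uniform(15.0, 70.0)
    spl = rng.uniform(200.0, 400.0)
    sma = rng.uniform(300.0, 600.0)
    targets = {"PHA": cha - gda, "GDA": gda, "SA": spl, "SMA": sma}
    if variant is Variant.MICHELS_VIII_REPLACED_RHA:
        targets["RHA"] = rng.uniform(45.0, 90.0)

    # First-order initial guesses, then tune the truth resistances exactly.
    for branch, q in targets.items():
        node = {"PHA": "LIV", "GDA": "PDA", "SA": "SPL", "SMA": "SMAJ",
                "RHA": "RHL"}[branch]
        net = net.with_outlet_resistance(node, net.inlet.pressure / q)
    truth_targets = [FlowMeasurement(branch=b, flow=q, variability=noise_variability)
                     for b, q in targets.items()]
    net, report = calibrate_outlets(net, truth_targets, tolerance=1e-7,
                                    max_iterations=500)
    if not report.converged:
        raise GenerationFailedError(seed, detail="truth calibration did not converge")

    if variant is Variant.CELIAC_STENOSIS:
        severity = rng.uniform(0.80, 0.95)
        ct = net.segment("CT")
        net = replace(
            net,
            segments=tuple(
                replace(s, area_reduction=severity, stenosis_length=s.length)
                if s.id == "CT" else s
                for s in net.segments
            ),
            variant=Variant.CELIAC_STENOSIS,
        )

    gain = rng.uniform(0.05, 0.35) if habr_gain_true is None else habr_gain_true
    truth_flows = {
        name: run_scenario(net, name, habr_gain=gain if name != BASELINE else 0.0)
        for name in SCENARIOS
    }

    branches_by_scenario = dict(MEASURED_BRANCHES)
    if variant is Variant.MICHELS_VIII_REPLACED_RHA:
        branches_by_scenario = {
            k: v + ("RHA",) for k, v in branches_by_scenario.items()
        }
    measurements = []
    for name in SCENARIOS:
        for branch in branches_by_scenario[name]:
            truth = truth_flows[name].flow(branch)
            measurements.append(
                FlowMeasurement(
                    branch=branch,
                    flow=truth * _noise_factor(rng, noise_variability),
                    variability=noise_variability,
                    scenario=name,
                )
            )
    return SyntheticPatient(
        patient_id=patient_id or f"SYN{seed}",
        truth_network=net,
        measurements=tuple(measurements),
        truth_flows=truth_flows,
        seed=seed,
        habr_gain_true=gain,
    )


def observed_network(patient: SyntheticPatient) -> ArterialNetwork:
    """The network a modeller would start from: truth geometry, default outlets.

    Imaging yields the patient's vessel geometry (including any stenosis)
    but not peripheral resistances, which must be calibrated from the flow
    measurements; outlet resistances are therefore reset to the template
    defaults and the clamp set cleared.
    """
    net = patient.truth_network
    outlets = tuple(
        replace(o, resistance=DEFAULT_OUTLET_RESISTANCES[o.node]) for o in net.outlets
    )
    return replace(net, outlets=outlets, clamped_segments=frozenset())


_MIX_VARIANTS = {
    "michels1": Variant.MICHELS_I,
    "stenosis": Variant.CELIAC_STENOSIS,
    "rha": Variant.MICHELS_VIII_REPLACED_RHA,
}


def generate_cohort(
    n: int,
    variant_mix: dict[str, float] | None = None,
    seed: int = 0,
    *,
    noise_variability: float = 0.12,
    habr_gain_true: float | None = None,
) -> list[SyntheticPatient]:
    """Generate ``n`` patients with per-patient seeds derived from ``seed``.

    ``variant_mix`` maps {"michels1", "stenosis", "rha"} to fractions summing
    to 1 (default: all Michels I); counts are deterministic (largest-fraction
    rounding) and so is the whole cohort for fixed arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(variant_mix or {"michels1": 1.0})
    unknown = set(mix) - set(_MIX_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variant keys: {sorted(unknown)}")
    total = sum(mix.values())
    if total <= 0 or any(f < 0 for f in mix.values()):
        raise ValueError("variant_mix fractions must be >= 0 and sum > 0")

    counts = {k: int(n * f / total) for k, f in mix.items()}
    order = sorted(mix, key=lambda k: (-(n * mix[k] / total - counts[k]), k))
    short = n - sum(counts.values())
    for k in order[:short]:
        counts[k] += 1

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    variants = [v for k in sorted(counts) for v in [_MIX_VARIANTS[k]] * counts[k]]
    return [
        generate_patient(
            variants[i],
            int(child_seeds[i]),
            noise_variability=noise_variability,
            habr_gain_true=habr_gain_true,
            patient_id=f"P{i + 1:03d}",
        )
        for i in range(n)
    ]
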