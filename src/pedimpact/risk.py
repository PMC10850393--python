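"""Weibull injury-risk functions anchored on published AIS4+ points.

The risk of severe (AIS4+) brain injury as a function of a criterion value x
is modeled as a two-parameter Weibull CDF,

    P(x) = 1 - exp(-(x / lam)**k),        lam > 0 (scale), k > 0 (shape),

the family used by the rotational brain-injury criterion literature. Two
anchor points determine (lam, k) in closed form:

    k   = ln( ln(1-p1) / ln(1-p2) ) / ln(x1 / x2)
    lam = x1 / (-ln(1-p1))**(1/k)

The brain criterion (BrIC) curve uses the two published anchors
(1.0 -> 50%, 1.5 -> 80%). The strain (MPS) curve has a single published
anchor (0.89 -> 50%); by default its shape k is borrowed from the fitted
BrIC curve and its scale solved from that anchor — a minimal assumption,
overridable in configuration. No CSDM risk curve ships by default; only the
0.49 diffuse-axonal-injury flag applies there, though user anchors are
accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .criteria import InjuryReport, Thresholds, apply_flags

#: published AIS4+ anchors: (criterion value, probability)
BRIC_AIS4_ANCHORS = ((1.0, 0.5), (1.5, 0.8))
MPS_AIS4_ANCHOR = (0.89, 0.5)


@dataclass(frozen=True)
class RiskFunction:
    """P(injury) = 1 - exp(-(x/scale)**shape) for one criterion."""

    criterion: str
    scale: float
    shape: float

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")

    def __call__(self, value: float) -> float:
        return risk_at(self, value)


def fit_weibull_anchors(anchors, criterion: str = "BrIC") -> RiskFunction:
    """Closed-form Weibull CDF through exactly two anchor points.

    Anchors are ``(value, probability)`` pairs with distinct positive values
    and probabilities in (0, 1); the pair must be co-monotone (larger
    criterion value, larger probability) for a valid increasing risk curve.
    """
    anchors = sorted(anchors)
    if len(anchors) != 2:
        raise ValueError("exactly two anchors are required")
    (x1, p1), (x2, p2) = anchors
    if x1 <= 0 or x1 == x2:
        raise ValueError("anchor values must be positive and distinct")
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("anchor probabilities must lie in (0, 1)")
    if p1 >= p2:
        raise ValueError(
            f"inconsistent anchors: probability must increase with the "
            f"criterion value, got {anchors}")
    shape = math.log(math.log(1 - p1) / math.log(1 - p2)) / math.log(x1 / x2)
    scale = x1 / (-math.log(1 - p1)) ** (1.0 / shape)
    return RiskFunction(criterion=criterion, scale=scale, shape=shape)


def fit_weibull_single_anchor(anchor, shape: float,
                              criterion: str = "MPS") -> RiskFunction:
    """Solve the scale from one anchor given a fixed (borrowed) shape."""
    x, p = anchor
    if x <= 0 or not 0.0 < p < 1.0:
        raise ValueError("anchor must have positive value and probability in (0,1)")
    scale = x / (-math.log(1 - p)) ** (1.0 / shape)
    return RiskFunction(criterion=criterion, scale=scale, shape=shape)


def risk_at(fn: RiskFunction, value: float) -> float:
    """Weibull CDF evaluation; P(0) = 0, strictly increasing, P -> 1."""
    if value < 0:
        raise ValueError("criterion value must be non-negative")
    return float(-np.expm1(-((value / fn.scale) ** fn.shape)))


def default_risk_functions(
        bric_anchors=BRIC_AIS4_ANCHORS,
        mps_anchor=MPS_AIS4_ANCHOR) -> dict[str, RiskFunction]:
    """The default curve set: a two-anchor BrIC curve and an MPS curve with
    the BrIC shape and scale solved from the single strain anchor."""
    bric_fn = fit_weibull_anchors(bric_anchors, criterion="BrIC")
    mps_fn = fit_weibull_single_anchor(mps_anchor, shape=bric_fn.shape,
                                       criterion="MPS")
    return {"BrIC": bric_fn, "MPS": mps_fn}


_CRITERION_FIELDS = {"BrIC": "bric", "MPS": "mps", "CSDM": "csdm"}


def classify(report: InjuryReport,
             risk_functions: dict[str, RiskFunction] | None = None,
             thresholds: Thresholds = Thresholds()) -> InjuryReport:
    """Attach threshold flags and AIS4+ risk probabilities to a report.

    Flags: skull fracture on any stress exceedance, brain tissue damage at
    MPS above 0.30, diffuse axonal injury at CSDM >= 0.49, severe-injury
    reference at HIC above 700. Risks are computed wherever a curve exists
    and the metric is present. Idempotent: classifying twice is a no-op.
    """
    if risk_functions is None:
        risk_functions = default_risk_functions()
    report = apply_flags(report, thresholds)
    risks, params = {}, {}
    for criterion, fn in risk_functions.items():
        attr = _CRITERION_FIELDS.get(criterion)
        if attr is None:
            raise ValueError(f"no report metric for criterion {criterion!r}")
        value = getattr(report, attr)
        if value is not None:
            risks[f"{criterion}_AIS4+"] = risk_at(fn, value)
            params[criterion] = {"scale": fn.scale, "shape": fn.shape}
    report.risks = risks
    report.risk_parameters = params
    return report
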