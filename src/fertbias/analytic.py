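"""Closed-form ascertainment-bias model for family fertility studies.

The model treats families as the unit of analysis. Families are either
schizotypal or not; schizotypal families are split into a high-fitness and
a low-fitness class, with prior probability ``p_low`` of being low-fitness
(0.5 under the symmetric-fitness assumption). A member of a low-fitness
schizotypal family is diagnosed with schizophrenia ``r`` times more often
than a member of a high-fitness one, so a study that recruits families
through diagnosed patients over-represents low-fitness families. Because
low-fitness families also have lower mean fertility (``W_L = W_H - d``),
the patient-ascertained estimate of mean relative fertility is deflated
below the population truth ``W`` by exactly

    bias = d * (P(L|D) - p_low)  =  d * (r - 1) / (2 * (r + 1))   [p_low = 0.5]

which is strictly positive whenever ``r > 1`` and ``d > 0``. When the true
relative fertility sits in the window ``1 <= W < 1 + bias`` the estimate
falls below 1, and neutral or positive selection on schizotypy is misread
as negative selection.

All fertilities are relative to the population mean (population mean = 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "SSMParams",
    "PosteriorResult",
    "BiasResult",
    "posterior_low_given_diagnosis",
    "posterior_high_given_diagnosis",
    "true_fertility",
    "estimated_fertility",
    "fertility_bias",
    "flip_condition",
    "classify_regime",
    "analyze",
    "REGIME_NEGATIVE",
    "REGIME_NEUTRAL",
    "REGIME_POSITIVE",
    "DEFAULT_REGIME_TOL",
]

REGIME_NEGATIVE = "negative"
REGIME_NEUTRAL = "neutral"
REGIME_POSITIVE = "positive"

#: Half-width of the neutrality band used when labelling selection regimes.
#: Exact neutrality (W == 1) is measure-zero in floating point.
DEFAULT_REGIME_TOL = 0.01


def _check_prob(name: str, value: float, *, open_interval: bool = True) -> None:
    if open_interval:
        if not (0.0 < value < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1); got {value!r}")
    else:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class SSMParams:
    """Parameters of the analytic ascertainment-bias model.

    Parameters
    ----------
    r
        Relative risk of diagnosis in low- vs. high-fitness schizotypal
        families, ``P(D|L)/P(D|H)``. Must be >= 1; ``r = 1`` is the
        degenerate no-signal case.
    d
        Fertility difference ``W_H - W_L`` between the class means, in
        relative-fertility units. Must be >= 0; it subsumes the
        fertility-reducing effect of the disorder itself.
    W
        True mean relative fertility of a random schizotypal-family member
        (population mean = 1).
    p_low
        Prior probability that a schizotypal family is low-fitness,
        ``P(L)``. Default 0.5 (symmetric fitness distribution); other
        priors are an extension of the symmetric model.

    The class means are derived: ``W_H = W + p_low*d`` and
    ``W_L = W - (1-p_low)*d``; both must be non-negative.
    """

    r: float
    d: float
    W: float
    p_low: float = 0.5

    def __post_init__(self) -> None:
        if not math.isfinite(self.r) or self.r < 1.0:
            raise ValueError(f"relative risk r must be finite and >= 1; got {self.r!r}")
        if not math.isfinite(self.d) or self.d < 0.0:
            raise ValueError(f"fertility difference d must be finite and >= 0; got {self.d!r}")
        if not math.isfinite(self.W) or self.W < 0.0:
            raise ValueError(f"relative fertility W must be finite and >= 0; got {self.W!r}")
        _check_prob("p_low", self.p_low)
        if self.w_low < 0.0:
            raise ValueError(
                f"derived low-class fertility W_L = W - (1-p_low)*d = {self.w_low!r} "
                "is negative; fertilities must be non-negative"
            )

    @property
    def w_high(self) -> float:
        """Mean relative fertility of high-fitness schizotypal families."""
        return self.W + self.p_low * self.d

    @property
    def w_low(self) -> float:
        """Mean relative fertility of low-fitness schizotypal families."""
        return self.W - (1.0 - self.p_low) * self.d

    def to_dict(self) -> dict:
        return {"r": self.r, "d": self.d, "W": self.W, "p_low": self.p_low}

    @classmethod
    def from_dict(cls, data: dict) -> "SSMParams":
        return cls(r=data["r"], d=data["d"], W=data["W"], p_low=data.get("p_low", 0.5))


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior class probabilities for the family of a random patient."""

    p_low_given_d: float
    p_high_given_d: float


def posterior_low_given_diagnosis(r: float, p_low: float = 0.5) -> float:
    """Probability that a randomly selected patient's family is low-fitness.

    By Bayes' theorem with ``P(D|L) = r * P(D|H)`` the baseline diagnosis
    probability cancels::

        P(L|D) = r * p_low / (r * p_low + (1 - p_low))

    which reduces to ``r / (r + 1)`` for the symmetric prior 0.5. The
    result always dominates the prior when ``r >= 1``.
    """
    if not math.isfinite(r) or r < 1.0:
        raise ValueError(f"relative risk r must be finite and >= 1; got {r!r}")
    _check_prob("p_low", p_low)
    return r * p_low / (r * p_low + (1.0 - p_low))


def posterior_high_given_diagnosis(r: float, p_low: float = 0.5) -> float:
    """Complement of :func:`posterior_low_given_diagnosis`."""
    return 1.0 - posterior_low_given_diagnosis(r, p_low)


def posteriors(r: float, p_low: float = 0.5) -> PosteriorResult:
    """Both posterior class probabilities as a :class:`PosteriorResult`."""
    low = posterior_low_given_diagnosis(r, p_low)
    return PosteriorResult(p_low_given_d=low, p_high_given_d=1.0 - low)


def true_fertility(params: SSMParams) -> float:
    """Expected relative fertility of a random schizotypal-family member.

    Computed as the prior-weighted mixture of the class means,
    ``(1 - p_low) * W_H + p_low * W_L``. Since the class means are derived
    from ``W`` and ``d``, this is an identity returning ``W`` up to
    floating-point round-off; it exists to assert that round trip.
    """
    return (1.0 - params.p_low) * params.w_high + params.p_low * params.w_low


def fertility_bias(params: SSMParams) -> float:
    """Underestimation ``W - What`` induced by patient-family ascertainment.

    Factored closed form::

        bias = d * p_low * (1 - p_low) * (r - 1) / (r * p_low + 1 - p_low)

    algebraically equal to ``d * (P(L|D) - p_low)`` and, for the symmetric
    prior, to ``d * (r - 1) / (2 * (r + 1))``. The factored form is exactly
    zero at ``r = 1`` or ``d = 0`` and strictly positive otherwise, and it
    is non-decreasing in ``r`` and linear in ``d``.
    """
    p = params.p_low
    return params.d * p * (1.0 - p) * (params.r - 1.0) / (params.r * p + (1.0 - p))


def estimated_fertility(params: SSMParams) -> float:
    """Mean relative fertility a patient-ascertained study would estimate.

    Equals the posterior-weighted mixture of the class means,
    ``P(H|D) * W_H + P(L|D) * W_L``; implemented as ``W - bias`` with the
    factored bias so that the consistency identity
    ``estimated = true - bias`` holds exactly in floating point. Always
    <= the true fertility.
    """
    return params.W - fertility_bias(params)


def classify_regime(w: float, tol: float = DEFAULT_REGIME_TOL) -> str:
    """Label a relative fertility as negative / neutral / positive selection.

    ``w < 1 - tol`` is negative selection, ``w > 1 + tol`` positive,
    anything inside the band neutral.
    """
    if not math.isfinite(w) or w < 0.0:
        raise ValueError(f"relative fertility must be finite and >= 0; got {w!r}")
    if not math.isfinite(tol) or tol < 0.0:
        raise ValueError(f"tolerance must be finite and >= 0; got {tol!r}")
    if w < 1.0 - tol:
        return REGIME_NEGATIVE
    if w > 1.0 + tol:
        return REGIME_POSITIVE
    return REGIME_NEUTRAL


def flip_condition(params: SSMParams, tol: float = 0.0) -> tuple[bool, float]:
    """Whether ascertainment flips a non-negative regime to negative.

    Returns ``(flipped, flip_threshold)`` where
    ``flip_threshold = 1 + bias`` is the upper bound on ``W`` below which
    the estimate falls under 1. With ``tol = 0`` the flip region is exactly
    ``1 <= W < 1 + bias``; with a positive ``tol`` the comparison uses the
    same neutrality band as :func:`classify_regime`, i.e. the true regime
    must not be negative (``W >= 1 - tol``) while the estimated fertility
    is below the band (``What < 1 - tol``).
    """
    threshold = 1.0 + fertility_bias(params)
    flipped = (params.W >= 1.0 - tol) and (params.W < threshold - tol)
    return flipped, threshold


@dataclass(frozen=True)
class BiasResult:
    """Full closed-form analysis for one parameter combination."""

    params: SSMParams
    posteriors: PosteriorResult
    w_true: float
    w_hat: float
    bias: float
    flip_threshold: float
    regime_true: str
    regime_estimated: str
    misclassified: bool

    def to_dict(self) -> dict:
        return {
            "r": self.params.r,
            "d": self.params.d,
            "W": self.params.W,
            "p_low": self.params.p_low,
            "posterior_low": self.posteriors.p_low_given_d,
            "posterior_high": self.posteriors.p_high_given_d,
            "w_hat": self.w_hat,
            "bias": self.bias,
            "flip_threshold": self.flip_threshold,
            "regime_true": self.regime_true,
            "regime_estimated": self.regime_estimated,
            "misclassified": self.misclassified,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def analyze(params: SSMParams, tol: float = DEFAULT_REGIME_TOL) -> BiasResult:
    """Run the whole closed-form pipeline for one parameter set."""
    post = posteriors(params.r, params.p_low)
    bias = fertility_bias(params)
    w_hat = estimated_fertility(params)
    _, threshold = flip_condition(params, tol=tol)
    regime_true = classify_regime(params.W, tol)
    regime_estimated = classify_regime(w_hat, tol)
    return BiasResult(
        params=params,
        posteriors=post,
        w_true=params.W,
        w_hat=w_hat,
        bias=bias,
        flip_threshold=threshold,
        regime_true=regime_true,
        regime_estimated=regime_estimated,
        misclassified=(regime_estimated == REGIME_NEGATIVE and regime_true != REGIME_NEGATIVE),
    )
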