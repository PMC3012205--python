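"""Parameter sweeps: bias surfaces over (r, d) and flip-region maps over (r, d, W)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .analytic import (
    DEFAULT_REGIME_TOL,
    SSMParams,
    analyze,
    fertility_bias,
    flip_condition,
)

__all__ = ["SweepGrid", "sweep_bias", "sweep_misclassification"]

logger = logging.getLogger(__name__)


def _check_axis(name: str, values, lower: float | None = None) -> tuple[float, ...]:
    values = tuple(float(v) for v in values)
    if not values:
        raise ValueError(f"{name} must be non-empty")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError(f"{name} must be strictly increasing; got {values!r}")
    if lower is not None and values[0] < lower:
        raise ValueError(f"{name} must all be >= {lower}; got {values!r}")
    return values


@dataclass(frozen=True)
class SweepGrid:
    """Axes of a parameter sweep; each axis strictly increasing."""

    r_values: tuple[float, ...]
    d_values: tuple[float, ...]
    w_values: tuple[float, ...] = (1.0,)
    p_low: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_values", _check_axis("r_values", self.r_values, lower=1.0))
        object.__setattr__(self, "d_values", _check_axis("d_values", self.d_values, lower=0.0))
        object.__setattr__(self, "w_values", _check_axis("w_values", self.w_values, lower=0.0))
        if not (0.0 < self.p_low < 1.0):
            raise ValueError(f"p_low must lie strictly in (0, 1); got {self.p_low!r}")


def sweep_bias(grid: SweepGrid) -> pd.DataFrame:
    """Analytic bias and flip threshold on the (r, d) grid.

    Within the table the bias is non-decreasing along increasing r at
    fixed d and linear along increasing d at fixed r. The bias does not
    depend on W, so the W axis is ignored here.
    """
    rows = []
    for r in grid.r_values:
        for d in grid.d_values:
            # W chosen large enough that the derived W_L is valid; the
            # bias and threshold are independent of W
            params = SSMParams(r=r, d=d, W=(1.0 - grid.p_low) * d + 1.0, p_low=grid.p_low)
            bias = fertility_bias(params)
            rows.append({"r": r, "d": d, "bias": bias, "flip_threshold": 1.0 + bias})
    return pd.DataFrame(rows, columns=["r", "d", "bias", "flip_threshold"])


def sweep_misclassification(
    grid: SweepGrid,
    tol: float = DEFAULT_REGIME_TOL,
    strict: bool = False,
) -> pd.DataFrame:
    """Regime labels and misclassification flags on the (r, d, W) grid.

    Cells whose derived low-class fertility W_L = W - (1 - p_low)*d would
    be negative are skipped with a warning (or raise when ``strict``).
    The misclassified flag is true exactly where patient-ascertained
    estimation turns a neutral-or-positive true regime into an estimated
    negative one, i.e. on the window 1 <= W < 1 + bias (up to ``tol``).
    """
    rows = []
    for r in grid.r_values:
        for d in grid.d_values:
            for w in grid.w_values:
                try:
                    params = SSMParams(r=r, d=d, W=w, p_low=grid.p_low)
                except ValueError as exc:
                    if strict:
                        raise
                    logger.warning("skipping grid cell (r=%g, d=%g, W=%g): %s", r, d, w, exc)
                    continue
                res = analyze(params, tol=tol)
                rows.append(
                    {
                        "r": r,
                        "d": d,
                        "W": w,
                        "w_hat": res.w_hat,
                        "bias": res.bias,
                        "flip_threshold": res.flip_threshold,
                        "regime_true": res.regime_true,
                        "regime_estimated": res.regime_estimated,
                        "misclassified": res.misclassified,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "r",
            "d",
            "W",
            "w_hat",
            "bias",
            "flip_threshold",
            "regime_true",
            "regime_estimated",
            "misclassified",
        ],
    )
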