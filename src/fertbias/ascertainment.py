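"""Proband-based ascertainment and Monte-Carlo fertility estimation.

Two estimands are contrasted on a simulated population:

* the *true* mean relative fertility of schizotypal-family members — mean
  offspring count over every member of every schizotypal family, divided
  by the whole-population mean offspring count; and
* the *ascertained* estimate — the same ratio computed only over families
  recruited through diagnosed patients (probands), each family entering
  the sample once per proband.

Patient-uniform (proband-wise) sampling weights a family by its number of
diagnosed members, which is the conditioning under which the empirical
low-fitness fraction converges to the Bayes posterior P(L|D). Family-wise
sampling ("any family with at least one patient") is offered as an option
but diverges from that posterior when families can hold multiple patients.

Standard errors are nonparametric-bootstrap over families (families, not
individuals, are the independent units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .analytic import SSMParams, estimated_fertility, fertility_bias
from .population import FamilyRecord, PopulationTable, SimulationParams, simulate_population

__all__ = [
    "FertilityEstimate",
    "EstimateResult",
    "MCComparisonReport",
    "ascertain_by_proband",
    "ascertain_by_family",
    "estimate_true_fertility",
    "estimate_ascertained_fertility",
    "estimate_bias",
    "compare_analytic_mc",
    "expected_normalization",
]

DEFAULT_N_BOOT = 500


@dataclass(frozen=True)
class FertilityEstimate:
    """A relative-fertility point estimate with its bootstrap SE."""

    value: float
    se: float
    n_families: int


@dataclass(frozen=True)
class EstimateResult:
    """Empirical counterparts of the analytic W, What and their difference."""

    w_true_hat: float
    w_ascertained_hat: float
    bias_hat: float
    se_true: float
    se_ascertained: float
    n_ascertained: int

    def to_dict(self) -> dict:
        return {
            "w_true_hat": self.w_true_hat,
            "w_ascertained_hat": self.w_ascertained_hat,
            "bias_hat": self.bias_hat,
            "se_true": self.se_true,
            "se_ascertained": self.se_ascertained,
            "n_ascertained": self.n_ascertained,
        }


def ascertain_by_proband(
    pop: PopulationTable,
    seed: int | None = None,
    n_probands: int | None = None,
) -> list[FamilyRecord]:
    """Sample families through diagnosed patients.

    With ``n_probands=None`` (default) every diagnosed individual serves
    as a proband, so each family appears once per diagnosed member — the
    exact-information version of drawing patients uniformly. With a given
    ``n_probands``, that many patients are drawn uniformly with
    replacement using ``seed``.
    """
    diagnosed_families = [f for f in pop.families if f.n_diagnosed > 0]
    if not diagnosed_families:
        raise ValueError(
            "population contains no diagnosed individuals; "
            "increase n_families or p_diag_high"
        )
    full = [f for f in diagnosed_families for _ in range(f.n_diagnosed)]
    if n_probands is None:
        return full
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(full), size=int(n_probands))
    return [full[i] for i in idx]


def ascertain_by_family(pop: PopulationTable) -> list[FamilyRecord]:
    """Family-wise variant: every family with >= 1 patient enters once."""
    sample = [f for f in pop.families if f.n_diagnosed > 0]
    if not sample:
        raise ValueError(
            "population contains no diagnosed individuals; "
            "increase n_families or p_diag_high"
        )
    return sample


def _population_mean_arrays(pop: PopulationTable):
    agg = pop.aggregates()
    return agg["offspring_total"].astype(float), agg["n_members"].astype(float)


def estimate_true_fertility(
    pop: PopulationTable,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> FertilityEstimate:
    """Mean relative fertility over all schizotypal-family members.

    The ratio (schizotypal-member mean offspring) / (whole-population mean
    offspring) is bootstrapped by resampling families with replacement;
    ``n_boot=0`` skips the bootstrap and reports SE 0.
    """
    agg = pop.aggregates()
    schizo = agg["schizotypal"]
    if not schizo.any():
        raise ValueError("population contains no schizotypal families")
    off, members = _population_mean_arrays(pop)
    value = (off[schizo].sum() / members[schizo].sum()) / (off.sum() / members.sum())

    se = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(pop)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            s = schizo[idx]
            if not s.any():
                vals[b] = np.nan
                continue
            o, m = off[idx], members[idx]
            vals[b] = (o[s].sum() / m[s].sum()) / (o.sum() / m.sum())
        se = float(np.nanstd(vals, ddof=1))
    return FertilityEstimate(value=float(value), se=se, n_families=int(schizo.sum()))


def estimate_ascertained_fertility(
    pop: PopulationTable,
    sample: Sequence[FamilyRecord],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> FertilityEstimate:
    """Mean relative fertility over members of the ascertained families.

    All members (patients and relatives) of each sampled family
    contribute, weighted by the family's sampling multiplicity; the
    denominator is the whole-population mean offspring. The bootstrap
    resamples the ascertained draws (numerator) and the population
    families (denominator) independently.
    """
    sample = list(sample)
    if not sample:
        raise ValueError("ascertained sample is empty")
    s_off = np.array([f.offspring_total for f in sample], dtype=float)
    s_members = np.array([f.n_members for f in sample], dtype=float)
    off, members = _population_mean_arrays(pop)
    pop_mean = off.sum() / members.sum()
    value = (s_off.sum() / s_members.sum()) / pop_mean

    se = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        m, n = len(sample), len(pop)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            si = rng.integers(0, m, size=m)
            pi = rng.integers(0, n, size=n)
            num = s_off[si].sum() / s_members[si].sum()
            den = off[pi].sum() / members[pi].sum()
            vals[b] = num / den
        se = float(np.std(vals, ddof=1))
    return FertilityEstimate(value=float(value), se=se, n_families=len(sample))


def estimate_bias(
    pop: PopulationTable,
    seed: int | None = None,
    n_boot: int = DEFAULT_N_BOOT,
) -> EstimateResult:
    """Ascertain by proband and contrast the two fertility estimands."""
    sample = ascertain_by_proband(pop)
    rng_seeds = np.random.SeedSequence(seed).generate_state(2)
    true = estimate_true_fertility(pop, n_boot=n_boot, seed=int(rng_seeds[0]))
    asc = estimate_ascertained_fertility(pop, sample, n_boot=n_boot, seed=int(rng_seeds[1]))
    return EstimateResult(
        w_true_hat=true.value,
        w_ascertained_hat=asc.value,
        bias_hat=true.value - asc.value,
        se_true=true.se,
        se_ascertained=asc.se,
        n_ascertained=len(sample),
    )


def expected_normalization(params: SimulationParams) -> float:
    """Expected whole-population mean fertility relative to the baseline.

    Relative fertilities are reported against the realized population
    mean; when the schizotypal-family mean W differs from 1, that mean is
    ``m = prop_schizotypal * W + (1 - prop_schizotypal)``, so the
    estimators converge to W/m and What/m rather than W and What.
    """
    q = params.prop_schizotypal
    return q * params.ssm.W + (1.0 - q)


@dataclass(frozen=True)
class MCComparisonReport:
    """Monte-Carlo means and CIs versus the analytic closed forms."""

    params: SimulationParams
    n_replicates: int
    ci_level: float
    expected_w_true: float
    expected_w_ascertained: float
    expected_bias: float
    mean_w_true: float
    mean_w_ascertained: float
    mean_bias: float
    ci_w_true: tuple[float, float]
    ci_w_ascertained: tuple[float, float]
    ci_bias: tuple[float, float]
    within_ci_w_true: bool
    within_ci_w_ascertained: bool
    within_ci_bias: bool
    frac_ascertained_below_one: float
    replicate_w_true: tuple[float, ...]
    replicate_w_ascertained: tuple[float, ...]

    @property
    def all_within_ci(self) -> bool:
        return self.within_ci_w_true and self.within_ci_w_ascertained and self.within_ci_bias

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "n_replicates": self.n_replicates,
            "ci_level": self.ci_level,
            "expected": {
                "w_true": self.expected_w_true,
                "w_ascertained": self.expected_w_ascertained,
                "bias": self.expected_bias,
            },
            "observed": {
                "w_true": self.mean_w_true,
                "w_ascertained": self.mean_w_ascertained,
                "bias": self.mean_bias,
            },
            "ci": {
                "w_true": list(self.ci_w_true),
                "w_ascertained": list(self.ci_w_ascertained),
                "bias": list(self.ci_bias),
            },
            "within_ci": {
                "w_true": self.within_ci_w_true,
                "w_ascertained": self.within_ci_w_ascertained,
                "bias": self.within_ci_bias,
            },
            "frac_ascertained_below_one": self.frac_ascertained_below_one,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


# normal quantiles for the CI levels used in practice; avoids a scipy dependency
_Z = {0.90: 1.6448536269514722, 0.95: 1.959963984540054, 0.99: 2.5758293035489004}


def _z_for(level: float) -> float:
    try:
        return _Z[round(level, 2)]
    except KeyError:
        raise ValueError(f"unsupported ci_level {level!r}; choose one of {sorted(_Z)}")


def compare_analytic_mc(
    params: SimulationParams,
    n_replicates: int,
    seed: int,
    ci_level: float = 0.99,
) -> MCComparisonReport:
    """Validate the closed forms by simulation.

    Runs simulate → ascertain → estimate for ``n_replicates`` independent
    populations (replicate seeds derived deterministically from ``seed``),
    and checks that the analytic triple (W, What, bias) — divided by the
    expected population normalization — lies inside the normal-theory CI
    of the replicate means.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1; got {n_replicates!r}")
    z = _z_for(ci_level)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)

    w_true = np.empty(n_replicates)
    w_asc = np.empty(n_replicates)
    for i in range(n_replicates):
        pop = simulate_population(params.with_seed(int(child_seeds[i])))
        sample = ascertain_by_proband(pop)
        w_true[i] = estimate_true_fertility(pop, n_boot=0).value
        w_asc[i] = estimate_ascertained_fertility(pop, sample, n_boot=0).value
    bias = w_true - w_asc

    m = expected_normalization(params)
    expected = (
        params.ssm.W / m,
        estimated_fertility(params.ssm) / m,
        fertility_bias(params.ssm) / m,
    )

    def _ci(x: np.ndarray) -> tuple[float, float]:
        mu = float(x.mean())
        half = z * float(x.std(ddof=1)) / np.sqrt(len(x)) if len(x) > 1 else np.inf
        return (float(mu - half), float(mu + half))

    cis = (_ci(w_true), _ci(w_asc), _ci(bias))
    within = tuple(lo <= e <= hi for e, (lo, hi) in zip(expected, cis))

    return MCComparisonReport(
        params=params,
        n_replicates=n_replicates,
        ci_level=ci_level,
        expected_w_true=expected[0],
        expected_w_ascertained=expected[1],
        expected_bias=expected[2],
        mean_w_true=float(w_true.mean()),
        mean_w_ascertained=float(w_asc.mean()),
        mean_bias=float(bias.mean()),
        ci_w_true=cis[0],
        ci_w_ascertained=cis[1],
        ci_bias=cis[2],
        within_ci_w_true=within[0],
        within_ci_w_ascertained=within[1],
        within_ci_bias=within[2],
        frac_ascertained_below_one=float((w_asc < 1.0).mean()),
        replicate_w_true=tuple(float(v) for v in w_true),
        replicate_w_ascertained=tuple(float(v) for v in w_asc),
    )
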