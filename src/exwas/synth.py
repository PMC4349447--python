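"""Synthetic exposome cohorts with controlled correlation and planted truth.

The generator emulates the structure of a large birth-cohort questionnaire
exposome: hundreds to thousands of mixed binary/ordinal/continuous variables
organised in ten thematic domains with strong within-domain and weaker
cross-domain correlation, ~16% missing data points, a small fraction of
subjects lacking all partner-reported variables, and a right-bounded,
left-skewed continuous outcome on a checklist-score scale.

Mechanism
---------
Variables arise from a Gaussian copula: a latent multivariate normal draw
with a block-exchangeable correlation matrix (``within_domain_corr`` inside a
domain, ``cross_domain_corr`` across domains) is discretized per variable
through quantile thresholds — one cutpoint for binary marginals, 3–5 for
ordinal ones, identity for continuous ones.  The outcome is a linear
combination of *planted effects* on the population-standardized observed
columns (so an effect of β means β outcome points per 1 SD of the analysed
variable, the unit used throughout the selection pipeline), plus optional
interaction products, an optional mediator path, and sinh–arcsinh-skewed
noise, truncated to the feasible outcome bounds.

Every generated dataset comes with a :class:`TruthRecord` that is sufficient
to regenerate it bit-identically and to score recovery of the planted
structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from exwas.codebook import Codebook, DOMAINS, ExposomeMatrix, ExposureVariable

__all__ = [
    "MediatorSpec",
    "SyntheticSpec",
    "SyntheticExposome",
    "TruthRecord",
    "default_spec",
    "generate_exposome",
    "generate_null_pvalue_set",
]

# Binary prevalences and ordinal level counts cycle deterministically over
# variables so marginals are varied but reproducible without extra RNG draws.
_BINARY_PREVALENCES = (0.5, 0.25, 0.65, 0.35, 0.75)
_ORDINAL_LEVELS = (4, 3, 5, 4, 3)


@dataclass(frozen=True)
class MediatorSpec:
    """Mediator structure: M = loading·(pooled planted causes) + noise.

    The mediator is standardized; ``effect`` is its coefficient (outcome
    points per SD of M) in the outcome equation.  The planted main effects in
    :class:`SyntheticSpec` are *direct* effects, so a planted variable's total
    effect is direct + loading-weighted indirect via the mediator.
    """

    loading: float
    effect: float

    def __post_init__(self) -> None:
        if not 0 <= self.loading <= 1:
            raise ValueError("mediator loading must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic exposome cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 600 variables in 10 domains, block correlation 0.3 within / 0.1
    across domains, 7600 subjects, 16% missing data under MAR, 2% of subjects
    without a partner, and a bounded left-skewed outcome on a 126–232
    checklist scale with noise SD 7.2 points.
    """

    n_subjects: int = 7600
    n_variables: int = 600
    n_domains: int = 10
    within_domain_corr: float = 0.3
    cross_domain_corr: float = 0.1
    type_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)  # binary, ordinal, continuous
    planted_effects: tuple[tuple[int, float], ...] = ()
    planted_interactions: tuple[tuple[tuple[int, int], float], ...] = ()
    mediator_spec: MediatorSpec | None = None
    outcome_noise_sd: float = 7.2
    outcome_skew: float = -0.6
    outcome_center: float = 200.0
    outcome_bounds: tuple[float, float] = (126.0, 232.0)
    missing_rate: float = 0.16
    missing_mechanism: str = "MAR"
    partner_var_fraction: float = 0.15
    partnerless_rate: float = 0.020
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_variables < 1:
            raise ValueError("n_subjects and n_variables must be positive")
        if not 1 <= self.n_domains <= len(DOMAINS):
            raise ValueError(f"n_domains must be in [1, {len(DOMAINS)}]")
        if not 0 <= self.within_domain_corr < 1:
            raise ValueError("within_domain_corr must be in [0, 1) for a positive-definite latent correlation")
        if not 0 <= self.cross_domain_corr <= self.within_domain_corr:
            raise ValueError(
                "cross_domain_corr must be in [0, within_domain_corr]; anything else "
                "makes the block latent correlation matrix non-positive-definite"
            )
        if abs(sum(self.type_mix) - 1) > 1e-9 or min(self.type_mix) < 0:
            raise ValueError("type_mix must be non-negative proportions summing to 1")
        ids = [i for i, _ in self.planted_effects]
        if len(set(ids)) != len(ids):
            raise ValueError("a variable appears twice in planted_effects")
        if ids and (min(ids) < 0 or max(ids) >= self.n_variables):
            raise ValueError("planted variable ids must be < n_variables")
        for (i, j), _ in self.planted_interactions:
            if not (0 <= i < self.n_variables and 0 <= j < self.n_variables) or i == j:
                raise ValueError("planted interaction ids must be distinct and < n_variables")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")
        if not 0 <= self.partnerless_rate < 1:
            raise ValueError("partnerless_rate must be in [0, 1)")
        if self.outcome_bounds[0] >= self.outcome_bounds[1]:
            raise ValueError("outcome_bounds must be (low, high) with low < high")


@dataclass
class TruthRecord:
    """Ground truth accompanying a generated dataset.

    Carries the full generating spec (hence sufficient to regenerate the data
    bit-identically with the same generator version) plus derived bookkeeping:
    planted effects/interactions keyed by variable *name*, per-variable
    marginal type, and the realised missingness-mechanism parameters.
    """

    spec: SyntheticSpec
    planted_effects: dict[str, float]
    planted_interactions: list[tuple[str, str, float]]
    var_types: dict[str, str]
    mar_anchors: list[str]
    mar_intercept: float | None
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "planted_effects": self.planted_effects,
            "planted_interactions": [list(t) for t in self.planted_interactions],
            "var_types": self.var_types,
            "mar_anchors": self.mar_anchors,
            "mar_intercept": self.mar_intercept,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TruthRecord":
        text = str(text_or_path)
        if "{" not in text:
            text = Path(text_or_path).read_text()
        payload = json.loads(text)
        sd = dict(payload["spec"])
        med = sd.pop("mediator_spec")
        sd["type_mix"] = tuple(sd["type_mix"])
        sd["outcome_bounds"] = tuple(sd["outcome_bounds"])
        sd["planted_effects"] = tuple((int(i), float(b)) for i, b in sd["planted_effects"])
        sd["planted_interactions"] = tuple(
            ((int(i), int(j)), float(b)) for (i, j), b in sd["planted_interactions"]
        )
        sd["mediator_spec"] = None if med is None else MediatorSpec(**med)
        spec = SyntheticSpec(**sd)
        return cls(
            spec=spec,
            planted_effects={k: float(v) for k, v in payload["planted_effects"].items()},
            planted_interactions=[(a, b, float(c)) for a, b, c in payload["planted_interactions"]],
            var_types=payload["var_types"],
            mar_anchors=payload["mar_anchors"],
            mar_intercept=payload["mar_intercept"],
            seed=int(payload["seed"]),
        )


@dataclass
class SyntheticExposome:
    """Bundle returned by :func:`generate_exposome`."""

    matrix: ExposomeMatrix
    outcome: pd.Series
    truth: TruthRecord
    mediator: pd.Series | None = None

    def __iter__(self):  # allow (matrix, outcome, truth) unpacking
        return iter((self.matrix, self.outcome, self.truth))


def default_spec(
    seed: int = 0,
    n_planted: int = 20,
    beta_range: tuple[float, float] = (0.4, 0.8),
    **overrides,
) -> SyntheticSpec:
    """The default recovery-study spec: 20 planted effects, 2 per domain.

    Effect magnitudes span ``beta_range`` (evenly spaced); consecutive
    magnitudes are paired within a domain — thematically clustered risk
    factors of comparable strength, sharing one sign — and the sign
    alternates across domains so no global confounding direction dominates.
    Planted ids are the first two variables of each domain, which double as
    the fully observed MAR anchor variables.
    """
    spec = SyntheticSpec(seed=seed, **overrides)
    per_dom = spec.n_variables // spec.n_domains
    betas = np.linspace(beta_range[0], beta_range[1], n_planted)
    effects = []
    for k in range(n_planted):
        dom = (k // 2) % spec.n_domains
        slot = k % 2 + 2 * (k // (2 * spec.n_domains))
        sign = 1 if dom % 2 == 0 else -1
        effects.append((dom * per_dom + slot, float(sign * betas[k])))
    return dataclasses.replace(spec, planted_effects=tuple(sorted(effects)))


# ---------------------------------------------------------------------------
# marginals


def _assign_types(spec: SyntheticSpec) -> list[str]:
    """Deterministic type assignment: each domain block gets the mix in order
    continuous → ordinal → binary, so the two leading (anchor) variables of a
    block are continuous whenever the mix allows."""
    per_dom = [spec.n_variables // spec.n_domains] * spec.n_domains
    for k in range(spec.n_variables % spec.n_domains):
        per_dom[k] += 1
    p_bin, p_ord, p_cont = spec.type_mix
    types: list[str] = []
    for size in per_dom:
        n_cont = int(round(p_cont * size))
        n_bin = int(round(p_bin * size))
        n_ord = size - n_cont - n_bin
        if n_ord < 0:
            n_bin += n_ord
            n_ord = 0
        types.extend(["continuous"] * n_cont + ["ordinal"] * n_ord + ["binary"] * n_bin)
    return types


def _marginal(latent_col: np.ndarray, var_type: str, idx: int) -> tuple[np.ndarray, float, float, tuple[float, ...]]:
    """Discretize one latent column; return (values, pop mean, pop sd, cutpoints)."""
    if var_type == "continuous":
        return latent_col, 0.0, 1.0, ()
    if var_type == "binary":
        prev = _BINARY_PREVALENCES[idx % len(_BINARY_PREVALENCES)]
        cut = stats.norm.ppf(1 - prev)
        vals = (latent_col > cut).astype(float)
        return vals, prev, float(np.sqrt(prev * (1 - prev))), (float(cut),)
    levels = _ORDINAL_LEVELS[idx % len(_ORDINAL_LEVELS)]
    qs = np.linspace(0, 1, levels + 1)[1:-1]
    cuts = stats.norm.ppf(qs)
    vals = np.searchsorted(cuts, latent_col).astype(float)
    probs = np.diff(np.concatenate([[0.0], qs, [1.0]]))
    scores = np.arange(levels)
    mean = float(probs @ scores)
    sd = float(np.sqrt(probs @ (scores - mean) ** 2))
    return vals, mean, sd, tuple(float(c) for c in cuts)


def _sinh_arcsinh_moments(skew: float) -> tuple[float, float]:
    """Exact mean and SD of sinh(asinh(Z) + skew) for Z ~ N(0,1)."""

    def _p(q: float) -> float:
        return float(
            np.exp(0.25) / np.sqrt(8 * np.pi) * (special.kv((q + 1) / 2, 0.25) + special.kv((q - 1) / 2, 0.25))
        )

    mean = np.sinh(skew) * _p(1.0)
    second = 0.5 * (np.cosh(2 * skew) * _p(2.0) - 1.0)
    return mean, float(np.sqrt(second - mean**2))


def _skewed_noise(rng: np.random.Generator, n: int, sd: float, skew: float) -> np.ndarray:
    z = rng.standard_normal(n)
    if skew == 0 or sd == 0:
        return sd * z
    w = np.sinh(np.arcsinh(z) + skew)
    mu, sigma = _sinh_arcsinh_moments(skew)
    return sd * (w - mu) / sigma


# ---------------------------------------------------------------------------
# generation


def generate_exposome(spec: SyntheticSpec) -> SyntheticExposome:
    """Generate a synthetic exposome cohort from ``spec``.

    Returns a :class:`SyntheticExposome` bundling the (unstandardized)
    exposure matrix with missingness applied, the outcome vector, the
    :class:`TruthRecord`, and the mediator column if a mediator was specified.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, d = spec.n_subjects, spec.n_variables, spec.n_domains
    w, c = spec.within_domain_corr, spec.cross_domain_corr

    per_dom = [m // d] * d
    for k in range(m % d):
        per_dom[k] += 1
    dom_idx = np.repeat(np.arange(d), per_dom)

    # latent block-exchangeable Gaussian via a two-level factor decomposition
    g = rng.standard_normal(n)
    f = rng.standard_normal((n, d))
    e = rng.standard_normal((n, m))
    latent = np.sqrt(c) * g[:, None] + np.sqrt(w - c) * f[:, dom_idx] + np.sqrt(1 - w) * e

    var_types = _assign_types(spec)
    data = np.empty_like(latent)
    z_std = np.empty_like(latent)  # population-standardized observed columns
    for j in range(m):
        vals, mu, sd, _ = _marginal(latent[:, j], var_types[j], j)
        data[:, j] = vals
        z_std[:, j] = (vals - mu) / sd

    planted = dict(spec.planted_effects)
    for j, beta in planted.items():
        if np.ptp(data[:, j]) == 0:
            raise ValueError(f"planted effect on degenerate variable {j}")

    # outcome: planted mains + interactions + optional mediator + skewed noise
    signal = np.zeros(n)
    for j, beta in planted.items():
        signal += beta * z_std[:, j]
    for (i, j), beta in spec.planted_interactions:
        prod = z_std[:, i] * z_std[:, j]
        signal += beta * (prod - prod.mean())

    mediator = None
    if spec.mediator_spec is not None:
        if not planted:
            raise ValueError("mediator_spec requires at least one planted variable as a cause")
        ids = sorted(planted)
        cause = z_std[:, ids].sum(axis=1)
        cause_sd = cause.std()
        lam = spec.mediator_spec.loading
        mediator = lam * cause / cause_sd + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        signal += spec.mediator_spec.effect * mediator

    noise = _skewed_noise(rng, n, spec.outcome_noise_sd, spec.outcome_skew)
    outcome = np.clip(spec.outcome_center + signal + noise, *spec.outcome_bounds)

    # partner structure: every ~1/fraction-th non-anchor variable is partner-reported
    anchors_per_dom = 2
    offsets = np.concatenate([[0], np.cumsum(per_dom)[:-1]])
    anchor_ids = set()
    for off, size in zip(offsets, per_dom):
        anchor_ids.update(range(off, off + min(anchors_per_dom, size)))
    reporters = np.array(["mother"] * m, dtype=object)
    if spec.partner_var_fraction > 0:
        stride = max(2, int(round(1 / spec.partner_var_fraction)))
        for j in range(m):
            if j % stride == stride - 1 and j not in anchor_ids:
                reporters[j] = "partner"
    partnerless = np.zeros(n, dtype=bool)
    if spec.partnerless_rate > 0:
        partnerless = rng.random(n) < spec.partnerless_rate

    # missingness
    mask = np.zeros((n, m), dtype=bool)
    mar_intercept = None
    anchor_names_flat: list[int] = sorted(anchor_ids)
    if spec.missing_rate > 0:
        if spec.missing_mechanism == "MCAR":
            mask = rng.random((n, m)) < spec.missing_rate
        else:
            # logistic MAR driven by the two fully observed anchors of each domain
            gamma = 0.5
            drives = np.empty((n, d))
            weights = np.empty(d)
            for dom, (off, size) in enumerate(zip(offsets, per_dom)):
                a = list(range(off, off + min(anchors_per_dom, size)))
                drives[:, dom] = gamma * z_std[:, a].sum(axis=1)
                weights[dom] = max(size - len(a), 0)  # non-anchor columns in the block
            if weights.sum() == 0:
                weights[:] = 1.0
            mar_intercept = _calibrate_logit_intercept(drives, spec.missing_rate, weights)
            prob = special.expit(mar_intercept + drives[:, dom_idx])
            mask = rng.random((n, m)) < prob
            mask[:, anchor_names_flat] = False  # anchors stay fully observed

    data = data.copy()
    data[mask] = np.nan
    # partner-reported columns wholly missing for partnerless subjects
    pcols = np.where(reporters == "partner")[0]
    if pcols.size and partnerless.any():
        data[np.ix_(partnerless, pcols)] = np.nan

    # codebook + containers
    width = len(str(m))
    names = [f"d{dom_idx[j] + 1:02d}_x{j:0{width}d}" for j in range(m)]
    variables = []
    for j in range(m):
        vt = var_types[j]
        if vt == "binary":
            rng_lo, rng_hi = 0.0, 1.0
        elif vt == "ordinal":
            rng_lo, rng_hi = 0.0, float(_ORDINAL_LEVELS[j % len(_ORDINAL_LEVELS)] - 1)
        else:
            rng_lo, rng_hi = float("nan"), float("nan")
        variables.append(
            ExposureVariable(
                name=names[j],
                domain=DOMAINS[dom_idx[j]],
                reporter=reporters[j],
                var_type=vt,
                direction=1,
                feasible_range=(rng_lo, rng_hi),
            )
        )
    index = pd.RangeIndex(n, name="subject")
    matrix = ExposomeMatrix(
        data=pd.DataFrame(data, columns=names, index=index),
        codebook=Codebook.from_variables(variables),
        partner_status=pd.Series(partnerless.astype(int), index=index, name="partner_status"),
    )
    truth = TruthRecord(
        spec=spec,
        planted_effects={names[j]: float(b) for j, b in sorted(planted.items())},
        planted_interactions=[(names[i], names[j], float(b)) for (i, j), b in spec.planted_interactions],
        var_types={names[j]: var_types[j] for j in range(m)},
        mar_anchors=[names[j] for j in anchor_names_flat],
        mar_intercept=mar_intercept,
        seed=spec.seed,
    )
    out = pd.Series(outcome, index=index, name="outcome")
    med = None if mediator is None else pd.Series(mediator, index=index, name="mediator")
    return SyntheticExposome(matrix=matrix, outcome=out, truth=truth, mediator=med)


def _calibrate_logit_intercept(u: np.ndarray, target: float, weights: np.ndarray | None = None) -> float:
    """Solve weighted-mean(expit(c + u)) = target for c by bisection."""
    lo, hi = -12.0, 12.0
    if weights is None:
        weights = np.ones(u.shape[1] if u.ndim == 2 else 1)
    w = weights / weights.sum()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(special.expit(mid + u).mean(axis=0) @ w) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def regenerate(truth: TruthRecord) -> SyntheticExposome:
    """Regenerate the dataset described by a TruthRecord (bit-identical)."""
    return generate_exposome(truth.spec)


def generate_null_pvalue_set(m: int, seed: int = 0) -> np.ndarray:
    """m i.i.d. Uniform(0,1) p-values — a fixture for FDR procedure tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.random.default_rng(seed).random(m)
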