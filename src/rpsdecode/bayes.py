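"""Group-level Bayesian inference on decoding accuracy curves.

Per time bin, evidence for above-chance decoding is quantified with a
directional interval-null Bayes factor: a Cauchy prior (scale r = sqrt(2)/2)
on the standardized effect size d is truncated to the alternative region
d > 0.5 versus the null region 0 <= d <= 0.5, excluding small effects from
the alternative. The Bayes factor is the ratio of the marginal likelihoods
of the observed one-sample t statistic under the two truncated priors,
computed by adaptive quadrature of the noncentral-t likelihood.

The winner-loser comparison uses the conventional two-tailed JZS test on
the paired within-dyad differences: an untruncated Cauchy prior on d versus
the point null d = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .decode import CHANCE_LEVEL, DecodingCurve, StreamKind
from .preprocess import Phase

__all__ = [
    "BayesConfig",
    "BFSeries",
    "cohens_d_one_sample",
    "bf_directional_interval",
    "bf_directional_interval_from_t",
    "bf_two_tailed_difference",
    "bf_two_tailed_from_t",
    "run_group_inference",
    "evidence_category",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class BayesConfig:
    """Prior and null-interval settings for the per-bin t tests."""

    null_interval_d: tuple[float, float] = (0.0, 0.5)
    prior_scale_r: float = DEFAULT_PRIOR_SCALE
    chance_level: float = CHANCE_LEVEL

    def __post_init__(self) -> None:
        lo, hi = self.null_interval_d
        if not 0.0 <= lo < hi:
            raise ValueError("null interval must satisfy 0 <= lower < upper")
        if self.prior_scale_r <= 0:
            raise ValueError("prior_scale_r must be positive")


def cohens_d_one_sample(values: np.ndarray, reference: float) -> float:
    """One-sample standardized effect size (mean - reference) / SD."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(values.mean())):
        raise ValueError("zero variance: effect size undefined")
    return float((values.mean() - reference) / sd)


def _marginal_likelihood(
    t: float, df: int, sqrt_n: float, r: float, lo: float, hi: float
) -> float:
    """Likelihood of t averaged over Cauchy(0, r) truncated to d in (lo, hi)."""
    cauchy = stats.cauchy(scale=r)
    mass = cauchy.cdf(hi) - cauchy.cdf(lo)
    if mass <= 0:
        raise ValueError(f"prior mass of interval ({lo}, {hi}) is zero")

    def integrand(d: float) -> float:
        return stats.nct.pdf(t, df, d * sqrt_n) * cauchy.pdf(d)

    val, _ = integrate.quad(
        integrand, lo, hi, epsabs=1e-12, epsrel=1e-8, limit=200
    )
    if not np.isfinite(val):
        raise ValueError(
            f"marginal likelihood integral diverged (t={t}, df={df}, d in [{lo}, {hi}])"
        )
    return val / mass


def bf_directional_interval_from_t(
    t: float, n: int, cfg: BayesConfig = BayesConfig()
) -> float:
    """Directional interval-null BF from a one-sample t statistic.

    BF > 1 favors an effect beyond the null interval (d above its upper
    edge); BF < 1 favors a null-to-small effect (d within the interval).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    lo, hi = cfg.null_interval_d
    sqrt_n = np.sqrt(n)
    m1 = _marginal_likelihood(t, n - 1, sqrt_n, cfg.prior_scale_r, hi, np.inf)
    m0 = _marginal_likelihood(t, n - 1, sqrt_n, cfg.prior_scale_r, lo, hi)
    return m1 / m0


def bf_directional_interval(
    values: np.ndarray, cfg: BayesConfig = BayesConfig()
) -> float:
    """Directional interval-null BF for values against the chance level."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 participants")
    if values.std(ddof=1) == 0:
        # degenerate zero-variance sample (e.g. ceiling accuracy): the
        # effect size is unbounded, so the evidence is one-sided and total
        mean = values.mean()
        if mean > cfg.chance_level:
            return np.inf
        if mean < cfg.chance_level:
            return 0.0
        return bf_directional_interval_from_t(0.0, values.size, cfg)
    t, _ = stats.ttest_1samp(values, cfg.chance_level)
    return bf_directional_interval_from_t(float(t), values.size, cfg)


def bf_two_tailed_from_t(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """Two-tailed JZS BF (Cauchy prior on d vs point null) from a t statistic."""
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 1
    sqrt_n = np.sqrt(n)
    m1 = _marginal_likelihood(t, df, sqrt_n, r, -np.inf, np.inf)
    m0 = stats.t.pdf(t, df)
    return m1 / m0


def bf_two_tailed_difference(
    values_a: np.ndarray,
    values_b: np.ndarray,
    cfg: BayesConfig = BayesConfig(),
) -> float:
    """Two-tailed BF on the paired difference (a minus b, within dyad)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"groups must pair one-to-one within dyads (got {a.size} vs {b.size})"
        )
    if a.size < 3:
        raise ValueError("need at least 3 dyads")
    diff = a - b
    if diff.std(ddof=1) == 0:
        if diff.mean() != 0:  # constant nonzero difference: unbounded effect
            return np.inf
        return bf_two_tailed_from_t(0.0, diff.size, cfg.prior_scale_r)
    t, _ = stats.ttest_1samp(diff, 0.0)
    return bf_two_tailed_from_t(float(t), diff.size, cfg.prior_scale_r)


def evidence_category(bf: float) -> str:
    """Conventional evidence band labels (for reporting only)."""
    strength = bf if bf >= 1 else 1.0 / bf
    if strength < 3:
        label = "anecdotal"
    elif strength < 10:
        label = "moderate"
    else:
        label = "strong"
    side = "alternative" if bf >= 1 else "null"
    return f"{label} ({side})"


@dataclass(frozen=True)
class BFSeries:
    """Per-bin Bayes factors for one stream and participant group."""

    bf: np.ndarray  # (n_bins,)
    n_participants: int
    kind: StreamKind
    group: str  # all | winners | losers | winners_vs_losers
    phase_of_bin: tuple[Phase, ...]

    def max_bf_per_phase(self) -> dict[Phase, float]:
        out = {}
        for phase in Phase:
            idx = [i for i, p in enumerate(self.phase_of_bin) if p is phase]
            out[phase] = float(np.max(self.bf[idx])) if idx else float("nan")
        return out


def run_group_inference(
    curves: list[DecodingCurve],
    roles: dict[str, int | None],
    cfg: BayesConfig = BayesConfig(),
) -> dict[StreamKind, dict[str, BFSeries]]:
    """Per-bin Bayes factors for each stream: all, winners, losers, difference.

    ``curves`` carry participant ids of the form ``"<pair_id>/p<player>"``;
    ``roles`` maps each pair id to its overall match winner (1 or 2), or
    ``None`` for a tied match, whose participants are excluded. The
    winner-loser comparison is paired within dyad.
    """
    by_kind: dict[StreamKind, dict[str, dict[str, np.ndarray]]] = {}
    phase_of_bin: tuple[Phase, ...] | None = None
    for curve in curves:
        pair_id, _, ptag = curve.participant.partition("/p")
        if not ptag:
            raise ValueError(
                f"curve participant id {curve.participant!r} is not '<pair>/p<player>'"
            )
        player = int(ptag)
        winner = roles.get(pair_id)
        if winner is None:
            continue
        role = "winner" if player == winner else "loser"
        by_kind.setdefault(curve.kind, {}).setdefault(pair_id, {})[role] = curve.accuracy
        phase_of_bin = curve.phase_of_bin

    results: dict[StreamKind, dict[str, BFSeries]] = {}
    for kind, pairs in by_kind.items():
        complete = {p: d for p, d in pairs.items() if {"winner", "loser"} <= set(d)}
        if not complete:
            raise ValueError(f"no complete winner/loser dyads for stream {kind.value}")
        winners = np.stack([d["winner"] for d in complete.values()])
        losers = np.stack([d["loser"] for d in complete.values()])
        everyone = np.concatenate([winners, losers])
        n_bins = everyone.shape[1]

        def _series(values: np.ndarray, group: str, directional: bool) -> BFSeries:
            bf = np.empty(n_bins)
            for b in range(n_bins):
                if directional:
                    bf[b] = bf_directional_interval(values[:, b], cfg)
                else:
                    bf[b] = bf_two_tailed_difference(winners[:, b], losers[:, b], cfg)
            return BFSeries(bf, values.shape[0], kind, group, phase_of_bin)

        results[kind] = {
            "all": _series(everyone, "all", True),
            "winners": _series(winners, "winners", True),
            "losers": _series(losers, "losers", True),
            "winners_vs_losers": _series(winners, "winners_vs_losers", False),
        }
    return results
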