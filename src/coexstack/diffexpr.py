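"""Per-feature two-group differential expression with empirical-Bayes
variance moderation.

The model is the classic two-group linear contrast on a log2-scale matrix:
the effect is the difference of group means, and the per-feature residual
variance s_g^2 (d_g residual degrees of freedom) is shrunk toward a global
prior via the standard empirical-Bayes construction on log-variances.
The prior (d0, s0^2) is estimated by matching the mean and variance of
log s_g^2 to the moments of a scaled log-F distribution, with the trigamma
function inverted by Newton iteration. The moderated statistic

    t_g = (mean_case - mean_ctrl) / (s~_g * sqrt(1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

is referred to a t distribution with d0 + d_g degrees of freedom. When the
log-variances show no excess dispersion beyond sampling noise the implied
d0 is infinite and the fully pooled variance s0^2 is used (a z test).

Significance is an uncorrected p < alpha call (default alpha = 0.05);
Benjamini-Hochberg q-values are reported as an extra column but never
drive the significance flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ConsistencyError, ExpressionMatrix


@dataclass
class DEResult:
    """Differential-expression results for one two-group contrast.

    ``table`` has one row per feature with columns: log2_fold_change,
    mean_signal, t_statistic, p_value, q_value, is_significant.
    """

    table: pd.DataFrame
    case_group: str
    control_group: str
    alpha: float
    prior_df: float
    prior_var: float

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["is_significant"]])

    def write_tsv(self, path) -> None:
        out = self.table.rename_axis("feature_id").reset_index()
        out.columns = ["feature_id", "log2FC", "mean", "t", "p", "q", "significant"]
        out["significant"] = out["significant"].astype(int)
        out.to_csv(path, sep="\t", index=False, float_format="%.9g")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on the
    monotone decreasing trigamma function."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_log_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the spread of log sample variances.

    The excess variance of log s_g^2 over its sampling component
    trigamma(d/2) identifies the prior degrees of freedom; non-positive
    excess yields d0 = inf (fully pooled variance).
    """
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ConsistencyError("all features have zero residual variance")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    evar_excess = evar - float(special.polygamma(1, df / 2.0))
    if evar_excess > 0:
        d0 = 2.0 * _trigamma_inverse(evar_excess)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: fully pooled variance (plain average of s^2)
        d0 = np.inf
        s0_2 = float(positive.mean())
    return d0, s0_2


def fit_two_group(matrix: ExpressionMatrix, case_group: str, control_group: str,
                  moderation: bool = True, alpha: float = 0.05,
                  prior_df: float | None = None) -> DEResult:
    """Fit the two-group contrast for every feature.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2-scale signal with sample_groups assigned; only samples in the
        two named groups are used.
    moderation : bool
        When True (default), shrink variances with the empirical-Bayes
        prior; when False, use the ordinary pooled two-sample t.
    prior_df : float, optional
        Override the estimated prior degrees of freedom d0 (0 recovers the
        ordinary t exactly; inf pools completely). Moderation only.
    """
    groups = matrix.groups()
    for g in (case_group, control_group):
        if len(groups.get(g, [])) < 2:
            raise ConsistencyError(
                f"group {g!r} has {len(groups.get(g, []))} sample(s); need >=2"
            )
    case = matrix.subset_samples(groups[case_group]).values
    ctrl = matrix.subset_samples(groups[control_group]).values
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2_fc = mean_case - mean_ctrl
    mean_signal = np.hstack([case, ctrl]).mean(axis=1)
    ss = ((case - mean_case[:, None]) ** 2).sum(axis=1) + \
         ((ctrl - mean_ctrl[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderation:
        d0, s0_2 = estimate_log_variance_prior(s2, d)
        if prior_df is not None:
            d0 = float(prior_df)
        # total df capped at the fully pooled residual df, so an infinite
        # prior yields a t reference with sum_g d_g degrees of freedom
        df_pooled = float(d * len(matrix.feature_ids))
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = df_pooled
        elif d0 == 0.0:
            s2_tilde = s2
            df_total = float(d)
        else:
            s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = min(d0 + d, df_pooled)
    else:
        if np.any(s2 == 0):
            bad = [matrix.feature_ids[i] for i in np.flatnonzero(s2 == 0)[:5]]
            raise ConsistencyError(
                f"zero residual variance without moderation (e.g. {bad}); "
                "p-value undefined — enable moderation"
            )
        d0, s0_2 = 0.0, float("nan")
        s2_tilde = s2
        df_total = float(d)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2_fc / (np.sqrt(s2_tilde) * se_factor)
    t = np.where((log2_fc == 0) & ~np.isfinite(t), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    q = stats.false_discovery_control(p, method="bh")

    table = pd.DataFrame(
        {
            "log2_fold_change": log2_fc,
            "mean_signal": mean_signal,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "is_significant": p < alpha,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    return DEResult(table, case_group, control_group, alpha,
                    prior_df=float(d0), prior_var=s0_2)


def overlap_summary(de_a: DEResult, de_b: DEResult,
                    universe_size: int | None = None,
                    ) -> tuple[int, int, int, float]:
    """Count features called significant in two contrasts over one universe
    and score the shared count with an upper-tail hypergeometric test.

    Returns (n_a, n_b, n_shared, hypergeometric_p).
    """
    from .integration import hypergeometric_upper

    if set(de_a.feature_ids) != set(de_b.feature_ids):
        raise ConsistencyError("contrasts cover different feature universes")
    universe = len(de_a.feature_ids)
    if universe_size is not None and universe_size != universe:
        raise ConsistencyError(
            f"stated universe size {universe_size} != table size {universe}"
        )
    sig_a = set(de_a.significant_features)
    sig_b = set(de_b.significant_features)
    shared = len(sig_a & sig_b)
    p = hypergeometric_upper(universe, len(sig_a), len(sig_b), shared)
    return len(sig_a), len(sig_b), shared, p
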