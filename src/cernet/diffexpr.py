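"""Two-group differential expression with empirical-Bayes variance moderation.

The screening statistic is a moderated t: per-feature pooled variances are
shrunk toward a common prior estimated by fitting a scaled-F model to the
observed variances (method of moments on ``log s_g^2``). With few samples
per group — the cohorts here go down to 3 vs 3 — raw per-feature variances
are unstable and the moderated statistic is the field's standard remedy.

Given groups of size :math:`n_1, n_2` and per-feature pooled variance
:math:`s_g^2` on :math:`d_g = n_1 + n_2 - 2` degrees of freedom, the prior
:math:`(d_0, s_0^2)` is estimated from the marginal distribution of
:math:`\\log s_g^2`, and the posterior variance is

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},

with moderated :math:`t_g = \\mathrm{log_2FC}_g / (\\tilde s_g
\\sqrt{1/n_1 + 1/n_2})` referred to a t distribution on
:math:`d_0 + d_g` degrees of freedom (a normal reference when
:math:`d_0 = \\infty`). ``prior_df=0`` recovers the classical pooled
two-sample t exactly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModeratedFit",
    "DERecord",
    "moderated_t_test",
    "screen_de",
    "combine_de",
    "intersect_de",
]

#: screening defaults: raw p below 0.05 and |log2FC| above 0.585
#: (fold change beyond 1.5x in either direction)
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 0.585


@dataclass
class ModeratedFit:
    """Result of a moderated two-group comparison.

    ``table`` is indexed by feature id with columns ``log2fc`` (case mean
    minus control mean), ``var`` (pooled within-group variance), ``var_post``
    (posterior variance after shrinkage), ``t`` and ``p``.
    """

    table: pd.DataFrame
    df_residual: float
    prior_df: float
    prior_var: float
    n_case: int
    n_control: int
    fallback_unmoderated: bool = False


@dataclass(frozen=True, order=True)
class DERecord:
    """One feature that passed the differential-expression screen."""

    feature: str
    feature_class: str  # lncRNA | miRNA | mRNA
    log2fc: float
    p: float
    direction: str  # up | down
    t: float = field(default=float("nan"), compare=False)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def _fit_scaled_f(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match ``log s2`` against a scaled-F model; return (d0, s0^2).

    When the observed spread of ``log s2`` is no larger than expected from
    chi-square sampling noise alone there is no evidence of variance
    heterogeneity and the prior df is infinite (complete shrinkage).
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    rhs = evar - float(special.polygamma(1, df / 2.0))
    if rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s02 = math.exp(
            emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return d0, s02


def moderated_t_test(
    matrix: ExpressionMatrix,
    case_label: str = "CAD",
    control_label: str = "control",
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ModeratedFit:
    """Moderated t-test of case versus control for every feature.

    Parameters
    ----------
    matrix
        Log2-scale expression with a ``group`` column in its metadata.
    case_label, control_label
        Group labels; log2FC is case mean minus control mean.
    prior_df
        If given, skip estimation and use this prior df directly
        (``0`` gives the classical pooled t; ``inf`` a normal reference).
    prior_var
        Prior variance to pair with a forced ``prior_df``; estimated from
        the data when omitted.

    Raises
    ------
    ValueError
        If either group has fewer than two samples.
    """
    case_ids = matrix.group_samples(case_label)
    ctrl_ids = matrix.group_samples(control_label)
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 samples per group, got {n1} {case_label!r} / "
            f"{n2} {control_label!r}"
        )
    x1 = matrix.values[case_ids].to_numpy(float)
    x2 = matrix.values[ctrl_ids].to_numpy(float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m1 - m2
    df_res = float(n1 + n2 - 2)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / df_res

    fallback = False
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0.0:
            s02 = 0.0
        elif prior_var is not None:
            s02 = float(prior_var)
        else:
            _, s02 = _fit_scaled_f(s2[s2 > 0], df_res) if (s2 > 0).any() else (
                math.inf,
                0.0,
            )
    elif not (s2 > 0).any():
        warnings.warn(
            "all features have zero pooled variance; falling back to the "
            "unmoderated t-test",
            RuntimeWarning,
            stacklevel=2,
        )
        d0, s02, fallback = 0.0, 0.0, True
    else:
        d0, s02 = _fit_scaled_f(s2[s2 > 0], df_res)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = df_res
    else:
        s2_post = (d0 * s02 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # degenerate rows: zero spread and zero difference carry no evidence
    p = np.where((se == 0) & (lfc == 0), 1.0, p)

    table = pd.DataFrame(
        {"log2fc": lfc, "var": s2, "var_post": s2_post, "t": t, "p": p},
        index=matrix.values.index,
    )
    return ModeratedFit(
        table=table,
        df_residual=df_res,
        prior_df=d0,
        prior_var=s02,
        n_case=n1,
        n_control=n2,
        fallback_unmoderated=fallback,
    )


def screen_de(
    fit: ModeratedFit,
    feature_class: str,
    p_thresh: float = DEFAULT_P_THRESHOLD,
    lfc_thresh: float = DEFAULT_LFC_THRESHOLD,
) -> list[DERecord]:
    """Retain features with ``p < p_thresh`` and ``|log2FC| > lfc_thresh``.

    Both inequalities are strict. The default fold-change cut of 0.585 on
    the log2 scale corresponds to fold changes beyond 1.5x up or down.
    Direction is the sign of log2FC.
    """
    if p_thresh <= 0 or lfc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    t = fit.table
    keep = t[(t["p"] < p_thresh) & (t["log2fc"].abs() > lfc_thresh)]
    return [
        DERecord(
            feature=str(idx),
            feature_class=feature_class,
            log2fc=float(row["log2fc"]),
            p=float(row["p"]),
            direction="up" if row["log2fc"] > 0 else "down",
            t=float(row["t"]),
        )
        for idx, row in keep.sort_index().iterrows()
    ]


def combine_de(
    *record_sets: list[DERecord],
) -> tuple[list[DERecord], list[tuple[str, str]]]:
    """Union DE lists from several datasets of the same feature class.

    A feature found in several lists with the same direction is emitted once,
    carrying the statistics of the list where it was most significant. A
    feature whose direction conflicts between lists is excluded from the
    union and reported in the second return value as ``(feature, "up/down")``
    pairs — downstream sign logic needs unambiguous directions.
    """
    if len(record_sets) < 2:
        raise ValueError("combine_de needs at least two DE lists")
    classes = {r.feature_class for recs in record_sets for r in recs}
    if len(classes) > 1:
        raise ValueError(f"mixed feature classes in combine_de: {classes}")
    best: dict[str, DERecord] = {}
    directions: dict[str, set[str]] = {}
    for recs in record_sets:
        for r in recs:
            directions.setdefault(r.feature, set()).add(r.direction)
            cur = best.get(r.feature)
            if cur is None or r.p < cur.p:
                best[r.feature] = r
    conflicts = sorted(
        (f, "/".join(sorted(d))) for f, d in directions.items() if len(d) > 1
    )
    conflicted = {f for f, _ in conflicts}
    combined = sorted(
        (r for f, r in best.items() if f not in conflicted),
        key=lambda r: r.feature,
    )
    if conflicts:
        logger.info("combine_de: %d direction conflicts excluded", len(conflicts))
    return combined, conflicts


def intersect_de(a: list[DERecord], b: list[DERecord]) -> list[DERecord]:
    """Features present in both lists with matching direction.

    Returns the record with the smaller p-value for each common feature,
    sorted by feature id.
    """
    bmap = {r.feature: r for r in b}
    out = []
    for r in a:
        other = bmap.get(r.feature)
        if other is not None and other.direction == r.direction:
            out.append(r if r.p <= other.p else other)
    return sorted(out, key=lambda r: r.feature)
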