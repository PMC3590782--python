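"""Replicate-variance statistics for reporter-ion ratio tables.

The quantities of interest mirror how multiplexed proteomics workflows
are benchmarked:

* per-protein **workflow CV** - within each workflow replicate, a
  protein's channel ratio is averaged over its technical replicates;
  the CV (sample SD / mean, ``ddof=1``) of those per-workflow values is
  the protein's total workflow-to-workflow variation.  The mean over
  proteins and non-reference channels is the scalar ``S_b``.
* per-protein **technical CV** - the CV of the ratio across technical
  replicates within one workflow replicate, for proteins quantified in
  at least two runs there; its mean is ``S_t``.
* the empirical CV distribution (histogram, quantiles, cumulative
  frequencies), the mean CV per spectral-count bin, SDs of log2 ratios,
  and a per-protein one-way ANOVA with workflow replicate as the factor
  that classifies proteins as consistently or inconsistently quantified
  across workflow repetitions.

CVs use the sample SD (n-1 denominator).  ANOVA runs on raw ratios by
default because ratios near 1 with moderate CVs are close to symmetric;
a log2 mode is provided and is the better choice when fold changes are
large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_DEFAULT_QUANTILES = (0.5, 0.75, 0.9)


@dataclass
class VarianceSummary:
    """Scalar variance estimates plus per-channel CV statistics."""

    reference_channel: int
    #: channel -> (mean CV, median CV), fractional
    per_channel_cv: dict[int, tuple[float, float]] = field(default_factory=dict)
    #: quantile level -> CV threshold (e.g. 0.75 -> "75% of proteins < x")
    cumulative_cv_quantiles: dict[float, float] = field(default_factory=dict)
    s_b: float = float("nan")
    s_t: float = float("nan")
    #: eligibility rule + protein count behind each scalar estimate
    n_proteins_used: dict[str, int] = field(default_factory=dict)


def _cv(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m == 0:
        raise ValueError("mean ratio is zero; CV undefined (ratios must be > 0)")
    return float(values.std(ddof=1) / m)


def workflow_replicate_means(quants: pd.DataFrame) -> pd.DataFrame:
    """Per (protein, channel, workflow replicate) mean ratio over technical reps.

    Also carries ``n_technical`` (runs averaged) and the workflow
    replicate's total spectral count for the protein.
    """
    sc = (
        quants.drop_duplicates(["protein_id", "workflow_rep", "technical_rep"])
        .groupby(["protein_id", "workflow_rep"])["spectral_count"]
        .sum()
        .rename("workflow_sc")
    )
    means = (
        quants.groupby(["protein_id", "channel", "workflow_rep"], sort=True)["ratio"]
        .agg(ratio="mean", n_technical="size")
        .reset_index()
    )
    return means.merge(sc, on=["protein_id", "workflow_rep"], how="left")


def workflow_cv(
    quants: pd.DataFrame,
    min_workflow_reps: int = 2,
) -> pd.DataFrame:
    """Per-protein, per-channel CV across workflow replicates.

    Only proteins quantified (post-filter) in at least ``min_workflow_reps``
    workflow replicates for the channel are reported.  Columns: protein_id,
    channel, cv, mean_ratio, n_workflow_reps, total_sc.
    """
    if min_workflow_reps < 2:
        raise ValueError("min_workflow_reps must be >= 2 (a CV needs >= 2 values)")
    means = workflow_replicate_means(quants)
    g = means.groupby(["protein_id", "channel"], sort=True)
    out = g["ratio"].agg(
        mean_ratio="mean",
        sd=lambda v: v.std(ddof=1),
        n_workflow_reps="size",
    )
    out["total_sc"] = g["workflow_sc"].sum()
    out = out[out["n_workflow_reps"] >= min_workflow_reps].reset_index()
    if (out["mean_ratio"] <= 0).any():
        raise ValueError("non-positive mean ratio encountered; ratios must be > 0")
    out["cv"] = out["sd"] / out["mean_ratio"]
    return out.drop(columns="sd")


def technical_cv(quants: pd.DataFrame) -> pd.DataFrame:
    """Per (protein, channel, workflow replicate) CV across technical reps.

    Restricted to proteins quantified in >= 2 technical replicates within
    the workflow replicate.
    """
    g = quants.groupby(["protein_id", "channel", "workflow_rep"], sort=True)
    out = g["ratio"].agg(
        mean_ratio="mean",
        sd=lambda v: v.std(ddof=1),
        n_technical="size",
    )
    out = out[out["n_technical"] >= 2].reset_index()
    if (out["mean_ratio"] <= 0).any():
        raise ValueError("non-positive mean ratio encountered; ratios must be > 0")
    out["cv"] = out["sd"] / out["mean_ratio"]
    return out.drop(columns="sd")


@dataclass
class CvDistribution:
    """Binned CV histogram plus the empirical quantile function."""

    cvs: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    def quantile(self, q: float, mode: str = "linear") -> float:
        """CV threshold below which a fraction ``q`` of proteins fall.

        ``mode='linear'`` interpolates between order statistics;
        ``mode='nearest_rank'`` returns the ceil(q*n)-th order statistic.
        """
        if mode == "linear":
            return float(np.quantile(self.cvs, q))
        if mode == "nearest_rank":
            return float(np.quantile(self.cvs, q, method="inverted_cdf"))
        raise ValueError("mode must be 'linear' or 'nearest_rank'")

    def fraction_below(self, threshold: float) -> float:
        """Empirical cumulative frequency: fraction of CVs < threshold."""
        return float(np.mean(self.cvs < threshold))


def cv_distribution(cvs, bin_width: float = 0.05, max_cv: float | None = None) -> CvDistribution:
    """Histogram + quantile view of a collection of per-protein CVs."""
    arr = np.sort(np.asarray(list(cvs), dtype=float))
    if arr.size == 0:
        raise ValueError("no CV values supplied")
    if np.any(arr < 0):
        raise ValueError("CVs must be >= 0")
    top = max_cv if max_cv is not None else max(arr.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    return CvDistribution(cvs=arr, bin_edges=edges, counts=counts)


def cv_vs_spectral_count(
    cv_table: pd.DataFrame, bin_edges
) -> pd.DataFrame:
    """Mean CV per spectral-count bin.

    ``cv_table`` needs ``cv`` and ``total_sc`` columns (the output of
    :func:`workflow_cv`).  Bins are right-open except the last.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D sequence")
    binned = pd.cut(cv_table["total_sc"], bins=edges, include_lowest=True)
    out = (
        cv_table.groupby(binned, observed=False)["cv"]
        .agg(mean_cv="mean", n_proteins="size")
        .reset_index()
        .rename(columns={"total_sc": "sc_bin"})
    )
    return out


def log2_sd_distribution(quants: pd.DataFrame, min_workflow_reps: int = 2) -> pd.DataFrame:
    """Per-protein sample SD of log2-transformed per-workflow-replicate ratios."""
    means = workflow_replicate_means(quants)
    means["log2_ratio"] = np.log2(means["ratio"])
    g = means.groupby(["protein_id", "channel"], sort=True)["log2_ratio"]
    out = g.agg(
        mean_log2_ratio="mean",
        sd_log2=lambda v: v.std(ddof=1),
        n_workflow_reps="size",
    ).reset_index()
    return out[out["n_workflow_reps"] >= min_workflow_reps].reset_index(drop=True)


def _anova_one(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA P value with the degenerate convention.

    If every group has zero within-group variance: P=1 when the group
    means are equal (nothing to distinguish), P=0 otherwise.
    """
    within = sum(float(np.var(g, ddof=0)) * len(g) for g in groups)
    if within == 0.0:
        gm = [float(np.mean(g)) for g in groups]
        if np.ptp(gm) == 0.0:
            logger.debug("ANOVA degenerate: zero variance, equal means -> P=1")
            return 1.0
        return 0.0
    return float(stats.f_oneway(*groups).pvalue)


def anova_across_workflows(
    quants: pd.DataFrame,
    alpha: float = 0.05,
    log2: bool = False,
    min_workflow_reps: int = 2,
    min_technical_reps: int = 2,
) -> pd.DataFrame:
    """Per-protein one-way ANOVA with workflow replicate as the factor.

    Observations are the technical-replicate ratios.  A protein/channel is
    called consistent across workflow replicates iff P >= ``alpha``.
    Requires >= ``min_workflow_reps`` workflow replicates each holding
    >= ``min_technical_reps`` ratio observations.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    work = quants.copy()
    work["obs"] = np.log2(work["ratio"]) if log2 else work["ratio"]
    rows = []
    for (pid, ch), grp in work.groupby(["protein_id", "channel"], sort=True):
        groups = [
            sub["obs"].to_numpy(dtype=float)
            for _, sub in grp.groupby("workflow_rep", sort=True)
            if len(sub) >= min_technical_reps
        ]
        if len(groups) < min_workflow_reps:
            continue
        p = _anova_one(groups)
        rows.append(
            {
                "protein_id": pid,
                "channel": int(ch),
                "p_value": p,
                "consistent": bool(p >= alpha),
                "n_groups": len(groups),
                "n_obs": int(sum(len(g) for g in groups)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "channel", "p_value", "consistent", "n_groups", "n_obs"],
    )
    if len(out):
        logger.info(
            "ANOVA: %.1f%% of %d protein x channel tests consistent at alpha=%g",
            100.0 * out["consistent"].mean(),
            len(out),
            alpha,
        )
    return out


def consistent_fraction(anova_table: pd.DataFrame) -> float:
    """Fraction of proteins with every tested channel consistent."""
    if anova_table.empty:
        raise ValueError("empty ANOVA table")
    per_protein = anova_table.groupby("protein_id")["consistent"].all()
    return float(per_protein.mean())


def summarize_variation(
    quants: pd.DataFrame,
    reference_channel: int = 114,
    min_workflow_reps: int = 2,
    quantiles=_DEFAULT_QUANTILES,
    quantile_mode: str = "linear",
) -> VarianceSummary:
    """Full variance decomposition of a quant table.

    ``s_b`` is the mean per-protein workflow CV pooled over the three
    non-reference channels (proteins quantified in at least
    ``min_workflow_reps`` workflow replicates); ``s_t`` is the mean
    technical CV over proteins, channels and workflow replicates
    (proteins quantified in at least two runs of a workflow).
    """
    wcv = workflow_cv(quants, min_workflow_reps=min_workflow_reps)
    tcv = technical_cv(quants)
    per_channel = {
        int(ch): (float(sub["cv"].mean()), float(sub["cv"].median()))
        for ch, sub in wcv.groupby("channel")
    }
    dist = cv_distribution(wcv["cv"]) if len(wcv) else None
    s_b = float(wcv["cv"].mean()) if len(wcv) else float("nan")
    s_t = float(tcv["cv"].mean()) if len(tcv) else float("nan")
    summary = VarianceSummary(
        reference_channel=reference_channel,
        per_channel_cv=per_channel,
        cumulative_cv_quantiles={
            float(q): dist.quantile(q, mode=quantile_mode) for q in quantiles
        }
        if dist
        else {},
        s_b=s_b,
        s_t=s_t,
        n_proteins_used={
            f"s_b (quantified in >= {min_workflow_reps} workflow replicates)": int(
                wcv["protein_id"].nunique()
            ),
            "s_t (quantified in >= 2 technical replicates of a workflow)": int(
                tcv["protein_id"].nunique()
            ),
        },
    )
    logger.info(
        "variance summary: S_b=%.4f (N=%d), S_t=%.4f (N=%d), reference %d",
        summary.s_b,
        wcv["protein_id"].nunique() if len(wcv) else 0,
        summary.s_t,
        tcv["protein_id"].nunique() if len(tcv) else 0,
        reference_channel,
    )
    return summary


def cohort_summary(quants: pd.DataFrame) -> pd.DataFrame:
    """Mean/median workflow CV split by number of workflow replicates.

    Separates proteins quantified in exactly two workflow replicates from
    those quantified in all available ones, the two cohorts whose pooled
    union drives the overall variance estimate.
    """
    wcv = workflow_cv(quants, min_workflow_reps=2)
    out = (
        wcv.groupby(["n_workflow_reps", "channel"])["cv"]
        .agg(mean_cv="mean", median_cv="median", n_proteins="size")
        .reset_index()
    )
    return out
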