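"""ExE-hyper-CGI methylation scoring.

A pan-cancer hypermethylation signature at CpG islands associated with
extra-embryonic ectoderm (ExE) is summarised per sample as a two-stage
mean: the mean beta of the interrogated CpGs inside each signature CpG
island, averaged over islands.  Signature intervals that do not coincide
with island coordinates are first mapped to the closest island on the
same chromosome.  Samples are classified against an upper bound derived
from the normal samples, and group differences are tested with a
Wilcoxon rank-sum test with continuity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, CpGAnnotation, RegionSet, ValidationError

logger = logging.getLogger("regmeth")

Z_95 = 1.959964


def assign_closest_cgi(intervals: RegionSet, cgis: RegionSet) -> pd.DataFrame:
    """Map each query interval to the closest CpG island.

    Distance is the gap between intervals (0 when overlapping) on the
    same chromosome; ties go to the island with the lower start, then
    the lexically smaller name.  Intervals on chromosomes without any
    island are dropped with a logged count.
    """
    if len(cgis) == 0:
        raise ValidationError("empty CGI collection")
    cgi_by_chrom = dict(tuple(cgis.intervals.groupby("chrom", sort=True)))
    rows = []
    dropped = 0
    for _, iv in intervals.intervals.iterrows():
        sub = cgi_by_chrom.get(iv["chrom"])
        if sub is None:
            dropped += 1
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        gap = np.maximum(starts - iv["end"], iv["start"] - ends)
        gap = np.maximum(gap, 0)
        best = np.lexsort((sub["name"].to_numpy(), starts, gap))[0]
        rows.append(
            (
                iv["name"], iv["chrom"], iv["start"], iv["end"],
                sub.iloc[best]["name"], int(gap[best]),
            )
        )
    if dropped:
        logger.info("dropped %d intervals on chromosomes without CGIs", dropped)
    return pd.DataFrame(
        rows,
        columns=["interval", "chrom", "start", "end", "cgi", "distance"],
    )


def compute_exe_scores(
    beta: BetaMatrix,
    annotation: CpGAnnotation,
    cgis: RegionSet,
    cgi_names: pd.Series | list | None = None,
) -> pd.Series:
    """Per-sample two-stage mean methylation over the mapped CGIs.

    For every island (optionally restricted to ``cgi_names``, e.g. the
    ``cgi`` column of :func:`assign_closest_cgi`), the unweighted mean
    beta of the interrogated CpGs inside it is computed per sample; the
    score is the unweighted mean of those island means.  Islands without
    interrogated CpGs are dropped with a logged count.
    """
    wanted = cgis.intervals
    if cgi_names is not None:
        names = set(cgi_names)
        wanted = wanted[wanted["name"].isin(names)]
    if wanted.empty:
        raise ValidationError("no CGIs to score")

    chroms = annotation.frame["chrom"].to_numpy()
    pos = annotation.frame["pos"].to_numpy()
    cpg_ids = np.array(annotation.cpg_ids)
    island_means = []
    skipped = 0
    for _, cgi in wanted.drop_duplicates("name").iterrows():
        inside = (
            (chroms == cgi["chrom"]) & (pos - 1 >= cgi["start"]) & (pos - 1 < cgi["end"])
        )
        members = cpg_ids[inside]
        members = [m for m in members if m in beta.frame.index]
        if not members:
            skipped += 1
            continue
        island_means.append(beta.frame.loc[members].mean(axis=0))
    if skipped:
        logger.info("dropped %d CGIs without interrogated CpGs", skipped)
    if not island_means:
        raise ValidationError("no CGI contains interrogated CpGs")
    scores = pd.concat(island_means, axis=1).mean(axis=1)
    scores.name = "exe_score"
    return scores


def normal_upper_limit(
    normal_scores: pd.Series | np.ndarray, level: float = 0.95, ci_mode: str = "samples"
) -> float:
    """Upper bound of the normal samples' score distribution.

    Default ``ci_mode='samples'`` returns mean + z * sd over the
    per-sample scores (an interval over samples, suitable for
    classifying individual samples); ``ci_mode='mean'`` returns
    mean + z * sd / sqrt(n), the upper confidence limit of the mean.
    """
    arr = np.asarray(normal_scores, dtype=float)
    if arr.size < 2:
        raise ValidationError("need >= 2 normal samples for the threshold")
    z = stats.norm.ppf(0.5 + level / 2.0)
    sd = float(arr.std(ddof=1))
    if sd == 0:
        logger.info("zero variance among normal scores; threshold equals common value")
    if ci_mode == "mean":
        return float(arr.mean() + z * sd / math.sqrt(arr.size))
    if ci_mode != "samples":
        raise ValidationError(f"unknown ci_mode {ci_mode!r}")
    return float(arr.mean() + z * sd)


def classify_scores(scores: pd.Series, tau: float) -> pd.DataFrame:
    """Score table with above/below classification against threshold tau."""
    return pd.DataFrame(
        {
            "score": scores,
            "class": np.where(scores > tau, "above", "below"),
        }
    )


@dataclass
class RankSumResult:
    W: float   # rank-sum statistic of the first sample
    p: float   # two-sided


def wilcoxon_rank_sum(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    continuity: bool = True,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact permutation distribution when both samples have at
    most 25 observations and there are no ties; otherwise the normal
    approximation with tie correction and (by default) a 0.5 continuity
    correction.  W is the rank sum of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return RankSumResult(W=w, p=float(res.pvalue))
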