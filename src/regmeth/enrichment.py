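"""Enrichment analyses for differentially methylated CpGs.

Three complementary views:

* locus-overlap enrichment -- for each curated region set, a two-sided
  Fisher's exact test of DM CpGs against the array universe, reported as
  odds ratios with a log-odds-ratio effect threshold;
* genomic-feature distribution -- Pearson residuals of the DM CpG counts
  over the feature-group x CGI-relation cross-classification, relative
  to the universe composition;
* preranked set enrichment (GSEA) -- a weighted Kolmogorov-Smirnov
  running sum over a moderated-t-ranked feature list, with a
  set-membership permutation null.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CpGAnnotation, RegionSetCollection, ValidationError
from .diffmeth import adjust_fdr_bh

logger = logging.getLogger("regmeth")


class DegenerateTableError(ValidationError):
    """A 2x2 table with an empty margin cannot be tested."""


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, log_odds_ratio, p).  The two-sided p-value sums
    hypergeometric probabilities at most (1 + 1e-7) times the observed
    table's probability, with margins fixed.  The odds ratio is the
    cross-product ad/bc; when any cell is zero the Haldane-Anscombe 0.5
    continuity correction is applied to the odds ratio (never to p).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValidationError(f"counts must be non-negative integers, got {v}")
    n = a + b + c + d
    if a + b == 0 or a + c == 0 or c + d == 0 or b + d == 0:
        raise DegenerateTableError(f"degenerate 2x2 table ({a}, {b}, {c}, {d})")

    lo = max(0, (a + b) + (a + c) - n)
    hi = min(a + b, a + c)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf with margins fixed, via log-gamma for speed
    lg = special.gammaln
    log_comb = (
        lg(a + c + 1) - lg(support + 1) - lg(a + c - support + 1)
        + lg(b + d + 1) - lg(a + b - support + 1) - lg(b + d - (a + b) + support + 1)
        - (lg(n + 1) - lg(a + b + 1) - lg(n - a - b + 1))
    )
    pmf = np.exp(log_comb)
    p = float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())
    p = min(p, 1.0)

    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return orr, math.log(orr), p


def locus_overlap_enrichment(
    query_cpgs: Iterable[str],
    universe_cpgs: Iterable[str],
    annotation: CpGAnnotation,
    regions: RegionSetCollection,
    logor_threshold: float = 0.6,
    fdr_threshold: float = 0.05,
    logor_base: float = math.e,
) -> pd.DataFrame:
    """Fisher locus-overlap enrichment of a CpG query against region sets.

    A CpG overlaps a set iff its 1-based position lies inside any of the
    set's intervals (BED half-open convention).  One two-sided Fisher
    test per set over the query / universe-complement split, BH-adjusted
    across sets, flagged enriched (logOR > threshold), depleted
    (logOR < -threshold) or neither, significance requiring
    q < fdr_threshold.
    """
    query = set(query_cpgs)
    universe = list(dict.fromkeys(universe_cpgs))
    if not query:
        raise ValidationError("empty query CpG set")
    if not query <= set(universe):
        extra = sorted(query - set(universe))[:5]
        raise ValidationError(f"query CpGs outside universe: {extra}")

    sub = annotation.frame.loc[universe]
    chroms = sub["chrom"].to_numpy()
    pos = sub["pos"].to_numpy()
    in_query = np.array([cpg in query for cpg in universe])

    log_base = math.log(logor_base)
    rows = []
    for name in regions.names:
        in_set = regions[name].contains_points(chroms, pos)
        a = int((in_query & in_set).sum())
        b = int((in_query & ~in_set).sum())
        c = int((~in_query & in_set).sum())
        d = int((~in_query & ~in_set).sum())
        orr, log_or, p = fisher_exact_two_sided(a, b, c, d)
        rows.append((name, a, b, c, d, orr, log_or / log_base, p))
    table = pd.DataFrame(
        rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "log_odds_ratio", "p"]
    )
    table["q"] = adjust_fdr_bh(table["p"].to_numpy())
    status = np.where(
        (table["q"] < fdr_threshold) & (table["log_odds_ratio"] > logor_threshold),
        "enriched",
        np.where(
            (table["q"] < fdr_threshold) & (table["log_odds_ratio"] < -logor_threshold),
            "depleted",
            "neither",
        ),
    )
    table["status"] = status
    return table


def feature_distribution_residuals(
    dm_calls: pd.Series,
    annotation: CpGAnnotation,
    directions: Sequence[str] = ("hyper", "hypo"),
    z_threshold: float = 1.959964,
) -> pd.DataFrame:
    """Pearson residuals of DM CpG counts over feature x CGI classes.

    Observed counts are DM CpGs per (feature_group, cgi_relation) cell;
    expected counts are the universe composition scaled to the DM total.
    Residuals r = (O - E) / sqrt(E); |r| above the 95% normal bound are
    flagged.  Cells absent from the universe get E = 0 and r = 0.
    """
    dm_ids = dm_calls.index[dm_calls.isin(directions)]
    if len(dm_ids) == 0:
        raise ValidationError("no DM CpGs for residual analysis")
    feature = annotation.primary_feature()
    cgi = annotation.frame["cgi_relation"]
    universe = pd.crosstab(feature, cgi)
    observed = pd.crosstab(feature.loc[dm_ids], cgi.loc[dm_ids])
    observed = observed.reindex(index=universe.index, columns=universe.columns, fill_value=0)
    expected = universe / universe.to_numpy().sum() * len(dm_ids)

    rows = []
    for f in universe.index:
        for g in universe.columns:
            e = float(expected.loc[f, g])
            o = int(observed.loc[f, g])
            r = (o - e) / math.sqrt(e) if e > 0 else 0.0
            rows.append((f, g, o, e, r, abs(r) > z_threshold))
    return pd.DataFrame(
        rows,
        columns=["feature_group", "cgi_relation", "observed", "expected", "residual", "flagged"],
    )


def build_direction_cpg_sets(
    stats_frame: pd.DataFrame,
    delta_min: float = 0.2,
    max_size: int = 2999,
) -> dict[str, list[str]]:
    """Hyper- and hypomethylated CpG sets from a DM table.

    Qualifying CpGs are those called in the direction with
    |delta beta| > delta_min; when more than ``max_size`` qualify, the
    top ``max_size`` by |delta beta| are kept (ties broken by smaller p,
    then lexically by id).
    """
    sets: dict[str, list[str]] = {}
    for direction in ("hyper", "hypo"):
        sub = stats_frame[
            (stats_frame["call"] == direction)
            & (stats_frame["delta_beta"].abs() > delta_min)
        ].copy()
        if sub.empty:
            logger.warning("no qualifying CpGs for %s set", direction)
            sets[direction] = []
            continue
        sub["_abs"] = sub["delta_beta"].abs()
        sub["_id"] = sub.index
        sub = sub.sort_values(["_abs", "p", "_id"], ascending=[False, True, True])
        sets[direction] = list(sub.index[:max_size])
    return sets


def _sample_hit_positions(
    rng: np.random.Generator, n: int, k: int, n_perm: int
) -> np.ndarray:
    """(n_perm, k) sorted random k-subsets of range(n)."""
    chunk = max(1, int(4_000_000 // max(n, 1)))
    out = np.empty((n_perm, k), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        r = rng.random((b, n))
        part = np.argpartition(r, k - 1, axis=1)[:, :k]
        part.sort(axis=1)
        out[done : done + b] = part
        done += b
    return out


def _running_sum_extrema(
    positions: np.ndarray, weights_ranked: np.ndarray, miss_dec: float
) -> np.ndarray:
    """ES for each row of sorted hit positions (2-D) or one set (1-D)."""
    single = positions.ndim == 1
    pos = np.atleast_2d(positions)
    w = weights_ranked[pos]
    wsum = w.sum(axis=1, keepdims=True)
    # all-zero weight rows fall back to unweighted hits
    zero = wsum[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    w = w / wsum
    cumw = np.cumsum(w, axis=1)
    i = np.arange(pos.shape[1])[None, :]
    at_hit = cumw - (pos - i) * miss_dec
    before_hit = at_hit - w
    pos_ext = at_hit.max(axis=1)
    neg_ext = before_hit.min(axis=1)
    es = np.where(np.abs(pos_ext) >= np.abs(neg_ext), pos_ext, neg_ext)
    return es[0] if single else es


def gsea_enrichment_score(
    scores: pd.Series,
    members: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[str]]:
    """Weighted KS running-sum enrichment score for one set.

    Features are ranked by decreasing score (ties broken lexically by
    id).  Hits increment the running sum by |score|^w normalised over
    the set; misses decrement by 1/(N - K).  The ES is the extremum of
    the running sum by absolute value; the second return value is the
    leading edge (members at or before a positive extremum, at or after
    a negative one), in rank order.
    """
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    order = np.lexsort((np.array(ranked.index, dtype=object), -ranked.to_numpy()))
    ranked = ranked.iloc[order]
    names = np.array(ranked.index, dtype=object)
    member_set = set(members) & set(names)
    n = len(names)
    k = len(member_set)
    if k == 0:
        raise ValidationError("set has no scored members")
    if k == n:
        raise ValidationError("set covers every scored feature")
    hit_mask = np.array([x in member_set for x in names])
    positions = np.flatnonzero(hit_mask)
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    miss_dec = 1.0 / (n - k)
    es = float(_running_sum_extrema(positions, weights, miss_dec))

    # leading edge
    w = weights[positions]
    wsum = w.sum()
    w = w / wsum if wsum > 0 else np.full(k, 1.0 / k)
    cumw = np.cumsum(w)
    i = np.arange(k)
    at_hit = cumw - (positions - i) * miss_dec
    before_hit = at_hit - w
    if es >= 0:
        ext = int(np.argmax(at_hit))
        leading = [str(x) for x in names[positions[: ext + 1]]]
    else:
        ext = int(np.argmin(before_hit))
        leading = [str(x) for x in names[positions[ext:]]]
    return es, leading


def preranked_gsea(
    scores: pd.Series,
    sets: Mapping[str, Iterable[str]],
    weight_exponent: float = 1.0,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked set enrichment over a scored feature list.

    The null distribution permutes set membership: for each set size,
    ``n_perm`` random same-size subsets of the ranked features.  The
    nominal p is the same-signed tail fraction (with add-one smoothing,
    so p >= 1/(n_perm + 1)); NES divides the ES by the mean |permuted
    ES| of the same sign; q is BH across sets.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    order = np.lexsort((np.array(ranked.index, dtype=object), -ranked.to_numpy()))
    ranked = ranked.iloc[order]
    names = np.array(ranked.index, dtype=object)
    name_pos = {x: i for i, x in enumerate(names)}
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    n = len(names)

    rng = np.random.default_rng(seed)
    perm_cache: dict[int, np.ndarray] = {}
    rows = []
    for set_name in sets:
        member_set = set(sets[set_name]) & set(names)
        k = len(member_set)
        if k == 0:
            logger.warning("set %s has no scored members; skipped", set_name)
            continue
        if k == n:
            raise ValidationError(f"set {set_name} covers every scored feature")
        es, leading = gsea_enrichment_score(
            pd.Series(ranked), member_set, weight_exponent
        )
        if k not in perm_cache:
            perm_cache[k] = _sample_hit_positions(rng, n, k, n_perm)
        miss_dec = 1.0 / (n - k)
        perm_es = _running_sum_extrema(perm_cache[k], weights, miss_dec)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = math.nan
        else:
            p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            denom = float(np.abs(perm_es[same_sign]).mean())
            nes = es / denom if denom > 0 else math.nan
        rows.append((set_name, k, es, nes, p, ";".join(leading)))

    table = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p", "leading_edge"]
    )
    if len(table):
        table["q"] = adjust_fdr_bh(table["p"].to_numpy())
    else:
        table["q"] = []
    return table
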