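"""CSS normalization, alpha-diversity, dissimilarity, PERMANOVA, SIMPER.

Cumulative sum scaling (CSS) divides each sample's counts by the sum of its
counts up to a chosen quantile of the positive counts, then rescales to a
common constant. Unlike total-sum scaling it is robust to a handful of
dominant taxa inflating the library size. The quantile is fixed (default
median of the positive counts) rather than searched adaptively, which keeps
the transform deterministic and easy to reason about on small tables.

PERMANOVA here is the one-factor pseudo-F test on a distance matrix, with
permutations optionally restricted to strata (e.g. field blocks) so that
labels are never exchanged across spatial units, and an exact mode that
enumerates every distinct label arrangement for small n.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import CountTable, TableError

logger = logging.getLogger(__name__)

METRICS = ("bray_curtis", "euclidean", "jaccard")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedTable:
    """Taxa x samples matrix of normalized (real-valued) abundances."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scaling_factors: np.ndarray
    method_tag: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)


def css_normalize(
    ct: CountTable, quantile_l: float = 0.5, scale_to: float = 1000.0
) -> NormalizedTable:
    """Cumulative sum scaling.

    For each sample: let q be the nearest-rank ``quantile_l`` quantile of
    the sample's positive counts (rank ``ceil(l * n)``). The scaling factor
    is the sum of all counts <= q, and every count is divided by it and
    multiplied by ``scale_to``. Zeros stay zero.
    """
    if not 0 < quantile_l <= 1:
        raise TableError("quantile_l must be in (0, 1]")
    counts = ct.counts.astype(float)
    n_samples = counts.shape[1]
    factors = np.empty(n_samples)
    for j in range(n_samples):
        col = counts[:, j]
        positive = np.sort(col[col > 0])
        if positive.size == 0:
            raise TableError(f"sample {ct.sample_ids[j]!r} has no positive counts")
        rank = math.ceil(quantile_l * positive.size)
        q = positive[rank - 1]
        factors[j] = col[col <= q].sum()
    values = counts / factors[None, :] * scale_to
    return NormalizedTable(
        list(ct.taxon_ids), list(ct.sample_ids), values, factors, "css"
    )


def relative_abundance(ct: CountTable) -> NormalizedTable:
    """Per-sample relative abundances (columns sum to 1)."""
    counts = ct.counts.astype(float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        j = int(np.argmax(totals == 0))
        raise TableError(f"sample {ct.sample_ids[j]!r} has no positive counts")
    return NormalizedTable(
        list(ct.taxon_ids), list(ct.sample_ids), counts / totals, totals, "relative"
    )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1)/(2(f2+1)).

    f1 and f2 are the numbers of singleton and doubleton taxa. Returns NaN
    for an empty or all-zero sample.
    """
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        return float("nan")
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def alpha_diversity(ct: CountTable) -> pd.DataFrame:
    """Per-sample Chao1, Shannon H (nats), Simpson 1 - sum(p^2), Pielou J.

    J = H / ln(S_obs); NaN when a sample has fewer than two observed taxa.
    """
    rows = []
    for j, sid in enumerate(ct.sample_ids):
        col = ct.counts[:, j]
        total = col.sum()
        if total == 0:
            raise TableError(f"sample {sid!r} has no positive counts")
        p = col[col > 0] / total
        h = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        s_obs = p.size
        pielou = h / math.log(s_obs) if s_obs > 1 else float("nan")
        rows.append(
            {
                "sample_id": sid,
                "chao1": chao1(col),
                "shannon": h,
                "simpson": simpson,
                "pielou": pielou,
                "observed": s_obs,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Dissimilarity
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    metric_tag: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def dissimilarity(nt: NormalizedTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample dissimilarity.

    ``bray_curtis``: sum|x-y| / sum(x+y); ``euclidean``; ``jaccard`` on
    presence/absence. A pair of all-zero samples gets distance 0 under the
    ratio metrics (logged).
    """
    if metric not in METRICS:
        raise TableError(f"unknown metric {metric!r}; options: {METRICS}")
    x = nt.values.T  # samples x taxa
    if x.shape[0] < 2:
        raise TableError("need at least two samples")
    if metric == "euclidean":
        d = pdist(x, metric="euclidean")
    elif metric == "bray_curtis":
        d = pdist(x, metric="braycurtis")
    else:
        d = pdist(x > 0, metric="jaccard")
    if np.isnan(d).any():
        logger.warning(
            "%d all-zero sample pair(s) assigned distance 0 under %s",
            int(np.isnan(d).sum()),
            metric,
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(list(nt.sample_ids), squareform(d), metric)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    stratum_label: str | None = None


def _ss_within(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    ss = 0.0
    for lev in levels:
        mask = labels == lev
        n_g = int(mask.sum())
        if n_g > 1:
            ss += d2[np.ix_(mask, mask)].sum() / (2 * n_g)
    return ss


def _pseudo_f(d2, labels, levels, ss_total):
    n = len(labels)
    a = len(levels)
    ss_w = _ss_within(d2, labels, levels)
    ss_b = ss_total - ss_w
    if ss_w == 0:
        return float("inf"), 1.0
    f = (ss_b / (a - 1)) / (ss_w / (n - a))
    return f, ss_b / ss_total if ss_total > 0 else 0.0


def permanova(
    dm: DistanceMatrix,
    grouping,
    strata=None,
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA with optional restricted permutations.

    ``grouping`` (and optionally ``strata``) are sequences aligned with the
    distance matrix's samples. The p-value uses the (1 + exceedances) /
    (1 + n_perm) estimator; with ``exact=True`` every distinct label
    arrangement (within strata) is enumerated instead and p is the exact
    exceedance fraction.
    """
    labels = np.asarray([str(g) for g in grouping])
    n = dm.matrix.shape[0]
    if len(labels) != n:
        raise TableError("grouping length does not match distance matrix")
    levels = np.unique(labels)
    if len(levels) < 2:
        raise TableError("grouping must have at least two levels")
    d2 = dm.matrix**2
    ss_total = d2.sum() / (2 * n)
    f_obs, r2 = _pseudo_f(d2, labels, levels, ss_total)

    strata_arr = (
        np.asarray([str(s) for s in strata]) if strata is not None else np.zeros(n)
    )
    strat_levels = np.unique(strata_arr)
    strat_idx = [np.flatnonzero(strata_arr == s) for s in strat_levels]

    if exact:
        count = 0
        total = 0
        for perm_labels in _enumerate_within_strata(labels, strat_idx):
            f_perm, _ = _pseudo_f(d2, perm_labels, levels, ss_total)
            total += 1
            if f_perm >= f_obs or (math.isinf(f_perm) and math.isinf(f_obs)):
                count += 1
        return PermanovaResult(f_obs, r2, count / total, total,
                               None if strata is None else "strata")

    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        for idx in strat_idx:
            perm[idx] = perm[rng.permutation(idx)]
        f_perm, _ = _pseudo_f(d2, perm, levels, ss_total)
        if f_perm >= f_obs or (math.isinf(f_perm) and math.isinf(f_obs)):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, None if strata is None else "strata")


def _enumerate_within_strata(labels: np.ndarray, strat_idx: list[np.ndarray]):
    """Yield every distinct arrangement of the label multiset within strata."""
    from sympy.utilities.iterables import multiset_permutations

    per_stratum = [
        [list(p) for p in multiset_permutations(list(labels[idx]))] for idx in strat_idx
    ]
    for combo in itertools.product(*per_stratum):
        out = labels.copy()
        for idx, arrangement in zip(strat_idx, combo):
            out[idx] = arrangement
        yield out


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


def simper(
    nt: NormalizedTable,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-taxon contributions to between-group Bray-Curtis dissimilarity.

    For a two-level grouping, each taxon's absolute contribution is the mean
    over between-group sample pairs (j, k) of |x_ij - x_ik| / sum_t(x_tj +
    x_tk). Contributions sum to the mean between-group Bray-Curtis
    dissimilarity; percents sum to 100. The permutation p-value is the
    fraction of group-label permutations whose contribution is >= observed.
    """
    labels = np.asarray([str(g) for g in grouping])
    levels = np.unique(labels)
    if len(levels) != 2:
        raise TableError("simper requires exactly two group levels")
    x = nt.values

    def contributions(lab: np.ndarray) -> np.ndarray:
        ia = np.flatnonzero(lab == levels[0])
        ib = np.flatnonzero(lab == levels[1])
        xa, xb = x[:, ia], x[:, ib]
        diff = np.abs(xa[:, :, None] - xb[:, None, :])  # taxa x nA x nB
        denom = xa.sum(axis=0)[:, None] + xb.sum(axis=0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, diff / denom, 0.0)
        return ratio.mean(axis=(1, 2))

    obs = contributions(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = contributions(rng.permutation(labels))
        exceed += perm >= obs
    p = (1 + exceed) / (1 + n_perm)
    total = obs.sum()
    percent = obs / total * 100 if total > 0 else np.zeros_like(obs)
    return pd.DataFrame(
        {
            "taxon_id": nt.taxon_ids,
            "contribution": obs,
            "percent": percent,
            "p": p,
        }
    ).set_index("taxon_id")
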