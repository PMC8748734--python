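"""Community-ecology statistics on taxon × sample count tables.

From-first-principles implementations of the alpha/beta-diversity and
group-difference toolkit used for depth-stratified marine amplicon and
miTag surveys: rarefaction to even depth, Chao1 richness, Bray-Curtis
dissimilarity, UPGMA (average-linkage) clustering with newick export,
row Z-scores for heatmaps, Kruskal-Wallis, PERMANOVA (Anderson's
pseudo-F), SIMPER decomposition, and indicator species analysis (IndVal)
with permutation p-values and the "signature species" screen
(p < 0.05 and stat ≥ 0.5).

Permutation tests accept ``n_permutations="exact"`` to enumerate every
distinct relabeling (feasible for small designs), in which case the
p-value is the exact fraction of relabelings — including the observed
one — whose statistic reaches the observed value. With random
permutations the standard ``(b + 1)/(n_perm + 1)`` estimator is used.
Statistic comparisons inside the permutation counts use a 1e-9 absolute
tolerance so that mathematically tied relabelings are not split by
floating-point noise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, NormalizationError

__all__ = [
    "rarefy",
    "chao1",
    "bray_curtis",
    "upgma",
    "Dendrogram",
    "row_zscores",
    "kruskal_wallis",
    "permanova",
    "PermanovaResult",
    "indval",
    "signature_share",
    "SignatureShare",
    "simper",
    "filter_min_count",
]

RAREFACTION_DEPTH = 15_400  # even-depth default for the bundled survey design
_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# alpha diversity


def rarefy(
    table: pd.DataFrame, depth: int = RAREFACTION_DEPTH, seed: int | None = None
) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Column sums of the result equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ConfigError("rarefaction depth must be positive")
    counts = _as_int_counts(table)
    rng = np.random.default_rng(seed)
    keep_cols, data = [], {}
    for col in counts.columns:
        total = int(counts[col].sum())
        if total < depth:
            warnings.warn(
                f"sample {col!r} has {total} < {depth} reads and was dropped",
                stacklevel=2,
            )
            continue
        data[col] = rng.multivariate_hypergeometric(counts[col].to_numpy(), depth)
        keep_cols.append(col)
    return pd.DataFrame(data, index=counts.index, columns=keep_cols)


def chao1(sample_counts, bias_corrected: bool = True) -> tuple[int, float]:
    """Observed richness and the Chao1 estimate for one sample.

    ``Chao1 = S_obs + f1(f1-1)/(2(f2+1))`` (bias-corrected, default) or the
    classic ``S_obs + f1²/(2 f2)`` when ``bias_corrected=False`` and
    doubletons exist (the bias-corrected form is used as the classic
    fallback at f2 = 0).
    """
    counts = np.asarray(sample_counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ConfigError("Chao1 requires integer counts")
        counts = np.round(counts).astype(np.int64)
    if (counts < 0).any():
        raise ConfigError("counts must be non-negative")
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        return 0, 0.0
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected or f2 == 0:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        est = s_obs + f1 * f1 / (2.0 * f2)
    return s_obs, float(est)


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(matrix: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between all sample pairs.

    ``BC(x, y) = Σ|xᵢ - yᵢ| / Σ(xᵢ + yᵢ)`` over taxa; symmetric, zero
    diagonal, values in [0, 1]. With ``normalize=True`` each sample is first
    scaled to relative abundance.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ConfigError("Bray-Curtis requires non-negative values")
    colsums = x.sum(axis=0)
    zero_cols = [matrix.columns[i] for i in np.flatnonzero(colsums == 0)]
    if len(zero_cols) >= 2:
        raise NormalizationError(
            f"Bray-Curtis undefined between all-zero samples: {zero_cols}"
        )
    if normalize:
        if zero_cols:
            raise NormalizationError(f"cannot normalize all-zero samples: {zero_cols}")
        x = x / colsums
    # n is small (samples); broadcast over pairs
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    tot = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class Dendrogram:
    """An average-linkage merge tree.

    ``linkage`` follows the scipy convention (rows: left id, right id,
    merge height, cluster size); node heights equal the average-linkage
    dissimilarity at which the merge happened, and newick branch lengths
    are parent-minus-child height differences (leaves sit at height 0).
    """

    linkage: np.ndarray
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def newick(self, precision: int = 10) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: str(self.labels[i]) for i in range(n)}
        for row_idx, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            nid = n + row_idx
            la = h - height[a]
            lb = h - height[b]
            node[nid] = (
                f"({node[a]}:{la:.{precision}f},{node[b]}:{lb:.{precision}f})"
            )
            height[nid] = h
        root = n + len(self.linkage) - 1 if len(self.linkage) else 0
        return node[root] + ";"


def upgma(dissimilarity: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a dissimilarity matrix.

    At each step the pair of clusters with the smallest average
    between-member dissimilarity is merged; ties are broken by the smallest
    (row, column) index pair for determinism. Ultrametric input is
    reproduced exactly.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ConfigError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ConfigError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ConfigError("dissimilarity must have a zero diagonal")
    labels = list(dissimilarity.columns) if isinstance(dissimilarity, pd.DataFrame) else list(
        range(d.shape[0])
    )
    n = d.shape[0]
    if n < 2:
        raise ConfigError("need at least two samples to cluster")

    work = d.copy()
    np.fill_diagonal(work, np.inf)
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    cluster_id = {i: i for i in range(n)}  # position in work -> node id
    pos_of = {i: i for i in range(n)}
    rows = []
    next_id = n
    # keep a growing matrix indexed by active positions
    mat = work
    act = np.ones(n, dtype=bool)
    ids = np.arange(n)
    heights = {i: 0.0 for i in range(n)}
    # mat grows by appending merged rows
    for _ in range(n - 1):
        sub = np.where(act[:, None] & act[None, :], mat, np.inf)
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        if i > j:
            i, j = j, i
        h = mat[i, j]
        a, b = int(ids[i]), int(ids[j])
        new_size = size[a] + size[b]
        rows.append([a, b, float(h), new_size])
        # average-linkage update against every other active cluster
        others = np.flatnonzero(act)
        others = others[(others != i) & (others != j)]
        new_d = (size[a] * mat[i, others] + size[b] * mat[j, others]) / new_size
        act[i] = act[j] = False
        mat = np.pad(mat, ((0, 1), (0, 1)), constant_values=np.inf)
        act = np.append(act, True)
        ids = np.append(ids, next_id)
        mat[-1, others] = new_d
        mat[others, -1] = new_d
        size[next_id] = new_size
        heights[next_id] = float(h)
        next_id += 1
    return Dendrogram(linkage=np.asarray(rows, dtype=float), labels=labels)


def row_zscores(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization: (value − row mean) / row sd (ddof = 1).

    Constant rows become all-zero with a warning; a single-column matrix is
    an error (sd undefined).
    """
    if matrix.shape[1] < 2:
        raise ConfigError("row Z-scores need at least two columns")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(
            f"{len(constant)} constant rows set to zero: {constant[:5]}", stacklevel=2
        )
    safe_sd = sd.replace(0, 1.0)
    z = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z


# ---------------------------------------------------------------------------
# group-difference tests


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-ranks, tie-corrected) with a χ² p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ConfigError("values and groups must align")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ConfigError("Kruskal-Wallis needs at least two groups")
    n = values.size
    ranks = sps.rankdata(values)
    h = 0.0
    for g in uniq:
        r = ranks[groups == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if tie_term >= 1.0:  # all observations tied
        return 0.0, 1.0
    h /= 1.0 - tie_term
    p = float(sps.chi2.sf(h, len(uniq) - 1))
    return float(h), p


def _as_int_counts(table: pd.DataFrame) -> pd.DataFrame:
    vals = table.to_numpy()
    if (vals < 0).any():
        raise ConfigError("counts must be non-negative")
    if not np.allclose(vals, np.round(vals)):
        raise ConfigError("counts must be integers")
    return table.round().astype(np.int64)


def _group_codes(groups) -> tuple[np.ndarray, list]:
    groups = pd.Series(list(groups))
    levels = sorted(groups.unique())
    codes = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    return codes, levels


def _distinct_labelings(codes: np.ndarray) -> np.ndarray:
    """All distinct permutations of a label vector (rows), observed first."""
    seen = {tuple(codes)}
    out = [tuple(codes)]
    for perm in itertools.permutations(codes):
        if perm not in seen:
            seen.add(perm)
            out.append(perm)
    return np.asarray(out, dtype=np.int64)


def _random_labelings(codes: np.ndarray, n_perm: int, rng) -> np.ndarray:
    return rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)


@dataclass(frozen=True)
class PermanovaResult:
    statistic: float  # pseudo-F
    r2: float
    p_value: float
    n_permutations: int
    method: str


def _permanova_f(d2: np.ndarray, labelings: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for each labeling (rows of ``labelings``), vectorized."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(labelings.shape[0])
    for g in range(n_groups):
        mask = (labelings == g).astype(float)  # (P, N)
        ng = mask.sum(axis=1)
        quad = np.einsum("pi,ij,pj->p", mask, d2, mask)
        ss_within += quad / (2.0 * np.where(ng > 0, ng, 1.0))
    ss_among = ss_total - ss_within
    k = n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (k - 1)) / (ss_within / (n - k))
    return f


def permanova(
    dissimilarity: pd.DataFrame,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance (pseudo-F).

    Uses the sums-of-squared-dissimilarities formulation:
    ``SS_total = Σ_{i<j} d²ᵢⱼ / N``, ``SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g``,
    ``F = (SS_among/(k−1)) / (SS_within/(N−k))``. Significance comes from
    freely permuting sample labels; pass ``n_permutations="exact"`` to
    enumerate every distinct labeling.
    """
    d = np.asarray(dissimilarity, dtype=float)
    codes, levels = _group_codes(groups)
    if d.shape[0] != d.shape[1] or d.shape[0] != codes.size:
        raise ConfigError("dissimilarity and groups must align")
    if len(levels) < 2:
        raise ConfigError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        warnings.warn("groups with a single sample present", stacklevel=2)
    d2 = d**2
    obs = float(_permanova_f(d2, codes[None, :], len(levels))[0])
    n = d.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    sw = _ss_within(d2, codes, len(levels))
    r2 = (ss_total - sw) / ss_total

    if n_permutations == "exact":
        labelings = _distinct_labelings(codes)
        f_perm = _permanova_f(d2, labelings, len(levels))
        p = float(np.mean(f_perm >= obs - _TIE_TOL))
        return PermanovaResult(obs, float(r2), p, labelings.shape[0], "exact")
    n_perm = int(n_permutations)
    if n_perm < 1:
        raise ConfigError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    labelings = _random_labelings(codes, n_perm, rng)
    f_perm = _permanova_f(d2, labelings, len(levels))
    b = int(np.sum(f_perm >= obs - _TIE_TOL))
    p = (b + 1) / (n_perm + 1)
    return PermanovaResult(obs, float(r2), float(p), n_perm, "random")


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    sw = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            sw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return sw


# ---------------------------------------------------------------------------
# indicator species analysis


def _indval_stats(
    x: np.ndarray, presence: np.ndarray, labelings: np.ndarray, k: int,
    group_equalized: bool,
) -> np.ndarray:
    """Max-over-groups IndVal statistic per taxon per labeling.

    Returns (taxa, labelings) array; used for both observed and permuted
    labelings.
    """
    n_lab = labelings.shape[0]
    stats_all = np.empty((x.shape[0], n_lab))
    # weight matrices: mean within group (means for A and for B via presence)
    for start in range(0, n_lab, 256):  # chunk to bound memory
        chunk = labelings[start : start + 256]
        p = chunk.shape[0]
        w = np.zeros((x.shape[1], p * k))
        for g in range(k):
            mask = chunk == g  # (p, N)
            ng = mask.sum(axis=1).astype(float)
            cols = np.arange(p) * k + g
            w[:, cols] = (mask / ng[:, None]).T
        gm = x @ w  # (t, p*k) group means
        gm = gm.reshape(x.shape[0], p, k)
        pres = (presence @ w).reshape(x.shape[0], p, k)  # fidelity B
        if group_equalized:
            denom = gm.sum(axis=2, keepdims=True)
        else:
            # classic variant: weight groups by their sizes (group totals)
            sizes = np.zeros((1, p, k))
            for g in range(k):
                sizes[0, :, g] = (chunk == g).sum(axis=1)
            gm = gm * sizes
            denom = gm.sum(axis=2, keepdims=True)
        a = np.divide(gm, denom, out=np.zeros_like(gm), where=denom > 0)
        stat = np.sqrt(a * pres).max(axis=2)
        stats_all[:, start : start + 256] = stat
    return stats_all


def indval(
    table: pd.DataFrame,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = None,
    group_equalized: bool = True,
) -> pd.DataFrame:
    """Indicator species analysis with a site-label permutation null.

    For each taxon and group *k*: specificity ``A = m̄ₖ / Σⱼ m̄ⱼ`` over
    group mean abundances (the group-equalized variant; set
    ``group_equalized=False`` for the classic total-abundance weighting),
    fidelity ``B`` = fraction of the group's sites where the taxon occurs,
    and ``stat = max_k √(A·B)`` with the best group reported. p-values
    count permuted statistics reaching the observed one; with
    ``n_permutations="exact"`` every distinct labeling is enumerated.

    Returns
    -------
    pandas.DataFrame
        Indexed by taxon: ``best_group``, ``A``, ``B``, ``stat``,
        ``p_value``.
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ConfigError("abundances must be non-negative")
    codes, levels = _group_codes(groups)
    if codes.size != x.shape[1]:
        raise ConfigError("groups must align with the table's samples")
    if len(levels) < 2:
        raise ConfigError("indicator analysis needs at least two groups")
    if (np.bincount(codes) == 0).any():
        raise ConfigError("empty group")
    k = len(levels)
    presence = (x > 0).astype(float)

    # observed A, B, stat, best group
    gm = np.stack([x[:, codes == g].mean(axis=1) for g in range(k)], axis=1)
    pres = np.stack([presence[:, codes == g].mean(axis=1) for g in range(k)], axis=1)
    if group_equalized:
        weighted = gm
    else:
        weighted = gm * np.bincount(codes)[None, :]
    denom = weighted.sum(axis=1, keepdims=True)
    a = np.divide(weighted, denom, out=np.zeros_like(weighted), where=denom > 0)
    stat_per_group = np.sqrt(a * pres)
    best = stat_per_group.argmax(axis=1)
    rows = np.arange(x.shape[0])
    obs = stat_per_group[rows, best]

    if n_permutations == "exact":
        labelings = _distinct_labelings(codes)
        perm_stats = _indval_stats(x, presence, labelings, k, group_equalized)
        p = np.mean(perm_stats >= obs[:, None] - _TIE_TOL, axis=1)
        n_perm = labelings.shape[0]
    else:
        n_perm = int(n_permutations)
        if n_perm < 1:
            raise ConfigError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        labelings = _random_labelings(codes, n_perm, rng)
        perm_stats = _indval_stats(x, presence, labelings, k, group_equalized)
        b = (perm_stats >= obs[:, None] - _TIE_TOL).sum(axis=1)
        p = (b + 1) / (n_perm + 1)

    return pd.DataFrame(
        {
            "best_group": [levels[i] for i in best],
            "A": a[rows, best],
            "B": pres[rows, best],
            "stat": obs,
            "p_value": p,
        },
        index=table.index,
    )


@dataclass
class SignatureShare:
    """Community share held by taxa passing the indicator screen."""

    per_sample: pd.Series
    mean: float
    group_means: pd.Series | None = None


def signature_share(
    relative_abundance: pd.DataFrame,
    indval_result: pd.DataFrame,
    p_max: float = 0.05,
    stat_min: float = 0.5,
    groups=None,
) -> SignatureShare:
    """Summed relative abundance of taxa with IndVal p < ``p_max`` and
    stat ≥ ``stat_min``, per sample (plus group means when ``groups`` is
    given)."""
    sums = relative_abundance.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        warnings.warn("relative abundances do not sum to 1 per sample", stacklevel=2)
    passing = indval_result.index[
        (indval_result["p_value"] < p_max) & (indval_result["stat"] >= stat_min)
    ]
    per_sample = relative_abundance.reindex(passing).sum(axis=0)
    group_means = None
    if groups is not None:
        group_means = per_sample.groupby(pd.Series(list(groups), index=per_sample.index)).mean()
    return SignatureShare(per_sample=per_sample, mean=float(per_sample.mean()),
                          group_means=group_means)


def simper(matrix: pd.DataFrame, groups):
    """Per-taxon contribution to the mean between-group Bray-Curtis.

    For two groups, the contribution of taxon *t* is the average over all
    between-group sample pairs (x, y) of ``|x_t − y_t| / Σ_s (x_s + y_s)``;
    contributions sum to the mean between-group dissimilarity. With more
    than two groups, a dict keyed by group pair is returned.
    """
    codes, levels = _group_codes(groups)
    if len(levels) < 2:
        raise ConfigError("SIMPER needs at least two groups")
    if len(levels) > 2:
        out = {}
        for g1, g2 in itertools.combinations(range(len(levels)), 2):
            sel = np.isin(codes, (g1, g2))
            sub = matrix.loc[:, np.asarray(sel)]
            out[(levels[g1], levels[g2])] = simper(sub, np.asarray(codes)[sel])
        return out
    x = matrix.to_numpy(dtype=float)
    idx1 = np.flatnonzero(codes == 0)
    idx2 = np.flatnonzero(codes == 1)
    contrib = np.zeros(x.shape[0])
    n_pairs = 0
    for i in idx1:
        for j in idx2:
            tot = (x[:, i] + x[:, j]).sum()
            if tot == 0:
                raise NormalizationError(
                    f"pair ({matrix.columns[i]}, {matrix.columns[j]}) is all-zero"
                )
            contrib += np.abs(x[:, i] - x[:, j]) / tot
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    pct = contrib / total * 100.0 if total > 0 else np.zeros_like(contrib)
    return pd.DataFrame(
        {"contribution": contrib, "pct": pct}, index=matrix.index
    ).sort_values("contribution", ascending=False)


def filter_min_count(
    table: pd.DataFrame, min_reads: int = 4, how: str = "all"
) -> pd.DataFrame:
    """Drop low-abundance taxa before cross-study comparison.

    A taxon is kept when its count strictly exceeds ``min_reads`` in all
    samples (``how="all"``, the default convention) or in at least one
    sample (``how="any"``).
    """
    if how == "all":
        keep = (table > min_reads).all(axis=1)
    elif how == "any":
        keep = (table > min_reads).any(axis=1)
    else:
        raise ConfigError("how must be 'all' or 'any'")
    return table.loc[keep]
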