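"""Group-level statistics for summary tables and clustered heatmaps.

One-way ANOVA with Duncan's multiple-range letters annotates the
physicochemical, color and sensory tables; pooled-variance t-tests feed
the differential screen; log10 transform, per-metabolite z-scoring,
sample–sample Pearson correlation and hierarchical clustering underpin
the QC checks and heatmaps.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from oenomet.io import MetaboliteTable, OenometError


@dataclasses.dataclass
class GroupSummary:
    """Mean ± SD of one group plus its Duncan letter-set.

    Groups sharing any letter are not significantly different at the
    test's alpha; letters are lowercase and contiguous from ``a``.
    """

    group: str
    n: int
    mean: float
    sd: float
    letters: str


def anova_oneway(values_by_group: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    If every observation is identical the ratio is undefined; by
    convention we report F = 0, p = 1 (no evidence of group differences).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise OenometError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise OenometError("every group needs n >= 2")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance, nonzero between
        return float("inf"), 0.0
    return float(f), float(p)


def _pooled_ms_error(groups: list[np.ndarray]) -> tuple[float, int]:
    """Within-group mean square and its degrees of freedom."""
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df = sum(len(g) for g in groups) - len(groups)
    if df < 1:
        raise OenometError("pooled error degrees of freedom < 1")
    return sse / df, df


def duncan_least_significant_ranges(
    n_means: int, ms_error: float, df_error: int, n_harmonic: float, alpha: float = 0.05
) -> dict[int, float]:
    """Duncan's least significant range for each span p = 2..n_means.

    Uses studentized-range quantiles at Duncan's protection levels
    alpha_p = 1 − (1 − alpha)^(p−1), scaled by sqrt(MSE / n_h) with n_h
    the (harmonic mean) per-group size.
    """
    se = np.sqrt(ms_error / n_harmonic)
    out = {}
    for p in range(2, n_means + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = sps.studentized_range.ppf(1.0 - alpha_p, p, df_error)
        out[p] = float(q * se)
    return out


def duncan_letters(
    values_by_group: Sequence[Sequence[float]],
    alpha: float = 0.05,
    group_names: Sequence[str] | None = None,
) -> list[GroupSummary]:
    """Duncan's multiple range test with letter display.

    The stepwise procedure orders the group means and compares the range
    of every contiguous span of p means against the least significant
    range LSR(p); a span whose range does not exceed LSR(p), or that lies
    inside an already-nonsignificant span, is declared homogeneous.
    Letters are then assigned to the maximal homogeneous spans so that
    two groups share a letter iff they were not separated.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    names = list(group_names) if group_names is not None else [
        f"G{i + 1}" for i in range(len(groups))
    ]
    if len(groups) == 1:
        g = groups[0]
        return [GroupSummary(names[0], len(g), float(g.mean()), float(g.std(ddof=1)) if len(g) > 1 else 0.0, "a")]
    mse, df = _pooled_ms_error(groups)
    means = np.array([g.mean() for g in groups])
    order = np.argsort(means)  # ascending
    k = len(groups)
    n_h = k / np.sum([1.0 / len(g) for g in groups])  # harmonic mean size
    if mse == 0:
        # degenerate: separation decided by exact equality of means
        lsr = {p: 0.0 for p in range(2, k + 1)}
    else:
        lsr = duncan_least_significant_ranges(k, mse, df, n_h, alpha)

    sorted_means = means[order]
    # homogeneous[i][j] True if the span i..j (sorted order) is not separated
    homogeneous = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(homogeneous, True)
    # test spans from widest to narrowest; protect subranges of accepted spans
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if homogeneous[i, j]:
                continue  # protected: inside an already-accepted wider span
            rng = sorted_means[j] - sorted_means[i]
            if rng <= lsr[span] + 1e-12:
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        homogeneous[a, b] = True

    # maximal homogeneous spans, left to right, get letters a, b, c ...
    spans: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous[i, j + 1]:
            j += 1
        if not spans or j > spans[-1][1]:
            spans.append((i, j))
    letters_by_pos: dict[int, list[str]] = {p: [] for p in range(k)}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # letters follow descending means (largest mean gets "a"), the table convention
    spans_desc = sorted(((k - 1 - b, k - 1 - a) for a, b in spans))
    for li, (a, b) in enumerate(spans_desc):
        for pos in range(a, b + 1):
            letters_by_pos[pos].append(alphabet[li % 26])

    out = []
    desc_order = order[::-1]  # descending means
    for pos, gi in enumerate(desc_order):
        g = groups[gi]
        out.append(
            GroupSummary(
                names[gi],
                len(g),
                float(means[gi]),
                float(g.std(ddof=1)),
                "".join(letters_by_pos[pos]),
            )
        )
    # return in input order
    out_by_name = {s.group: s for s in out}
    return [out_by_name[n] for n in names]


def ttest_two_group(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided pooled-variance Student t-test p-value.

    Degenerate conventions: zero pooled variance with equal means → p = 1
    (indistinguishable); with unequal means → p = 0 (perfect separation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise OenometError("t-test needs n >= 2 per group")
    sp2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / (
        len(x) + len(y) - 2
    )
    if sp2 == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(sps.ttest_ind(x, y, equal_var=True).pvalue)


def log10_transform(table: MetaboliteTable) -> np.ndarray:
    """Elementwise log10 of the imputed (zero-free) intensity matrix."""
    return np.log10(table.imputed())


def zscore_rows(X: np.ndarray) -> np.ndarray:
    """Per-row z-score (mean 0, sd 1); constant rows map to all zeros."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(X)
    ok = (sd > 0).ravel()
    out[ok] = (X[ok] - mu[ok]) / sd[ok]
    return out


def sample_correlation(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between sample (column) profiles.

    Requires >= 3 metabolites; returns a symmetric matrix with unit
    diagonal and entries in [−1, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise OenometError("sample correlation needs >= 3 metabolites")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def hierarchical_cluster(
    X: np.ndarray, linkage: str = "average", metric: str = "euclidean"
) -> np.ndarray:
    """Agglomerative clustering; returns the scipy linkage (merge-tree) matrix.

    Rows of ``X`` are items.  If ``X`` is a square symmetric matrix with a
    zero diagonal, it is taken to already be a distance matrix.  Scipy's
    implementation merges lowest-index pairs first on ties, making the
    tree deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    is_dist = (
        X.ndim == 2
        and X.shape[0] == X.shape[1]
        and np.allclose(X, X.T)
        and np.allclose(np.diag(X), 0.0)
    )
    d = squareform(X, checks=False) if is_dist else X
    if is_dist:
        if np.isnan(d).any():
            raise OenometError("NaN in distance matrix")
        return hierarchy.linkage(d, method=linkage)
    if X.shape[0] < 2:
        raise OenometError("need >= 2 items to cluster")
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    if np.isnan(Z[:, 2]).any():
        raise OenometError("NaN distances during clustering")
    return Z
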