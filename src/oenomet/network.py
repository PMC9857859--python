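"""Weighted co-abundance network: soft threshold, TOM, modules, eigengenes.

Metabolite co-abundance is modelled as a weighted network in which the
edge weight between metabolites i and j is the unsigned adjacency
|cor(x_i, x_j)|^β.  The soft-threshold power β is chosen so that the
connectivity distribution approximates a scale-free (power-law) form.
Adjacency is converted to the topological overlap measure (TOM), which
rewards shared neighbourhoods; 1 − TOM is the clustering dissimilarity.
Average-linkage clustering with a dynamic tree cut yields modules
(named by colors, size-ranked; "grey" collects unassigned metabolites),
each summarised by its eigengene — the first principal component of the
module's profiles across samples.  Modules with highly correlated
eigengenes are merged, and the final eigengenes are correlated with the
per-sample sensory traits (Pearson r with its t-transform p-value).

The model/results pattern: construct :class:`CoexpressionNetwork` from
a samples × metabolites matrix, :meth:`fit` returns
:class:`CoexpressionResults`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from oenomet.io import OenometError

#: Conventional module color palette, assigned by descending module size.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
)

GREY = "grey"


@dataclasses.dataclass
class NetworkConfig:
    """Network construction parameters.

    power : soft-threshold exponent β (integer >= 1; default 6).
    network_type : only "unsigned" in v1 (adjacency = |r|^β).
    min_module_size : smallest allowed module (default 50).
    merge_similarity : modules whose eigengene correlation reaches this
        value are merged (default 0.75, i.e. merge cut height 0.25).
    cut_height : dendrogram height for the dynamic cut (fraction of the
        maximum merge height; default 0.99).
    assign_unlabelled : after the cut, attach unassigned metabolites to
        the nearest module when their average TOM dissimilarity to it is
        below ``cut_height`` (a light-weight analogue of the hybrid
        cut's assignment stage).
    kme_stay : module-membership cleanup threshold: after the cut,
        members whose |cor(profile, module eigengene)| falls below this
        value revert to grey (default 0.5), removing weakly attached
        metabolites that joined a branch by chance.
    """

    power: int = 6
    network_type: str = "unsigned"
    min_module_size: int = 50
    merge_similarity: float = 0.75
    cut_height: float = 0.99
    assign_unlabelled: bool = True
    kme_stay: float = 0.5

    def __post_init__(self) -> None:
        if self.power < 1 or int(self.power) != self.power:
            raise OenometError("power must be an integer >= 1")
        if self.network_type != "unsigned":
            raise OenometError("only unsigned networks are supported")
        if self.min_module_size < 2:
            raise OenometError("min_module_size must be >= 2")
        if not 0 < self.merge_similarity < 1:
            raise OenometError("merge_similarity must lie in (0, 1)")


# ---------------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------------


def adjacency(X: np.ndarray, config: NetworkConfig | None = None) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^β for columns of ``X``.

    ``X`` is samples × metabolites; every metabolite must have nonzero
    variance (filter upstream).
    """
    config = config or NetworkConfig()
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise OenometError(f"zero-variance metabolite at column {bad}")
    r = np.corrcoef(X, rowvar=False)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** config.power
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency matrix in [0, 1].

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu; TOM_ii = 1.
    """
    A = np.asarray(adj, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise OenometError("adjacency must be square symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0  # L_ij = Σ_u a_iu a_uj (u≠i and u≠j handled by zero diagonal)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def pick_soft_threshold(
    X: np.ndarray,
    candidate_powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology fit per candidate power.

    For each β the connectivity k_i = Σ_j a_ij is binned, and
    log10 p(k) is regressed on log10 k̄ per bin; the signed fit index is
    R² · (−sign(slope)), positive for the decreasing (scale-free-like)
    distributions.  The returned frame carries ``power``, ``sft_r2``
    (NaN when fewer than 3 occupied bins) and ``mean_connectivity``; the
    recommended power (smallest reaching ``r2_target``, else the best
    fit) is stored in ``DataFrame.attrs["recommended_power"]``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 20:
        raise OenometError("soft-threshold selection needs >= 20 metabolites")
    r = np.abs(np.clip(np.corrcoef(X, rowvar=False), -1.0, 1.0))
    np.fill_diagonal(r, 0.0)
    rows = []
    for beta in candidate_powers:
        a = r**beta
        k = a.sum(axis=1)
        rows.append((int(beta), _scale_free_r2(k, n_bins), float(k.mean())))
    df = pd.DataFrame(rows, columns=["power", "sft_r2", "mean_connectivity"])
    ok = df.dropna(subset=["sft_r2"])
    reaching = ok[ok["sft_r2"] >= r2_target]
    if len(reaching):
        rec = int(reaching["power"].iloc[0])
    elif len(ok):
        rec = int(ok.loc[ok["sft_r2"].idxmax(), "power"])
    else:
        rec = None
        warnings.warn("scale-free fit undefined for every candidate power")
    df.attrs["recommended_power"] = rec
    return df


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    if np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return float("nan")
    slope, _, rval, _, _ = sps.linregress(xs, ys)
    return float(rval**2 * (-np.sign(slope)))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModulePartition:
    """Per-metabolite module labels (colors; grey = unassigned)."""

    labels: list[str]
    linkage: np.ndarray | None = None

    @property
    def module_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def modules(self) -> list[str]:
        """Non-grey module colors, by descending size; ties keep palette order."""
        sizes = self.module_sizes

        def rank(m: str) -> int:
            return MODULE_COLORS.index(m) if m in MODULE_COLORS else len(MODULE_COLORS)

        return sorted(
            (m for m in sizes if m != GREY), key=lambda m: (-sizes[m], rank(m), m)
        )

    def members(self, module: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == module)


def cluster_modules(
    diss_tom: np.ndarray, config: NetworkConfig | None = None
) -> ModulePartition:
    """Average-linkage dendrogram + dynamic cut of a TOM dissimilarity.

    The dendrogram is cut at ``cut_height`` × (maximum merge height);
    branches with at least ``min_module_size`` members become modules
    (colors assigned by descending size), everything else is grey.
    Optionally, unassigned metabolites whose mean dissimilarity to the
    closest module falls below the cut height are attached to it.
    """
    config = config or NetworkConfig()
    D = np.asarray(diss_tom, dtype=float)
    n = D.shape[0]
    if n < config.min_module_size:
        warnings.warn("fewer metabolites than min_module_size; all grey")
        return ModulePartition([GREY] * n, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    cut = config.cut_height * Z[:, 2].max()
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = np.full(n, GREY, dtype=object)
    sizes = pd.Series(flat).value_counts()
    big = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    big.sort(key=lambda c: -sizes[c])
    for rank, c in enumerate(big):
        color = MODULE_COLORS[rank % len(MODULE_COLORS)]
        labels[flat == c] = color
    if config.assign_unlabelled and big:
        grey_idx = np.flatnonzero(labels == GREY)
        for i in grey_idx:
            best, best_d = None, np.inf
            for rank, c in enumerate(big):
                members = np.flatnonzero(flat == c)
                d = float(D[i, members].mean())
                if d < best_d:
                    best, best_d = MODULE_COLORS[rank % len(MODULE_COLORS)], d
            if best is not None and best_d < cut:
                labels[i] = best
    return ModulePartition(list(labels), Z)


@dataclasses.dataclass
class EigengeneSet:
    """Per-module eigengene (over samples) and variance explained."""

    eigengenes: pd.DataFrame  # samples × modules
    variance_explained: dict[str, float]


def kme_cleanup(
    X_z: np.ndarray, partition: ModulePartition, threshold: float = 0.5
) -> ModulePartition:
    """Revert weakly-connected module members to grey.

    A member stays in its module only while the absolute correlation of
    its profile with the module eigengene (its module membership, kME)
    reaches ``threshold``; eigengenes are recomputed until stable.
    Modules falling under way of cleanup keep their label (size rules
    were enforced at cut time).
    """
    labels = list(partition.labels)
    while True:
        part = ModulePartition(labels, partition.linkage)
        if not part.modules:
            return part
        egs = module_eigengene(X_z, part)
        changed = False
        for module in part.modules:
            eg = egs.eigengenes[module].to_numpy()
            for i in part.members(module):
                r = np.corrcoef(X_z[i], eg)[0, 1]
                if abs(r) < threshold:
                    labels[i] = GREY
                    changed = True
        if not changed:
            return ModulePartition(labels, partition.linkage)


def module_eigengene(
    X_z: np.ndarray, partition: ModulePartition, sample_ids: Sequence[str] | None = None
) -> EigengeneSet:
    """First principal component of each module's z-scored profiles.

    The eigengene is the first right-singular vector over samples, unit
    norm, sign-oriented so that its correlation with the module's mean
    profile is positive.
    """
    X_z = np.asarray(X_z, dtype=float)  # metabolites × samples
    cols = {}
    varexp = {}
    for module in partition.modules:
        rows = partition.members(module)
        M = X_z[rows]
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        eg = Vt[0]
        mean_profile = M.mean(axis=0)
        if np.dot(eg, mean_profile) < 0:
            eg = -eg
        cols[module] = eg
        total = float(np.sum(s**2))
        varexp[module] = float(s[0] ** 2 / total) if total > 0 else 0.0
    index = (
        list(sample_ids)
        if sample_ids is not None
        else [f"S{j + 1}" for j in range(X_z.shape[1])]
    )
    return EigengeneSet(pd.DataFrame(cols, index=index), varexp)


def merge_modules(
    X_z: np.ndarray,
    partition: ModulePartition,
    config: NetworkConfig | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[ModulePartition, EigengeneSet]:
    """Iteratively merge module pairs with eigengene correlation >= threshold.

    After each merge the eigengenes are recomputed; the procedure stops
    at a fixed point (no pair qualifies), so it is idempotent.  Merged
    modules keep the color of the larger partner, then colors are
    re-ranked by size.
    """
    config = config or NetworkConfig()
    labels = list(partition.labels)
    while True:
        part = ModulePartition(labels, partition.linkage)
        egs = module_eigengene(X_z, part, sample_ids)
        mods = part.modules
        if len(mods) < 2:
            return _recolor(part), egs
        E = egs.eigengenes[mods].to_numpy()
        C = np.corrcoef(E, rowvar=False)
        best, best_r = None, config.merge_similarity
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                if C[i, j] >= best_r:
                    best, best_r = (mods[i], mods[j]), C[i, j]
        if best is None:
            part = _recolor(part)
            return part, module_eigengene(X_z, part, sample_ids)
        keep, absorb = best  # modules list is size-ordered: keep the larger
        labels = [keep if lab == absorb else lab for lab in labels]


def _recolor(partition: ModulePartition) -> ModulePartition:
    """Re-assign colors by descending module size (deterministic naming)."""
    mapping = {
        m: MODULE_COLORS[r % len(MODULE_COLORS)]
        for r, m in enumerate(partition.modules)
    }
    mapping[GREY] = GREY
    return ModulePartition(
        [mapping[lab] for lab in partition.labels], partition.linkage
    )


# ---------------------------------------------------------------------------
# module–trait correlation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModuleTraitMatrix:
    """Pearson r and p per (module, trait); NaN r flags degenerate traits."""

    r: pd.DataFrame  # modules × traits
    p: pd.DataFrame


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> ModuleTraitMatrix:
    """Correlate each module eigengene with each per-sample trait.

    p-values come from the t-transform t = r·sqrt(n−2)/sqrt(1−r²),
    two-sided.  A zero-variance trait yields NaN r and p = 1 (flagged).
    """
    if len(eigengenes) != len(traits):
        raise OenometError("eigengene and trait tables must align on samples")
    n = len(eigengenes)
    if n < 3:
        raise OenometError("module–trait correlation needs n >= 3 samples")
    rmat = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    pmat = rmat.copy()
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy()
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            if np.std(t) == 0 or np.std(e) == 0:
                rmat.loc[mod, trait] = np.nan
                pmat.loc[mod, trait] = 1.0
                continue
            r = float(np.corrcoef(e, t)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
                p = float(2 * sps.t.sf(abs(tstat), df=n - 2))
            rmat.loc[mod, trait] = r
            pmat.loc[mod, trait] = max(p, np.finfo(float).tiny)
    return ModuleTraitMatrix(rmat, pmat)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class CoexpressionResults:
    """Fitted co-abundance network: modules, eigengenes, trait correlations."""

    def __init__(
        self,
        model: "CoexpressionNetwork",
        partition: ModulePartition,
        eigengenes: EigengeneSet,
        module_trait: ModuleTraitMatrix | None,
        tom: np.ndarray,
    ) -> None:
        self.model = model
        self.partition = partition
        self.eigengenes = eigengenes
        self.module_trait = module_trait
        self.tom = tom

    def module_members(self, module: str) -> list[str]:
        return [self.model.metabolite_ids[i] for i in self.partition.members(module)]

    def summary(self) -> pd.DataFrame:
        """Module table: size, variance explained, strongest trait link."""
        rows = []
        sizes = self.partition.module_sizes
        for mod in self.partition.modules + ([GREY] if GREY in sizes else []):
            row = {
                "module": mod,
                "size": sizes[mod],
                "unassigned": mod == GREY,
                "variance_explained": self.eigengenes.variance_explained.get(
                    mod, float("nan")
                ),
            }
            if self.module_trait is not None and mod in self.module_trait.r.index:
                rr = self.module_trait.r.loc[mod].astype(float)
                best = rr.abs().idxmax()
                row["top_trait"] = best
                row["top_trait_r"] = rr[best]
                row["top_trait_p"] = float(self.module_trait.p.loc[mod, best])
            rows.append(row)
        return pd.DataFrame(rows)


class CoexpressionNetwork:
    """Weighted co-abundance network model of a metabolite matrix.

    Parameters
    ----------
    X : samples × metabolites matrix (log10 intensities; z-scoring for
        eigengene extraction happens internally).
    metabolite_ids, sample_ids : optional names.
    config : :class:`NetworkConfig`.
    """

    def __init__(
        self,
        X,
        metabolite_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
        config: NetworkConfig | None = None,
    ) -> None:
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance metabolite(s) "
                "before network construction"
            )
        self.X = X[:, keep]
        self.kept_mask = keep
        ids = (
            list(metabolite_ids)
            if metabolite_ids is not None
            else [f"M{i + 1}" for i in range(X.shape[1])]
        )
        self.metabolite_ids = [m for m, k in zip(ids, keep) if k]
        self.sample_ids = (
            list(sample_ids)
            if sample_ids is not None
            else [f"S{j + 1}" for j in range(X.shape[0])]
        )
        self.config = config or NetworkConfig()

    def fit(self, traits: pd.DataFrame | None = None) -> CoexpressionResults:
        """Adjacency → TOM → modules → merge → eigengenes (→ trait correlation)."""
        adj = adjacency(self.X, self.config)
        tom = tom_similarity(adj)
        partition = cluster_modules(1.0 - tom, self.config)
        Xz = _zscore_cols_as_rows(self.X)
        if partition.modules and self.config.kme_stay > 0:
            partition = kme_cleanup(Xz, partition, self.config.kme_stay)
            # cleanup may shrink a module below the size rule: demote it
            sizes = partition.module_sizes
            labels = [
                GREY
                if lab != GREY and sizes[lab] < self.config.min_module_size
                else lab
                for lab in partition.labels
            ]
            partition = ModulePartition(labels, partition.linkage)
        if partition.modules:
            partition, egs = merge_modules(Xz, partition, self.config, self.sample_ids)
        else:
            egs = module_eigengene(Xz, partition, self.sample_ids)
        mt = None
        if traits is not None and len(egs.eigengenes.columns):
            aligned = traits.loc[self.sample_ids] if set(self.sample_ids) <= set(traits.index) else traits
            mt = module_trait_correlation(egs.eigengenes, aligned)
        return CoexpressionResults(self, partition, egs, mt, tom)


def _zscore_cols_as_rows(X: np.ndarray) -> np.ndarray:
    """Columns of samples × metabolites ``X`` → z-scored metabolites × samples."""
    Xt = X.T
    mu = Xt.mean(axis=1, keepdims=True)
    sd = Xt.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xt - mu) / sd
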