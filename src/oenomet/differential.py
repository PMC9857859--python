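"""Pairwise differential-metabolite screening and biomarker calls.

A metabolite is differential between two wines when it passes the
conjunction rule VIP >= 1 (from the pairwise two-class OPLS-DA) and
two-sided t-test p < 0.05 (pooled variance, on log10 intensities).
Direction is reported for the *latter* group relative to the *former*
in the comparison's name, with log2 fold change on raw group means.
Venn intersections of per-pair significant sets give the core
differential metabolites; a one-vs-rest sweep gives each variety's
characteristic metabolites, flagged as biomarkers when the variety also
shows the maximal mean intensity.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from oenomet.chemometrics import OPLSDA
from oenomet.io import MetaboliteTable, OenometError
from oenomet.stats import ttest_two_group


@dataclasses.dataclass
class ScreenConfig:
    """Tunables of the differential screen.

    vip_threshold / p_threshold implement the VIP >= 1 ∧ p < 0.05 rule;
    ``bh_correct`` switches on Benjamini–Hochberg adjustment of the
    t-test p-values across metabolites (off by default: the screen uses
    raw p-values).
    """

    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    k_ortho: int = 1
    cv_folds: int = 7
    bh_correct: bool = False


@dataclasses.dataclass
class DiffRecord:
    """Per-metabolite result of one ordered comparison (former vs latter)."""

    metabolite_id: str
    comparison: str
    p: float
    vip: float
    log2fc: float  # log2(mean_latter / mean_former), raw intensities
    direction: str  # "up" | "down": latter relative to former
    significant: bool


@dataclasses.dataclass
class ComparisonSummary:
    comparison: str
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


def screen_pair(
    table: MetaboliteTable,
    former: str,
    latter: str,
    config: ScreenConfig | None = None,
) -> tuple[list[DiffRecord], ComparisonSummary]:
    """Screen one ordered comparison ``former`` vs ``latter``.

    Produces one :class:`DiffRecord` per metabolite; significance is the
    VIP/p conjunction, orientation is "up" when the latter group's raw
    mean exceeds the former's.
    """
    config = config or ScreenConfig()
    cols_a = table.columns_for(former)
    cols_b = table.columns_for(latter)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise OenometError("each group needs >= 2 replicates")
    raw = table.imputed()
    logX = np.log10(raw)

    # per-pair OPLS-DA on the autoscaled log intensities of these samples only
    cols = np.concatenate([cols_a, cols_b])
    y = np.array([0] * len(cols_a) + [1] * len(cols_b))
    model = OPLSDA(
        logX[:, cols].T,
        y,
        k_ortho=config.k_ortho,
        cv_folds=config.cv_folds,
        var_names=table.metabolite_ids,
    )
    vip_full = np.zeros(table.n_metabolites)
    res = model.fit()
    vip_full[model.kept_mask] = res.vip

    pvals = np.array(
        [
            ttest_two_group(logX[i, cols_a], logX[i, cols_b])
            for i in range(table.n_metabolites)
        ]
    )
    p_eff = (
        multipletests(pvals, method="fdr_bh")[1] if config.bh_correct else pvals
    )

    comparison = f"{former} vs {latter}"
    records = []
    n_up = n_down = 0
    for i, mid in enumerate(table.metabolite_ids):
        mean_a = float(raw[i, cols_a].mean())
        mean_b = float(raw[i, cols_b].mean())
        log2fc = float(np.log2(mean_b / mean_a))
        sig = bool(vip_full[i] >= config.vip_threshold and p_eff[i] < config.p_threshold)
        direction = "up" if log2fc > 0 else "down"
        if sig:
            if direction == "up":
                n_up += 1
            else:
                n_down += 1
        records.append(
            DiffRecord(mid, comparison, float(p_eff[i]), float(vip_full[i]), log2fc, direction, sig)
        )
    return records, ComparisonSummary(comparison, n_up, n_down)


def screen_all_pairs(
    table: MetaboliteTable,
    varieties: Sequence[str],
    config: ScreenConfig | None = None,
) -> dict[tuple[str, str], tuple[list[DiffRecord], ComparisonSummary]]:
    """All unordered pairs, each screened once in lexicographic order."""
    out = {}
    for a, b in combinations(varieties, 2):
        out[(a, b)] = screen_pair(table, a, b, config)
    return out


def significant_ids(records: Sequence[DiffRecord]) -> set[str]:
    return {r.metabolite_id for r in records if r.significant}


def venn_core(
    sets: Mapping[str, set[str]]
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Exact intersection plus every Venn region cardinality.

    Each of the 2^k − 1 regions is keyed by the frozenset of set names
    whose members belong to *exactly* those sets.
    """
    if not sets:
        raise OenometError("venn_core needs at least one set")
    if len(sets) < 2:
        raise OenometError("venn_core needs >= 2 sets")
    names = list(sets)
    universe = set().union(*sets.values())
    regions: dict[frozenset[str], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = 0
    for item in universe:
        membership = frozenset(n for n in names if item in sets[n])
        regions[membership] += 1
    core = set.intersection(*sets.values())
    return core, regions


@dataclasses.dataclass
class CharacteristicMetabolite:
    """A metabolite differential in every comparison against a focal variety."""

    metabolite_id: str
    variety: str
    min_vip: float
    max_p: float
    is_biomarker: bool  # focal variety also has the maximal group mean


def characteristic_metabolites(
    table: MetaboliteTable,
    variety: str,
    varieties: Sequence[str],
    config: ScreenConfig | None = None,
    _screens: Mapping[tuple[str, str], tuple[list[DiffRecord], ComparisonSummary]] | None = None,
) -> list[CharacteristicMetabolite]:
    """One-vs-rest characteristic metabolites of one variety.

    A metabolite qualifies when it is significant in *all* pairwise
    comparisons of the focal variety against every other variety.  It is
    flagged a biomarker when the focal variety's raw group mean is the
    maximum over all varieties ("relatively high level"); a uniquely
    depleted metabolite is characteristic but not a biomarker.
    Results are ranked by minimum VIP across comparisons, descending.
    """
    others = [v for v in varieties if v != variety]
    if len(others) < 2:
        raise OenometError("need >= 2 other varieties")
    per_pair: dict[str, list[DiffRecord]] = {}
    for other in others:
        key = tuple(sorted((variety, other)))
        if _screens is not None and key in _screens:
            recs = _screens[key][0]
        else:
            recs, _ = screen_pair(table, key[0], key[1], config)
        per_pair[other] = recs

    raw = table.imputed()
    group_means = {
        v: raw[:, table.columns_for(v)].mean(axis=1) for v in varieties
    }
    idx = {m: i for i, m in enumerate(table.metabolite_ids)}

    out = []
    common = set(table.metabolite_ids)
    rec_by_pair = {
        other: {r.metabolite_id: r for r in recs} for other, recs in per_pair.items()
    }
    for other, recs in rec_by_pair.items():
        common &= {m for m, r in recs.items() if r.significant}
    for mid in common:
        i = idx[mid]
        vips = [rec_by_pair[o][mid].vip for o in others]
        ps = [rec_by_pair[o][mid].p for o in others]
        focal_mean = group_means[variety][i]
        is_max = all(focal_mean >= group_means[v][i] for v in others)
        out.append(
            CharacteristicMetabolite(mid, variety, min(vips), max(ps), bool(is_max))
        )
    out.sort(key=lambda c: -c.min_vip)
    return out
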