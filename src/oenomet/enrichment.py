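"""Hypergeometric pathway enrichment with Benjamini–Hochberg FDR.

For a pathway annotated to M of the N background metabolites, of which
a selected set (differential metabolites or a module) contains n
metabolites with m falling in the pathway, the enrichment p-value is the
upper hypergeometric tail

    P = 1 − Σ_{i=0}^{m−1} C(M, i) C(N−M, n−i) / C(N, n) = P(X >= m),

evaluated in log space via the survival function for numerical
stability.  The background is every metabolite carrying at least one
pathway annotation; unannotated metabolites are excluded from both the
set and the background.  p-values are adjusted across pathways by the
BH step-up procedure, with significance at FDR <= 0.05.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from oenomet.io import OenometError, PathwayMap


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    N: background size; n: selected-set size; M: pathway size within the
    background; m: selected metabolites in the pathway.
    """
    N, n, M, m = int(N), int(n), int(M), int(m)
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise OenometError(
            f"invalid hypergeometric arguments N={N}, n={n}, M={M}, m={m}"
        )
    if m == 0:
        return 1.0
    # sf(m-1) = P(X >= m); scipy's parametrisation: (k, M=N, n=M, N=n)
    return float(sps.hypergeom.sf(m - 1, N, M, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise OenometError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclasses.dataclass
class EnrichmentRow:
    """One pathway's enrichment bookkeeping.

    N / n / M / m are the background size, set size, pathway size and
    pathway∩set size (all within the annotated background); ``p`` the
    upper-tail probability and ``fdr`` its BH adjustment.
    """

    pathway: str
    N: int
    n: int
    M: int
    m: int
    p: float
    fdr: float
    significant: bool
    category: str | None = None


def enrich(
    selected: Iterable[str],
    background: Iterable[str],
    pathway_map: PathwayMap,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentRow]:
    """Enrichment of a metabolite set against an annotated background.

    Returns one row per pathway with >= 1 background member, sorted by
    FDR then p then pathway id.  The first 20 rows are the "top 20 by
    q-value" slice conventionally plotted.
    """
    background = set(background)
    selected = set(selected)
    if not selected <= background:
        raise OenometError("selected set must be a subset of the background")
    bg = pathway_map.annotated(background)
    sel = selected & bg
    if not sel:
        warnings.warn("no annotated metabolite in the selected set; empty result")
        return []
    N, n = len(bg), len(sel)
    rows = []
    for pw in sorted(pathway_map.pathways):
        members = pathway_map.members(pw) & bg
        M = len(members)
        if M == 0:
            continue
        m = len(members & sel)
        rows.append((pw, M, m, hypergeom_p(N, n, M, m)))
    fdrs = bh_fdr([r[3] for r in rows])
    out = [
        EnrichmentRow(
            pathway=pw,
            N=N,
            n=n,
            M=M,
            m=m,
            p=p,
            fdr=float(q),
            significant=bool(q <= fdr_threshold and m > 0),
            category=pathway_map.categories.get(pw),
        )
        for (pw, M, m, p), q in zip(rows, fdrs)
    ]
    out.sort(key=lambda r: (r.fdr, r.p, r.pathway))
    return out


def enrichment_frame(rows: Sequence[EnrichmentRow], top: int | None = None) -> pd.DataFrame:
    """Result rows as a DataFrame (optionally the top-k by q-value)."""
    df = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "category": r.category,
                "N": r.N,
                "n": r.n,
                "M": r.M,
                "m": r.m,
                "p": r.p,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
    return df.head(top) if top else df
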