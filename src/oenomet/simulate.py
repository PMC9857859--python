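"""Synthetic wine-metabolome bundles with known ground truth.

The generator emulates the study design the pipeline targets: six wine
varieties (A1–A6) × three fermentation replicates plus pooled QC
injections, a few hundred metabolites with planted co-abundance modules,
planted between-variety differential metabolites, sensory traits driven
by the module latent factors, and a pathway map with planted enriched
pathways.  Every random draw flows from a single seed, so the bundle is
bitwise reproducible.

Model (log10 scale): for metabolite i in sample s of variety v,

    log10 x[i, s] = baseline_i + amp_i · (c_m f[m, s] + sqrt(1−c_m²) ε)
                    + δ[i, v]                     (module members)
    log10 x[i, s] = baseline_i + σ ε + δ[i, v]    (background)

where f[m, s] is module m's standardized latent factor (a per-variety
level plus replicate scatter), c_m the planted metabolite–factor
correlation, and δ[i, v] = ±(effect · σ_i) the planted variety shifts in
pooled-SD units.  Intensities are 10^(log10 x), hence strictly positive.
QC samples are the arithmetic mean of all wine-sample intensity profiles
times a small multiplicative noise, mirroring a pooled-mixture QC.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from oenomet.io import (
    COMPOUND_CLASSES,
    MetaboliteTable,
    OenometError,
    PathwayMap,
    SampleInfo,
    TraitTable,
    TASTE_TRAITS,
)

#: Cultivar names of the six study wines, by variety code.
CULTIVAR_NAMES: dict[str, str] = {
    "A1": "Hassan",
    "A2": "Zuoshaner",
    "A3": "Beibinghong",
    "A4": "Shuanghong",
    "A5": "Zijingganlu",
    "A6": "Cabernet Sauvignon",
}


@dataclasses.dataclass
class ModuleSpec:
    """One planted co-abundance module: member count and metabolite–factor
    correlation (pairwise within-module correlation is its square)."""

    size: int
    latent_cor: float = 0.8


@dataclasses.dataclass
class TraitLoading:
    """trait = base + coef · (module latent, variety level) + N(0, noise_sd)."""

    module: int
    coef: float
    noise_sd: float
    base: float = 7.0


def default_trait_loadings() -> dict[str, TraitLoading]:
    """Default sensory wiring: color tied to the two largest modules,
    taste attributes split over modules with mixed signs (some wines'
    best traits trade off against others, as sensory panels report)."""
    return {
        "L_star": TraitLoading(0, -8.0, 2.0, base=65.0),
        "a_star": TraitLoading(0, 25.0, 4.0, base=60.0),
        "b_star": TraitLoading(3, 4.0, 1.5, base=10.0),
        "balance_coordination": TraitLoading(1, -1.1, 0.35, base=7.0),
        "thickness": TraitLoading(1, 1.1, 0.35, base=7.0),
        "astringency": TraitLoading(1, 1.0, 0.4, base=7.0),
        "aftertaste": TraitLoading(2, -1.0, 0.4, base=7.0),
        "layering": TraitLoading(2, -0.9, 0.45, base=7.5),
        "acidity": TraitLoading(2, 1.0, 0.4, base=6.5),
    }


@dataclasses.dataclass
class PathwayConfig:
    """Random pathway map with planted enrichment.

    ``annotated_fraction`` of metabolites receive >= 1 annotation;
    ``n_pathways`` random pathways of size 10–40 are drawn; for each of
    ``planted_enriched`` modules (starting from the largest) one pathway
    of size ``planted_size`` draws an ``overlap`` fraction of its members
    from that module.
    """

    n_pathways: int = 30
    planted_enriched: int = 1
    planted_size: int = 20
    overlap: float = 0.75
    annotated_fraction: float = 0.85


@dataclasses.dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults mirror the target design: 6 varieties × 3 replicates plus 3
    pooled QC injections; 600 metabolites with four planted modules of
    sizes 120/100/80/60 at metabolite–factor correlation 0.8; 30
    differential metabolites planted per variety at 4 pooled-SD effect.
    """

    seed: int = 0
    n_varieties: int = 6
    n_reps: int = 3
    n_qc: int = 3
    n_metabolites: int = 600
    modules: Sequence[ModuleSpec] = dataclasses.field(
        default_factory=lambda: [
            ModuleSpec(120),
            ModuleSpec(100),
            ModuleSpec(80),
            ModuleSpec(60),
        ]
    )
    n_differential: int = 30  # planted per variety, outside modules by default
    differential_effect: float = 4.0  # in pooled-SD units
    noise_sd: float = 0.2  # residual log10 SD of background metabolites
    module_amplitude: float = 0.25  # total stochastic log10 SD of module members
    latent_within_sd: float = 0.4  # replicate scatter of the module latent factor
    baseline_mean: float = 6.0  # log10 peak-area location
    baseline_sd: float = 1.0
    qc_noise_sd: float = 0.02  # multiplicative log10 noise of QC injections
    differential_in_modules: bool = False
    trait_loadings: dict[str, TraitLoading] = dataclasses.field(
        default_factory=default_trait_loadings
    )
    pathways: PathwayConfig = dataclasses.field(default_factory=PathwayConfig)

    def __post_init__(self) -> None:
        # coerce plain dicts (YAML configs) into the spec dataclasses
        self.modules = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in self.modules
        ]
        self.trait_loadings = {
            k: v if isinstance(v, TraitLoading) else TraitLoading(**v)
            for k, v in self.trait_loadings.items()
        }
        if not isinstance(self.pathways, PathwayConfig):
            self.pathways = PathwayConfig(**self.pathways)
        if sum(m.size for m in self.modules) > self.n_metabolites:
            raise OenometError("module sizes exceed the metabolite count")
        if self.noise_sd <= 0 or self.module_amplitude <= 0:
            raise OenometError("all standard deviations must be > 0")
        if self.n_varieties < 2 or self.n_reps < 2:
            raise OenometError("need >= 2 varieties with >= 2 replicates")
        free = self.n_metabolites - sum(m.size for m in self.modules)
        if not self.differential_in_modules and self.n_differential * self.n_varieties > free:
            raise OenometError(
                "not enough background metabolites for the planted differential sets"
            )


@dataclasses.dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests.

    ``differential`` maps each ordered variety pair to
    {metabolite_id: "up" | "down"} — direction of the latter relative to
    the former, consistent with the screen's orientation convention.
    """

    module_assignment: dict[str, int]  # metabolite -> module index (unassigned absent)
    module_latent: pd.DataFrame  # samples × modules, realized f[m, s]
    variety_latent: pd.DataFrame  # varieties × modules, standardized levels
    planted_shift: dict[str, dict[str, float]]  # variety -> {metabolite: ±effect·σ}
    differential: dict[tuple[str, str], dict[str, str]]
    trait_loadings: dict[str, TraitLoading]
    enriched_pathways: dict[str, int]  # pathway id -> target module index


def generate(
    config: GeneratorConfig | None = None,
) -> tuple[MetaboliteTable, list[SampleInfo], TraitTable, PathwayMap, GroundTruth]:
    """Generate a complete input bundle plus its ground truth."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    varieties = [f"A{v + 1}" for v in range(config.n_varieties)]
    n_wine = config.n_varieties * config.n_reps
    p = config.n_metabolites

    samples = [
        SampleInfo(f"{v}_r{r + 1}", v, r + 1)
        for v in varieties
        for r in range(config.n_reps)
    ]
    variety_of = np.repeat(np.arange(config.n_varieties), config.n_reps)

    metabolite_ids = [f"met_{i + 1:04d}" for i in range(p)]
    classes = list(rng.choice(COMPOUND_CLASSES, size=p))

    # -- module membership ---------------------------------------------------
    module_of = np.full(p, -1, dtype=int)
    cursor = 0
    for k, spec in enumerate(config.modules):
        module_of[cursor : cursor + spec.size] = k
        cursor += spec.size

    # -- latent factors ------------------------------------------------------
    # Variety-level factor levels are drawn Gaussian, centered, then
    # orthogonalised (Gram–Schmidt): with only a handful of varieties two
    # independent draws can correlate strongly by chance, which would make
    # two planted modules indistinguishable; orthogonal levels plant
    # genuinely distinct modules.
    n_mod = len(config.modules)
    if n_mod >= config.n_varieties:
        raise OenometError("need fewer modules than varieties for distinct factors")
    if n_mod:
        g = rng.standard_normal((config.n_varieties, n_mod))
        g -= g.mean(axis=0)
        q, _ = np.linalg.qr(g)
        g_std = (q - q.mean(axis=0)) / q.std(axis=0, ddof=0)
    else:
        g_std = np.zeros((config.n_varieties, 0))
    f = g_std[variety_of] + config.latent_within_sd * rng.standard_normal(
        (n_wine, n_mod)
    )
    f /= np.sqrt(1.0 + config.latent_within_sd**2)  # unit-variance latent factor

    # -- planted variety shifts ---------------------------------------------
    pool = (
        np.arange(p)
        if config.differential_in_modules
        else np.flatnonzero(module_of == -1)
    )
    pool = rng.permutation(pool)
    planted_shift: dict[str, dict[str, float]] = {v: {} for v in varieties}
    delta = np.zeros((p, config.n_varieties))
    take = 0
    for vi, v in enumerate(varieties):
        chosen = pool[take : take + config.n_differential]
        take += config.n_differential
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        for i, s in zip(chosen, signs):
            sd_i = (
                config.module_amplitude if module_of[i] >= 0 else config.noise_sd
            )
            shift = s * config.differential_effect * sd_i
            delta[i, vi] = shift
            planted_shift[v][metabolite_ids[i]] = float(shift)

    # -- log-intensities -----------------------------------------------------
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(p)
    logX = np.empty((p, n_wine))
    eps = rng.standard_normal((p, n_wine))
    for i in range(p):
        m = module_of[i]
        if m >= 0:
            c = config.modules[m].latent_cor
            stoch = config.module_amplitude * (
                c * f[:, m] + np.sqrt(1.0 - c**2) * eps[i]
            )
        else:
            stoch = config.noise_sd * eps[i]
        logX[i] = baseline[i] + stoch + delta[i, variety_of]
    X = 10.0**logX

    # -- QC: pooled mean + small multiplicative noise ------------------------
    if config.n_qc:
        qc_mean = X.mean(axis=1, keepdims=True)
        qc = qc_mean * 10.0 ** (
            config.qc_noise_sd * rng.standard_normal((p, config.n_qc))
        )
        X = np.hstack([X, qc])
        samples = samples + [
            SampleInfo(f"QC_r{r + 1}", "QC", r + 1, is_qc=True)
            for r in range(config.n_qc)
        ]

    table = MetaboliteTable(metabolite_ids, classes, X, samples)

    # -- traits --------------------------------------------------------------
    trait_rows = {}
    effective_loadings: dict[str, TraitLoading] = {}
    for trait, tl in config.trait_loadings.items():
        if n_mod == 0:  # no modules: traits are pure noise around their base
            tl = dataclasses.replace(tl, coef=0.0)
            factor = np.zeros(config.n_varieties)
        else:
            if tl.module >= n_mod:  # fewer modules than the default wiring assumes
                tl = dataclasses.replace(tl, module=tl.module % n_mod)
            factor = g_std[:, tl.module]
        effective_loadings[trait] = tl
        vals = tl.base + tl.coef * factor + tl.noise_sd * rng.standard_normal(
            config.n_varieties
        )
        if trait in TASTE_TRAITS:
            vals = np.clip(vals, 0.0, 10.0)
        trait_rows[trait] = vals
    traits = TraitTable(pd.DataFrame(trait_rows, index=varieties))

    # -- pathway map ---------------------------------------------------------
    pw = config.pathways
    annotated = rng.permutation(p)[: int(round(pw.annotated_fraction * p))]
    annotated_set = set(annotated.tolist())
    mapping: dict[str, set[str]] = {}

    def annotate(i: int, pathway: str) -> None:
        mapping.setdefault(metabolite_ids[i], set()).add(pathway)

    enriched: dict[str, int] = {}
    module_rank = sorted(range(n_mod), key=lambda k: -config.modules[k].size)
    for j in range(min(pw.planted_enriched, n_mod)):
        mod = module_rank[j]
        name = f"path_planted_{j + 1}"
        members = [i for i in np.flatnonzero(module_of == mod) if i in annotated_set]
        n_in = int(round(pw.overlap * pw.planted_size))
        inside = rng.choice(members, size=min(n_in, len(members)), replace=False)
        outside_pool = [i for i in annotated if module_of[i] != mod]
        outside = rng.choice(
            outside_pool, size=pw.planted_size - len(inside), replace=False
        )
        for i in np.concatenate([inside, outside]):
            annotate(int(i), name)
        enriched[name] = mod
    for j in range(pw.n_pathways):
        size = int(rng.integers(10, 41))
        for i in rng.choice(annotated, size=size, replace=False):
            annotate(int(i), f"path_{j + 1:03d}")
    # guarantee every "annotated" metabolite has at least one pathway
    for i in annotated:
        if metabolite_ids[i] not in mapping:
            annotate(int(i), f"path_{int(rng.integers(1, pw.n_pathways + 1)):03d}")
    pathway_map = PathwayMap(mapping)

    # -- ground truth --------------------------------------------------------
    differential: dict[tuple[str, str], dict[str, str]] = {}
    for a in range(config.n_varieties):
        for b in range(config.n_varieties):
            if a == b:
                continue
            va, vb = varieties[a], varieties[b]
            d: dict[str, str] = {}
            for i in range(p):
                if delta[i, a] != delta[i, b]:
                    d[metabolite_ids[i]] = "up" if delta[i, b] > delta[i, a] else "down"
            differential[(va, vb)] = d

    truth = GroundTruth(
        module_assignment={
            metabolite_ids[i]: int(module_of[i])
            for i in range(p)
            if module_of[i] >= 0
        },
        module_latent=pd.DataFrame(
            f, index=[s.sample_id for s in samples[:n_wine]], columns=range(n_mod)
        ),
        variety_latent=pd.DataFrame(g_std, index=varieties, columns=range(n_mod)),
        planted_shift=planted_shift,
        differential=differential,
        trait_loadings=effective_loadings,
        enriched_pathways=enriched,
    )
    return table, samples, traits, pathway_map, truth


def worked_fixture_table3() -> TraitTable:
    """The six study wines' published L*, a*, b* means (colorimetry fixture).

    Returned as a :class:`TraitTable` fragment indexed by variety code;
    cultivar names are attached in ``values.attrs["cultivar"]``.
    """
    lab = {
        "A1": (66.91, 40.15, 7.00),
        "A2": (41.65, 167.48, 21.76),
        "A3": (73.76, 35.46, 7.24),
        "A4": (59.65, 53.30, 4.95),
        "A5": (63.22, 39.84, 17.34),
        "A6": (84.65, 17.05, 5.57),
    }
    df = pd.DataFrame(
        [lab[c] for c in lab], index=list(lab), columns=["L_star", "a_star", "b_star"]
    )
    df.attrs["cultivar"] = dict(CULTIVAR_NAMES)
    return TraitTable(df)
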