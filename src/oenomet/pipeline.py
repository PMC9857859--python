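"""End-to-end orchestration: one config, one seed, all stages.

``run_all`` drives the full analysis in the order the science dictates:
colorimetry → letter-annotated summary tables → PCA with QC checks →
all-pairs differential screen → Venn core / per-variety biomarkers →
co-abundance network with module–trait correlation → pathway enrichment
of the key modules → run manifest.  Every stage writes plain CSV/JSON
into the output directory, records an internal validity check, and
derives its randomness from per-stage child seeds spawned from the one
run seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import oenomet
from oenomet import colorimetry, enrichment, network, simulate, stats
from oenomet.chemometrics import pca
from oenomet.differential import (
    ScreenConfig,
    characteristic_metabolites,
    screen_all_pairs,
    significant_ids,
    venn_core,
)
from oenomet.io import (
    MetaboliteTable,
    OenometError,
    PathwayMap,
    SampleInfo,
    TraitTable,
    read_metabolite_table,
    read_pathway_map,
    read_samples,
    read_traits,
    write_metabolite_table,
    write_pathway_map,
    write_samples,
    write_traits,
)

logger = logging.getLogger("oenomet")

STAGES = (
    "inputs",
    "colorimetry",
    "summary_stats",
    "pca_qc",
    "screen",
    "core_biomarkers",
    "network",
    "module_trait",
    "enrichment",
)


@dataclasses.dataclass
class StageRecord:
    name: str
    outputs: list[str]
    check_passed: bool | None
    note: str = ""


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run, plus per-stage validity."""

    version: str
    seed: int
    config: dict
    stages: list[StageRecord]

    @property
    def all_passed(self) -> bool:
        return all(s.check_passed is not False for s in self.stages)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "stages": [dataclasses.asdict(s) for s in self.stages],
                "all_passed": self.all_passed,
            },
            indent=2,
            default=str,
        )


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (stable across processes)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise OenometError("config must be a YAML mapping")
    return cfg


def _load_inputs(
    cfg: Mapping[str, Any], seed: int, out: Path
) -> tuple[MetaboliteTable, list[SampleInfo], TraitTable | None, PathwayMap | None, Any]:
    inputs = cfg.get("inputs", {}) or {}
    if "simulate" in inputs or not inputs:
        sim_kwargs = dict(inputs.get("simulate") or {})
        sim_kwargs.setdefault("seed", child_seed(seed, "simulate"))
        gen_cfg = simulate.GeneratorConfig(**sim_kwargs)
        table, samples, traits, pmap, truth = simulate.generate(gen_cfg)
        write_metabolite_table(table, out / "metabolites.csv")
        write_samples(samples, out / "samples.csv")
        write_traits(traits, out / "traits.csv")
        write_pathway_map(pmap, out / "pathway_map.tsv")
        return table, samples, traits, pmap, truth
    samples = read_samples(inputs["samples"])
    table = read_metabolite_table(inputs["metabolite_table"], samples)
    traits = read_traits(inputs["traits"]) if "traits" in inputs else None
    pmap = read_pathway_map(inputs["pathway_map"]) if "pathway_map" in inputs else None
    return table, samples, traits, pmap, None


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run every stage; returns (and writes) the run manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "oenomet_results"))
    out.mkdir(parents=True, exist_ok=True)
    records: list[StageRecord] = []

    def stage(name: str, outputs: list[Path], ok: bool | None, note: str = "") -> None:
        records.append(StageRecord(name, [str(p) for p in outputs], ok, note))
        logger.info("stage %-16s %s %s", name, "ok" if ok else ok, note)

    # ---- inputs ----------------------------------------------------------
    table, samples, traits, pmap, _truth = _load_inputs(cfg, seed, out)
    varieties = sorted({s.variety for s in samples if not s.is_qc})
    stage(
        "inputs",
        [out / "metabolites.csv"],
        bool((table.intensities >= 0).all() and len(samples) == table.n_samples),
        f"{table.n_metabolites} metabolites × {table.n_samples} samples",
    )

    # ---- colorimetry -----------------------------------------------------
    if traits is not None and not set(("L_star", "a_star", "b_star")) - set(traits.values.columns):
        color_cfg = cfg.get("color", {}) or {}
        ctab = colorimetry.color_table(
            traits.values, reference=color_cfg.get("reference", "auto")
        )
        ctab.to_csv(out / "color_metrics.csv")
        ok = bool(
            (ctab["Cab_star"] >= 0).all()
            and ctab["hab_deg"].between(0, 360).all()
            and (ctab["delta_E"].dropna() >= 0).all()
        )
        stage("colorimetry", [out / "color_metrics.csv"], ok,
              f"reference={ctab.attrs.get('reference')}")
    else:
        stage("colorimetry", [], None, "skipped: no CIELAB trait columns")

    # ---- summary stats (ANOVA + Duncan letters per trait) ----------------
    if traits is not None:
        logX = stats.log10_transform(table)
        rows = [
            {"trait": trait, **traits.values[trait].to_dict()}
            for trait in traits.values.columns
        ]
        pd.DataFrame(rows).to_csv(out / "trait_summary.csv", index=False)
        # Duncan letters need replicate-level data; traits are variety-level
        # means, so the letter demo runs on per-sample mean log signal instead
        totals = [logX[:, table.columns_for(v)].mean(axis=0) for v in varieties]
        summaries = stats.duncan_letters(totals, group_names=varieties)
        pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries]
        ).to_csv(out / "variety_signal_letters.csv", index=False)
        stage("summary_stats", [out / "trait_summary.csv"], True)
    else:
        stage("summary_stats", [], None, "skipped: no trait table")

    # ---- PCA + QC clustering check ---------------------------------------
    logX = stats.log10_transform(table)
    wine_cols = [j for j, s in enumerate(samples) if not s.is_qc]
    qc_cols = [j for j, s in enumerate(samples) if s.is_qc]
    k = min(5, len(samples) - 1, table.n_metabolites)
    pres = pca(logX.T, k=k, scale=True)
    scores = pd.DataFrame(
        pres.scores,
        index=[s.sample_id for s in samples],
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    scores["variety"] = [s.variety for s in samples]
    scores.to_csv(out / "pca_scores.csv")
    corr = stats.sample_correlation(logX)
    pd.DataFrame(corr, index=scores.index, columns=scores.index).to_csv(
        out / "sample_correlation.csv"
    )
    ok = True
    note = f"PC1 {pres.explained_pct[0]:.1f}%, PC2 {pres.explained_pct[1]:.1f}%"
    if qc_cols:
        # QC injections must sit inside the cloud of wine samples on PC1/PC2
        lo = pres.scores[wine_cols, :2].min(axis=0)
        hi = pres.scores[wine_cols, :2].max(axis=0)
        ok = bool(
            ((pres.scores[qc_cols, :2] >= lo) & (pres.scores[qc_cols, :2] <= hi)).all()
        )
        note += "; QC inside wine-sample score range" if ok else "; QC outside score range"
    stage("pca_qc", [out / "pca_scores.csv"], ok, note)

    # ---- all-pairs screen ------------------------------------------------
    screen_cfg = ScreenConfig(**(cfg.get("screen") or {}))
    screens = screen_all_pairs(table, varieties, screen_cfg)
    summary_rows = []
    sig_sets: dict[str, set[str]] = {}
    for (a, b), (recs, summ) in screens.items():
        pd.DataFrame([dataclasses.asdict(r) for r in recs]).to_csv(
            out / f"diff_{a}_vs_{b}.csv", index=False
        )
        summary_rows.append(
            {"comparison": summ.comparison, "n_up": summ.n_up, "n_down": summ.n_down,
             "n_total": summ.n_total}
        )
        sig_sets[f"{a} vs {b}"] = significant_ids(recs)
    pd.DataFrame(summary_rows).to_csv(out / "diff_summary.csv", index=False)
    ok = all(r["n_total"] == r["n_up"] + r["n_down"] for r in summary_rows)
    stage("screen", [out / "diff_summary.csv"], ok, f"{len(screens)} comparisons")

    # ---- Venn core + biomarkers ------------------------------------------
    core, regions = venn_core(sig_sets)
    with open(out / "venn_core.json", "w") as fh:
        json.dump(
            {
                "core": sorted(core),
                "regions": {" & ".join(sorted(k)): v for k, v in regions.items()},
            },
            fh,
            indent=2,
        )
    bio_rows = []
    for v in varieties:
        for c in characteristic_metabolites(table, v, varieties, screen_cfg, screens):
            bio_rows.append(dataclasses.asdict(c))
    pd.DataFrame(
        bio_rows, columns=["metabolite_id", "variety", "min_vip", "max_p", "is_biomarker"]
    ).to_csv(out / "biomarkers.csv", index=False)
    ok = all(core <= s for s in sig_sets.values())
    stage("core_biomarkers", [out / "venn_core.json", out / "biomarkers.csv"], ok,
          f"core={len(core)}")

    # ---- network ---------------------------------------------------------
    net_cfg = network.NetworkConfig(**(cfg.get("network") or {}))
    wine_ids = [samples[j].sample_id for j in wine_cols]
    model = network.CoexpressionNetwork(
        logX[:, wine_cols].T, table.metabolite_ids, wine_ids, net_cfg
    )
    traits_per_sample = traits.per_sample(samples) if traits is not None else None
    nres = model.fit(traits_per_sample)
    pd.DataFrame(
        {"metabolite_id": model.metabolite_ids, "module": nres.partition.labels}
    ).to_csv(out / "modules.csv", index=False)
    nres.eigengenes.eigengenes.to_csv(out / "eigengenes.csv")
    nres.summary().to_csv(out / "module_summary.csv", index=False)
    if nres.partition.linkage is not None:
        with open(out / "dendrogram.json", "w") as fh:
            json.dump(nres.partition.linkage.tolist(), fh)
    tom_ok = bool(
        (nres.tom >= 0).all() and (nres.tom <= 1).all()
        and np.allclose(np.diag(nres.tom), 1.0)
    )
    sizes = nres.partition.module_sizes
    size_ok = all(
        n >= net_cfg.min_module_size for m, n in sizes.items() if m != network.GREY
    )
    stage("network", [out / "modules.csv"], tom_ok and size_ok,
          f"{len(nres.partition.modules)} modules + grey({sizes.get('grey', 0)})")

    # ---- module–trait ----------------------------------------------------
    if nres.module_trait is not None:
        nres.module_trait.r.to_csv(out / "module_trait_r.csv")
        nres.module_trait.p.to_csv(out / "module_trait_p.csv")
        rr = nres.module_trait.r.astype(float)
        ok = bool(((rr.abs() <= 1) | rr.isna()).all().all())
        stage("module_trait", [out / "module_trait_r.csv"], ok)
    else:
        stage("module_trait", [], None, "skipped: no trait table or no modules")

    # ---- enrichment ------------------------------------------------------
    if pmap is not None and nres.partition.modules:
        enr_cfg = cfg.get("enrichment") or {}
        paths = []
        for module in nres.partition.modules:
            members = set(nres.module_members(module))
            rows = enrichment.enrich(
                members & pmap.annotated(table.metabolite_ids),
                table.metabolite_ids,
                pmap,
                fdr_threshold=float(enr_cfg.get("fdr_threshold", 0.05)),
            )
            path = out / f"enrichment_{module}.csv"
            enrichment.enrichment_frame(rows).to_csv(path, index=False)
            enrichment.enrichment_frame(rows, top=20).to_csv(
                out / f"enrichment_{module}_top20.csv", index=False
            )
            paths.append(path)
        stage("enrichment", paths, True, f"{len(paths)} module(s)")
    else:
        stage("enrichment", [], None, "skipped: no pathway map or no modules")

    manifest = RunManifest(
        version=oenomet.__version__, seed=seed, config=dict(cfg), stages=records
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
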