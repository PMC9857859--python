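"""Tabular input/output and the shared data model.

The pipeline's central object is :class:`MetaboliteTable`, a non-negative
peak-area matrix (metabolites × samples) in which every metabolite carries
one of the 18 controlled compound-class labels used for widely-targeted
wine metabolomics deliverables.  Sample metadata, per-variety sensory
traits and the metabolite→pathway annotation map are small companion
tables.  All readers accept comma- or tab-delimited text with a dot
decimal separator, regardless of locale.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oenomet")

#: Controlled compound-class vocabulary (18 classes).
COMPOUND_CLASSES: tuple[str, ...] = (
    "amino acids",
    "alkaloids",
    "flavonoids",
    "phenols",
    "terpenoids",
    "quinones",
    "steroids",
    "lignans",
    "coumarins",
    "carboxylic acids & organic oxygen",
    "vitamins & organic acids",
    "nucleotides",
    "phenylpropanoids",
    "sugars & alcohols",
    "lipids & aromatics",
    "phytohormones",
    "tryptamines/indoles/pyridines/imidazoles",
    "other",
)

#: Wine variety codes; QC marks pooled quality-control injections.
VARIETY_CODES: tuple[str, ...] = ("A1", "A2", "A3", "A4", "A5", "A6")

#: Sensory trait columns: CIELAB color coordinates plus six 0–10 taste scores.
COLOR_TRAITS: tuple[str, ...] = ("L_star", "a_star", "b_star")
TASTE_TRAITS: tuple[str, ...] = (
    "balance_coordination",
    "thickness",
    "astringency",
    "aftertaste",
    "layering",
    "acidity",
)
TRAIT_COLUMNS: tuple[str, ...] = COLOR_TRAITS + TASTE_TRAITS


class OenometError(ValueError):
    """Hard validation error on malformed input."""


@dataclasses.dataclass(frozen=True)
class SampleInfo:
    """One injection: wine sample or pooled QC.

    ``variety`` is a code in A1..A6 or ``"QC"``; QC samples carry
    ``is_qc=True`` and their replicate number indexes repeat injections.
    """

    sample_id: str
    variety: str
    replicate: int
    is_qc: bool = False

    def __post_init__(self) -> None:
        if self.variety not in VARIETY_CODES and self.variety != "QC":
            raise OenometError(
                f"unknown variety code {self.variety!r} for sample "
                f"{self.sample_id!r}; expected one of {VARIETY_CODES + ('QC',)}"
            )
        if self.variety == "QC" and not self.is_qc:
            raise OenometError(f"sample {self.sample_id!r} has variety QC but is_qc=False")
        if self.replicate < 1:
            raise OenometError(f"replicate must be a positive integer ({self.sample_id!r})")


class MetaboliteTable:
    """Annotated intensity matrix (metabolites × samples).

    Parameters
    ----------
    metabolite_ids : sequence of unique strings
    class_labels : one controlled compound-class string per metabolite;
        unknown labels are coerced to ``"other"`` with a warning.
    intensities : array-like, shape (n_metabolites, n_samples), all >= 0
    samples : optional list of :class:`SampleInfo`; if given its length
        must equal the column count.
    sample_ids : optional column names used when ``samples`` is absent.
    """

    def __init__(
        self,
        metabolite_ids: Sequence[str],
        class_labels: Sequence[str],
        intensities,
        samples: Sequence[SampleInfo] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        ids = list(metabolite_ids)
        seen: set[str] = set()
        for mid in ids:
            if mid in seen:
                raise OenometError(f"duplicate metabolite id {mid!r}")
            seen.add(mid)
        X = np.asarray(intensities, dtype=float)
        if X.ndim != 2 or X.shape[0] != len(ids):
            raise OenometError(
                f"intensity matrix shape {X.shape} does not match {len(ids)} metabolites"
            )
        neg = np.argwhere(X < 0)
        if neg.size:
            i, j = neg[0]
            raise OenometError(
                f"negative intensity at metabolite {ids[i]!r}, column {j} ({X[i, j]})"
            )
        labels = []
        for mid, lab in zip(ids, class_labels, strict=True):
            lab = str(lab).strip().lower()
            if lab not in COMPOUND_CLASSES:
                warnings.warn(
                    f"unknown compound class {lab!r} for {mid!r}; set to 'other'",
                    stacklevel=2,
                )
                lab = "other"
            labels.append(lab)
        if samples is not None and len(samples) != X.shape[1]:
            raise OenometError(
                f"{len(samples)} sample records for {X.shape[1]} intensity columns"
            )
        self.metabolite_ids: list[str] = ids
        self.class_labels: list[str] = labels
        self.intensities: np.ndarray = X
        self.samples: list[SampleInfo] | None = list(samples) if samples is not None else None
        if sample_ids is not None and len(sample_ids) != X.shape[1]:
            raise OenometError("sample_ids length does not match column count")
        self._sample_ids: list[str] | None = list(sample_ids) if sample_ids is not None else None

    # -- basic container protocol -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        if self.samples is not None:
            return [s.sample_id for s in self.samples]
        if self._sample_ids is not None:
            return list(self._sample_ids)
        return [f"S{j + 1}" for j in range(self.n_samples)]

    def to_frame(self) -> pd.DataFrame:
        """Intensities as a DataFrame indexed by metabolite id."""
        return pd.DataFrame(
            self.intensities, index=self.metabolite_ids, columns=self.sample_ids
        )

    def columns_for(self, variety: str) -> np.ndarray:
        """Column indices of the non-QC samples of one variety."""
        if self.samples is None:
            raise OenometError("table carries no sample metadata")
        idx = [
            j
            for j, s in enumerate(self.samples)
            if s.variety == variety and not s.is_qc
        ]
        if not idx:
            raise OenometError(f"no samples for variety {variety!r}")
        return np.asarray(idx, dtype=int)

    def subset(self, metabolite_ids: Iterable[str]) -> "MetaboliteTable":
        wanted = list(metabolite_ids)
        pos = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows = [pos[m] for m in wanted]
        return MetaboliteTable(
            wanted,
            [self.class_labels[i] for i in rows],
            self.intensities[rows],
            self.samples,
            sample_ids=self._sample_ids,
        )

    def imputed(self) -> np.ndarray:
        """Intensities with exact zeros replaced for log transforms.

        Zeros are treated as missing and imputed with half the metabolite's
        minimum positive value (standard practice for peak-area matrices);
        an all-zero metabolite raises, since no log scale exists for it.
        """
        X = self.intensities.copy()
        for i in range(X.shape[0]):
            row = X[i]
            zero = row == 0
            if zero.any():
                pos = row[~zero]
                if pos.size == 0:
                    raise OenometError(
                        f"metabolite {self.metabolite_ids[i]!r} is all-zero; cannot impute"
                    )
                row[zero] = pos.min() / 2.0
        return X


@dataclasses.dataclass
class TraitTable:
    """Per-variety sensory traits: CIELAB color plus six 0–10 taste scores.

    ``values`` is a DataFrame indexed by variety code with columns from
    :data:`TRAIT_COLUMNS`; optional columns may be absent (flagged in
    ``missing``).  Taste attributes must lie in [0, 10].
    """

    values: pd.DataFrame
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for v in self.values.index:
            if v not in VARIETY_CODES:
                raise OenometError(f"trait table row {v!r} is not a variety code")
        if self.values.index.has_duplicates:
            raise OenometError("duplicate variety rows in trait table")
        for col in self.values.columns:
            if col not in TRAIT_COLUMNS:
                raise OenometError(f"unknown trait column {col!r}")
            if col in TASTE_TRAITS:
                bad = self.values[(self.values[col] < 0) | (self.values[col] > 10)]
                if len(bad):
                    raise OenometError(
                        f"taste score out of [0, 10] for {col!r} in variety "
                        f"{bad.index[0]!r}: {bad[col].iloc[0]}"
                    )

    @property
    def varieties(self) -> list[str]:
        return list(self.values.index)

    def per_sample(self, samples: Sequence[SampleInfo]) -> pd.DataFrame:
        """Broadcast variety-level traits to a per-sample matrix (QC dropped).

        Traits are measured once per wine; correlating them with per-sample
        module expression requires repeating each variety's row across its
        replicates.
        """
        rows = []
        index = []
        for s in samples:
            if s.is_qc:
                continue
            rows.append(self.values.loc[s.variety])
            index.append(s.sample_id)
        return pd.DataFrame(rows, index=index)


@dataclasses.dataclass
class PathwayMap:
    """Metabolite → set-of-pathway-ids annotation (KEGG-style codes accepted).

    ``categories`` optionally carries a pathway → hierarchy-category label
    (e.g. "metabolism"); it is reported, never tested.
    """

    mapping: dict[str, set[str]]
    categories: dict[str, str] = dataclasses.field(default_factory=dict)

    @property
    def pathways(self) -> set[str]:
        out: set[str] = set()
        for s in self.mapping.values():
            out |= s
        return out

    def members(self, pathway: str) -> set[str]:
        return {m for m, ps in self.mapping.items() if pathway in ps}

    def annotated(self, universe: Iterable[str] | None = None) -> set[str]:
        """Metabolites with at least one annotation, optionally ∩ universe."""
        ids = set(self.mapping)
        if universe is not None:
            ids &= set(universe)
        return ids

    def flag_unknown(self, universe: Iterable[str]) -> set[str]:
        """Annotated metabolites absent from ``universe`` (retained, flagged)."""
        extra = set(self.mapping) - set(universe)
        if extra:
            logger.warning(
                "pathway map contains %d metabolites absent from the table", len(extra)
            )
        return extra


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    """Auto-detect comma vs tab from the header line."""
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _read_delimited(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise OenometError(f"file not found: {p}")
    return pd.read_csv(p, sep=_sniff_sep(p))


def read_metabolite_table(
    path: str | Path, samples: Sequence[SampleInfo] | None = None
) -> MetaboliteTable:
    """Read an intensity table: id, class, then one numeric column per sample."""
    df = _read_delimited(path)
    if df.shape[1] < 3:
        raise OenometError(f"{path}: need id, class and at least one sample column")
    ids = df.iloc[:, 0].astype(str).tolist()
    classes = df.iloc[:, 1].astype(str).tolist()
    try:
        X = df.iloc[:, 2:].astype(float).to_numpy()
    except ValueError as exc:
        raise OenometError(f"{path}: non-numeric intensity value ({exc})") from exc
    return MetaboliteTable(
        ids, classes, X, samples, sample_ids=None if samples else list(df.columns[2:])
    )


def write_metabolite_table(table: MetaboliteTable, path: str | Path, sep: str = ",") -> None:
    df = table.to_frame()
    out = pd.DataFrame({"metabolite_id": table.metabolite_ids, "class": table.class_labels})
    out = pd.concat([out, df.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False)


def read_samples(path: str | Path) -> list[SampleInfo]:
    """Read sample metadata: sample_id, variety, replicate[, is_qc]."""
    df = _read_delimited(path)
    required = {"sample_id", "variety", "replicate"}
    if not required <= set(df.columns):
        raise OenometError(f"{path}: sample table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        variety = str(row["variety"])
        is_qc = bool(row["is_qc"]) if "is_qc" in df.columns else variety == "QC"
        out.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                variety=variety,
                replicate=int(row["replicate"]),
                is_qc=is_qc,
            )
        )
    return out


def write_samples(samples: Sequence[SampleInfo], path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "variety": [s.variety for s in samples],
            "replicate": [s.replicate for s in samples],
            "is_qc": [s.is_qc for s in samples],
        }
    ).to_csv(path, sep=sep, index=False)


def read_traits(path: str | Path) -> TraitTable:
    """Read per-variety traits; first column is the variety code."""
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    present = [c for c in TRAIT_COLUMNS if c in df.columns]
    unknown = [c for c in df.columns if c not in TRAIT_COLUMNS]
    if unknown:
        raise OenometError(f"{path}: unknown trait columns {unknown}")
    missing = tuple(c for c in TRAIT_COLUMNS if c not in present)
    if missing:
        logger.warning("trait table lacks optional columns: %s", ", ".join(missing))
    return TraitTable(df[present].astype(float), missing=missing)


def write_traits(traits: TraitTable, path: str | Path, sep: str = ",") -> None:
    traits.values.rename_axis("variety").to_csv(path, sep=sep)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a two-column map: metabolite_id, pathway_id with optional ;category."""
    p = Path(path)
    if not p.exists():
        raise OenometError(f"file not found: {p}")
    sep = _sniff_sep(p)
    mapping: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    lines = p.read_text().splitlines()
    for k, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.split(sep)
        if k == 0 and parts[0].strip().lower() in {"metabolite_id", "metabolite"}:
            continue
        if len(parts) < 2:
            raise OenometError(f"{p}:{k + 1}: expected metabolite_id{sep}pathway_id")
        mid, pw = parts[0].strip(), parts[1].strip()
        if ";" in pw:
            pw, cat = pw.split(";", 1)
            categories[pw] = cat.strip()
        mapping.setdefault(mid, set()).add(pw)
    return PathwayMap(mapping, categories)


def write_pathway_map(pmap: PathwayMap, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"metabolite_id{sep}pathway_id\n")
        for mid in sorted(pmap.mapping):
            for pw in sorted(pmap.mapping[mid]):
                cat = pmap.categories.get(pw)
                fh.write(f"{mid}{sep}{pw}{';' + cat if cat else ''}\n")


def broadcast_traits(traits: TraitTable, samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Convenience alias for :meth:`TraitTable.per_sample`."""
    return traits.per_sample(samples)
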