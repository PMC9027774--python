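"""Domain containers and text-format I/O shared by every pipeline stage.

All tabular data travels as plain TSV/CSV; gene sets use the de-facto GMT
exchange format. The in-memory containers are thin, validated wrappers around
:class:`pandas.DataFrame` so downstream stages can lean on pandas alignment.

File conventions
----------------
* methylation matrix: TSV, probes as rows, first column ``probe_id``,
  remaining columns sample ids. β values or M values.
* paired signal intensities: same layout, two columns per sample named
  ``<sample>.Meth`` and ``<sample>.Unmeth``.
* annotation: BED-like TSV with 1-based positions and the columns
  ``chromosome, position, probe_id, promoter_id, gene_id, tiling_id,
  cpg_island_id, promoter_annotated``; missing region memberships are ``NA``.
* sample sheet: CSV with columns ``sample_id, group`` (+ optional covariates);
  group is ``case``/``hypersensitive`` or ``control``/``tolerant``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SampleSheet",
    "SignalIntensities",
    "MethylationMatrix",
    "ProbeAnnotation",
    "GeneSetCollection",
    "read_sample_sheet",
    "read_dataset",
    "read_gene_sets_gmt",
    "write_tables",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "REGION_KINDS",
]

#: region categories a probe can belong to
REGION_KINDS = ("tiling", "gene", "promoter", "cpg_island")

#: numeric print precision for every table written by the pipeline
FLOAT_FORMAT = "%.10g"

_GROUP_ALIASES = {
    "case": "case",
    "hypersensitive": "case",
    "hypersensitivity": "case",
    "control": "control",
    "tolerant": "control",
    "normal": "control",
}


@dataclass
class SampleSheet:
    """Sample-to-group assignment (case = drug-hypersensitive, control = tolerant)."""

    data: pd.DataFrame  # index: sample_id; columns: group (+ covariates)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if "group" not in self.data.columns:
            raise ValueError("sample sheet needs a 'group' column")
        bad = set(self.data["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.data["group"].value_counts()
        for g in ("case", "control"):
            if counts.get(g, 0) < 2:
                raise ValueError(f"need at least 2 samples in group '{g}'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def ids_in(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])

    @property
    def n_case(self) -> int:
        return len(self.ids_in("case"))

    @property
    def n_control(self) -> int:
        return len(self.ids_in("control"))


@dataclass
class MethylationMatrix:
    """Probes × samples methylation values with an explicit scale flag.

    ``scale='beta'`` constrains finite values to [0, 1]; ``scale='m'`` is the
    unbounded logit scale. NaN entries are permitted only until QC.
    """

    values: pd.DataFrame  # index: probe_id, columns: sample_id
    scale: str  # 'beta' | 'm'

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ValueError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids in matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in matrix")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "beta":
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("β out of range: values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples absent from matrix: {sorted(missing)}")
        return MethylationMatrix(self.values.loc[:, ids].copy(), self.scale)


@dataclass
class SignalIntensities:
    """Paired methylated/unmethylated channel intensities per probe and sample.

    ``alpha`` is the offset added to the denominator when converting to β; the
    array default is 100.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    alpha: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be ≥ 0")
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("methylated/unmethylated matrices must share probe and sample ids")
        for name, frame in (("methylated", self.meth), ("unmethylated", self.unmeth)):
            vals = frame.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"negative {name} intensity")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.meth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    def select_samples(self, sample_ids: Iterable[str]) -> "SignalIntensities":
        ids = list(sample_ids)
        missing = set(ids) - set(self.meth.columns)
        if missing:
            raise KeyError(f"samples absent from intensities: {sorted(missing)}")
        return SignalIntensities(
            self.meth.loc[:, ids].copy(), self.unmeth.loc[:, ids].copy(), self.alpha
        )


_ANNOTATION_COLUMNS = [
    "chromosome",
    "position",
    "probe_id",
    "promoter_id",
    "gene_id",
    "tiling_id",
    "cpg_island_id",
    "promoter_annotated",
]


@dataclass
class ProbeAnnotation:
    """Probe → genomic location and region memberships.

    ``promoter_annotated`` marks probes whose promoter is an annotated
    protein-coding promoter; ribosomal-RNA, pseudogene and unannotated
    promoters carry ``False`` and are excluded from promoter-level summaries.
    """

    data: pd.DataFrame  # index: probe_id

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        missing = set(_ANNOTATION_COLUMNS) - {"probe_id"} - set(self.data.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        bad = self.data["promoter_annotated"] & self.data["promoter_id"].isna()
        if bad.any():
            raise ValueError(
                "promoter_annotated=True requires a promoter_id "
                f"(offending probes: {list(self.data.index[bad])[:5]})"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def region_column(self, kind: str) -> pd.Series:
        if kind not in REGION_KINDS:
            raise ValueError(f"kind must be one of {REGION_KINDS}, got {kind!r}")
        return self.data[f"{kind}_id"]

    def restrict(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        keep = self.data.index.intersection(list(probe_ids))
        return ProbeAnnotation(self.data.loc[keep].copy())

    def promoter_gene_map(self) -> pd.Series:
        """promoter_id → gene_id, restricted to annotated promoters."""
        ann = self.data[self.data["promoter_annotated"] & self.data["promoter_id"].notna()]
        return ann.groupby("promoter_id")["gene_id"].first()


@dataclass
class GeneSetCollection:
    """Named gene sets (flat, deduplicated) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# readers


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("sample sheet must have 'sample_id' and 'group' columns")
    df = df.set_index("sample_id")
    unknown = set(df["group"].str.lower()) - set(_GROUP_ALIASES)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    df["group"] = df["group"].str.lower().map(_GROUP_ALIASES)
    return SampleSheet(df)


def read_matrix_tsv(path: str | Path, index_col: str = "probe_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if index_col not in df.columns:
        raise ValueError(f"matrix file must have a first column {index_col!r}")
    return df.set_index(index_col)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chromosome": str})
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    df = df.set_index("probe_id")
    df["promoter_annotated"] = df["promoter_annotated"].astype(bool)
    df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def _split_intensity_columns(df: pd.DataFrame) -> SignalIntensities:
    meth_cols = [c for c in df.columns if c.endswith(".Meth")]
    unmeth_cols = [c for c in df.columns if c.endswith(".Unmeth")]
    samples_m = [c[: -len(".Meth")] for c in meth_cols]
    samples_u = [c[: -len(".Unmeth")] for c in unmeth_cols]
    if not samples_m or sorted(samples_m) != sorted(samples_u):
        raise ValueError(
            "intensity matrix needs paired '<sample>.Meth'/'<sample>.Unmeth' columns"
        )
    meth = df[meth_cols].copy()
    meth.columns = samples_m
    unmeth = df[unmeth_cols].copy()
    unmeth.columns = samples_u
    return SignalIntensities(meth, unmeth[samples_m])


def read_dataset(
    sample_sheet_path: str | Path,
    matrix_path: str | Path,
    annotation_path: str | Path,
    matrix_kind: str = "beta",
    alpha: float = 100.0,
) -> tuple[SampleSheet, MethylationMatrix | SignalIntensities, ProbeAnnotation]:
    """Read and align the three input files of a study.

    The matrix may carry extra samples (dropped); a sample-sheet sample absent
    from the matrix is an error. Probes present in the matrix but missing from
    the annotation are reported via :class:`UserWarning` and the returned
    annotation is restricted to the matrix probes, order preserved.
    """
    if matrix_kind not in ("beta", "intensities"):
        raise ValueError("matrix_kind must be 'beta' or 'intensities'")
    sheet = read_sample_sheet(sample_sheet_path)
    raw = read_matrix_tsv(matrix_path)
    annotation = read_annotation(annotation_path)

    data: MethylationMatrix | SignalIntensities
    if matrix_kind == "beta":
        data = MethylationMatrix(raw.astype(float), scale="beta").select_samples(
            sheet.sample_ids
        )
    else:
        data = _split_intensity_columns(raw.astype(float))
        data.alpha = alpha
        data = data.select_samples(sheet.sample_ids)

    probe_ids = data.probe_ids
    unannotated = [p for p in probe_ids if p not in annotation.data.index]
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} matrix probe(s) missing from annotation: "
            f"{unannotated[:10]}",
            UserWarning,
            stacklevel=2,
        )
    annotated = annotation.data.reindex([p for p in probe_ids if p in annotation.data.index])
    return sheet, data, ProbeAnnotation(annotated)


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Within-set duplicates are dropped; a line without genes is skipped with a
    warning; a repeated set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need at least name and description")
            name, description, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} lists no genes; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            sets[name] = frozenset(genes)
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# writers


def write_matrix_tsv(
    frame: pd.DataFrame, path: str | Path, index_label: str = "probe_id"
) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label, na_rep="NA")


def write_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | Path, index_labels: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Write every result table as TSV under ``out_dir`` plus a JSON manifest.

    Returns the manifest mapping table name → file name. Column order is the
    DataFrame's own (deterministic); floats print at 10 significant digits so a
    written matrix re-reads to within 1e-9.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_labels = dict(index_labels or {})
    manifest: dict[str, str] = {}
    for name in results:
        fname = f"{name}.tsv"
        label = index_labels.get(name, results[name].index.name or "id")
        write_matrix_tsv(results[name], out / fname, index_label=label)
        manifest[name] = fname
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
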