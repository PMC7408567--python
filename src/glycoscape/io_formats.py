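"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated with a header row; matrices carry gene
identifiers in the first column and sample identifiers in the header.  Readers
validate aggressively and never silently coerce: a bad value is rejected with
its gene/sample coordinate in the message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

REGIONS = ("core", "edge", "middle")

CLINICAL_COLUMNS = [
    "sample_id",
    "cancer_type",
    "sample_type",
    "stage",
    "os_time",
    "os_event",
    "aneuploidy_score",
    "genome_doublings",
]

MUTATION_COLUMNS = ["sample_id", "gene_id", "nonsynonymous"]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2(TPM+1) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene (set {self.name!r})")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CNAMatrix:
    """Genes x samples GISTIC-thresholded calls in {-1, 0, 1}."""

    gene_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if not np.issubdtype(self.calls.dtype, np.integer):
            as_int = self.calls.astype(int, casting="unsafe")
            if not np.array_equal(as_int, self.calls):
                raise FormatError("CNA calls must be integers")
            self.calls = as_int
        if self.calls.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("CNA call shape does not match ids")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        bad = np.argwhere(~np.isin(self.calls, (-1, 0, 1)))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"CNA entry {self.calls[i, j]} outside {{-1,0,1}} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CellMatrix:
    """Single-cell raw counts plus per-cell patient and spatial-region labels."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sparse.csr_matrix
    cell_meta: pd.DataFrame  # indexed by cell_id; columns patient_id, region

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"count shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count encountered")
        if not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise FormatError("counts must be integers")
        if list(self.cell_meta.index) != list(self.cell_ids):
            raise FormatError("cell metadata rows must align with cell ids")
        for col in ("patient_id", "region"):
            if col not in self.cell_meta.columns:
                raise FormatError(f"cell metadata missing column {col!r}")
            if self.cell_meta[col].isna().any():
                raise FormatError(f"cell metadata column {col!r} has missing values")
        bad = set(self.cell_meta["region"]) - set(REGIONS)
        if bad:
            raise FormatError(
                f"unknown region label(s) {sorted(bad)}; allowed: {list(REGIONS)}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Parse a Broad-dialect GMT file: name <tab> description <tab> genes..."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name in names:
                raise FormatError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            names.add(name)
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "gene set %r: removed %d duplicate gene(s)", name, len(genes) - len(deduped)
                )
            sets.append(GeneSet(name=name, genes=deduped))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def read_matrix(path, kind: str = "expression"):
    """Read a genes-x-samples TSV (first column gene ids, header sample ids)."""
    if kind not in ("expression", "cna"):
        raise ValueError(f"kind must be 'expression' or 'cna', got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    if kind == "expression":
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
        return ExpressionMatrix(genes, samples, values)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        flt = df.to_numpy(dtype=float)
        if not np.array_equal(flt, np.round(flt)):
            bad = np.argwhere(flt != np.round(flt))[0]
            raise FormatError(
                f"{path}: non-integer CNA entry at gene {genes[bad[0]]!r}, "
                f"sample {samples[bad[1]]!r}"
            )
        values = flt.astype(int)
    return CNAMatrix(genes, samples, values)


def write_matrix(mat, path, float_format: str = "%.10g") -> None:
    df = mat.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# clinical / mutation tables
# ---------------------------------------------------------------------------


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV with fixed header; empty strings are explicit missing."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: clinical table missing columns {missing_cols}")
    df = df[CLINICAL_COLUMNS].copy()
    _check_unique(df["sample_id"], "clinical sample")
    bad_type = set(df["sample_type"]) - {"tumor", "normal"}
    if bad_type:
        raise FormatError(f"{path}: unknown sample_type value(s) {sorted(bad_type)}")
    for col in ("os_time", "os_event", "aneuploidy_score", "genome_doublings"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["os_time"].dropna() < 0).any():
        raise FormatError(f"{path}: negative os_time")
    if not df["os_event"].dropna().isin([0, 1]).all():
        raise FormatError(f"{path}: os_event must be 0 or 1")
    if not df["genome_doublings"].dropna().isin([0, 1, 2]).all():
        raise FormatError(f"{path}: genome_doublings must be 0, 1 or 2")
    ok_stage = df["stage"].isna() | df["stage"].isin(["I", "II", "III", "IV"])
    if not ok_stage.all():
        bad = df.loc[~ok_stage, "stage"].unique().tolist()
        raise FormatError(f"{path}: unknown stage value(s) {bad}")
    return df.set_index("sample_id", drop=False)


def write_clinical(df: pd.DataFrame, path) -> None:
    df[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: mutation table missing columns {missing}")
    df = df[MUTATION_COLUMNS].copy()
    if not df["nonsynonymous"].isin([True, False]).all():
        raise FormatError(f"{path}: nonsynonymous must be boolean")
    df["nonsynonymous"] = df["nonsynonymous"].astype(bool)
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def read_cells(mtx_path, genes_path, meta_path) -> CellMatrix:
    """Load MatrixMarket counts with a one-column gene list and a cell-metadata TSV."""
    counts = sparse.csr_matrix(spio.mmread(mtx_path))
    genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if meta.empty:
        raise FormatError(f"{meta_path}: cell metadata is empty")
    for col in ("cell_id", "patient_id", "region"):
        if col not in meta.columns:
            raise FormatError(f"{meta_path}: metadata missing column {col!r}")
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"MTX has {counts.shape[0]} rows but gene list has {len(genes)} entries"
        )
    if counts.shape[1] != len(meta):
        raise FormatError(
            f"MTX has {counts.shape[1]} columns but metadata has {len(meta)} rows"
        )
    meta = meta.set_index("cell_id", drop=False)
    return CellMatrix(genes, list(meta.index), counts, meta[["patient_id", "region"]])


def write_cells(cells: CellMatrix, mtx_path, genes_path, meta_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(cells.counts))
    with open(genes_path, "w") as fh:
        fh.write("\n".join(cells.gene_ids) + "\n")
    meta = cells.cell_meta.copy()
    meta.insert(0, "cell_id", cells.cell_ids)
    meta.to_csv(meta_path, sep="\t", index=False)
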