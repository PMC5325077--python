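"""Readers and writers for every external file the pipeline touches.

Dialects (all plain text, tab separated):

* **Expression table** — first column ``gene_id``, then one column per slice
  labelled ``EMBRYOID_sliceNN`` with NN 1-based anterior-to-posterior;
  column blocks are contiguous per embryo and FPKM values are written with
  6 significant digits.
* **Metadata** — columns ``embryo_id, genotype, stage, n_slices,
  failed_slices`` where ``failed_slices`` is a comma-separated list of
  1-based slice numbers (empty if none failed).
* **Peaks / enhancers** — BED4+ (0-based half-open; column 4 = TF or
  enhancer name, optional column 5 = score).
* **TSS table** — columns ``gene_id, chrom, position, strand`` with
  1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EmbryoSample

__all__ = [
    "ExpressionTable",
    "PeakSet",
    "write_expression_table",
    "read_expression_table",
    "read_peaks",
    "read_enhancers",
    "enhancer_centers",
    "read_tss",
    "write_tss",
    "write_peaks",
]

_SLICE_SEP = "_slice"


@dataclass(frozen=True)
class ExpressionTable:
    """A cohort: ordered genes, ordered embryos, concatenated slice columns."""

    gene_ids: tuple
    embryos: tuple  # of EmbryoSample, column blocks in this order

    @property
    def values(self) -> np.ndarray:
        """genes x (sum of slice counts) FPKM matrix."""
        return np.hstack([e.values for e in self.embryos])

    def embryo(self, embryo_id: str) -> EmbryoSample:
        for e in self.embryos:
            if e.embryo_id == embryo_id:
                return e
        raise KeyError(embryo_id)

    def by_genotype(self, genotype: str, stage=None) -> list[EmbryoSample]:
        return [e for e in self.embryos
                if e.genotype == genotype and (stage is None or e.stage == stage)]


def _column_labels(embryo: EmbryoSample) -> list[str]:
    return [f"{embryo.embryo_id}{_SLICE_SEP}{i + 1:02d}"
            for i in range(embryo.n_slices)]


def write_expression_table(embryos, path, metadata_path) -> None:
    """Write a cohort as expression + metadata TSVs (deterministic order)."""
    embryos = list(embryos)
    if not embryos:
        raise ValueError("no embryos to write")
    gene_ids = embryos[0].gene_ids
    for e in embryos:
        if e.gene_ids != gene_ids:
            raise ValueError(f"embryo {e.embryo_id}: gene list differs")
        if _SLICE_SEP in e.embryo_id:
            raise ValueError(f"embryo id may not contain {_SLICE_SEP!r}")
    header = ["gene_id"]
    for e in embryos:
        header.extend(_column_labels(e))
    matrix = np.hstack([e.values for e in embryos])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for gene, row in zip(gene_ids, matrix):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    meta = pd.DataFrame({
        "embryo_id": [e.embryo_id for e in embryos],
        "genotype": [e.genotype for e in embryos],
        "stage": [e.stage for e in embryos],
        "n_slices": [e.n_slices for e in embryos],
        "failed_slices": [
            ",".join(str(i + 1) for i in np.flatnonzero(~e.qc_mask))
            for e in embryos],
    })
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression_table(path, metadata_path) -> ExpressionTable:
    """Read an expression TSV plus its metadata TSV back into embryo samples."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id'")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError(f"{path}: expression values must be finite and >= 0")
    gene_ids = tuple(df["gene_id"])

    # parse EMBRYOID_sliceNN labels into contiguous per-embryo blocks
    blocks: list[tuple[str, int, int]] = []  # (embryo_id, start_col, n)
    for j, label in enumerate(df.columns[1:]):
        if _SLICE_SEP not in label:
            raise ValueError(
                f"{path}: column {label!r} lacks the {_SLICE_SEP!r} separator")
        embryo_id, _, num = label.rpartition(_SLICE_SEP)
        try:
            slice_no = int(num)
        except ValueError:
            raise ValueError(f"{path}: bad slice number in column {label!r}")
        if blocks and blocks[-1][0] == embryo_id:
            if slice_no != blocks[-1][2] + 1:
                raise ValueError(
                    f"{path}: embryo {embryo_id} slice numbering not dense "
                    f"(got {slice_no} after {blocks[-1][2]})")
            blocks[-1] = (embryo_id, blocks[-1][1], slice_no)
        else:
            if any(b[0] == embryo_id for b in blocks):
                raise ValueError(
                    f"{path}: embryo {embryo_id} columns are not contiguous")
            if slice_no != 1:
                raise ValueError(
                    f"{path}: embryo {embryo_id} numbering must start at 1")
            blocks.append((embryo_id, j, 1))

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"failed_slices": str},
                       keep_default_na=False)
    meta_idx = {row.embryo_id: row for row in meta.itertuples()}
    for embryo_id in meta_idx:
        if not any(b[0] == embryo_id for b in blocks):
            raise ValueError(
                f"{metadata_path}: unknown embryo id {embryo_id!r} "
                "(no matching columns in the expression table)")

    embryos = []
    for embryo_id, start, n in blocks:
        if embryo_id not in meta_idx:
            raise ValueError(f"{path}: embryo {embryo_id!r} missing from metadata")
        row = meta_idx[embryo_id]
        if int(row.n_slices) != n:
            raise ValueError(
                f"metadata n_slices={row.n_slices} but table has {n} columns "
                f"for embryo {embryo_id}")
        qc_mask = np.ones(n, dtype=bool)
        failed = str(row.failed_slices).strip()
        if failed:
            for tok in failed.split(","):
                idx = int(tok)
                if not 1 <= idx <= n:
                    raise ValueError(
                        f"metadata: failed slice {idx} out of range for "
                        f"embryo {embryo_id}")
                qc_mask[idx - 1] = False
        embryos.append(EmbryoSample(
            embryo_id, str(row.genotype), int(row.stage), gene_ids,
            values[:, start:start + n], qc_mask))
    return ExpressionTable(gene_ids, tuple(embryos))


@dataclass(frozen=True)
class PeakSet:
    """Genomic intervals (0-based half-open) with a name per interval."""

    intervals: pd.DataFrame  # columns: chrom, start, end, name, score

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def names(self) -> pd.Series:
        return self.intervals["name"]


def read_peaks(path) -> PeakSet:
    """Parse a BED4+ file; column 4 names the TF (or enhancer).

    Comment (#) and track/browser header lines are skipped.  Coordinates are
    kept 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line.strip() or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            if not name:
                raise ValueError(f"{path}:{lineno}: empty name field")
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in ("", ".") else 0.0
            rows.append((chrom, start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    if df.empty:
        df = df.astype({"start": int, "end": int, "score": float})
    return PeakSet(df)


read_enhancers = read_peaks


def enhancer_centers(enhancers: PeakSet) -> pd.DataFrame:
    """Per-enhancer centre coordinate, floor((start + end) / 2), 0-based."""
    df = enhancers.intervals
    out = df[["chrom", "name"]].copy()
    out["center"] = (df["start"] + df["end"]) // 2
    return out


def read_tss(path) -> pd.DataFrame:
    """Read a TSS table (gene_id, chrom, position, strand; 1-based positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    df["position"] = df["position"].astype(int)
    return df.reset_index(drop=True)


def write_tss(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_peaks(peaks: PeakSet, path) -> None:
    peaks.intervals.to_csv(path, sep="\t", index=False, header=False)
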