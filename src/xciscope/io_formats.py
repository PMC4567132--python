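"""Readers and writers for every external file format the pipeline touches.

All readers validate strictly and raise :class:`~xciscope.types.ValidationError`
rather than coercing bad data. Formats are deliberately plain text:

* probe manifest — TSV with header ``probe_id  chrom  pos  cpg_island``
* methylation — TSV, first column ``probe_id``, one column per sample,
  empty cell = missing beta
* copy number — SEG (IGV/Firehose dialect): ``Sample  Chromosome  Start  End
  [Num_Probes]  Segment_Mean``; chromosome ``23``/``X`` is normalized to
  ``chrX``
* expression — TSV, first column ``gene_id``, one column per sample (RSEM)
* clinical — CSV with a ``sample_id`` column; empty cell = missing
* CTA panels — one gene per line, ``#`` comments and blank lines ignored;
  an optional ``# location: X_linked|autosomal`` pragma sets the panel location
* calls — TSV emitted by :func:`write_calls`, round-trippable via
  :func:`read_calls`

Positions are 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CALLS_COLUMNS,
    CLINICAL_COLUMNS,
    ClinicalTable,
    CnvSegmentSet,
    CTAPanel,
    ExpressionMatrix,
    MethylationMatrix,
    ProbeManifest,
    ValidationError,
    XciCall,
    calls_to_frame,
    frame_to_calls,
    normalize_chromosome,
)

logger = logging.getLogger(__name__)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(raw: str, where: str) -> bool:
    val = str(raw).strip().lower()
    if val in _TRUE:
        return True
    if val in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean {raw!r} at {where}")


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest TSV (``probe_id chrom pos cpg_island``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["probe_id", "chrom", "pos", "cpg_island"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns {missing}")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise ValidationError(f"manifest {path} line {i}: bad position {row.pos!r}")
        rows.append(
            {
                "probe_id": row.probe_id,
                "chromosome": normalize_chromosome(row.chrom),
                "position": pos,
                "cpg_island": _parse_bool(row.cpg_island, f"line {i}"),
            }
        )
    return ProbeManifest(pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "cpg_island"]))


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    out = manifest.df.rename(columns={"chromosome": "chrom", "position": "pos"})
    out.to_csv(path, sep="\t", index=False)


def read_methylation(path: str | Path, manifest: ProbeManifest) -> MethylationMatrix:
    """Read a beta-value matrix, restricted to probes present in ``manifest``.

    Probes absent from the manifest are dropped (count logged); beta values
    outside [0, 1] are rejected with probe/sample coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    df = df.apply(pd.to_numeric, errors="raise")
    known = set(manifest.probe_ids)
    keep = df.index.isin(known)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_methylation: dropped %d probes absent from manifest", dropped)
    df = df.loc[keep]
    return MethylationMatrix(df.astype(float))


def write_methylation(matrix: MethylationMatrix, path: str | Path) -> None:
    matrix.beta.to_csv(path, sep="\t", index_label="probe_id")


def read_seg(path: str | Path) -> CnvSegmentSet:
    """Read a SEG file (tab-separated, IGV/Firehose dialect)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {c.lower(): c for c in df.columns}
    required = ["sample", "chromosome", "start", "end", "segment_mean"]
    missing = [c for c in required if c not in colmap]
    if missing:
        raise ValidationError(f"SEG file {path} missing columns {missing}")
    seg = pd.DataFrame(
        {
            "sample_id": df[colmap["sample"]],
            "chromosome": [normalize_chromosome(c) for c in df[colmap["chromosome"]]],
            "start": pd.to_numeric(df[colmap["start"]]).astype(int),
            "end": pd.to_numeric(df[colmap["end"]]).astype(int),
            "seg_mean": pd.to_numeric(df[colmap["segment_mean"]]).astype(float),
        }
    )
    return CnvSegmentSet(seg)


def write_seg(segments: CnvSegmentSet, path: str | Path) -> None:
    out = segments.segments.rename(
        columns={
            "sample_id": "Sample",
            "chromosome": "Chromosome",
            "start": "Start",
            "end": "End",
            "seg_mean": "Segment_Mean",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples RSEM matrix; empty cells are missing."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df = df.apply(pd.to_numeric, errors="raise").astype(float)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.rsem.to_csv(path, sep="\t", index_label="gene_id")


_CLINICAL_BOOL = ("os_event", "dfs_event")
_CLINICAL_FLOAT = ("age", "os_time", "dfs_time")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read the clinical CSV; empty cells become NaN (missing)."""
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"clinical file {path} lacks sample_id column")
    df = df.set_index("sample_id")
    for col in _CLINICAL_FLOAT:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _CLINICAL_BOOL:
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: np.nan if pd.isna(v) or str(v).strip() == ""
                else _parse_bool(v, f"column {col}")
            )
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    out = table.df.copy()
    for col in _CLINICAL_BOOL:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(bool(v)).lower())
    out.to_csv(path, index_label="sample_id")


def read_panel(path: str | Path, name: str | None = None, location: str | None = None) -> CTAPanel:
    """Read a plain-text gene list (one gene per line, ``#`` comments ignored).

    A ``# location: X_linked`` (or ``autosomal``) pragma inside the file sets
    the panel location unless ``location`` is given explicitly.
    """
    path = Path(path)
    genes: list[str] = []
    file_location = None
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("location:"):
                file_location = body.split(":", 1)[1].strip()
            continue
        genes.append(stripped)
    return CTAPanel(
        name=name or path.stem,
        gene_ids=tuple(dict.fromkeys(genes)),
        location=location or file_location or "autosomal",
    )


def write_panel(panel: CTAPanel, path: str | Path) -> None:
    lines = [f"# location: {panel.location}"] + list(panel.gene_ids)
    Path(path).write_text("\n".join(lines) + "\n")


def write_calls(calls: list[XciCall] | pd.DataFrame, path: str | Path) -> None:
    """Write one row per sample with its XCI group and evidence fields."""
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    out = df.copy()
    out["override_applied"] = out["override_applied"].map(lambda v: str(bool(v)).lower())
    out.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[XciCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CALLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"calls file {path} missing columns {missing}")
    df["override_applied"] = df["override_applied"].map(
        lambda v: _parse_bool(v, "override_applied")
    )
    return frame_to_calls(df)


def read_calls_frame(path: str | Path) -> pd.DataFrame:
    """Calls file as a DataFrame (convenience for the stats stages)."""
    return calls_to_frame(read_calls(path))
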