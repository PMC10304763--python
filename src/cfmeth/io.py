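"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions are normalised at this boundary: internally every
position is the 1-based cytosine position on the plus strand.  Bismark
coverage files are already 1-based; bedGraph-dialect files (as emitted by
MethylDackel) are 0-based half-open and are shifted on input.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import MethylationAtlas, SignatureMatrix
from .deconv import BulkProfile
from .probemap import CALL_COLUMNS, MethylationCallSet, ProbeManifest

__all__ = [
    "read_calls",
    "write_calls",
    "read_atlas",
    "write_atlas",
    "read_manifest",
    "write_manifest",
    "read_signature",
    "write_signature",
    "read_sample_sheet",
    "read_bulk_profile",
    "write_bulk_profile",
]

DIALECTS = ("bismark_cov", "bedgraph")
_CALL_FILE_COLUMNS = ["chrom", "start", "end", "meth_pct", "n_meth", "n_unmeth"]


def read_calls(path, dialect: str = "bismark_cov", sample_id: str | None = None) -> MethylationCallSet:
    """Read a per-CpG methylation call file.

    Both dialects share the six columns chrom, start, end, methylation %,
    methylated count, unmethylated count; ``bismark_cov`` starts are
    1-based, ``bedgraph`` starts 0-based (converted on input).  A stated
    percentage inconsistent with the counts triggers a warning naming the
    line; the counts win.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    table = pd.read_csv(
        path,
        sep=r"\s+",
        comment="t",  # skips optional 'track ...' header lines
        names=_CALL_FILE_COLUMNS,
        header=None,
        dtype={"chrom": str},
    )
    if table[["start", "n_meth", "n_unmeth"]].isna().any().any():
        bad = table[table[["start", "n_meth", "n_unmeth"]].isna().any(axis=1)]
        raise ValueError(f"malformed lines in {path.name}: {list(bad.index + 1)[:5]}")
    if (table[["n_meth", "n_unmeth"]] < 0).any().any():
        raise ValueError(f"negative counts in {path.name}")
    pos = table["start"].astype(int) + (1 if dialect == "bedgraph" else 0)
    coverage = (table["n_meth"] + table["n_unmeth"]).astype(int)
    with np.errstate(invalid="ignore"):
        implied = 100.0 * table["n_meth"] / coverage.replace(0, np.nan)
    off = (table["meth_pct"] - implied).abs() > 0.5
    if off.any():
        lines = list(table.index[off] + 1)
        warnings.warn(
            f"{int(off.sum())} lines in {path.name} state a methylation % "
            f"inconsistent with the counts (e.g. line {lines[0]}); counts win"
        )
    calls = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": pos,
            "strand": "+",
            "n_meth": table["n_meth"].astype(int),
            "coverage": coverage,
        }
    )[CALL_COLUMNS]
    calls = calls[calls["coverage"] >= 1].reset_index(drop=True)
    return MethylationCallSet(sample_id or path.stem, calls)


def write_calls(callset: MethylationCallSet, path, dialect: str = "bismark_cov") -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    calls = callset.calls
    start = calls["pos"] - (1 if dialect == "bedgraph" else 0)
    pct = 100.0 * calls["n_meth"] / calls["coverage"]
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": start,
            "end": calls["pos"],
            "meth_pct": pct.round(6),
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["coverage"] - calls["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_atlas(path, coords_path=None) -> MethylationAtlas:
    """Atlas CSV: first column probe ID, remaining columns cell-type betas.

    An optional coordinate sidecar CSV (probe_id, chrom, pos, strand)
    populates the atlas coordinates.
    """
    beta = pd.read_csv(path, index_col=0)
    beta.index.name = "probe_id"
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, index_col=0, dtype={"chrom": str})
        coords.index.name = "probe_id"
    return MethylationAtlas(beta, coords)


def write_atlas(atlas: MethylationAtlas, path, coords_path=None) -> None:
    atlas.beta.to_csv(path)
    if coords_path is not None and atlas.coords is not None:
        atlas.coords.to_csv(coords_path)


_MANIFEST_ALIASES = {"IlmnID": "probe_id", "CHR": "chrom", "MAPINFO": "pos", "Strand": "strand"}


def read_manifest(path) -> ProbeManifest:
    """Manifest CSV with columns IlmnID/CHR/MAPINFO/Strand or probe_id/chrom/pos/strand."""
    table = pd.read_csv(path, dtype=str).rename(columns=_MANIFEST_ALIASES)
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    table["pos"] = table["pos"].astype(int)
    if "strand" not in table.columns:
        table["strand"] = "+"
    return ProbeManifest(table.set_index("probe_id")[["chrom", "pos", "strand"]])


def write_manifest(manifest: ProbeManifest, path) -> None:
    out = manifest.table.reset_index(names="probe_id")
    out.columns = ["IlmnID", "CHR", "MAPINFO", "Strand"]
    out.to_csv(path, index=False)


def write_signature(signature: SignatureMatrix, path) -> None:
    out = signature.beta.copy()
    out["provenance"] = signature.provenance
    out.to_csv(path, sep="\t")


def read_signature(path) -> SignatureMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    provenance = table.pop("provenance")
    return SignatureMatrix(table, provenance)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV indexed by sample with at least group and ccfdna_ng_per_ml."""
    sheet = pd.read_csv(path, index_col=0)
    for col in ("group", "ccfdna_ng_per_ml"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    return sheet


def read_bulk_profile(path, sample_id: str | None = None) -> BulkProfile:
    table = pd.read_csv(path, sep="\t", index_col=0)
    series = table.iloc[:, 0]
    return BulkProfile(sample_id or Path(path).stem, series)


def write_bulk_profile(bulk: BulkProfile, path) -> None:
    bulk.beta.rename("beta").to_frame().rename_axis("probe_id").to_csv(path, sep="\t")
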