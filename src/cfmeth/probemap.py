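"""Map bisulfite methylation calls in genomic coordinates to array probe IDs.

Bisulfite callers emit per-cytosine counts on both strands.  CpG dyads are
symmetric, so a minus-strand call at position p belongs to the same CpG as
the plus-strand call at p - 1; :func:`collapse_strands` merges them.
:func:`map_to_probes` then matches the collapsed calls to a methylation
array probe manifest by exact (chrom, position), yielding a probe-indexed
bulk beta vector suitable for deconvolution.

All coordinates are 1-based and fully closed; file readers normalise other
dialects on input (see :mod:`cfmeth.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconv import BulkProfile

__all__ = ["MethylationCallSet", "ProbeManifest", "collapse_strands", "map_to_probes"]

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "coverage"]


@dataclass
class MethylationCallSet:
    """Per-sample stranded CpG methylation counts.

    ``calls`` has columns chrom, pos (1-based cytosine position), strand
    ('+'/'-'), n_meth (methylated reads) and coverage (total reads).
    """

    sample_id: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CALL_COLUMNS) - set(self.calls.columns)
        if missing:
            raise ValueError(f"call table missing columns: {sorted(missing)}")
        calls = self.calls
        if (calls["coverage"] < 1).any():
            raise ValueError("coverage must be >= 1")
        if ((calls["n_meth"] < 0) | (calls["n_meth"] > calls["coverage"])).any():
            raise ValueError("need 0 <= n_meth <= coverage")
        if calls.duplicated(subset=["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) records")

    @property
    def beta(self) -> pd.Series:
        return self.calls["n_meth"] / self.calls["coverage"]


@dataclass
class ProbeManifest:
    """Array probe manifest: probe_id -> (chrom, 1-based + strand CpG position)."""

    table: pd.DataFrame  # indexed by probe_id; columns chrom, pos, strand

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("probe IDs in manifest must be unique")
        for col in ("chrom", "pos"):
            if col not in self.table.columns:
                raise ValueError(f"manifest missing column {col!r}")


def collapse_strands(callset: MethylationCallSet) -> MethylationCallSet:
    """Merge minus-strand calls into their CpG dyad partner on the plus strand.

    A '-' record at position p is summed into the '+' record at p - 1.  A
    minus-strand call with no plus partner is still moved to p - 1 (the
    cytosine position of its dyad) with a warning.  Output is entirely on
    the plus strand; total counts are conserved.
    """
    calls = callset.calls
    minus = calls[calls["strand"] == "-"].copy()
    plus = calls[calls["strand"] == "+"].copy()
    if not minus.empty:
        minus["pos"] = minus["pos"] - 1
        minus["strand"] = "+"
        plus_keys = set(zip(plus["chrom"], plus["pos"]))
        orphans = [
            key for key in zip(minus["chrom"], minus["pos"]) if key not in plus_keys
        ]
        if orphans:
            warnings.warn(
                f"{len(orphans)} minus-strand calls had no plus-strand dyad "
                "partner; kept at the dyad cytosine position"
            )
    merged = (
        pd.concat([plus, minus], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "coverage"]]
        .sum()
    )
    merged["strand"] = "+"
    return MethylationCallSet(callset.sample_id, merged[CALL_COLUMNS])


def map_to_probes(
    callset: MethylationCallSet,
    manifest: ProbeManifest,
    min_coverage: int = 1,
) -> BulkProfile:
    """Aggregate strand-collapsed calls onto manifest probes by exact position.

    Calls below ``min_coverage`` are dropped first.  When several call
    records match one probe the beta is the coverage-weighted mean,
    ``sum(n_meth) / sum(coverage)``.  Probes without a matching call are
    absent from the output vector.
    """
    calls = callset.calls
    if (calls["strand"] != "+").any():
        raise ValueError("calls must be strand-collapsed before probe mapping")
    calls = calls[calls["coverage"] >= min_coverage]
    manifest_keyed = manifest.table.reset_index(names="probe_id")
    joined = calls.merge(manifest_keyed, on=["chrom", "pos"], how="inner")
    if joined.empty:
        raise ValueError(
            f"no overlap between calls of sample {callset.sample_id!r} and manifest"
        )
    agg = joined.groupby("probe_id")[["n_meth", "coverage"]].sum()
    beta = (agg["n_meth"] / agg["coverage"]).rename(callset.sample_id)
    return BulkProfile(callset.sample_id, beta.sort_index())
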