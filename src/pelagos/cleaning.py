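"""Quality control of depth-georeferenced occurrence records.

Two anomalies occur in depth-referenced occurrence data: negative depths
(typically intertidal records) and sample depths that exceed the gridded
bottom depth.  The second arises because the sample depth is a point
measurement while bottom depth is a cell average, or from imprecise sounding;
such samples are taken to be from the sea bed, the sample depth is trusted,
and the bottom depth is reconciled to it.

Rules are applied in a fixed order — negative depths are dropped first, then
exceedances reconciled — because the exceedance fraction's denominator
depends on the order.  Zero depths are surface samples and are retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["CleaningReport", "clean_records", "count_unique_locations"]


@dataclass(frozen=True)
class CleaningReport:
    """What cleaning changed.

    ``frac_exceed`` uses the pre-removal record count ``n_input`` as its
    denominator; the post-removal fraction is recoverable from the counts.
    """

    n_input: int
    n_negative_sample_removed: int
    n_negative_bottom_removed: int
    n_exceed_reconciled: int
    frac_exceed: float
    n_output: int
    n_unique_locations: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def clean_records(records: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the QC rules and report what was changed.

    Records with a negative sample depth are removed, then records with a
    negative bottom depth; for every remaining record with
    ``sample_depth > bottom_depth`` the bottom depth is set equal to the
    sample depth.  The output satisfies ``sample_depth <= bottom_depth``
    everywhere, and cleaning is idempotent.  Empty input yields empty output
    and a zeroed report.
    """
    if "sample_depth" not in records.columns or "bottom_depth" not in records.columns:
        raise ValueError("clean_records needs both sample_depth and bottom_depth")
    n_input = len(records)
    sample = records["sample_depth"].to_numpy(dtype=float)
    bottom = records["bottom_depth"].to_numpy(dtype=float)

    neg_sample = sample < 0
    neg_bottom = ~neg_sample & (bottom < 0)
    keep = ~neg_sample & ~neg_bottom
    out = records.loc[keep].copy()

    exceed = out["sample_depth"].to_numpy(dtype=float) > out["bottom_depth"].to_numpy(dtype=float)
    n_exceed = int(exceed.sum())
    out.loc[exceed, "bottom_depth"] = out.loc[exceed, "sample_depth"]
    out = out.reset_index(drop=True)

    report = CleaningReport(
        n_input=n_input,
        n_negative_sample_removed=int(neg_sample.sum()),
        n_negative_bottom_removed=int(neg_bottom.sum()),
        n_exceed_reconciled=n_exceed,
        frac_exceed=n_exceed / n_input if n_input else 0.0,
        n_output=len(out),
        n_unique_locations=count_unique_locations(out),
    )
    assert (out["sample_depth"] <= out["bottom_depth"]).all()
    return out, report


def count_unique_locations(records: pd.DataFrame) -> int:
    """Distinct (latitude, longitude, sample_depth) triples, exact equality."""
    if len(records) == 0:
        return 0
    return int(len(records[["latitude", "longitude", "sample_depth"]].drop_duplicates()))
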