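"""Visualization-grade 4C interaction profiles.

Raw fragment counts are normalized to reads per million (RPM) within each
library, smoothed with a centered running mean over fragment indices, and
averaged across replicates of the same condition.  Smoothing comes before
averaging, and at chromosome edges the window shrinks to the available
fragments so the profile stays full-length for bedGraph export.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix


@dataclass
class Profile:
    """Per-fragment signal aligned 1:1 with the fragment map."""

    values: pd.Series  # index: fragment index
    label: str
    smooth_window: int = 1

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")


def normalize_rpm(cm: CountMatrix, library_id: str) -> Profile:
    """Reads-per-million: count * 1e6 / library total over counted fragments."""
    total = cm.total(library_id)
    if total == 0:
        raise ValueError(f"library {library_id!r} has zero total count; "
                         "cannot normalize to RPM")
    values = cm.counts[library_id].astype(float) * 1e6 / total
    return Profile(values=values, label=library_id)


def smooth_running_mean(p: Profile, window: int = 5) -> Profile:
    """Centered running mean over fragment indices; edges shrink the window."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    # min_periods=1 implements the edge-shrink rule.
    smoothed = p.values.rolling(window, center=True, min_periods=1).mean()
    return Profile(values=smoothed, label=p.label, smooth_window=window)


def average_replicates(profiles: Sequence[Profile],
                       label: str | None = None) -> Profile:
    """Per-fragment arithmetic mean of replicate profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if not p.values.index.equals(first.values.index):
            raise ValueError("profiles are on different fragment maps")
    stacked = pd.concat([p.values for p in profiles], axis=1)
    mean = stacked.mean(axis=1)
    return Profile(values=mean,
                   label=label or "+".join(p.label for p in profiles),
                   smooth_window=first.smooth_window)


def write_bedgraph(p: Profile, fragments, path: str | Path,
                   track_name: str | None = None) -> None:
    """bedGraph export (chrom, start, end, value), one line per fragment."""
    by_index = {f.index: f for f in fragments}
    with open(path, "w") as fh:
        name = track_name or p.label
        fh.write(f'track type=bedGraph name="{name}"\n')
        for idx, val in p.values.items():
            f = by_index[idx]
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{val:.6g}\n")
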