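"""From electropherogram profiles to the cross-sample community matrix.

The fingerprint of each sample is reduced to relative peak areas inside
the sizing window, thresholded at a minimum relative area, and binned on
a fixed base-pair grid anchored at the window minimum so that fragment
sizes align across samples.  Bins are half-open ``[c, c+w)``; the window
itself is closed and the final bin absorbs the upper edge exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyProfileError, UsageError
from .types import Peak, PeakProfile

log = logging.getLogger(__name__)


def window_filter(
    profile: PeakProfile, window: tuple[float, float] | None = None
) -> PeakProfile:
    """Drop peaks outside the closed sizing window ``[min, max]``."""
    win = window if window is not None else profile.window
    lo, hi = win
    if not lo < hi:
        raise UsageError(f"invalid window {win}")
    kept = [p for p in profile.peaks if lo <= p.size_bp <= hi]
    removed = len(profile.peaks) - len(kept)
    if removed:
        log.info(
            "%s/%s: removed %d of %d peaks outside [%g, %g]",
            profile.sample_id, profile.enzyme, removed, len(profile.peaks), lo, hi,
        )
    return PeakProfile(profile.sample_id, profile.enzyme, kept, win)


def normalize_profile(profile: PeakProfile, min_rel_area: float = 0.0) -> PeakProfile:
    """Convert areas to relative areas, drop peaks below ``min_rel_area``,
    and renormalize the remainder to sum to 1."""
    if not 0 <= min_rel_area < 1:
        raise UsageError("min_rel_area must be in [0, 1)")
    total = profile.total_area
    if total <= 0:
        raise EmptyProfileError(
            f"{profile.sample_id}/{profile.enzyme}: zero total area"
        )
    kept = [p for p in profile.peaks if p.area / total >= min_rel_area]
    if not kept:
        raise EmptyProfileError(
            f"{profile.sample_id}/{profile.enzyme}: no peaks above "
            f"min_rel_area={min_rel_area}"
        )
    new_total = sum(p.area for p in kept)
    peaks = [Peak(p.size_bp, p.height, p.area / new_total) for p in kept]
    return PeakProfile(profile.sample_id, profile.enzyme, peaks, profile.window)


@dataclass
class CommunityMatrix:
    """Samples × binned fragment sizes, holding relative areas in [0, 1]."""

    sample_ids: list[str]
    bins: list[float]  # bin centers, bp
    values: np.ndarray  # shape (n_samples, n_bins)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.bins)):
            raise UsageError("matrix shape does not match labels")
        if len(self.bins) > 1 and not np.all(np.diff(self.bins) > 0):
            raise UsageError("bins must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bins)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CommunityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(
            sample_ids=[str(s) for s in df.index],
            bins=[float(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


def build_matrix(
    profiles: list[PeakProfile], bin_width_bp: float = 1.0
) -> CommunityMatrix:
    """Bin normalized profiles of a single enzyme onto a common grid.

    Bin ``i`` covers ``[min + i*w, min + (i+1)*w)`` with the window
    maximum folded into the last bin; bins empty in every sample are
    dropped.  Binning conserves each row's total relative area.
    """
    if not profiles:
        raise UsageError("build_matrix: no profiles")
    enzymes = {p.enzyme for p in profiles}
    if len(enzymes) > 1:
        raise UsageError(f"build_matrix: mixed enzymes {sorted(enzymes)}")
    if bin_width_bp <= 0:
        raise UsageError("bin_width_bp must be positive")
    lo, hi = profiles[0].window
    n_bins = int(np.ceil((hi - lo) / bin_width_bp))
    values = np.zeros((len(profiles), n_bins))
    for row, profile in enumerate(profiles):
        for peak in profile.peaks:
            if not lo <= peak.size_bp <= hi:
                raise UsageError(
                    f"{profile.sample_id}: peak at {peak.size_bp} bp outside "
                    "window; apply window_filter first"
                )
            idx = min(int((peak.size_bp - lo) / bin_width_bp), n_bins - 1)
            values[row, idx] += peak.area
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width_bp
    occupied = values.sum(axis=0) > 0
    return CommunityMatrix(
        sample_ids=[p.sample_id for p in profiles],
        bins=[float(c) for c in centers[occupied]],
        values=values[:, occupied],
    )
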