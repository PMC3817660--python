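"""Attribution of electropherogram peaks to clone-derived taxa.

Predicted terminal fragments from the in silico digest are the typed
evidence; observed peaks are noisy measurements.  Each detected fragment
therefore seeks its nearest peak within a sizing tolerance, and the area
of every peak is credited to the taxonomic groups of the fragments it
collected.  Peaks claimed by more than one group at the chosen level are
reported once under a combined label (e.g.
``Bacteroidetes+Epsilonproteobacteria``) — groups that share a fragment
size cannot be separated by a single-enzyme fingerprint — unless the
equal-split mode is selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyProfileError, UsageError
from .types import Peak, PeakProfile, TerminalFragment, group_label

log = logging.getLogger(__name__)

UNATTRIBUTED = "unattributed"
UNCLASSIFIED = "unclassified"


@dataclass
class PeakAttribution:
    """One observed peak and the predicted fragments assigned to it."""

    sample_id: str
    enzyme: str
    peak: Peak
    matched_fragments: list[TerminalFragment] = field(default_factory=list)

    @property
    def taxa(self) -> set[str]:
        return {f.taxon for f in self.matched_fragments if f.taxon is not None}

    def groups(self, level: str) -> set[str]:
        """Group labels implied by the matches at ``level`` (phylum|class)."""
        out: set[str] = set()
        for f in self.matched_fragments:
            g = group_label(f.taxon, level)
            out.add(g if g is not None else UNCLASSIFIED)
        return out


@dataclass
class CoverageReport:
    """Per-group percentages of total profile area for one electropherogram.

    ``percentages`` may contain combined ``A+B`` labels for shared peaks;
    together with ``unattributed`` the entries always total 100.
    """

    sample_id: str
    enzyme: str
    percentages: dict[str, float]
    unattributed: float

    def total(self) -> float:
        return sum(self.percentages.values()) + self.unattributed


def match_fragments(
    fragments: list[TerminalFragment],
    profile: PeakProfile,
    tolerance_bp: float = 1.0,
) -> list[PeakAttribution]:
    """Assign each detected fragment to its nearest peak within tolerance.

    Returns one attribution per peak (possibly with no matches), ordered
    by peak size.  Distance ties break toward the smaller peak size.
    Fragments for other enzymes are a usage error; undetected fragments
    and fragments with no peak in tolerance are logged as unmatched.
    """
    wrong = {f.enzyme for f in fragments} - {profile.enzyme}
    if wrong:
        raise UsageError(
            f"fragments for enzymes {sorted(wrong)} do not match profile "
            f"enzyme {profile.enzyme}"
        )
    if tolerance_bp <= 0:
        raise UsageError("tolerance_bp must be positive")
    peaks = profile.sorted_by_size()
    attributions = [
        PeakAttribution(profile.sample_id, profile.enzyme, p) for p in peaks
    ]
    sizes = np.array([p.size_bp for p in peaks])
    n_unmatched = 0
    for frag in fragments:
        if not frag.detected:
            continue
        if sizes.size == 0:
            n_unmatched += 1
            continue
        dist = np.abs(sizes - frag.length_bp)
        best = int(np.argmin(dist))  # argmin takes the first = smallest size on ties
        if dist[best] <= tolerance_bp:
            attributions[best].matched_fragments.append(frag)
        else:
            n_unmatched += 1
    if n_unmatched:
        log.info(
            "%s/%s: %d fragments had no peak within %g bp",
            profile.sample_id, profile.enzyme, n_unmatched, tolerance_bp,
        )
    return attributions


def unmatched_fragments(
    fragments: list[TerminalFragment], attributions: list[PeakAttribution]
) -> list[TerminalFragment]:
    """Detected fragments that were not assigned to any peak."""
    matched = {
        id(f) for a in attributions for f in a.matched_fragments
    }
    return [f for f in fragments if f.detected and id(f) not in matched]


def coverage_percentages(
    attributions: list[PeakAttribution],
    profile: PeakProfile,
    group_level: str = "class",
    shared_mode: str = "combined",
) -> CoverageReport:
    """Percentage of total profile area credited to each taxonomic group.

    ``shared_mode="combined"`` reports multi-group peaks once under a
    joined ``A+B`` label; ``"split"`` divides their area equally among the
    groups.  The unattributed percentage is the exact complement of the
    attributed total, so conservation to 100 holds by construction.
    """
    if shared_mode not in ("combined", "split"):
        raise UsageError(f"unknown shared_mode {shared_mode!r}")
    total = profile.total_area
    if total <= 0 or not attributions:
        raise EmptyProfileError(
            f"{profile.sample_id}/{profile.enzyme}: empty profile"
        )
    areas: dict[str, float] = {}
    for att in attributions:
        groups = sorted(att.groups(group_level))
        if not groups:
            continue
        if len(groups) == 1 or shared_mode == "combined":
            label = "+".join(groups)
            areas[label] = areas.get(label, 0.0) + att.peak.area
        else:
            share = att.peak.area / len(groups)
            for g in groups:
                areas[g] = areas.get(g, 0.0) + share
    percentages = {g: 100.0 * a / total for g, a in sorted(areas.items())}
    unattributed = 100.0 - sum(percentages.values())
    return CoverageReport(profile.sample_id, profile.enzyme, percentages, unattributed)


def aggregate_replicates(
    reports_by_site: dict[str, list[CoverageReport]]
) -> pd.DataFrame:
    """Mean and sample standard deviation of group percentages per site.

    A group absent from a replicate counts as 0% in that replicate.
    Returns a tidy frame with columns site, group, mean, sd, n_replicates;
    ``unattributed`` appears as a regular group row.
    """
    rows = []
    for site, reports in reports_by_site.items():
        if not reports:
            raise UsageError(f"site {site}: no replicate reports")
        labels = sorted({g for r in reports for g in r.percentages})
        for group in labels + [UNATTRIBUTED]:
            vals = np.array(
                [
                    r.unattributed if group == UNATTRIBUTED
                    else r.percentages.get(group, 0.0)
                    for r in reports
                ]
            )
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "site": site,
                    "group": group,
                    "mean": float(vals.mean()),
                    "sd": sd,
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(rows, columns=["site", "group", "mean", "sd", "n_replicates"])


# ---------------------------------------------------------------------------
# Serialization

def write_coverage_table(reports: list[CoverageReport], path: str | Path) -> None:
    rows = []
    for r in reports:
        for group, pct in r.percentages.items():
            rows.append(
                {"sample_id": r.sample_id, "enzyme": r.enzyme,
                 "group": group, "percent": pct}
            )
        rows.append(
            {"sample_id": r.sample_id, "enzyme": r.enzyme,
             "group": UNATTRIBUTED, "percent": r.unattributed}
        )
    pd.DataFrame(rows, columns=["sample_id", "enzyme", "group", "percent"]).to_csv(
        path, sep="\t", index=False
    )


def write_aggregate_json(aggregate: pd.DataFrame, path: str | Path) -> None:
    out: dict[str, dict[str, dict[str, float]]] = {}
    for row in aggregate.itertuples():
        out.setdefault(str(row.site), {})[str(row.group)] = {
            "mean": round(float(row.mean), 6),
            "sd": round(float(row.sd), 6),
            "n_replicates": int(row.n_replicates),
        }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))
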