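"""Detection and bookkeeping of two-parent chimeric clones.

PCR chimeras recombine two parent templates at a single breakpoint.  The
detector slides candidate breakpoints along a pre-aligned clone and asks
whether attributing the flanks to two *different* best-matching reference
sequences improves identity over the best single parent by more than a
margin; identity is computed on windows flanking the candidate
breakpoint, which localizes the signal near the recombination site.

A clone called chimeric is split at the breakpoint and its halves enter
downstream library statistics as independent sequences — the bookkeeping
convention for a library where both halves carry signal from genuinely
different organisms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError
from .types import SequenceRecord

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 300
DEFAULT_STEP_BP = 50
DEFAULT_MARGIN = 0.03


@dataclass(frozen=True)
class ChimeraCall:
    """Detector verdict for one clone; ``score`` is the identity improvement
    of the best two-parent split over the best single parent."""

    clone_id: str
    is_chimeric: bool
    breakpoint: int | None = None
    parent_a_id: str | None = None
    parent_b_id: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.is_chimeric != (self.breakpoint is not None):
            raise UsageError("breakpoint must be present iff is_chimeric")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def detect_chimera(
    clone: SequenceRecord,
    references: list[SequenceRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    margin: float = DEFAULT_MARGIN,
) -> ChimeraCall:
    """Score candidate breakpoints and call the clone chimeric when a
    two-parent split beats the best single parent by more than ``margin``.

    All sequences must be pre-aligned to equal length.  For each
    breakpoint ``b`` on the ``step_bp`` grid, the left window
    ``[b-window_bp, b)`` and right window ``[b, b+window_bp)`` are
    matched against every reference; the split score is the mean of the
    two best per-window identities (different parents), the single-parent
    score the best mean using one reference for both windows.
    """
    if len(references) < 2:
        raise UsageError("detect_chimera needs at least 2 references")
    L = len(clone.seq)
    if any(len(r.seq) != L for r in references):
        raise UsageError("references must be aligned to the clone length")
    if window_bp <= 0 or step_bp <= 0:
        raise UsageError("window_bp and step_bp must be positive")

    c = _encode(clone.seq)
    refs = np.stack([_encode(r.seq) for r in references])
    # cumulative per-reference match counts -> O(1) window identities
    matches = (refs == c[None, :]).astype(np.int64)
    cum = np.concatenate(
        [np.zeros((len(references), 1), dtype=np.int64), np.cumsum(matches, axis=1)],
        axis=1,
    )

    def window_identity(a: int, b: int) -> np.ndarray:
        """Identity of clone[a:b] against every reference."""
        return (cum[:, b] - cum[:, a]) / max(b - a, 1)

    best = None  # (improvement, breakpoint, parent_a, parent_b, split_score)
    for b in range(step_bp, L, step_bp):
        left = window_identity(max(0, b - window_bp), b)
        right = window_identity(b, min(L, b + window_bp))
        ia = int(np.argmax(left))
        ib = int(np.argmax(right))
        if ia == ib:
            # force distinct parents: take the better substitution
            alt_a = np.copy(left)
            alt_a[ia] = -1
            alt_b = np.copy(right)
            alt_b[ib] = -1
            if left[ia] + alt_b.max() >= alt_a.max() + right[ib]:
                ib = int(np.argmax(alt_b))
            else:
                ia = int(np.argmax(alt_a))
        split = (left[ia] + right[ib]) / 2.0
        single = float(np.max((left + right) / 2.0))
        improvement = split - single
        if best is None or improvement > best[0]:
            best = (improvement, b, ia, ib, split)

    improvement, b, ia, ib, _ = best
    if improvement > margin:
        return ChimeraCall(
            clone.id,
            True,
            breakpoint=b,
            parent_a_id=references[ia].id,
            parent_b_id=references[ib].id,
            score=float(improvement),
        )
    return ChimeraCall(clone.id, False, score=float(improvement))


def split_chimera(
    clone: SequenceRecord, call: ChimeraCall
) -> tuple[SequenceRecord, SequenceRecord]:
    """Cut a chimeric clone at the breakpoint into two independent records
    (ids suffixed ``a``/``b``); concatenating them reconstructs the clone."""
    if not call.is_chimeric:
        raise UsageError(f"clone {clone.id}: split_chimera on a non-chimeric call")
    b = call.breakpoint
    if not 0 < b < len(clone.seq):
        raise UsageError(f"clone {clone.id}: breakpoint {b} outside the sequence")
    left = SequenceRecord(
        clone.id + "a", clone.seq[:b], clone.taxon, clone.source_library
    )
    right = SequenceRecord(
        clone.id + "b", clone.seq[b:], clone.taxon, clone.source_library
    )
    return left, right


def apply_calls(
    library: list[SequenceRecord],
    calls: list[ChimeraCall],
    pad_to_alignment: bool = False,
) -> list[SequenceRecord]:
    """Replace each chimeric clone by its two halves; everything else passes
    through.  Total nucleotide count across the library is conserved.

    With ``pad_to_alignment`` the halves are N-padded back to the clone
    length so they keep alignment coordinates and can enter distance-based
    statistics (N positions are excluded from pairwise comparisons).
    """
    by_id = {c.clone_id: c for c in calls}
    out: list[SequenceRecord] = []
    for clone in library:
        call = by_id.get(clone.id)
        if call is not None and call.is_chimeric:
            left, right = split_chimera(clone, call)
            if pad_to_alignment:
                b = call.breakpoint
                left = SequenceRecord(
                    left.id, left.seq + "N" * (len(clone.seq) - b),
                    left.taxon, left.source_library,
                )
                right = SequenceRecord(
                    right.id, "N" * b + right.seq,
                    right.taxon, right.source_library,
                )
            out.extend([left, right])
        else:
            out.append(clone)
    return out


def percent_chimeric(n_chimeric: int, n_total: int) -> float:
    """Chimera percentage of a library, half-up rounded to one decimal."""
    if n_total <= 0:
        raise ZeroDivisionError("percent_chimeric: n_total must be > 0")
    if not 0 <= n_chimeric <= n_total:
        raise UsageError("percent_chimeric: need 0 <= n_chimeric <= n_total")
    pct = Decimal(100 * n_chimeric) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_call_table(calls: list[ChimeraCall], path: str | Path) -> None:
    rows = [
        {
            "clone_id": c.clone_id,
            "is_chimeric": c.is_chimeric,
            "breakpoint": "" if c.breakpoint is None else c.breakpoint,
            "parent_a_id": c.parent_a_id or "",
            "parent_b_id": c.parent_b_id or "",
            "score": round(c.score, 6),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["clone_id", "is_chimeric", "breakpoint",
                 "parent_a_id", "parent_b_id", "score"],
    ).to_csv(path, sep="\t", index=False)
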