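"""In silico terminal restriction digestion.

Each clone is anchored at the labeled forward primer, then scanned 5'→3'
for the first restriction site; the predicted terminal restriction
fragment (T-RF) runs from the 5' base of the primer to the cut.  Because
the fluorescent label sits on the primer, the primer is part of the
detected fragment and lengths are measured from its first base.

Absence of a site, an unlocatable primer, or a length outside the sizing
window are modeled outcomes (``reason`` on the fragment), never silent
drops: some taxa genuinely have their first site outside the 50–500 bp
interval and disappear from the fingerprint of one enzyme.
"""

from __future__ import annotations

import logging
from collections import Counter

from .config import RunConfig
from .errors import EmptyInputError
from .types import (
    IUPAC_CODES,
    Primer,
    RestrictionEnzyme,
    SequenceRecord,
    TerminalFragment,
)

log = logging.getLogger(__name__)

#: reasons a fragment can be undetected
NO_PRIMER = "no_primer"
NO_SITE = "no_site"
OUT_OF_WINDOW = "out_of_window"


def locate_primer(
    seq: SequenceRecord | str, primer: Primer, max_mismatch: int = 2
) -> int | None:
    """Return the smallest offset where the primer matches with at most
    ``max_mismatch`` mismatches, or ``None``.

    Degenerate primer positions match any base of their IUPAC expansion
    set; an ambiguity code in the *clone* counts as a mismatch unless it
    is a concrete base inside the primer's set.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    s = seq.seq if isinstance(seq, SequenceRecord) else seq.upper()
    sets = primer.position_sets()
    m = len(sets)
    if len(s) < m:
        return None
    for offset in range(len(s) - m + 1):
        mismatches = 0
        for j, allowed in enumerate(sets):
            if s[offset + j] not in allowed:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        if mismatches <= max_mismatch:
            return offset
    return None


def _site_compatible(chunk: str, site: str) -> bool:
    """True when every (possibly ambiguous) clone base could read as the site."""
    return all(site[i] in IUPAC_CODES.get(c, frozenset()) for i, c in enumerate(chunk))


def terminal_fragment(
    seq: SequenceRecord,
    enzyme: RestrictionEnzyme,
    primer_offset: int = 0,
) -> TerminalFragment:
    """Predict the labeled T-RF of one clone for one enzyme.

    The scan is conservative: ambiguity codes in the clone never match the
    site (only certain cuts are predicted).  When an ambiguous potential
    site occurs upstream of the first certain site it is logged, since a
    real digest might cut there.
    """
    s = seq.seq
    pos = s.find(enzyme.site, primer_offset)
    if pos == -1:
        return TerminalFragment(seq.id, enzyme.name, None, NO_SITE, seq.taxon)
    # warn about an earlier ambiguous site the conservative scan skipped
    k = len(enzyme.site)
    for i in range(primer_offset, pos):
        chunk = s[i : i + k]
        if len(chunk) == k and chunk != enzyme.site and _site_compatible(chunk, enzyme.site):
            log.debug(
                "clone %s: ambiguous potential %s site at %d upstream of "
                "first certain site at %d",
                seq.id, enzyme.name, i, pos,
            )
            break
    length = (pos - primer_offset) + enzyme.cut_offset
    return TerminalFragment(seq.id, enzyme.name, length, None, seq.taxon)


def digest_library(
    library: list[SequenceRecord], config: RunConfig
) -> list[TerminalFragment]:
    """Digest every clone with every configured enzyme.

    Returns one fragment per clone per enzyme; fragments whose length
    falls outside the sizing window are flagged ``out_of_window`` and
    clones without a locatable primer are flagged ``no_primer``.  A
    summary of undetected reasons is logged.
    """
    if not library:
        raise EmptyInputError("digest_library: empty library")
    lo, hi = config.window
    fragments: list[TerminalFragment] = []
    reasons: Counter[str] = Counter()
    for clone in library:
        offset = locate_primer(clone, config.primer, config.max_primer_mismatch)
        for enzyme in config.enzymes:
            if offset is None:
                frag = TerminalFragment(clone.id, enzyme.name, None, NO_PRIMER, clone.taxon)
            else:
                frag = terminal_fragment(clone, enzyme, offset)
                if frag.detected and not lo <= frag.length_bp <= hi:
                    frag = TerminalFragment(
                        clone.id, enzyme.name, None, OUT_OF_WINDOW, clone.taxon
                    )
            if not frag.detected:
                reasons[frag.reason] += 1
            fragments.append(frag)
    log.info(
        "digested %d clones x %d enzymes: %d fragments detected, undetected by reason %s",
        len(library),
        len(config.enzymes),
        sum(f.detected for f in fragments),
        dict(reasons) or "{}",
    )
    return fragments
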