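"""Domain types for T-RFLP fingerprint analysis.

Conventions used throughout the package:

* sequence coordinates are 0-based, half-open;
* fragment lengths are counts of bases (the electrophoretic convention);
* only the labeled (given) strand is ever scanned — reverse-complement
  handling is the caller's job.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import FormatError, UsageError

#: IUPAC nucleotide one-letter codes mapped to the set of concrete bases
#: each stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CONCRETE_BASES = frozenset("ACGT")


def _check_alphabet(seq: str, who: str) -> None:
    bad = set(seq) - set(IUPAC_CODES)
    if bad:
        raise FormatError(
            f"{who}: non-IUPAC characters {sorted(bad)} in sequence"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A clone or reference 16S-like nucleotide sequence.

    ``taxon`` is an optional hierarchical label (``Phylum`` or
    ``Phylum/Class``) carried as input metadata; taxonomic assignment
    itself is outside the package's scope.
    """

    id: str
    seq: str
    taxon: str | None = None
    source_library: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        _check_alphabet(self.seq, f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def taxon_levels(self) -> tuple[str, ...]:
        """The taxon label split into hierarchy levels (empty if unlabeled)."""
        if self.taxon is None:
            return ()
        return tuple(part for part in self.taxon.split("/") if part)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease with an unambiguous recognition site.

    ``cut_offset`` places the cut after that many bases of the site on the
    labeled strand: BsuRI GG^CC is ``site="GGCC", cut_offset=2``.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", self.site.upper())
        if len(self.site) < 4:
            raise UsageError(f"enzyme {self.name}: site shorter than 4 bases")
        if not set(self.site) <= CONCRETE_BASES:
            raise UsageError(f"enzyme {self.name}: site must be unambiguous A/C/G/T")
        if not 0 <= self.cut_offset <= len(self.site):
            raise UsageError(f"enzyme {self.name}: cut_offset outside the site")


#: The two enzymes used for harbor-sediment fingerprints.
BSURI = RestrictionEnzyme("BsuRI", "GGCC", 2)
RSAI = RestrictionEnzyme("RsaI", "GTAC", 2)

KNOWN_ENZYMES: dict[str, RestrictionEnzyme] = {e.name: e for e in (BSURI, RSAI)}


@dataclass(frozen=True)
class Primer:
    """A PCR primer, possibly degenerate; ``labeled`` marks the dye-carrying end."""

    name: str
    seq: str
    labeled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        _check_alphabet(self.seq, f"primer {self.name!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def expansions(self) -> list[str]:
        """All concrete sequences the degenerate primer stands for."""
        pools = [sorted(IUPAC_CODES[c]) for c in self.seq]
        return ["".join(p) for p in itertools.product(*pools)]

    def position_sets(self) -> list[frozenset[str]]:
        """Per-position sets of acceptable concrete bases."""
        return [IUPAC_CODES[c] for c in self.seq]


#: Universal bacterial forward primer 8F, FAM-labeled in the fingerprint assay.
PRIMER_8F = Primer("8F", "AGAGTTTGATYMTGGCTCAG", labeled=True)


@dataclass(frozen=True)
class Peak:
    """One sized electropherogram peak."""

    size_bp: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise UsageError(f"peak size must be positive, got {self.size_bp}")
        if self.height < 0 or self.area < 0:
            raise UsageError("peak height and area must be nonnegative")


@dataclass
class PeakProfile:
    """One sample × one enzyme electropherogram: sized peaks with areas."""

    sample_id: str
    enzyme: str
    peaks: list[Peak]
    window: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise UsageError(f"invalid window {self.window}")

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.peaks)

    def sorted_by_size(self) -> list[Peak]:
        return sorted(self.peaks, key=lambda p: p.size_bp)


@dataclass(frozen=True)
class TerminalFragment:
    """The predicted labeled-end fragment of one clone for one enzyme.

    ``length_bp`` is ``None`` when the fragment is undetected, with the
    cause in ``reason`` (``no_primer``, ``no_site`` or ``out_of_window``).
    """

    clone_id: str
    enzyme: str
    length_bp: int | None
    reason: str | None = None
    taxon: str | None = None

    def __post_init__(self) -> None:
        if (self.length_bp is None) == (self.reason is None):
            raise UsageError(
                "exactly one of length_bp and reason must be set "
                f"(clone {self.clone_id}, enzyme {self.enzyme})"
            )
        if self.length_bp is not None and self.length_bp < 1:
            raise UsageError(f"fragment length must be >= 1, got {self.length_bp}")

    @property
    def detected(self) -> bool:
        return self.length_bp is not None


def group_label(taxon: str | None, level: str) -> str | None:
    """Collapse a hierarchical ``Phylum/Class`` label to one grouping level.

    ``level="phylum"`` keeps the first component; ``level="class"`` keeps
    the deepest available component (falling back to the phylum when no
    class level was supplied).
    """
    if taxon is None:
        return None
    parts = [p for p in taxon.split("/") if p]
    if not parts:
        return None
    if level == "phylum":
        return parts[0]
    if level == "class":
        return parts[-1]
    raise UsageError(f"unknown group level {level!r} (use 'phylum' or 'class')")
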