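"""Readers and writers for FASTA libraries and sized peak tables.

Peak tables are plain delimited text emulating a GeneScan export
(columns ``sample_id, enzyme, size_bp, height, area``); the delimiter is
autodetected from the extension (``.csv`` → comma, anything else → tab).
Raw ``.fsa`` capillary traces are out of scope — sizing happens upstream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import EmptyInputError, FormatError, SchemaError
from .types import Peak, PeakProfile, SequenceRecord

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["sample_id", "enzyme", "size_bp", "height", "area"]


# ---------------------------------------------------------------------------
# FASTA

def _parse_description(desc: str) -> dict[str, str]:
    """Extract ``key=value`` tokens from a FASTA description line."""
    out: dict[str, str] = {}
    for token in desc.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA library; ``taxon=`` and ``library=`` keys in the
    description populate the corresponding record metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        meta = _parse_description(rec.description)
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    seq=str(rec.seq),
                    taxon=meta.get("taxon"),
                    source_library=meta.get("library"),
                )
            )
        except FormatError as err:
            raise FormatError(f"{path}: {err}") from err
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records with metadata round-tripped through the description."""
    bio_records = []
    for r in records:
        desc_parts = []
        if r.taxon is not None:
            desc_parts.append(f"taxon={r.taxon}")
        if r.source_library is not None:
            desc_parts.append(f"library={r.source_library}")
        bio_records.append(
            BioSeqRecord(Seq(r.seq), id=r.id, description=" ".join(desc_parts))
        )
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Peak tables

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peak_table(path: str | Path) -> list[PeakProfile]:
    """Read sized peaks and group them into per-(sample, enzyme) profiles.

    The sizing window is NOT applied here; profiles carry the default
    window and downstream filtering is explicit.  Rows are never dropped
    silently: any unparseable row raises with its line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except pd.errors.EmptyDataError as err:
        raise EmptyInputError(f"peak table {path} is empty") from err
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    for col in ("size_bp", "height", "area"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise FormatError(
                f"{path}: non-numeric {col!r} at line {int(bad[0]) + 2}"
            )
        df[col] = numeric

    profiles: list[PeakProfile] = []
    for (sample_id, enzyme), group in df.groupby(
        ["sample_id", "enzyme"], sort=True
    ):
        peaks = [
            Peak(float(row.size_bp), float(row.height), float(row.area))
            for row in group.itertuples()
        ]
        profiles.append(PeakProfile(str(sample_id), str(enzyme), peaks))
    n_rows = len(df)
    n_peaks = sum(len(p.peaks) for p in profiles)
    log.info("read %d peaks in %d profiles from %s", n_peaks, len(profiles), path)
    assert n_peaks == n_rows, "peak rows lost during grouping"
    return profiles


def write_peak_table(profiles: list[PeakProfile], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "sample_id": p.sample_id,
            "enzyme": p.enzyme,
            "size_bp": round(pk.size_bp, 4),
            "height": round(pk.height, 4),
            "area": round(pk.area, 6),
        }
        for p in profiles
        for pk in p.peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


# ---------------------------------------------------------------------------
# Fragment tables

def write_fragment_table(fragments, path: str | Path) -> None:
    """Write predicted terminal fragments as TSV (empty length when undetected)."""
    rows = [
        {
            "clone_id": f.clone_id,
            "enzyme": f.enzyme,
            "length_bp": "" if f.length_bp is None else f.length_bp,
            "reason": f.reason or "",
            "taxon": f.taxon or "",
        }
        for f in fragments
    ]
    pd.DataFrame(
        rows, columns=["clone_id", "enzyme", "length_bp", "reason", "taxon"]
    ).to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path):
    """Read a fragment TSV back into :class:`~trflpkit.types.TerminalFragment`."""
    from .types import TerminalFragment

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fragments = []
    for row in df.itertuples():
        length = int(float(row.length_bp)) if row.length_bp != "" else None
        fragments.append(
            TerminalFragment(
                clone_id=row.clone_id,
                enzyme=row.enzyme,
                length_bp=length,
                reason=row.reason or None if length is None else None,
                taxon=row.taxon or None,
            )
        )
    return fragments
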