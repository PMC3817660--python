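"""Run configuration: enzymes, primer, window and thresholds for a pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import UsageError
from .types import (
    BSURI,
    PRIMER_8F,
    RSAI,
    Primer,
    RestrictionEnzyme,
)


@dataclass
class RunConfig:
    """Knobs shared by every stage of the pipeline.

    Defaults reflect standard capillary T-RFLP practice: a 50–500 bp sizing
    window, ±1 bp fragment-to-peak matching, 1 bp bins and a 0.5% minimum
    relative peak area.
    """

    enzymes: list[RestrictionEnzyme] = field(default_factory=lambda: [BSURI, RSAI])
    primer: Primer = PRIMER_8F
    window: tuple[float, float] = (50.0, 500.0)
    match_tolerance_bp: float = 1.0
    bin_width_bp: float = 1.0
    min_rel_area: float = 0.005
    max_primer_mismatch: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not 0 < lo < hi:
            raise UsageError(f"invalid window {self.window}")
        if self.match_tolerance_bp <= 0:
            raise UsageError("match_tolerance_bp must be positive")
        if self.bin_width_bp <= 0:
            raise UsageError("bin_width_bp must be positive")
        if not 0 <= self.min_rel_area < 1:
            raise UsageError("min_rel_area must be in [0, 1)")
        if self.max_primer_mismatch < 0:
            raise UsageError("max_primer_mismatch must be >= 0")

    # -- flat key-value (YAML) persistence ---------------------------------

    def to_dict(self) -> dict:
        return {
            "enzymes": [
                {"name": e.name, "site": e.site, "cut_offset": e.cut_offset}
                for e in self.enzymes
            ],
            "primer_name": self.primer.name,
            "primer_seq": self.primer.seq,
            "primer_labeled": self.primer.labeled,
            "window_min_bp": self.window[0],
            "window_max_bp": self.window[1],
            "match_tolerance_bp": self.match_tolerance_bp,
            "bin_width_bp": self.bin_width_bp,
            "min_rel_area": self.min_rel_area,
            "max_primer_mismatch": self.max_primer_mismatch,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "enzymes" in d:
            kwargs["enzymes"] = [
                RestrictionEnzyme(e["name"], e["site"], int(e["cut_offset"]))
                for e in d["enzymes"]
            ]
        if "primer_seq" in d:
            kwargs["primer"] = Primer(
                d.get("primer_name", "primer"),
                d["primer_seq"],
                bool(d.get("primer_labeled", True)),
            )
        if "window_min_bp" in d or "window_max_bp" in d:
            kwargs["window"] = (
                float(d.get("window_min_bp", 50.0)),
                float(d.get("window_max_bp", 500.0)),
            )
        for key in (
            "match_tolerance_bp",
            "bin_width_bp",
            "min_rel_area",
        ):
            if key in d:
                kwargs[key] = float(d[key])
        for key in ("max_primer_mismatch", "rng_seed"):
            if key in d:
                kwargs[key] = int(d[key])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise UsageError(f"config file {path} is not a key-value mapping")
        return cls.from_dict(data)
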