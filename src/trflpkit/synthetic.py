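"""Ground-truth synthetic communities, clone libraries and electropherograms.

The generator emulates the statistical structure the analysis assumes: a
multi-taxon sediment community with uneven abundances, clone libraries
sampled multinomially from it (with per-base sequencing error and
two-parent single-breakpoint chimeras), and per-enzyme electropherograms
whose peaks sit at the true terminal-fragment sizes plus Gaussian sizing
noise, with areas proportional to abundance and a few spurious low-level
peaks.

Reference sequences are evolved from a common ancestor by substitution
only, so every library is born pre-aligned; each reference carries the
labeled forward primer at position 0 and planted restriction sites whose
first occurrence puts both terminal fragments inside the sizing window.
Every generator is fully deterministic under its seed, and truth tables
are sufficient to score every downstream stage without re-generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest import locate_primer, terminal_fragment
from .errors import GenerationError, UsageError
from .types import (
    BSURI,
    PRIMER_8F,
    RSAI,
    Peak,
    PeakProfile,
    RestrictionEnzyme,
    SequenceRecord,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: concrete expansion of the degenerate 8F primer planted in every reference
PRIMER_CONCRETE = "AGAGTTTGATCATGGCTCAG"

#: two-level taxon labels echoing the dominant groups of harbor sediments
TAXON_GROUPS = (
    "Proteobacteria/Gammaproteobacteria",
    "Proteobacteria/Deltaproteobacteria",
    "Proteobacteria/Alphaproteobacteria",
    "Proteobacteria/Epsilonproteobacteria",
    "Bacteroidetes/Flavobacteriia",
)


@dataclass(frozen=True)
class CommunityTaxon:
    label: str
    reference: SequenceRecord
    abundance: float


@dataclass
class SyntheticCommunity:
    """A known community: labeled reference sequences with relative abundances."""

    taxa: list[CommunityTaxon]
    abundance_model: str
    seed: int | None

    @property
    def references(self) -> list[SequenceRecord]:
        return [t.reference for t in self.taxa]

    @property
    def abundances(self) -> np.ndarray:
        return np.array([t.abundance for t in self.taxa])

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.taxa]

    def shannon(self) -> float:
        from .diversity import shannon

        return shannon(self.abundances)


def _pairwise_to_rate(divergence: float) -> float:
    """Per-taxon substitution rate giving the requested mean pairwise
    mismatch fraction (two independent branches from one ancestor:
    pairwise = 2r - (4/3) r^2)."""
    disc = 4.0 - (16.0 / 3.0) * divergence
    return (2.0 - np.sqrt(disc)) / (8.0 / 3.0)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            protected_from: int = 0) -> np.ndarray:
    """Substitute bases at ``rate`` (uniform among the 3 alternatives),
    leaving positions before ``protected_from`` untouched."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    hit[:protected_from] = False
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _plant_site(seq: np.ndarray, site: str, start: int) -> None:
    seq[start : start + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)


def _first_occurrence(seq: np.ndarray, site: str) -> int:
    return seq.tobytes().decode().find(site)


def _repair_early_sites(
    seq: np.ndarray,
    site: str,
    planted_start: int,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> bool:
    """Destroy occurrences of ``site`` upstream of the planted one by point
    mutation, avoiding protected regions.  Returns False on failure."""
    k = len(site)
    for _ in range(max_rounds):
        pos = _first_occurrence(seq, site)
        if pos == planted_start:
            return True
        if pos == -1 or pos > planted_start:
            # planted site was damaged or lost: unrecoverable here
            return False
        candidates = [
            i for i in range(pos, pos + k)
            if not any(a <= i < b for a, b in protected)
        ]
        if not candidates:
            return False
        i = int(rng.choice(candidates))
        choices = BASES[BASES != seq[i]]
        seq[i] = rng.choice(choices)
    return False


def geometric_abundances(n_taxa: int, ratio: float = 0.9) -> np.ndarray:
    """Geometric rank-abundance series p_i proportional to ratio**i."""
    if not 0 < ratio < 1:
        raise UsageError("geometric ratio must be in (0, 1)")
    w = ratio ** np.arange(n_taxa)
    return w / w.sum()


def logseries_abundances(n_taxa: int, x: float = 0.95) -> np.ndarray:
    """Truncated log-series rank abundances p_i proportional to x**(i+1)/(i+1)."""
    if not 0 < x < 1:
        raise UsageError("log-series parameter must be in (0, 1)")
    i = np.arange(1, n_taxa + 1)
    w = x**i / i
    return w / w.sum()


def generate_references(
    n_taxa: int = 30,
    length: int = 1400,
    divergence: float = 0.10,
    seed: int | None = None,
    max_retries: int = 50,
) -> list[SequenceRecord]:
    """Evolve ``n_taxa`` pre-aligned references from one random ancestor.

    Each reference starts with the 8F primer, and its first BsuRI and
    RsaI sites are planted so both terminal fragments land strictly
    inside the 50–500 bp window at taxon-specific, well-separated sizes.
    Taxa are labeled cyclically from the five dominant sediment groups.
    """
    if not 0 < divergence < 0.3:
        raise UsageError("divergence must be in (0, 0.3)")
    rng = np.random.default_rng(seed)
    plen = len(PRIMER_CONCRETE)
    if length < 600:
        raise UsageError("length must be >= 600 to fit the sizing window")
    rate = _pairwise_to_rate(divergence)

    # taxon-specific target T-RF lengths, >= 4 bp apart within each enzyme
    candidates = np.arange(60, 481, 4)
    if n_taxa > candidates.size:
        raise UsageError("too many taxa for distinct fragment sizes")
    targets_bsu = rng.choice(candidates, size=n_taxa, replace=False)
    targets_rsa = rng.choice(candidates, size=n_taxa, replace=False)

    ancestor = np.empty(length, dtype=np.uint8)
    ancestor[:plen] = np.frombuffer(PRIMER_CONCRETE.encode(), dtype=np.uint8)
    ancestor[plen:] = rng.choice(BASES, size=length - plen)

    records: list[SequenceRecord] = []
    for t in range(n_taxa):
        # site start = T-RF length - cut_offset, measured from the primer base
        s_b = int(targets_bsu[t]) - BSURI.cut_offset
        s_r = int(targets_rsa[t]) - RSAI.cut_offset
        if abs(s_b - s_r) < 4:
            s_r = s_r + 8 if s_r + 8 + 4 < length else s_r - 8
        protected = [(0, plen), (s_b, s_b + 4), (s_r, s_r + 4)]
        ok = False
        for _ in range(max_retries):
            seq = _mutate(ancestor, rate, rng, protected_from=plen)
            _plant_site(seq, BSURI.site, s_b)
            _plant_site(seq, RSAI.site, s_r)
            if not _repair_early_sites(seq, BSURI.site, s_b, protected, rng):
                continue
            if not _repair_early_sites(seq, RSAI.site, s_r, protected, rng):
                continue
            if (
                _first_occurrence(seq, BSURI.site) == s_b
                and _first_occurrence(seq, RSAI.site) == s_r
            ):
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not satisfy site constraints for taxon {t} "
                f"after {max_retries} retries"
            )
        records.append(
            SequenceRecord(
                id=f"ref{t:03d}",
                seq=seq.tobytes().decode(),
                taxon=TAXON_GROUPS[t % len(TAXON_GROUPS)],
            )
        )
    return records


def generate_community(
    n_taxa: int = 30,
    length: int = 1400,
    divergence: float = 0.10,
    abundance_model: str = "geometric",
    model_param: float = 0.9,
    seed: int | None = None,
) -> SyntheticCommunity:
    """A complete known community: references plus rank abundances."""
    refs = generate_references(n_taxa, length, divergence, seed=seed)
    if abundance_model == "geometric":
        ab = geometric_abundances(n_taxa, model_param)
    elif abundance_model == "logseries":
        ab = logseries_abundances(n_taxa, model_param)
    else:
        raise UsageError(f"unknown abundance model {abundance_model!r}")
    taxa = [
        CommunityTaxon(r.taxon, r, float(a)) for r, a in zip(refs, ab)
    ]
    return SyntheticCommunity(taxa, abundance_model, seed)


def generate_library(
    community: SyntheticCommunity,
    n_clones: int = 100,
    error_rate: float = 0.005,
    chimera_rate: float = 0.0,
    seed: int | None = None,
    library_id: str = "lib",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Sample a clone library from the community.

    Clones are drawn multinomially by abundance; a ``chimera_rate``
    fraction is replaced by two-parent recombinants with one uniform
    breakpoint in the middle 60% of the alignment; per-base substitution
    errors are applied last.  The truth table records taxon, parents and
    breakpoint per clone.
    """
    if not 0 <= error_rate < 1 or not 0 <= chimera_rate < 1:
        raise UsageError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ab = community.abundances
    refs = [
        np.frombuffer(t.reference.seq.encode(), dtype=np.uint8)
        for t in community.taxa
    ]
    L = refs[0].size
    n_taxa = len(refs)
    records: list[SequenceRecord] = []
    truth_rows = []
    for i in range(n_clones):
        clone_id = f"{library_id}_c{i:04d}"
        a = int(rng.choice(n_taxa, p=ab))
        is_chimeric = bool(rng.random() < chimera_rate)
        if is_chimeric:
            b = a
            while b == a:
                b = int(rng.choice(n_taxa, p=ab))
            bp = int(rng.integers(int(0.2 * L), int(0.8 * L) + 1))
            seq = np.concatenate([refs[a][:bp], refs[b][bp:]])
            parent_b, breakpoint = community.taxa[b].reference.id, bp
        else:
            seq = refs[a].copy()
            parent_b, breakpoint = "", -1
        seq = _mutate(seq, error_rate, rng)
        records.append(
            SequenceRecord(
                id=clone_id,
                seq=seq.tobytes().decode(),
                taxon=community.taxa[a].label,
                source_library=library_id,
            )
        )
        truth_rows.append(
            {
                "clone_id": clone_id,
                "library": library_id,
                "taxon": community.taxa[a].label,
                "is_chimeric": is_chimeric,
                "parent_a": community.taxa[a].reference.id,
                "parent_b": parent_b,
                "breakpoint": breakpoint,
            }
        )
    return records, pd.DataFrame(truth_rows)


def true_fragments(
    community: SyntheticCommunity,
    enzymes: tuple[RestrictionEnzyme, ...] = (BSURI, RSAI),
) -> pd.DataFrame:
    """The ground-truth T-RF length of every taxon for every enzyme,
    computed with the digest stage itself (references are noise-free,
    so the prediction is exact by construction)."""
    rows = []
    for taxon in community.taxa:
        offset = locate_primer(taxon.reference, PRIMER_8F, 0)
        for enzyme in enzymes:
            frag = terminal_fragment(taxon.reference, enzyme, offset)
            rows.append(
                {
                    "taxon": taxon.label,
                    "reference": taxon.reference.id,
                    "enzyme": enzyme.name,
                    "length_bp": frag.length_bp,
                    "abundance": taxon.abundance,
                }
            )
    return pd.DataFrame(rows)


def generate_profiles(
    community: SyntheticCommunity,
    enzymes: tuple[RestrictionEnzyme, ...] = (BSURI, RSAI),
    sizing_sd_bp: float = 0.3,
    spurious_rate: float = 2.0,
    n_sites: int = 5,
    n_replicates: int = 3,
    site_effect_sd: float = 0.5,
    replicate_sd: float = 0.2,
    window: tuple[float, float] = (50.0, 500.0),
    total_area: float = 10_000.0,
    seed: int | None = None,
) -> tuple[list[PeakProfile], pd.DataFrame]:
    """Simulate sized electropherograms for ``n_sites`` x ``n_replicates``
    samples per enzyme (sample ids ``site.replicate``).

    Each taxon contributes one peak at its true T-RF length plus Gaussian
    sizing noise; areas are proportional to site-perturbed abundances
    times lognormal replicate noise; spurious low-area peaks arrive as a
    Poisson count uniform over the window.  Replicates of a site share
    the same perturbed community and differ only in noise.
    """
    if sizing_sd_bp < 0:
        raise UsageError("sizing_sd_bp must be >= 0")
    rng = np.random.default_rng(seed)
    frag_truth = true_fragments(community, enzymes)
    ab = community.abundances
    n_taxa = ab.size
    profiles: list[PeakProfile] = []
    truth_rows = []
    for site in range(1, n_sites + 1):
        site_ab = ab * rng.lognormal(0.0, site_effect_sd, size=n_taxa)
        site_ab = site_ab / site_ab.sum()
        for rep in range(1, n_replicates + 1):
            sample_id = f"{site}.{rep}"
            rep_noise = rng.lognormal(0.0, replicate_sd, size=n_taxa)
            areas = site_ab * rep_noise
            areas = areas / areas.sum() * total_area
            for enzyme in enzymes:
                sub = frag_truth[frag_truth["enzyme"] == enzyme.name]
                peaks = []
                for t, row in enumerate(sub.itertuples()):
                    size = float(row.length_bp) + rng.normal(0.0, sizing_sd_bp)
                    area = float(areas[t])
                    peaks.append(Peak(size, area / 2.0, area))
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "enzyme": enzyme.name,
                            "taxon": row.taxon,
                            "true_size_bp": int(row.length_bp),
                            "size_bp": size,
                            "area": area,
                            "spurious": False,
                        }
                    )
                n_spur = int(rng.poisson(spurious_rate))
                for _ in range(n_spur):
                    size = float(rng.uniform(*window))
                    area = float(total_area * rng.uniform(0.0005, 0.003))
                    peaks.append(Peak(size, area / 2.0, area))
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "enzyme": enzyme.name,
                            "taxon": "",
                            "true_size_bp": -1,
                            "size_bp": size,
                            "area": area,
                            "spurious": True,
                        }
                    )
                profiles.append(PeakProfile(sample_id, enzyme.name, peaks, window))
    return profiles, pd.DataFrame(truth_rows)


def default_study(seed: int | None = 0) -> dict:
    """The default emulated study: one 30-taxon community, two clone
    libraries at the emulated scale (101 clones / 11.9% chimeras and
    93 clones / 4.3% chimeras), and 5 sites x 3 replicates of two-enzyme
    electropherograms.  Returns a dict of all pieces plus truth tables.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=4)
    community = generate_community(seed=int(seeds[0]))
    lib1, truth1 = generate_library(
        community, n_clones=101, error_rate=0.005, chimera_rate=0.119,
        seed=int(seeds[1]), library_id="1.2",
    )
    lib2, truth2 = generate_library(
        community, n_clones=93, error_rate=0.005, chimera_rate=0.043,
        seed=int(seeds[2]), library_id="2.1",
    )
    profiles, peak_truth = generate_profiles(community, seed=int(seeds[3]))
    return {
        "community": community,
        "libraries": {"1.2": lib1, "2.1": lib2},
        "library_truth": pd.concat([truth1, truth2], ignore_index=True),
        "profiles": profiles,
        "peak_truth": peak_truth,
    }
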