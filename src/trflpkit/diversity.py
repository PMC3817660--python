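"""Alpha/beta diversity and library-comparison statistics.

Implements the clone-library statistics of the pipeline: Shannon entropy
(nats) and the Chao1 richness estimator, Jukes-Cantor distances on
pre-aligned sequences, furthest-neighbor (complete-linkage) OTU
clustering at distance cutoffs, shared-OTU counts between libraries,
homologous/heterologous coverage curves with the associated permutation
test of library identity (the LIBSHUFF procedure), Bray-Curtis
dissimilarity, and nonmetric multidimensional scaling of the fingerprint
matrix.

Sequence distances assume pre-aligned, equal-length input (the synthetic
generator evolves sequences by substitution only); external alignment is
out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .errors import DomainError, UsageError
from .types import CONCRETE_BASES, SequenceRecord

log = logging.getLogger(__name__)

#: distance assigned to sequence pairs past the Jukes-Cantor saturation point
DEFAULT_SATURATION_CEILING = 2.0

#: default coverage-curve grid: evolutionary distance 0 to 0.5 in 0.01 steps
def default_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 0.5 + 1e-9, 0.01), 10)


# ---------------------------------------------------------------------------
# Alpha diversity

def shannon(p) -> float:
    """Shannon entropy H = -sum(p_i ln p_i) in nats of a probability vector.

    Zero entries contribute nothing; negative entries or a total away
    from 1 are a domain error.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DomainError("shannon: empty probability vector")
    if np.any(p < 0):
        raise DomainError("shannon: negative probabilities")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError(f"shannon: probabilities sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass(frozen=True)
class AbundanceSummary:
    """Observed richness with singleton/doubleton counts of one library."""

    abundances: tuple[int, ...]

    @property
    def s_obs(self) -> int:
        return int(sum(1 for a in self.abundances if a > 0))

    @property
    def n1(self) -> int:
        return int(sum(1 for a in self.abundances if a == 1))

    @property
    def n2(self) -> int:
        return int(sum(1 for a in self.abundances if a == 2))

    @classmethod
    def from_counts(cls, counts) -> "AbundanceSummary":
        counts = [int(c) for c in counts]
        if any(c < 0 for c in counts):
            raise DomainError("abundances must be nonnegative")
        return cls(tuple(counts))


def chao1(summary) -> float:
    """Chao1 richness estimate S_obs + n1^2 / (2 n2).

    When no doubletons are observed the printed form divides by zero, so
    the standard bias-corrected estimator
    ``S_obs + n1 (n1 - 1) / (2 (n2 + 1))`` is used instead; it reduces to
    nothing more than S_obs when there are no singletons either.
    """
    if not isinstance(summary, AbundanceSummary):
        summary = AbundanceSummary.from_counts(summary)
    s, n1, n2 = summary.s_obs, summary.n1, summary.n2
    if n2 > 0:
        return s + n1 * n1 / (2.0 * n2)
    return s + n1 * (n1 - 1) / (2.0 * (n2 + 1))


# ---------------------------------------------------------------------------
# Sequence distances

def _encode_valid(records: list[SequenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise UsageError("sequences must be pre-aligned to equal length")
    X = np.stack([np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8) for r in records])
    valid = np.isin(X, np.frombuffer(b"ACGT", dtype=np.uint8))
    return X, valid


def jc_distance(
    seq_a: SequenceRecord | str,
    seq_b: SequenceRecord | str,
    ceiling: float = DEFAULT_SATURATION_CEILING,
) -> float:
    """Jukes-Cantor distance D = -(3/4) ln(1 - 4p/3) between two aligned
    sequences.

    Positions where either sequence carries a non-ACGT code are excluded
    from both numerator and denominator.  A mismatch fraction at or past
    the 3/4 saturation point returns ``ceiling``.
    """
    a = seq_a.seq if isinstance(seq_a, SequenceRecord) else seq_a.upper()
    b = seq_b.seq if isinstance(seq_b, SequenceRecord) else seq_b.upper()
    if len(a) != len(b):
        raise UsageError("jc_distance: sequences must be aligned to equal length")
    included = mismatches = 0
    for ca, cb in zip(a, b):
        if ca in CONCRETE_BASES and cb in CONCRETE_BASES:
            included += 1
            if ca != cb:
                mismatches += 1
    if included == 0:
        raise DomainError("jc_distance: no comparable positions")
    p = mismatches / included
    if p >= 0.75:
        return ceiling
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(
    records: list[SequenceRecord],
    ceiling: float = DEFAULT_SATURATION_CEILING,
) -> np.ndarray:
    """Pairwise Jukes-Cantor distance matrix over an aligned library.

    Pairs sharing no comparable position (e.g. complementary N-padded
    chimera halves) get the saturation ceiling rather than an error, so
    split fragments can enter library statistics as independent
    maximally-distant sequences.
    """
    X, valid = _encode_valid(records)
    n = len(records)
    D = np.zeros((n, n))
    warned = False
    for i in range(n):
        both = valid[i] & valid
        included = both.sum(axis=1)
        empty = included == 0
        if np.any(empty) and not warned:
            log.warning(
                "jc_distance_matrix: pairs with no comparable positions set "
                "to the saturation ceiling %g", ceiling,
            )
            warned = True
        mism = ((X[i] != X) & both).sum(axis=1)
        p = np.where(empty, 1.0, mism / np.maximum(included, 1))
        row = np.where(
            p >= 0.75, ceiling, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0)
        )
        D[i] = row
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# OTU clustering

@dataclass
class OTUPartition:
    """Assignment of clones to OTUs at one distance cutoff."""

    cutoff: float
    assignment: dict[str, str]
    library_of: dict[str, str] = field(default_factory=dict)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for clone, otu in self.assignment.items():
            out.setdefault(otu, []).append(clone)
        return out

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))


def _check_square(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise UsageError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise UsageError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise UsageError("distance matrix must have a zero diagonal")
    return dist


def cluster_otus(
    dist: np.ndarray,
    ids: list[str],
    cutoff: float,
    library_of: dict[str, str] | None = None,
) -> OTUPartition:
    """Furthest-neighbor (complete-linkage) OTU clustering at a cutoff.

    Clusters are grown until the next merge would join groups whose
    maximum inter-member distance exceeds ``cutoff``; OTU labels are
    assigned in order of each cluster's smallest member id so partitions
    are deterministic.
    """
    dist = _check_square(dist)
    if len(ids) != dist.shape[0]:
        raise UsageError("ids do not match the distance matrix")
    if cutoff < 0:
        raise UsageError("cutoff must be >= 0")
    n = len(ids)
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(Z, t=cutoff, criterion="distance")
    # relabel deterministically by smallest member id
    groups: dict[int, list[str]] = {}
    for clone_id, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(clone_id)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    assignment = {
        clone: f"OTU_{k + 1:04d}" for k, group in enumerate(ordered) for clone in group
    }
    return OTUPartition(cutoff, assignment, dict(library_of or {}))


def shared_otus(partition: OTUPartition) -> int:
    """Number of OTUs whose members span both libraries."""
    if not partition.library_of:
        raise UsageError("shared_otus: partition carries no library labels")
    libraries = set(partition.library_of.values())
    if len(libraries) < 2:
        log.warning("shared_otus: single-library partition, count is 0")
        return 0
    count = 0
    for members in partition.members().values():
        libs = {partition.library_of[m] for m in members if m in partition.library_of}
        if len(libs) >= 2:
            count += 1
    return count


def abundances_from_partition(
    partition: OTUPartition, library: str | None = None
) -> AbundanceSummary:
    """Per-OTU clone counts, optionally restricted to one source library."""
    counts: dict[str, int] = {}
    for clone, otu in partition.assignment.items():
        if library is not None and partition.library_of.get(clone) != library:
            continue
        counts[otu] = counts.get(otu, 0) + 1
    return AbundanceSummary.from_counts(list(counts.values()))


def diversity_report(
    libraries: dict[str, list[SequenceRecord]],
    cutoffs: tuple[float, ...] = (0.01, 0.03, 0.05),
    ceiling: float = DEFAULT_SATURATION_CEILING,
) -> pd.DataFrame:
    """Per-library alpha diversity at each cutoff (observed OTUs, Chao1,
    Shannon of OTU relative abundances), each library clustered on its
    own Jukes-Cantor distance matrix."""
    rows = []
    for name, records in libraries.items():
        D = jc_distance_matrix(records, ceiling=ceiling)
        ids = [r.id for r in records]
        for cutoff in cutoffs:
            part = cluster_otus(D, ids, cutoff)
            summary = abundances_from_partition(part)
            counts = np.array(summary.abundances, dtype=float)
            rows.append(
                {
                    "library": name,
                    "cutoff": cutoff,
                    "s_obs": summary.s_obs,
                    "chao1": chao1(summary),
                    "shannon": shannon(counts / counts.sum()),
                }
            )
    return pd.DataFrame(rows, columns=["library", "cutoff", "s_obs", "chao1", "shannon"])


# ---------------------------------------------------------------------------
# Coverage curves and the library-comparison permutation test

@dataclass
class CoverageCurve:
    """Homologous (and optionally heterologous) coverage as a function of
    evolutionary distance."""

    distances: np.ndarray
    c_x: np.ndarray
    c_xy: np.ndarray | None = None


def _coverage_from_mins(mins: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """C(D) = fraction of sequences whose nearest neighbor is within D."""
    return np.searchsorted(np.sort(mins), grid, side="right") / mins.size


def coverage_curve(
    dist_within_x: np.ndarray,
    dist_x_to_y: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> CoverageCurve:
    """Coverage curves of library X against itself and optionally against Y.

    ``C_X(D)`` is the fraction of X sequences with another X sequence
    within distance D; ``C_XY(D)`` the fraction with a Y sequence within
    D.  Both are nondecreasing step functions of D.
    """
    dist_within_x = _check_square(dist_within_x)
    if dist_within_x.shape[0] < 1:
        raise UsageError("coverage_curve: empty library")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise UsageError("coverage_curve: grid must be increasing")
    masked = dist_within_x + np.diag(np.full(dist_within_x.shape[0], np.inf))
    c_x = _coverage_from_mins(masked.min(axis=1), grid)
    c_xy = None
    if dist_x_to_y is not None:
        dist_x_to_y = np.asarray(dist_x_to_y, dtype=float)
        if dist_x_to_y.shape[0] != dist_within_x.shape[0]:
            raise UsageError("coverage_curve: cross-distance rows must match X")
        c_xy = _coverage_from_mins(dist_x_to_y.min(axis=1), grid)
    return CoverageCurve(grid, c_x, c_xy)


@dataclass(frozen=True)
class LibshuffResult:
    """One direction of the coverage-curve comparison."""

    direction: str
    delta_c: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class LibshuffComparison:
    xy: LibshuffResult
    yx: LibshuffResult

    def min_p(self) -> float:
        return min(self.xy.p_value, self.yx.p_value)

    def significant(self, alpha: float = 0.05) -> bool:
        """Bonferroni over the reciprocal pair: reject at alpha/2 per direction."""
        return self.min_p() <= alpha / 2.0


def _delta_c_pair(
    D_masked: np.ndarray,
    D: np.ndarray,
    ix: np.ndarray,
    iy: np.ndarray,
    grid: np.ndarray,
    step: float,
) -> tuple[float, float]:
    min_xx = D_masked[np.ix_(ix, ix)].min(axis=1)
    min_yy = D_masked[np.ix_(iy, iy)].min(axis=1)
    cross = D[np.ix_(ix, iy)]
    min_xy = cross.min(axis=1)
    min_yx = cross.min(axis=0)
    cx = _coverage_from_mins(min_xx, grid)
    cy = _coverage_from_mins(min_yy, grid)
    cxy = _coverage_from_mins(min_xy, grid)
    cyx = _coverage_from_mins(min_yx, grid)
    dxy = float(((cx - cxy) ** 2).sum() * step)
    dyx = float(((cy - cyx) ** 2).sum() * step)
    return dxy, dyx


def libshuff_test(
    lib_x: list[SequenceRecord],
    lib_y: list[SequenceRecord],
    n_permutations: int = 999,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    ceiling: float = DEFAULT_SATURATION_CEILING,
) -> LibshuffComparison:
    """Monte-Carlo test of whether two clone libraries sample the same
    community, via the integrated squared difference of homologous and
    heterologous coverage curves.

    The statistic per direction is
    ``delta_C = sum_grid (C_X(D) - C_XY(D))^2 * step``; the null
    distribution shuffles library labels over the pooled sequences with
    library sizes preserved, and
    ``p = (1 + #{null >= observed}) / (n_permutations + 1)``.  For the
    reciprocal pair of comparisons the conventional Bonferroni-corrected
    significance threshold is alpha/2 (0.025 at alpha = 0.05).
    """
    if len(lib_x) < 3 or len(lib_y) < 3:
        raise UsageError("libshuff_test: need at least 3 sequences per library")
    if n_permutations < 99:
        raise UsageError("libshuff_test: need at least 99 permutations")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    step = float(np.median(np.diff(grid)))
    pooled = list(lib_x) + list(lib_y)
    D = jc_distance_matrix(pooled, ceiling=ceiling)
    D_masked = D + np.diag(np.full(len(pooled), np.inf))
    nx = len(lib_x)
    n = len(pooled)
    ix0 = np.arange(nx)
    iy0 = np.arange(nx, n)
    obs_xy, obs_yx = _delta_c_pair(D_masked, D, ix0, iy0, grid, step)

    rng = np.random.default_rng(seed)
    ge_xy = ge_yx = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        dxy, dyx = _delta_c_pair(D_masked, D, perm[:nx], perm[nx:], grid, step)
        if dxy >= obs_xy:
            ge_xy += 1
        if dyx >= obs_yx:
            ge_yx += 1
    p_xy = (1 + ge_xy) / (n_permutations + 1)
    p_yx = (1 + ge_yx) / (n_permutations + 1)
    return LibshuffComparison(
        LibshuffResult("X_vs_Y", obs_xy, p_xy, n_permutations, seed),
        LibshuffResult("Y_vs_X", obs_yx, p_yx, n_permutations, seed),
    )


# ---------------------------------------------------------------------------
# Beta diversity / ordination

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two nonnegative
    abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("bray_curtis: vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("bray_curtis: abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise DomainError("bray_curtis: both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between matrix rows."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(values[i], values[j])
    return D


@dataclass
class NMDSResult:
    coords: np.ndarray
    stress: float  # Kruskal stress-1
    n_restarts: int


def classical_scaling(dist: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling coordinates used as the NMDS start."""
    dist = _check_square(dist)
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def stress1(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix,
    with disparities from monotone (isotonic) regression.

    Mirrors the nonmetric SMACOF convention: zero dissimilarities are
    treated as unconstrained, and disparities are rescaled to the number
    of constrained pairs before comparison.
    """
    dist = _check_square(dist)
    d_flat = squareform(dist, checks=False)
    config = pdist(np.asarray(coords, dtype=float))
    w = d_flat != 0
    if not np.any(w):
        return 0.0
    ir = IsotonicRegression(out_of_bounds="clip")
    disp = np.zeros_like(config)
    disp[w] = ir.fit_transform(d_flat[w], config[w])
    disp *= np.sqrt(w.sum() / (disp**2).sum()) if (disp**2).sum() > 0 else 1.0
    num = ((config - disp) ** 2).sum()
    den = (config**2).sum()
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def nmds(
    dist: np.ndarray,
    dims: int = 2,
    seed: int | None = 0,
    restarts: int = 4,
    max_iter: int = 500,
) -> NMDSResult:
    """Nonmetric MDS minimizing Kruskal stress-1 by iterative majorization
    (SMACOF) with monotone regression.

    One run starts from classical scaling and ``restarts`` further runs
    from seeded random configurations; the lowest-stress solution wins.
    Deterministic for a fixed seed.
    """
    dist = _check_square(dist)
    n = dist.shape[0]
    if n < 3:
        raise UsageError("nmds: need at least 3 samples")
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray | None] = [classical_scaling(dist, dims)]
    starts += [None] * max(0, restarts)
    best_coords, best_stress = None, np.inf
    for init in starts:
        state = int(rng.integers(2**31))
        coords, stress, _ = smacof(
            dist,
            metric=False,
            n_components=dims,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            random_state=state,
            normalized_stress=True,
            return_n_iter=True,
        )
        if stress < best_stress:
            best_coords, best_stress = coords, float(stress)
    return NMDSResult(best_coords, best_stress, len(starts))
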