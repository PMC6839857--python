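"""Pairwise Rst between populations via two-level AMOVA on repeat scores.

Rst is the STR-specific analogue of Fst: the molecular distance between two
haplotypes is the sum over loci of squared repeat-count differences, and a
two-level analysis of molecular variance partitions the total squared
distance into among-population (sigma_a^2) and within-population (sigma_w^2)
variance components, with

    Rst = sigma_a^2 / (sigma_a^2 + sigma_w^2).

Multi-copy loci contribute via ascending-sorted copy pairing; pairs whose
copy counts differ at a variable-copy locus skip that locus for that pair.
Significance is assessed by permuting individuals across population labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .haplotypes import Haplotype, Panel, Sample
from .loci import LocusSpec, resolve_subset

logger = logging.getLogger(__name__)


@dataclass
class RstResult:
    """AMOVA variance components and Rst for one population comparison."""

    sigma_a: float
    sigma_w: float
    rst: float
    rst_clamped: float
    n_per_pop: dict[str, int]
    loci_used: list[str]
    p_value: float | None = None
    degenerate: bool = False  # no molecular variance at all

    def __post_init__(self) -> None:
        if not 0.0 <= self.rst_clamped <= 1.0 + 1e-12:
            raise ValueError(f"rst_clamped {self.rst_clamped} outside [0, 1]")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix (zero diagonal, non-negative)."""

    labels: list[str]
    values: np.ndarray
    raw: np.ndarray | None = None  # unclamped values, where applicable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix entries must be non-negative")
        self.values = np.clip(self.values, 0.0, None)

    @property
    def size(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# molecular distances
# ---------------------------------------------------------------------------

def haplotype_squared_distance(
    h1: Haplotype,
    h2: Haplotype,
    loci: Sequence[LocusSpec],
    skipped: list[str] | None = None,
) -> float:
    """Sum over loci of squared repeat differences between paired copies.

    Copies at multi-copy loci are paired in ascending order. If the two
    haplotypes show different copy counts at a locus the locus is skipped
    for this pair and (optionally) recorded in ``skipped``. Microvariant
    alleles contribute their literal decimal value.
    """
    total = 0.0
    for spec in loci:
        a = h1.alleles.get(spec.name, ())
        b = h2.alleles.get(spec.name, ())
        if len(a) != len(b) or not a:
            if skipped is not None:
                skipped.append(spec.name)
            continue
        total += sum((x - y) ** 2 for x, y in zip(a, b))
    return total


def _uniform_copy_counts(
    samples: Sequence[Sample], loci: Sequence[LocusSpec]
) -> bool:
    for spec in loci:
        counts = {len(s.haplotype.alleles.get(spec.name, ())) for s in samples}
        if len(counts) != 1 or 0 in counts:
            return False
    return True


def squared_distance_matrix(
    samples: Sequence[Sample], loci: Sequence[LocusSpec]
) -> np.ndarray:
    """All-pairs squared molecular distance over complete-case samples.

    Uses a vectorized Gram-matrix path when every sample shows the same copy
    count at every locus (always true for simulated panels); otherwise falls
    back to explicit pairwise accumulation with per-pair locus skipping.
    """
    n = len(samples)
    if n == 0:
        return np.zeros((0, 0))
    if _uniform_copy_counts(samples, loci):
        rows = [
            [v for spec in loci for v in s.haplotype.alleles[spec.name]]
            for s in samples
        ]
        x = np.asarray(rows, dtype=float)
        sq = (x * x).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
        np.fill_diagonal(d2, 0.0)
        return np.clip(d2, 0.0, None)
    d2 = np.zeros((n, n))
    skipped: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = haplotype_squared_distance(
                samples[i].haplotype, samples[j].haplotype, loci, skipped
            )
    if skipped:
        logger.info(
            "copy-count mismatches: skipped %d locus/pair combinations (%s)",
            len(skipped),
            ", ".join(sorted(set(skipped))),
        )
    return d2


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _variance_components(
    d2: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[float, float, float, bool]:
    """(sigma_a, sigma_w, rst_raw, degenerate) from a squared-distance matrix.

    Standard two-level AMOVA sums of squared deviations expressed through
    pairwise distances: SSD_total = (1/N) sum_{i<j} d2_ij, SSD_within =
    sum_p (1/n_p) sum_{i<j in p} d2_ij.
    """
    sizes = np.array([len(g) for g in groups])
    n_total = int(sizes.sum())
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("AMOVA requires at least two populations")
    if (sizes < 2).any():
        raise ValueError("each population needs at least 2 complete-case samples")
    ssd_total = d2.sum() / (2.0 * n_total)
    ssd_within = sum(
        d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups
    )
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (n_groups - 1)
    ms_within = ssd_within / (n_total - n_groups)
    n_c = (n_total - (sizes**2).sum() / n_total) / (n_groups - 1)
    sigma_a = (ms_among - ms_within) / n_c
    sigma_w = ms_within
    denom = sigma_a + sigma_w
    if ssd_total <= 1e-12 or abs(denom) <= 1e-300:
        return 0.0, float(sigma_w), 0.0, True
    return float(sigma_a), float(sigma_w), float(sigma_a / denom), False


def _complete_case_groups(
    panel: Panel, populations: Sequence[str], loci: Sequence[LocusSpec]
) -> tuple[list[Sample], list[np.ndarray], dict[str, int]]:
    names = [spec.name for spec in loci]
    samples: list[Sample] = []
    groups: list[np.ndarray] = []
    sizes: dict[str, int] = {}
    for pop in populations:
        pool = [
            s for s in panel.samples_for(pop) if s.haplotype.is_unflagged(names)
        ]
        idx = np.arange(len(samples), len(samples) + len(pool))
        samples.extend(pool)
        groups.append(idx)
        sizes[pop] = len(pool)
    return samples, groups, sizes


def _resolve_loci(
    panel: Panel,
    loci: str | Sequence[str] | Sequence[LocusSpec] | None,
    include_multicopy: bool,
) -> list[LocusSpec]:
    if loci is None:
        loci = "yfiler_plus"
    if isinstance(loci, str):
        return resolve_subset(panel.loci, loci, include_multicopy=include_multicopy)
    seq = list(loci)
    if seq and isinstance(seq[0], LocusSpec):
        return resolve_subset(
            panel.loci, [s.name for s in seq], include_multicopy=include_multicopy
        )
    return resolve_subset(panel.loci, seq, include_multicopy=include_multicopy)


def amova(
    panel: Panel,
    populations: Sequence[str] | None = None,
    loci: str | Sequence[str] | Sequence[LocusSpec] | None = None,
    *,
    include_multicopy: bool = True,
) -> RstResult:
    """Two-level AMOVA across the given populations (default: all in panel).

    ``loci`` accepts ``"all"``, ``"yfiler_plus"`` (the default, matching
    cross-population comparison practice) or an explicit locus list.
    Complete-case analysis: samples flagged at any selected locus are
    dropped before distances are computed.
    """
    pops = list(populations) if populations is not None else panel.populations()
    specs = _resolve_loci(panel, loci, include_multicopy)
    samples, groups, sizes = _complete_case_groups(panel, pops, specs)
    n_excluded = sum(len(panel.samples_for(p)) for p in pops) - len(samples)
    if n_excluded:
        logger.info("AMOVA: excluded %d incomplete samples", n_excluded)
    d2 = squared_distance_matrix(samples, specs)
    sigma_a, sigma_w, rst, degenerate = _variance_components(d2, groups)
    return RstResult(
        sigma_a=sigma_a,
        sigma_w=sigma_w,
        rst=rst,
        rst_clamped=max(rst, 0.0),
        n_per_pop=sizes,
        loci_used=[s.name for s in specs],
        degenerate=degenerate,
    )


def amova_pair(
    panel: Panel,
    pop_a: str,
    pop_b: str,
    loci: str | Sequence[str] | Sequence[LocusSpec] | None = None,
    *,
    include_multicopy: bool = True,
    permutations: int = 0,
    seed: int | None = None,
) -> RstResult:
    """Rst between two populations, optionally with a permutation p-value."""
    result = amova(
        panel, [pop_a, pop_b], loci, include_multicopy=include_multicopy
    )
    if permutations:
        result.p_value = rst_permutation_pvalue(
            panel,
            pop_a,
            pop_b,
            loci,
            n_perm=permutations,
            seed=seed,
            include_multicopy=include_multicopy,
        )
    return result


def rst_permutation_pvalue(
    panel: Panel,
    pop_a: str,
    pop_b: str,
    loci: str | Sequence[str] | Sequence[LocusSpec] | None = None,
    *,
    n_perm: int = 999,
    seed: int | None = None,
    include_multicopy: bool = True,
) -> float:
    """Permutation tail probability for the observed pairwise Rst.

    Individuals are shuffled across the two population labels with group
    sizes preserved; the add-one estimator
    ``p = (1 + #{Rst_perm >= Rst_obs}) / (n_perm + 1)`` bounds p away from
    zero at 1/(n_perm + 1).
    """
    specs = _resolve_loci(panel, loci, include_multicopy)
    samples, groups, _ = _complete_case_groups(panel, [pop_a, pop_b], specs)
    d2 = squared_distance_matrix(samples, specs)
    *_, rst_obs, _deg = _variance_components(d2, groups)
    n_a = len(groups[0])
    n = len(samples)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g = [perm[:n_a], perm[n_a:]]
        *_, rst_p, _ = _variance_components(d2, g)
        if rst_p >= rst_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def pairwise_rst_matrix(
    panel: Panel,
    loci: str | Sequence[str] | Sequence[LocusSpec] | None = None,
    *,
    include_multicopy: bool = True,
    permutations: int = 0,
    seed: int | None = None,
) -> tuple[DistanceMatrix, dict[tuple[str, str], RstResult]]:
    """Rst for every unordered population pair.

    Returns the clamped symmetric matrix (raw values retained in ``raw``)
    plus the per-pair :class:`RstResult` details keyed by (pop_a, pop_b).
    """
    pops = panel.populations()
    if len(pops) < 2:
        raise ValueError("pairwise Rst needs at least two populations")
    m = len(pops)
    clamped = np.zeros((m, m))
    raw = np.zeros((m, m))
    details: dict[tuple[str, str], RstResult] = {}
    ss = np.random.SeedSequence(seed) if seed is not None else None
    for i in range(m):
        for j in range(i + 1, m):
            pair_seed = (
                int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)) if ss else None
            )
            res = amova_pair(
                panel,
                pops[i],
                pops[j],
                loci,
                include_multicopy=include_multicopy,
                permutations=permutations,
                seed=pair_seed,
            )
            clamped[i, j] = clamped[j, i] = res.rst_clamped
            raw[i, j] = raw[j, i] = res.rst
            details[(pops[i], pops[j])] = res
    return DistanceMatrix(labels=pops, values=clamped, raw=raw), details
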