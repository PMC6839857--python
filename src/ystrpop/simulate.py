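"""Synthetic Y-STR panels with controllable population structure.

A forward-time haploid Wright-Fisher simulator under the single-step
stepwise mutation model (SMM): each generation every one of N haplotypes
picks a uniformly random parent, and each allele copy mutates with its
locus's per-copy rate by +-1 repeat with equal probability (reflecting at
one repeat). An ancestral population founded monomorphic burns in for 4N
generations to approach mutation-drift equilibrium, then splits star-like
into ``n_pops`` copies which evolve independently for the configured number
of generations before samples are drawn without replacement.

Panels with *exact* known haplotype spectra (e.g. 392 singletons plus 4
doubletons) can instead be constructed with :func:`sample_from_spectra`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .forensic import FrequencySpectrum
from .haplotypes import Haplotype, Panel, Sample
from .loci import LocusSpec, default_panel, dump_locus_panel, load_locus_panel


@dataclass
class SimConfig:
    """Parameters of one forward simulation.

    ``split_generations`` is a single divergence time T for a star split, or
    one value per population for a star with unequal branch lengths.
    ``founder_allele`` seeds every copy of every locus (or a per-locus
    mapping). ``burn_in`` defaults to 4 * ``pop_size`` generations.
    """

    n_pops: int = 2
    pop_size: int = 100
    sample_size: int = 50
    split_generations: int | tuple[int, ...] = 100
    loci: list[LocusSpec] = field(default_factory=default_panel)
    founder_allele: int | Mapping[str, int] = 14
    seed: int = 0
    burn_in: int | None = None
    population_prefix: str = "P"

    def __post_init__(self) -> None:
        if min(self.n_pops, self.pop_size, self.sample_size) < 1:
            raise ValueError("n_pops, pop_size and sample_size must be >= 1")
        if self.sample_size > self.pop_size:
            raise ValueError("sample_size cannot exceed pop_size")
        if not self.loci:
            raise ValueError("at least one locus required")
        ts = self.split_times()
        if any(t < 0 for t in ts):
            raise ValueError("split_generations must be non-negative")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")

    def split_times(self) -> tuple[int, ...]:
        if isinstance(self.split_generations, (int, np.integer)):
            return (int(self.split_generations),) * self.n_pops
        ts = tuple(int(t) for t in self.split_generations)
        if len(ts) != self.n_pops:
            raise ValueError("need one split time per population")
        return ts

    def founder_for(self, locus: str) -> int:
        if isinstance(self.founder_allele, Mapping):
            return int(self.founder_allele[locus])
        return int(self.founder_allele)


def smm_mutate(value: float, rate: float, rng: np.random.Generator) -> float:
    """Apply one generation of single-step mutation to one allele copy.

    With probability ``rate`` the repeat count steps +1 or -1 with equal
    probability; the boundary at one repeat reflects (1 stepping down
    becomes 2).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate {rate} outside [0, 1]")
    if rate == 0.0 or rng.random() >= rate:
        return value
    step = 1 if rng.random() < 0.5 else -1
    new = value + step
    if new == 0:
        new = 2
    return new


def _mutate_population(
    pop: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> None:
    mask = rng.random(pop.shape) < rates
    if not mask.any():
        return
    steps = rng.integers(0, 2, size=int(mask.sum())) * 2 - 1
    pop[mask] += steps
    pop[pop == 0] = 2


def _evolve(
    pop: np.ndarray, generations: int, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = pop.shape[0]
    for _ in range(generations):
        pop = pop[rng.integers(0, n, n)]
        _mutate_population(pop, rates, rng)
    return pop


def _copy_layout(loci: Sequence[LocusSpec]) -> list[tuple[str, int]]:
    return [(spec.name, spec.copy_number) for spec in loci]


def simulate_panel(config: SimConfig) -> Panel:
    """Run the forward simulation and return the sampled panel.

    The same seed and configuration always produce an identical panel;
    per-population random streams are derived deterministically from the
    master seed, so adding populations does not disturb earlier ones.
    """
    layout = _copy_layout(config.loci)
    n_copies = sum(c for _, c in layout)
    rates = np.repeat(
        [spec.mutation_rate for spec in config.loci],
        [spec.copy_number for spec in config.loci],
    ).reshape(1, n_copies)
    founder = np.concatenate(
        [np.full(c, config.founder_for(name)) for name, c in layout]
    )

    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_pops + 1)
    rng0 = np.random.default_rng(streams[0])

    burn_in = 4 * config.pop_size if config.burn_in is None else config.burn_in
    ancestral = np.tile(founder, (config.pop_size, 1)).astype(np.int64)
    ancestral = _evolve(ancestral, burn_in, rates, rng0)

    samples: list[Sample] = []
    for p, t in enumerate(config.split_times()):
        rng = np.random.default_rng(streams[p + 1])
        pop = _evolve(ancestral.copy(), t, rates, rng)
        chosen = rng.choice(config.pop_size, size=config.sample_size, replace=False)
        pop_id = f"{config.population_prefix}{p + 1}"
        for s_idx, row_idx in enumerate(chosen):
            row = pop[row_idx]
            alleles: dict[str, tuple[float, ...]] = {}
            offset = 0
            for name, copies in layout:
                alleles[name] = tuple(
                    sorted(float(v) for v in row[offset : offset + copies])
                )
                offset += copies
            samples.append(
                Sample(f"{pop_id}_{s_idx + 1:04d}", pop_id, Haplotype(alleles))
            )
    return Panel(loci=list(config.loci), samples=samples)


# ---------------------------------------------------------------------------
# spectrum-driven construction
# ---------------------------------------------------------------------------

def haplotype_from_key(
    key: Sequence[Sequence[float]], loci: Sequence[LocusSpec]
) -> Haplotype:
    """Build a haplotype from an identity tuple aligned with ``loci``."""
    if len(key) != len(loci):
        raise ValueError("haplotype key length does not match locus list")
    return Haplotype(
        {spec.name: tuple(vals) for spec, vals in zip(loci, key) if vals}
    )


def sample_from_spectra(
    spectra: Mapping[str, FrequencySpectrum],
    loci: Sequence[LocusSpec],
    *,
    mode: str = "exact",
    sample_size: int | None = None,
    seed: int | None = None,
) -> Panel:
    """Construct a panel whose haplotype spectrum is known by design.

    ``spectra`` maps population label -> haplotype :class:`FrequencySpectrum`
    whose keys are haplotype identity tuples aligned with ``loci``. In
    ``"exact"`` mode every key appears exactly its recorded count (the
    panel's spectrum equals the input; ``sample_size`` is ignored); in
    ``"multinomial"`` mode ``sample_size`` haplotypes per population are
    drawn with probabilities proportional to the counts.
    """
    if mode not in ("exact", "multinomial"):
        raise ValueError(f"mode must be 'exact' or 'multinomial', got {mode!r}")
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    for pop, spectrum in spectra.items():
        keys = list(spectrum.counts)
        if mode == "exact":
            drawn = [k for k in keys for _ in range(spectrum.counts[k])]
            rng.shuffle(drawn)
        else:
            if sample_size is None:
                raise ValueError("multinomial mode requires sample_size")
            probs = np.array([spectrum.counts[k] for k in keys], dtype=float)
            probs /= probs.sum()
            counts = rng.multinomial(sample_size, probs)
            drawn = [k for k, c in zip(keys, counts) for _ in range(c)]
            rng.shuffle(drawn)
        for i, key in enumerate(drawn):
            samples.append(
                Sample(f"{pop}_{i + 1:05d}", pop, haplotype_from_key(key, loci))
            )
    return Panel(loci=list(loci), samples=samples)


def distinct_haplotype_keys(
    n: int, loci: Sequence[LocusSpec], *, base_allele: int = 10, span: int = 7
) -> list[tuple[tuple[float, ...], ...]]:
    """Deterministically enumerate ``n`` distinct haplotype identity tuples.

    Index ``i`` is written in mixed radix ``span`` across allele slots; each
    copy of a multi-copy locus lives in a disjoint allele range so that
    ascending sorting never collapses two distinct indices.
    """
    slots = [(spec.name, c) for spec in loci for c in range(spec.copy_number)]
    capacity = span ** len(slots)
    if n > capacity:
        raise ValueError(f"cannot enumerate {n} haplotypes over {len(slots)} slots")
    keys = []
    for i in range(n):
        digits = []
        rem = i
        for _ in slots:
            digits.append(rem % span)
            rem //= span
        key = []
        pos = 0
        for spec in loci:
            vals = []
            for c in range(spec.copy_number):
                vals.append(float(base_allele + 10 * c + digits[pos]))
                pos += 1
            key.append(tuple(sorted(vals)))
        keys.append(tuple(key))
    return keys


# ---------------------------------------------------------------------------
# YAML round trip for CLI use
# ---------------------------------------------------------------------------

def sim_config_to_yaml(config: SimConfig) -> str:
    data = {
        "n_pops": config.n_pops,
        "pop_size": config.pop_size,
        "sample_size": config.sample_size,
        "split_generations": (
            config.split_generations
            if isinstance(config.split_generations, int)
            else list(config.split_generations)
        ),
        "founder_allele": (
            dict(config.founder_allele)
            if isinstance(config.founder_allele, Mapping)
            else config.founder_allele
        ),
        "seed": config.seed,
        "burn_in": config.burn_in,
        "population_prefix": config.population_prefix,
        "loci": yaml.safe_load(dump_locus_panel(config.loci))["loci"],
    }
    return yaml.safe_dump(data, sort_keys=False)


def sim_config_from_yaml(text: str) -> SimConfig:
    data = yaml.safe_load(text)
    loci = (
        load_locus_panel(yaml.safe_dump({"loci": data["loci"]}))
        if "loci" in data and data["loci"] != "default"
        else default_panel()
    )
    split = data.get("split_generations", 100)
    if isinstance(split, list):
        split = tuple(split)
    return SimConfig(
        n_pops=int(data.get("n_pops", 2)),
        pop_size=int(data.get("pop_size", 100)),
        sample_size=int(data.get("sample_size", 50)),
        split_generations=split,
        loci=loci,
        founder_allele=data.get("founder_allele", 14),
        seed=int(data.get("seed", 0)),
        burn_in=data.get("burn_in"),
        population_prefix=str(data.get("population_prefix", "P")),
    )
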