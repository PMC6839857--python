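"""In-memory model of Y-STR haplotypes and multi-sample panels.

Alleles are repeat counts stored as floats; microvariant (incomplete-repeat)
alleles carry one decimal digit, e.g. ``17.2`` for 17 repeats plus 2 bases.
A haplotype maps each locus to the ascending-sorted tuple of its allele
copies. Per-locus quality flags record missing calls and copy-number
anomalies (e.g. a duplication at a nominally single-copy locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .loci import LocusSpec

#: Flag value: no allele call at this locus.
MISSING = "missing"
#: Flag value: observed copy count differs from the locus specification.
COPY_ANOMALY = "copy_number_anomaly"

#: Permitted fractional parts of an allele value, in tenths.
_ALLOWED_TENTHS = (0, 1, 2, 3)


def validate_allele(value: float) -> float:
    """Validate and canonicalize a repeat-count value.

    Canonical alleles are positive with at most one decimal digit drawn from
    {.1, .2, .3} (ISFG microvariant nomenclature). Returns the value rounded
    to one decimal so that equal alleles compare equal as floats.
    """
    v = float(value)
    if v <= 0:
        raise ValueError(f"allele value must be positive, got {value!r}")
    tenths = round(v * 10)
    if abs(v * 10 - tenths) > 1e-6:
        raise ValueError(f"allele value {value!r} has more than one decimal digit")
    if tenths % 10 not in _ALLOWED_TENTHS:
        raise ValueError(
            f"allele value {value!r}: fractional part must be one of .0/.1/.2/.3"
        )
    return tenths / 10.0


def format_allele(value: float) -> str:
    """Render an allele the way forensic tables print it (``14``, ``17.2``)."""
    if value == int(value):
        return str(int(value))
    return f"{value:.1f}"


@dataclass
class Haplotype:
    """One male sample's joint allele state across a locus panel.

    ``alleles`` maps locus name -> ascending-sorted tuple of allele values.
    Loci flagged :data:`MISSING` have no entry in ``alleles``; loci flagged
    :data:`COPY_ANOMALY` keep their observed alleles (they still contribute
    to whole-haplotype identity) but are excluded from per-locus statistics.
    """

    alleles: dict[str, tuple[float, ...]]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = {
            name: tuple(sorted(vals)) for name, vals in self.alleles.items()
        }

    def key(self, loci: Sequence[str]) -> tuple[tuple[float, ...], ...]:
        """Identity tuple over the given loci (missing loci appear empty)."""
        return tuple(self.alleles.get(name, ()) for name in loci)

    def has_missing(self, loci: Iterable[str]) -> bool:
        return any(self.flags.get(name) == MISSING for name in loci)

    def is_unflagged(self, loci: Iterable[str]) -> bool:
        """True when no quality flag is set at any of the given loci."""
        return all(name not in self.flags for name in loci)


@dataclass
class Sample:
    sample_id: str
    population: str
    haplotype: Haplotype


@dataclass
class Panel:
    """A labelled collection of haplotypes over a common locus panel."""

    loci: list[LocusSpec]
    samples: list[Sample]

    def __post_init__(self) -> None:
        names = [spec.name for spec in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in panel")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample IDs: {dupes}")
        known = set(names)
        for s in self.samples:
            extra = set(s.haplotype.alleles) - known
            if extra:
                raise ValueError(
                    f"sample {s.sample_id} references loci not in panel: {sorted(extra)}"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def locus_names(self) -> list[str]:
        return [spec.name for spec in self.loci]

    def locus(self, name: str) -> LocusSpec:
        for spec in self.loci:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown locus {name!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def samples_for(self, population: str) -> list[Sample]:
        out = [s for s in self.samples if s.population == population]
        if not out:
            raise KeyError(f"no samples for population {population!r}")
        return out

    def complete_samples(
        self,
        loci: Sequence[str] | None = None,
        *,
        require_unflagged: bool = True,
    ) -> list[Sample]:
        """Samples usable over a locus subset.

        With ``require_unflagged`` (the default, appropriate for distance
        computations) any flag excludes the sample; otherwise only missing
        calls do (appropriate for whole-haplotype counting, where anomalous
        loci still carry identity information).
        """
        names = list(loci) if loci is not None else self.locus_names
        if require_unflagged:
            return [s for s in self.samples if s.haplotype.is_unflagged(names)]
        return [s for s in self.samples if not s.haplotype.has_missing(names)]


def subpanel(panel: Panel, populations: Iterable[str]) -> Panel:
    """Restrict a panel to the given populations (sample order preserved)."""
    keep = set(populations)
    return Panel(
        loci=list(panel.loci),
        samples=[s for s in panel.samples if s.population in keep],
    )
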