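"""Y-STR locus panel definitions.

A locus is described by its name, the number of allele copies a single male
carries (1 for ordinary loci, 2 for duplicated loci such as DYS385a/b; some
duplicated loci occasionally amplify one or three copies and are marked
``variable_copy``), and a per-generation per-copy mutation rate used only by
the forward simulator.

The module ships the 36-locus panel of the Goldeneye Y-PLUS multiplex and the
27-amplicon Yfiler-Plus subset commonly used for inter-population Rst
comparisons (25 locus names; DYS385a/b and DYF387S1 contribute two amplicons
each).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

#: Default per-generation, per-copy stepwise mutation probability.
DEFAULT_MUTATION_RATE = 0.002


@dataclass(frozen=True)
class LocusSpec:
    """Description of one Y-STR locus.

    Parameters
    ----------
    name:
        Locus identifier, e.g. ``"DYS19"``.
    copy_number:
        Expected number of allele copies per male sample (1 for single-copy
        loci, 2 for duplicated loci).
    variable_copy:
        If True the locus may legitimately show any number >= 1 of copies
        (e.g. DYF387S1, DYS527, DYF404S1); copy-count checks are relaxed.
    mutation_rate:
        Per-generation, per-copy single-step mutation probability used by the
        simulator. Must lie in [0, 0.1].
    """

    name: str
    copy_number: int = 1
    variable_copy: bool = False
    mutation_rate: float = DEFAULT_MUTATION_RATE

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")
        if not 0.0 <= self.mutation_rate <= 0.1:
            raise ValueError(
                f"{self.name}: mutation_rate {self.mutation_rate} outside [0, 0.1]"
            )

    @property
    def is_multicopy(self) -> bool:
        return self.copy_number > 1 or self.variable_copy


_SINGLE_COPY_NAMES = (
    "DYS19", "DYS460", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392",
    "DYS393", "DYS437", "DYS438", "DYS439", "DYS448", "Y-GATA-H4", "DYS449",
    "DYS456", "DYS458", "DYS481", "DYS533", "DYS570", "DYS627", "DYS635",
    "DYS576", "DYS388", "DYS549", "DYS444", "DYS643", "DYS447", "DYS557",
    "DYS596", "DYS593", "DYS645", "DYS518",
)

_MULTI_COPY = (
    ("DYS385", 2, False),
    ("DYF387S1", 2, True),
    ("DYS527", 2, True),
    ("DYF404S1", 2, True),
)

#: Locus names of the Yfiler-Plus panel (27 amplicons over 25 names).
YFILER_PLUS_LOCI = frozenset(
    {
        "DYS19", "DYS385", "DYS389I", "DYS389II", "DYS390", "DYS391",
        "DYS392", "DYS393", "DYS437", "DYS438", "DYS439", "DYS448", "DYS449",
        "DYS456", "DYS458", "DYS460", "DYS481", "DYS518", "DYS533", "DYS570",
        "DYS576", "DYS627", "DYS635", "DYF387S1", "Y-GATA-H4",
    }
)


def default_panel(mutation_rate: float = DEFAULT_MUTATION_RATE) -> list[LocusSpec]:
    """The 36-locus Goldeneye Y-PLUS panel (32 single-copy + 4 multi-copy)."""
    loci = [
        LocusSpec(name, mutation_rate=mutation_rate) for name in _SINGLE_COPY_NAMES
    ]
    loci += [
        LocusSpec(name, copy_number=cn, variable_copy=var, mutation_rate=mutation_rate)
        for name, cn, var in _MULTI_COPY
    ]
    return loci


def resolve_subset(
    loci: Sequence[LocusSpec],
    subset: str | Iterable[str] = "all",
    *,
    include_multicopy: bool = True,
) -> list[LocusSpec]:
    """Select a locus subset from a panel.

    ``subset`` is either ``"all"``, ``"yfiler_plus"`` or an explicit iterable
    of locus names. ``include_multicopy=False`` additionally drops duplicated
    loci (useful when comparing against tools that restrict Rst to
    single-copy loci).
    """
    if isinstance(subset, str):
        if subset == "all":
            wanted = {spec.name for spec in loci}
        elif subset == "yfiler_plus":
            wanted = set(YFILER_PLUS_LOCI)
        else:
            raise ValueError(f"unknown locus subset {subset!r}")
    else:
        wanted = set(subset)
        known = {spec.name for spec in loci}
        unknown = wanted - known
        if unknown:
            raise ValueError(f"loci not in panel: {sorted(unknown)}")
    out = [spec for spec in loci if spec.name in wanted]
    if not include_multicopy:
        out = [spec for spec in out if not spec.is_multicopy]
    return out


def load_locus_panel(source: str | Path) -> list[LocusSpec]:
    """Read a locus panel from YAML (path, file object or YAML text).

    Expected layout::

        loci:
          - name: DYS19
            copy_number: 1
            mutation_rate: 0.002
          - name: DYS385
            copy_number: 2
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = source
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "loci" not in data:
        raise ValueError("locus panel YAML must contain a top-level 'loci' list")
    loci = []
    for entry in data["loci"]:
        loci.append(
            LocusSpec(
                name=str(entry["name"]),
                copy_number=int(entry.get("copy_number", 1)),
                variable_copy=bool(entry.get("variable_copy", False)),
                mutation_rate=float(entry.get("mutation_rate", DEFAULT_MUTATION_RATE)),
            )
        )
    names = [spec.name for spec in loci]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names in panel definition")
    return loci


def dump_locus_panel(loci: Sequence[LocusSpec]) -> str:
    """Serialize a locus panel to YAML text (inverse of :func:`load_locus_panel`)."""
    return yaml.safe_dump({"loci": [asdict(spec) for spec in loci]}, sort_keys=False)
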