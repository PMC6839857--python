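"""Forensic summary statistics by direct counting.

Implements the standard Y-STR population-report statistics:

* per-locus gene diversity (Nei's unbiased heterozygosity analogue)
  ``GD = n/(n-1) * (1 - sum_i p_i^2)`` over allele frequencies,
* haplotype diversity ``HD`` — the same statistic over whole-haplotype
  frequencies,
* haplotype match probability ``HMP = sum_i p_i^2``,
* discrimination capacity ``DC = k/n`` (distinct haplotypes over samples).

All frequencies come from direct counting. Multi-copy loci (DYS385a/b and
friends) expose two allele spectra: a *pooled* spectrum over individual
copies (n = total copies observed) and a *combination* spectrum over the
sorted allele multiset per sample (n = samples); gene diversity for
multi-copy loci is reported on the combination spectrum, matching how
forensic tables report one GD for "DYS385a/b".
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import math
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping, Sequence

from .haplotypes import MISSING, Panel, format_allele
from .loci import resolve_subset


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given spectrum (e.g. n < 2)."""


@dataclass(frozen=True)
class FrequencySpectrum:
    """Occurrence counts of alleles (per locus) or of whole haplotypes.

    ``unit`` is ``"allele"`` or ``"haplotype"``; ``counts`` maps a hashable
    key (an allele value, an allele-combination tuple, or a haplotype key)
    to its occurrence count. ``excluded`` records sample IDs dropped for
    missing data; it does not participate in equality.
    """

    unit: str
    counts: Mapping[Hashable, int]
    excluded: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.unit not in ("allele", "haplotype"):
            raise ValueError(f"unit must be 'allele' or 'haplotype', got {self.unit!r}")
        object.__setattr__(self, "counts", dict(self.counts))
        if any(c < 1 or c != int(c) for c in self.counts.values()):
            raise ValueError("all counts must be positive integers")

    @property
    def n(self) -> int:
        """Total number of observations."""
        return int(sum(self.counts.values()))

    @property
    def k(self) -> int:
        """Number of distinct keys observed."""
        return len(self.counts)

    @property
    def n_unique(self) -> int:
        """Number of keys observed exactly once (singletons)."""
        return sum(1 for c in self.counts.values() if c == 1)

    def frequencies(self) -> dict[Hashable, float]:
        n = self.n
        return {key: c / n for key, c in self.counts.items()}

    def sum_squared_frequencies(self) -> float:
        n = self.n
        if n == 0:
            raise UndefinedStatisticError("empty spectrum")
        return sum(c * c for c in self.counts.values()) / (n * n)


# ---------------------------------------------------------------------------
# spectra from panels
# ---------------------------------------------------------------------------

def allele_frequency_spectrum(
    panel: Panel, locus: str, *, pooled: bool = True
) -> FrequencySpectrum:
    """Direct-count allele spectrum at one locus.

    Samples flagged at the locus (missing call or copy-number anomaly) are
    excluded and recorded in ``excluded``. For multi-copy loci the default
    ``pooled=True`` counts every allele copy separately (n = samples x
    copies); ``pooled=False`` counts sorted allele combinations (n =
    samples). For single-copy loci both modes coincide up to key type.
    """
    spec = panel.locus(locus)  # raises KeyError for unknown locus
    counts: dict[Hashable, int] = {}
    excluded: list[str] = []
    for s in panel.samples:
        if locus in s.haplotype.flags:
            excluded.append(s.sample_id)
            continue
        vals = s.haplotype.alleles.get(locus)
        if not vals:
            excluded.append(s.sample_id)
            continue
        if pooled and spec.copy_number == 1 and not spec.variable_copy:
            counts[vals[0]] = counts.get(vals[0], 0) + 1
        elif pooled:
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
        else:
            counts[vals] = counts.get(vals, 0) + 1
    return FrequencySpectrum("allele", counts, tuple(excluded))


def allele_combination_spectrum(panel: Panel, locus: str) -> FrequencySpectrum:
    """Spectrum over sorted allele multisets per sample (n = samples)."""
    return allele_frequency_spectrum(panel, locus, pooled=False)


def haplotype_spectrum(
    panel: Panel, loci: Sequence[str] | None = None
) -> FrequencySpectrum:
    """Whole-haplotype spectrum over a locus subset (default: all loci).

    Haplotype identity is the tuple of ascending-sorted allele multisets over
    the subset. Samples missing any subset locus are excluded and recorded;
    copy-number-anomalous loci keep their observed alleles in the identity.
    """
    names = list(loci) if loci is not None else panel.locus_names
    unknown = set(names) - set(panel.locus_names)
    if unknown:
        raise KeyError(f"unknown loci {sorted(unknown)}")
    counts: dict[Hashable, int] = {}
    excluded: list[str] = []
    for s in panel.samples:
        if s.haplotype.has_missing(names):
            excluded.append(s.sample_id)
            continue
        key = s.haplotype.key(names)
        counts[key] = counts.get(key, 0) + 1
    return FrequencySpectrum("haplotype", counts, tuple(excluded))


# ---------------------------------------------------------------------------
# statistics on spectra
# ---------------------------------------------------------------------------

def match_probability(spectrum: FrequencySpectrum) -> float:
    """Probability two random samples share a key: ``sum_i p_i^2``."""
    return spectrum.sum_squared_frequencies()


def gene_diversity(spectrum: FrequencySpectrum) -> float:
    """Nei's unbiased diversity ``n/(n-1) * (1 - sum_i p_i^2)``.

    Undefined for n < 2 (the unbiasing factor diverges); raises
    :class:`UndefinedStatisticError` in that case.
    """
    n = spectrum.n
    if n < 2:
        raise UndefinedStatisticError(f"gene diversity undefined for n={n}")
    return n / (n - 1) * (1.0 - spectrum.sum_squared_frequencies())


def haplotype_diversity(spectrum: FrequencySpectrum) -> float:
    """Nei diversity applied to the whole-haplotype spectrum."""
    return gene_diversity(spectrum)


def discrimination_capacity(spectrum: FrequencySpectrum) -> float:
    """Distinct haplotypes over samples, ``DC = k/n``."""
    n = spectrum.n
    if n < 1:
        raise UndefinedStatisticError("empty spectrum")
    return spectrum.k / n


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal round-half-up at ``ndigits`` places (0.00255 -> 0.0026)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def round_toward_zero(x: float, ndigits: int = 4) -> float:
    """Decimal truncation at ``ndigits`` places (0.99995 -> 0.9999)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_DOWN))


@dataclass
class ForensicSummary:
    """Aggregate forensic report for one panel.

    ``gd`` maps locus name to gene diversity (None where undefined);
    ``total_alleles_pooled`` counts distinct alleles per locus with
    multi-copy loci pooled over copies, ``total_alleles_combination``
    counts distinct sorted combinations instead — forensic reports are
    ambiguous about which convention a printed allele total uses, so both
    are emitted.
    """

    n_samples: int
    n_complete: int
    excluded_samples: tuple[str, ...]
    k: int
    n_unique: int
    hd: float
    hmp: float
    dc: float
    gd: dict[str, float | None]
    total_alleles_pooled: int
    total_alleles_combination: int
    loci_used: list[str]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, *, precision: int | None = None) -> str:
        d = self.to_dict()
        if precision is not None:
            for key in ("hd", "hmp", "dc"):
                d[key] = round(d[key], precision)
            d["gd"] = {
                k: (None if v is None else round(v, precision))
                for k, v in d["gd"].items()
            }
        d["excluded_samples"] = list(d["excluded_samples"])
        return json.dumps(d, indent=2)

    def to_text(self, *, precision: int = 4) -> str:
        lines = [
            f"samples                 {self.n_samples}",
            f"complete haplotypes     {self.n_complete}",
            f"distinct haplotypes (k) {self.k}",
            f"unique haplotypes       {self.n_unique}",
            f"haplotype diversity     {self.hd:.{precision}f}",
            f"match probability       {self.hmp:.{precision}f}",
            f"discrimination capacity {self.dc:.{precision}f}",
            f"distinct alleles        {self.total_alleles_pooled} pooled"
            f" / {self.total_alleles_combination} as combinations",
            "",
            "locus\tGD",
        ]
        for name in self.loci_used:
            v = self.gd.get(name)
            lines.append(f"{name}\t" + ("NA" if v is None else f"{v:.{precision}f}"))
        return "\n".join(lines) + "\n"


def forensic_report(panel: Panel, loci: Sequence[str] | None = None) -> ForensicSummary:
    """Compute the full forensic summary for a panel.

    ``loci`` restricts haplotype-level statistics to a subset (per-locus GD
    and allele totals are still reported for that subset only).
    """
    names = list(loci) if loci is not None else panel.locus_names
    hspec = haplotype_spectrum(panel, names)
    if hspec.n < 2:
        raise UndefinedStatisticError(
            "forensic report requires at least 2 complete haplotypes"
        )
    hmp = match_probability(hspec)
    hd = haplotype_diversity(hspec)
    dc = discrimination_capacity(hspec)
    gd: dict[str, float | None] = {}
    pooled_total = 0
    combo_total = 0
    for name in names:
        spec = panel.locus(name)
        pooled = allele_frequency_spectrum(panel, name, pooled=True)
        combo = allele_combination_spectrum(panel, name)
        pooled_total += pooled.k
        combo_total += combo.k
        basis = combo if spec.is_multicopy else pooled
        try:
            gd[name] = gene_diversity(basis)
        except UndefinedStatisticError:
            gd[name] = None
    return ForensicSummary(
        n_samples=panel.n_samples,
        n_complete=hspec.n,
        excluded_samples=hspec.excluded,
        k=hspec.k,
        n_unique=hspec.n_unique,
        hd=hd,
        hmp=hmp,
        dc=dc,
        gd=gd,
        total_alleles_pooled=pooled_total,
        total_alleles_combination=combo_total,
        loci_used=names,
    )
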