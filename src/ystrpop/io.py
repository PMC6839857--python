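"""Reading and writing the pipeline's external formats.

Haplotype tables are tab- or comma-separated, one row per male sample, one
column per locus; multi-copy loci hold delimited allele lists ("13-14"),
microvariants keep their decimal notation ("17.2"). Outputs are frequency
tables (TSV), square PHYLIP distance matrices, and Newick trees.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .amova import DistanceMatrix
from .forensic import (
    FrequencySpectrum,
    UndefinedStatisticError,
    gene_diversity,
)
from .haplotypes import (
    COPY_ANOMALY,
    MISSING,
    Haplotype,
    Panel,
    Sample,
    format_allele,
    validate_allele,
)
from .loci import LocusSpec
from .ordination import Tree

#: Cell tokens treated as a missing call (case-insensitive).
DEFAULT_MISSING_TOKENS = frozenset({"", "-", "n", "null"})

_ALLELE_DELIMITERS = "-,/"

_SAMPLE_COLUMNS = {"sample", "sample_id", "sampleid", "id"}
_POPULATION_COLUMNS = {"population", "population_id", "pop", "group"}


class TableParseError(ValueError):
    """A haplotype-table cell could not be interpreted."""


def parse_allele_cell(
    cell: str,
    spec: LocusSpec,
    *,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
) -> tuple[tuple[float, ...], str | None]:
    """Parse one raw table cell into a sorted allele tuple plus a flag.

    Accepts "-", "," and "/" as delimiters between copies of multi-copy
    loci; decimal microvariants are preserved exactly. Recognized missing
    markers yield ``((), MISSING)``. A copy count that contradicts the locus
    spec yields the alleles plus a :data:`COPY_ANOMALY` flag. Non-numeric
    tokens raise :class:`TableParseError`.
    """
    token = cell.strip()
    if token.lower() in missing_tokens:
        return (), MISSING
    parts = [p for p in _split_alleles(token) if p.strip()]
    values = []
    for part in parts:
        try:
            values.append(validate_allele(float(part)))
        except ValueError as exc:
            raise TableParseError(f"cannot parse allele token {cell!r}: {exc}") from exc
    if not values:
        return (), MISSING
    values.sort()
    flag = None
    if spec.variable_copy:
        pass  # any count >= 1 is acceptable
    elif len(values) != spec.copy_number:
        flag = COPY_ANOMALY
    return tuple(values), flag


def _split_alleles(token: str) -> list[str]:
    out, cur = [], []
    for ch in token:
        if ch in _ALLELE_DELIMITERS:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return out


def _as_text(source: str | Path | TextIO) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            return source
        return Path(source).read_text()
    return source.read()


def read_haplotype_table(
    source: str | Path | TextIO,
    loci: Sequence[LocusSpec],
    *,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    default_population: str = "ALL",
) -> Panel:
    """Read a haplotype table into a :class:`Panel`.

    The first row must be a header with a sample-ID column (named sample/
    sample_id/id, otherwise the first column is used), an optional
    population column, and one column per locus. Unknown columns are
    reported via a warning and skipped; loci absent from the table are
    dropped from the returned panel with a warning.
    """
    text = _as_text(source)
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(
        _io.StringIO(text), sep=delimiter, dtype=str, keep_default_na=False
    )
    columns = list(df.columns)
    by_name = {spec.name: spec for spec in loci}

    sample_col = next((c for c in columns if c.strip().lower() in _SAMPLE_COLUMNS), None)
    pop_col = next((c for c in columns if c.strip().lower() in _POPULATION_COLUMNS), None)
    locus_cols = [c for c in columns if c.strip() in by_name]
    if not locus_cols:
        raise TableParseError(
            "no locus columns recognized — is the header row present?"
        )
    if sample_col is None:
        candidates = [c for c in columns if c not in locus_cols and c != pop_col]
        if candidates:
            sample_col = candidates[0]
    unknown = [
        c for c in columns if c not in locus_cols and c not in (sample_col, pop_col)
    ]
    if unknown:
        warnings.warn(f"skipping unknown columns: {unknown}", stacklevel=2)
    absent = [name for name in by_name if name not in {c.strip() for c in locus_cols}]
    if absent:
        warnings.warn(f"loci absent from table: {absent}", stacklevel=2)

    kept_specs = [by_name[c.strip()] for c in locus_cols]
    samples: list[Sample] = []
    for row_idx, row in df.iterrows():
        sid = str(row[sample_col]).strip() if sample_col else f"S{row_idx + 1}"
        pop = str(row[pop_col]).strip() if pop_col else default_population
        alleles: dict[str, tuple[float, ...]] = {}
        flags: dict[str, str] = {}
        for col, spec in zip(locus_cols, kept_specs):
            try:
                vals, flag = parse_allele_cell(
                    str(row[col]), spec, missing_tokens=missing_tokens
                )
            except TableParseError as exc:
                raise TableParseError(
                    f"row {row_idx + 2} (sample {sid!r}), column {spec.name}: {exc}"
                ) from exc
            if flag == MISSING:
                flags[spec.name] = MISSING
            else:
                alleles[spec.name] = vals
                if flag:
                    flags[spec.name] = flag
        samples.append(Sample(sid, pop or default_population, Haplotype(alleles, flags)))
    return Panel(loci=kept_specs, samples=samples)


def write_haplotype_table(
    panel: Panel,
    *,
    delimiter: str = "\t",
    allele_delimiter: str = "-",
    include_population: bool = True,
) -> str:
    """Serialize a panel back to table text (inverse of the reader)."""
    header = ["sample_id"]
    if include_population:
        header.append("population")
    header += panel.locus_names
    lines = [delimiter.join(header)]
    for s in panel.samples:
        row = [s.sample_id]
        if include_population:
            row.append(s.population)
        for name in panel.locus_names:
            vals = s.haplotype.alleles.get(name, ())
            row.append(allele_delimiter.join(format_allele(v) for v in vals))
        lines.append(delimiter.join(row))
    return "\n".join(lines) + "\n"


def write_frequency_table(
    spectra: Mapping[str, FrequencySpectrum],
    *,
    orient: str = "wide",
    precision: int = 4,
) -> str:
    """Render per-locus allele spectra as a TSV frequency table.

    ``orient="wide"`` mirrors the usual supplementary layout: allele values
    as rows, loci as columns, a final GD row; ``orient="long"`` emits
    locus/allele/count/frequency records. Combination keys print joined by
    "-". Frequencies are written at ``precision`` decimals.
    """
    loci = list(spectra)

    def fmt_key(key) -> str:
        if isinstance(key, tuple):
            return "-".join(format_allele(v) for v in key)
        return format_allele(key)

    def gd_text(spec: FrequencySpectrum) -> str:
        try:
            return f"{gene_diversity(spec):.{precision}f}"
        except UndefinedStatisticError:
            return "NA"

    if orient == "long":
        lines = ["locus\tallele\tcount\tfrequency\tGD"]
        for name in loci:
            spec = spectra[name]
            gd = gd_text(spec)
            freqs = spec.frequencies()
            for key in sorted(spec.counts, key=fmt_key):
                lines.append(
                    f"{name}\t{fmt_key(key)}\t{spec.counts[key]}"
                    f"\t{freqs[key]:.{precision}f}\t{gd}"
                )
        return "\n".join(lines) + "\n"
    if orient != "wide":
        raise ValueError(f"orient must be 'wide' or 'long', got {orient!r}")

    all_keys: dict[str, None] = {}
    for name in loci:
        for key in spectra[name].counts:
            all_keys.setdefault(fmt_key(key), None)

    def sort_key(label: str):
        parts = label.split("-")
        try:
            return (0, tuple(float(p) for p in parts))
        except ValueError:
            return (1, (label,))

    rows = sorted(all_keys, key=sort_key)
    lines = ["Allele\t" + "\t".join(loci)]
    freq_by_locus = {
        name: {fmt_key(k): f for k, f in spectra[name].frequencies().items()}
        for name in loci
    }
    for label in rows:
        cells = [
            f"{freq_by_locus[name][label]:.{precision}f}"
            if label in freq_by_locus[name]
            else ""
            for name in loci
        ]
        lines.append(label + "\t" + "\t".join(cells))
    lines.append("GD\t" + "\t".join(gd_text(spectra[name]) for name in loci))
    return "\n".join(lines) + "\n"


def write_distance_matrix(d: DistanceMatrix, *, precision: int = 4) -> str:
    """Square PHYLIP-format distance matrix (relaxed label width)."""
    lines = [str(d.size)]
    for label, row in zip(d.labels, d.values):
        lines.append(label + " " + " ".join(f"{v:.{precision}f}" for v in row))
    return "\n".join(lines) + "\n"


def read_distance_matrix(source: str | Path | TextIO) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by the writer above."""
    text = _as_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty distance matrix")
    m = int(lines[0].split()[0])
    labels: list[str] = []
    values = np.zeros((m, m))
    if len(lines) - 1 != m:
        raise ValueError(f"expected {m} matrix rows, found {len(lines) - 1}")
    for i, line in enumerate(lines[1:]):
        fields = line.split()
        labels.append(fields[0])
        row = [float(x) for x in fields[1:]]
        if len(row) != m:
            raise ValueError(f"row {fields[0]!r} has {len(row)} values, expected {m}")
        values[i] = row
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=labels, values=values)


def write_newick(tree: Tree) -> str:
    """Newick serialization with branch lengths, ';'-terminated."""
    return tree.to_newick()
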