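"""One-command reproduction of the full analysis chain.

Given a haplotype table (read from disk or freshly simulated), the pipeline
computes allele-frequency tables, the forensic summary, the pairwise Rst
matrix over the configured locus subset, MDS coordinates and a
neighbor-joining tree, and writes a manifest recording the seed, the locus
subset, per-stage sample exclusions and every artifact produced. With a
single population the comparison stages are skipped with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any

from . import forensic as _forensic
from . import io as _io
from . import ordination as _ordination
from .amova import pairwise_rst_matrix
from .haplotypes import Panel
from .loci import LocusSpec, default_panel
from .simulate import SimConfig, sim_config_to_yaml, simulate_panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``sim`` must be set. ``subset`` selects
    the loci used for Rst/MDS/NJ ("all", "yfiler_plus", or a name list);
    forensic statistics always use the full panel.
    """

    outdir: Path
    input_path: Path | None = None
    sim: SimConfig | None = None
    loci: list[LocusSpec] | None = None
    subset: str = "yfiler_plus"
    include_multicopy: bool = True
    permutations: int = 0
    seed: int = 0
    precision: int = 4
    mds_dims: int = 2

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be provided")
        self.outdir = Path(self.outdir)


def _load_panel(config: PipelineConfig) -> tuple[Panel, dict[str, Any]]:
    if config.sim is not None:
        panel = simulate_panel(config.sim)
        table_path = config.outdir / "haplotypes.tsv"
        table_path.write_text(_io.write_haplotype_table(panel))
        cfg_path = config.outdir / "simulation.yaml"
        cfg_path.write_text(sim_config_to_yaml(config.sim))
        return panel, {
            "kind": "simulated",
            "table": str(table_path),
            "sim_config": str(cfg_path),
        }
    loci = config.loci if config.loci is not None else default_panel()
    panel = _io.read_haplotype_table(config.input_path, loci)
    return panel, {"kind": "table", "table": str(config.input_path)}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the artifact manifest."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "ystrpop",
        "version": _package_version(),
        "seed": config.seed,
        "locus_subset": config.subset,
        "include_multicopy": config.include_multicopy,
        "permutations": config.permutations,
        "stages": {},
        "artifacts": {},
    }

    try:
        panel, input_info = _load_panel(config)
    except Exception as exc:  # noqa: BLE001 - report the stage that failed
        raise PipelineError("input", str(exc)) from exc
    manifest["input"] = input_info
    logger.info("input: %d samples, %d loci", panel.n_samples, len(panel.loci))

    # -- frequencies ------------------------------------------------------
    try:
        spectra = {}
        for spec in panel.loci:
            spectra[spec.name] = (
                _forensic.allele_combination_spectrum(panel, spec.name)
                if spec.is_multicopy
                else _forensic.allele_frequency_spectrum(panel, spec.name)
            )
        freq_path = config.outdir / "frequencies.tsv"
        freq_path.write_text(
            _io.write_frequency_table(spectra, precision=config.precision)
        )
        manifest["artifacts"]["frequencies"] = str(freq_path)
        excluded = {
            name: len(s.excluded) for name, s in spectra.items() if s.excluded
        }
        manifest["stages"]["frequencies"] = {
            "loci": len(spectra),
            "excluded_per_locus": excluded,
        }
        logger.info("frequencies: %d loci, exclusions at %d loci",
                    len(spectra), len(excluded))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("frequencies", str(exc)) from exc

    # -- forensic summary -------------------------------------------------
    try:
        report = _forensic.forensic_report(panel)
        rep_path = config.outdir / "forensic.json"
        rep_path.write_text(report.to_json(precision=None))
        manifest["artifacts"]["forensic"] = str(rep_path)
        manifest["stages"]["forensic"] = {
            "retained": report.n_complete,
            "excluded": panel.n_samples - report.n_complete,
        }
        logger.info("forensic: retained %d / excluded %d",
                    report.n_complete, panel.n_samples - report.n_complete)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("forensic", str(exc)) from exc

    # -- comparison stages ------------------------------------------------
    pops = panel.populations()
    if len(pops) < 2:
        logger.info("single population: skipping Rst/MDS/NJ stages")
        manifest["stages"]["rst"] = {"skipped": "single population"}
    else:
        try:
            dm, details = pairwise_rst_matrix(
                panel,
                config.subset,
                include_multicopy=config.include_multicopy,
                permutations=config.permutations,
                seed=config.seed,
            )
            rst_path = config.outdir / "rst.phylip"
            rst_path.write_text(
                _io.write_distance_matrix(dm, precision=config.precision)
            )
            manifest["artifacts"]["rst"] = str(rst_path)
            first = next(iter(details.values()))
            retained = {pop: 0 for pop in pops}
            for (pa, pb), res in details.items():
                retained[pa] = res.n_per_pop[pa]
                retained[pb] = res.n_per_pop[pb]
            manifest["stages"]["rst"] = {
                "loci_used": first.loci_used,
                "retained_per_population": retained,
                "excluded_per_population": {
                    pop: len(panel.samples_for(pop)) - retained[pop] for pop in pops
                },
            }
            logger.info("rst: %d populations, %d loci",
                        len(pops), len(first.loci_used))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("rst", str(exc)) from exc

        try:
            mds = _ordination.classical_mds(dm, dims=min(config.mds_dims, len(pops) - 1))
            mds_path = config.outdir / "mds.tsv"
            mds_path.write_text(_format_mds(mds, config.precision))
            manifest["artifacts"]["mds"] = str(mds_path)
            manifest["stages"]["mds"] = {
                "dims": mds.coordinates.shape[1],
                "goodness": mds.goodness,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mds", str(exc)) from exc

        try:
            tree = _ordination.neighbor_joining(dm)
            tree_path = config.outdir / "nj_tree.nwk"
            tree_path.write_text(_io.write_newick(tree) + "\n")
            manifest["artifacts"]["tree"] = str(tree_path)
            manifest["stages"]["njtree"] = {"leaves": len(tree.leaves())}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("njtree", str(exc)) from exc

    manifest_path = config.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("wrote manifest %s", manifest_path)
    return manifest


def _format_mds(mds, precision: int) -> str:
    dims = mds.coordinates.shape[1]
    lines = ["population\t" + "\t".join(f"dim{i + 1}" for i in range(dims))]
    for label, row in zip(mds.labels, mds.coordinates):
        lines.append(label + "\t" + "\t".join(f"{v:.{precision}f}" for v in row))
    lines.append(
        "# eigenvalues\t" + "\t".join(f"{v:.{precision}f}" for v in mds.eigenvalues)
    )
    lines.append(f"# goodness\t{mds.goodness:.{precision}f}")
    return "\n".join(lines) + "\n"


def _package_version() -> str:
    try:
        return metadata.version("ystrpop")
    except metadata.PackageNotFoundError:
        return "unknown"
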