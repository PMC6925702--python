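"""End-to-end pipeline: structure → assembly → scoring → pathway → transport.

``run_pipeline`` executes the configured stages in order and writes a report
bundle (PDB assembly, TSV/JSON per stage, a transport summary table and a
plain-text log of every default in force). Reports contain no timestamps, so
two runs with the same config and seed produce byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import constraints as cst
from .assembly import (
    AssemblyModel,
    HelicalParams,
    align_to_axis,
    apply_helical_symmetry,
    measure_diameter,
)
from .pathway import (
    DEFAULT_CUTOFF,
    DEFAULT_SUBUNIT_P,
    build_graph,
    extract_symmetric_unit,
    shortest_path,
    write_pathway_report,
)
from .structure import read_pdb, write_pdb
from .synthetic import SyntheticSpec, make_pathway_pilus
from .transport import (
    TransportResult,
    read_transport_inputs,
    transport_report,
    write_transport_table,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("pilitransport")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and a remedy."""


_KNOWN_KEYS = {
    "input_mode",
    "input_pdb",
    "helical_params",
    "synthetic",
    "constraint_file",
    "pathway_cutoff",
    "subunit_p",
    "transport",
    "out_dir",
    "seed",
    "log_level",
}

_HELICAL_KEYS = {"rise", "rotation", "radius_to_com", "n_subunits", "right_handed"}
_SYNTHETIC_KEYS = {"distances", "rise", "rotation", "anchor_radius", "n_subunits", "noise_sigma"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``input_mode`` is either ``"synthetic"`` (planted-geometry pilus from the
    synthetic generator) or ``"pdb"`` (subunit read from ``input_pdb``,
    aligned to the axis and replicated with ``helical_params``).
    """

    input_mode: str = "synthetic"
    input_pdb: str | None = None
    helical_params: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] = field(default_factory=dict)
    constraint_file: str | None = None
    pathway_cutoff: float | None = DEFAULT_CUTOFF
    subunit_p: int = DEFAULT_SUBUNIT_P
    transport: dict[str, Any] | None = None
    out_dir: str = "pilitransport_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "pdb"):
            raise ValueError(f"input_mode must be 'synthetic' or 'pdb', got {self.input_mode!r}")
        if self.input_mode == "pdb" and not self.input_pdb:
            raise ValueError("input_mode 'pdb' requires input_pdb")
        if self.pathway_cutoff is not None and self.pathway_cutoff <= 0:
            raise ValueError(f"pathway_cutoff must be positive, got {self.pathway_cutoff}")
        if self.subunit_p < 1:
            raise ValueError("subunit_p must be >= 1")
        unknown = set(self.helical_params) - _HELICAL_KEYS
        if unknown:
            raise ValueError(f"unknown helical_params key(s): {sorted(unknown)}")
        unknown = set(self.synthetic) - _SYNTHETIC_KEYS
        if unknown:
            raise ValueError(f"unknown synthetic key(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yml", ".yaml"))
            else json.loads(text)
        )
        return cls.from_dict(data or {})


def _build_assembly(config: PipelineConfig) -> AssemblyModel:
    if config.input_mode == "synthetic":
        syn = dict(config.synthetic)
        if "distances" in syn:
            syn["distances"] = tuple(syn["distances"])
        spec = SyntheticSpec(seed=config.seed, **syn)
        logger.info("synthetic pilus: %s", spec)
        return make_pathway_pilus(spec)
    try:
        chains = read_pdb(config.input_pdb)
    except Exception as exc:
        raise PipelineError(
            f"stage 'structure' failed reading {config.input_pdb}: {exc}; "
            "check that the file is a valid PDB"
        ) from exc
    hp = dict(config.helical_params)
    params = HelicalParams(
        rise_per_subunit=hp.get("rise", 10.5),
        rotation_per_subunit=hp.get("rotation", 100.8),
        radius_to_com=hp.get("radius_to_com", 0.0),
        n_subunits=hp.get("n_subunits", 21),
        right_handed=hp.get("right_handed", True),
    )
    aligned = align_to_axis(chains[0], radius_to_com=params.radius_to_com)
    logger.info("helical parameters: %s", params)
    return apply_helical_symmetry(aligned, params)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages and write the report bundle.

    Returns the summary report as a dict (also written to
    ``out_dir/summary.json``). Stages without configuration (no constraint
    file, no transport block) are skipped with a logged warning; the run
    still succeeds with a geometry-only report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    summary: dict[str, Any] = {"seed": config.seed, "input_mode": config.input_mode}
    try:
        logger.info(
            "defaults in force: cutoff=%s Å, subunit_p=%d, seed=%d",
            config.pathway_cutoff,
            config.subunit_p,
            config.seed,
        )
        assembly = _build_assembly(config)
        write_pdb(assembly.subunits, out / "assembly.pdb")
        summary["n_subunits"] = assembly.n_subunits
        summary["diameter_A"] = measure_diameter(assembly)

        if config.constraint_file:
            try:
                constraints = cst.read_constraints(config.constraint_file)
                total, breakdown = cst.score_constraints(assembly, constraints)
            except Exception as exc:
                raise PipelineError(
                    f"stage 'constraint_scoring' failed: {exc}; "
                    "check selectors against the assembly chains"
                ) from exc
            summary["constraint_total"] = total
            summary["constraint_breakdown"] = breakdown
        else:
            logger.info("no constraint file: skipping constraint scoring")

        graph = build_graph(assembly, config.pathway_cutoff)
        source = graph.find(0, 1)
        target = graph.find(assembly.n_subunits - 1, 1)
        path, length = shortest_path(graph, source, target)
        if path is None:
            raise PipelineError(
                "stage 'pathway' failed: source and target rings are disconnected; "
                "increase pathway_cutoff"
            )
        unit = extract_symmetric_unit(path, config.subunit_p)
        write_pathway_report(path, unit, out / "pathway.tsv", out / "pathway.json")
        summary["pathway_length_A"] = length
        summary["pathway_residues"] = sorted({r.residue_seq for r in path})
        summary["unit_distances_A"] = list(unit.distances)
        summary["bottleneck_A"] = max(unit.distances)

        result: TransportResult | None = None
        if config.transport:
            inputs = read_transport_inputs(config.transport)
            result = transport_report(unit, inputs)
            (out / "transport.json").write_text(
                json.dumps(result.to_dict(), indent=2) + "\n"
            )
            write_transport_table(result, out / "transport.tsv")
            summary["transport"] = result.to_dict()
        else:
            logger.warning("no transport block: geometry-only report")

        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        logger.info("pipeline complete: %s", out / "summary.json")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
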