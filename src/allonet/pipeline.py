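"""End-to-end orchestration: structures in, centrality and delta tables out.

A run is described by a :class:`RunConfig` (YAML/JSON-serialisable), each
variant coming either from a structure file or from a synthetic-dimer
spec. The pipeline materialises every default into a JSON manifest so
that a finished run can be re-executed from its manifest alone and
reproduce every data file byte for byte: no timestamps or other
nondeterministic content ever enters a result file.

Output layout under the configured directory::

    <outdir>/<variant>/network.graphml
    <outdir>/<variant>/edges.tsv
    <outdir>/<variant>/profile.tsv
    <outdir>/compare_<ref>_vs_<alt>/delta.tsv
    <outdir>/compare_<ref>_vs_<alt>/extremes.tsv
    <outdir>/manifest.json
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import centrality as _centrality
from . import compare as _compare
from . import network as _network
from . import structure_io as _io
from . import synthetic as _synthetic

__all__ = [
    "PipelineError",
    "RunConfig",
    "run_variant",
    "run_comparison",
    "run_pipeline",
    "run_from_manifest",
]

logger = logging.getLogger("allonet")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the variant and stage that raised it."""

    def __init__(self, variant: str, stage: str, message: str):
        self.variant = variant
        self.stage = stage
        super().__init__(f"[{variant}/{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Fully materialised parameters of one analysis run.

    ``variants`` maps a label to either ``{"structure": path}`` (with the
    shared chain/model settings applied) or ``{"simulate": {...}}`` with
    :class:`allonet.synthetic.DimerSpec` fields. ``reference`` names the
    variant every other variant is compared against.
    """

    variants: dict[str, dict[str, Any]]
    outdir: str = "allonet_out"
    reference: str | None = None
    chains: tuple[str, str] = ("A", "B")
    model_index: int = 1
    threshold: float = _network.DEFAULT_THRESHOLD
    average: str = "mean"
    betweenness_scope: str = "dimer"
    top_n: int = 6
    numbering_offset: int = 0
    mutations: tuple[str, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["chains"] = list(self.chains)
        d["mutations"] = list(self.mutations)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        if "chains" in data:
            data["chains"] = tuple(data["chains"])
        if "mutations" in data:
            data["mutations"] = tuple(data["mutations"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dimer_spec(config: RunConfig, params: Mapping[str, Any]) -> _synthetic.DimerSpec:
    params = dict(params)
    pert = params.pop("perturbation", None)
    if isinstance(pert, Mapping):
        pert = _synthetic.Perturbation(**pert)
    params.setdefault("seed", config.seed)
    params.setdefault("threshold", config.threshold)
    return _synthetic.DimerSpec(perturbation=pert, **params)


def _load_variant_model(config: RunConfig, variant: str) -> tuple[_io.StructureModel, dict]:
    source = config.variants[variant]
    meta: dict[str, Any] = {}
    if "structure" in source:
        path = Path(source["structure"])
        if not path.exists():
            raise PipelineError(variant, "load", f"structure file not found: {path}")
        try:
            model = _io.load_structure(
                path,
                chain_ids=config.chains,
                model_index=config.model_index,
                source_label=f"{variant}: {path}",
            )
        except _io.StructureError as exc:
            raise PipelineError(variant, "load", str(exc)) from exc
        meta["structure"] = str(path)
        meta["structure_sha256"] = _sha256(path)
    elif "simulate" in source:
        try:
            spec = _dimer_spec(config, source["simulate"])
            model = _synthetic.generate_dimer(spec)
        except (ValueError, _synthetic.GenerationError) as exc:
            raise PipelineError(variant, "simulate", str(exc)) from exc
        meta["simulate"] = source["simulate"]
    else:
        raise PipelineError(
            variant, "load", "variant needs a 'structure' path or a 'simulate' spec"
        )
    if config.numbering_offset:
        model = _io.renumber(model, config.numbering_offset)
    return model, meta


def run_variant(config: RunConfig, variant: str) -> _centrality.CentralityProfile:
    """Load → contact network → centrality for one variant, writing the
    network export and profile TSV under ``<outdir>/<variant>/``."""
    if variant not in config.variants:
        raise PipelineError(variant, "config", "variant not present in config")
    t0 = time.perf_counter()
    model, _ = _load_variant_model(config, variant)
    outdir = Path(config.outdir) / variant
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        net = _network.build_contact_network(model, threshold=config.threshold)
        _network.write_graphml(net, outdir / "network.graphml")
        _network.write_edgelist_tsv(net, outdir / "edges.tsv")
    except ValueError as exc:
        raise PipelineError(variant, "network", str(exc)) from exc
    try:
        profile = _centrality.centrality_profile(
            net,
            variant_label=variant,
            scope=config.betweenness_scope,  # type: ignore[arg-type]
            average=config.average,  # type: ignore[arg-type]
        )
    except ValueError as exc:
        raise PipelineError(variant, "centrality", str(exc)) from exc
    profile.to_tsv(outdir / "profile.tsv")
    logger.info(
        "variant %s: %d nodes, %d edges, %.2fs",
        variant,
        net.n_nodes,
        net.n_edges,
        time.perf_counter() - t0,
    )
    return profile


def run_comparison(
    config: RunConfig, ref: str, alt: str
) -> _compare.VariantComparison:
    """Differential analysis between two already-computed variants.

    Reads the profile TSVs from the run directory (so the comparison sees
    exactly what was reported) and writes ``delta.tsv`` plus a
    human-readable ``extremes.tsv``.
    """
    base = Path(config.outdir)
    profiles = {}
    for label in (ref, alt):
        path = base / label / "profile.tsv"
        if not path.exists():
            raise PipelineError(label, "compare", f"profile not found: {path}")
        profiles[label] = _centrality.CentralityProfile.from_tsv(path, variant_label=label)
    try:
        cmp = _compare.delta_profiles(
            profiles[ref], profiles[alt], mutations=config.mutations
        )
    except ValueError as exc:
        raise PipelineError(f"{ref}_vs_{alt}", "compare", str(exc)) from exc

    outdir = base / f"compare_{ref}_vs_{alt}"
    outdir.mkdir(parents=True, exist_ok=True)
    frame = _compare.comparison_frame(cmp, n=config.top_n)
    frame.to_csv(outdir / "delta.tsv", sep="\t", index=False, float_format="%.12g")

    with open(outdir / "extremes.tsv", "w") as fh:
        fh.write(
            f"# positive delta = greater connectivity in reference ({ref}); "
            f"negative = greater in alternative ({alt})\n"
        )
        fh.write("measure\tend\trank\tposition\tresidue_name\tauthor_number\tdelta\n")
        for measure in ("beta", "rho"):
            top, bottom = _compare.rank_extremes(cmp, measure, n=config.top_n)
            for end, extremes in (("top", top), ("bottom", bottom)):
                for rank, e in enumerate(extremes, start=1):
                    fh.write(
                        f"{measure}\t{end}\t{rank}\t{e.position}\t{e.residue_name}"
                        f"\t{e.author_number}\t{e.delta:.12g}\n"
                    )
    return cmp


def _write_manifest(config: RunConfig, checksums: dict[str, dict]) -> Path:
    manifest = {
        "tool": "allonet",
        "config": config.to_dict(),
        "inputs": checksums,
    }
    path = Path(config.outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every variant and compare the reference against each other
    variant. Returns the profiles and comparisons keyed by label."""
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    profiles: dict[str, _centrality.CentralityProfile] = {}
    checksums: dict[str, dict] = {}
    for variant, source in config.variants.items():
        if "structure" in source:
            path = Path(source["structure"])
            checksums[variant] = {
                "structure": str(path),
                "structure_sha256": _sha256(path) if path.exists() else None,
            }
        else:
            checksums[variant] = {"simulate": source.get("simulate")}
        profiles[variant] = run_variant(config, variant)
    comparisons: dict[str, _compare.VariantComparison] = {}
    ref = config.reference
    if ref is None and len(config.variants) >= 2:
        ref = next(iter(config.variants))
    if ref is not None:
        if ref not in config.variants:
            raise PipelineError(ref, "config", "reference variant not in config")
        for alt in config.variants:
            if alt != ref:
                comparisons[f"{ref}_vs_{alt}"] = run_comparison(config, ref, alt)
    _write_manifest(config, checksums)
    return {"profiles": profiles, "comparisons": comparisons}


def run_from_manifest(manifest_path: str | Path, outdir: str | Path | None = None) -> dict[str, Any]:
    """Re-execute a run from its manifest; with the same inputs this
    reproduces every output file byte-identically."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    if outdir is not None:
        config = RunConfig.from_dict({**config.to_dict(), "outdir": str(outdir)})
    return run_pipeline(config)
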