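"""Pipeline orchestration and command-line interface.

Two main commands: ``build-blocks`` derives the hydrated-building-block
library from a corpus of structures, ``predict`` overlays a library
onto a target structure and optionally scores the prediction against
its crystallographic waters.  ``synth`` generates a synthetic corpus
and ``curate`` runs the chain-selection pipeline on a CSV table.

Exit codes: 0 success, 2 ran-but-empty result, 1 failure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from . import curation as curation_mod
from . import density as density_mod
from . import predict as predict_mod
from . import structure_io, synthetic
from .blocks import AssociationParams, BlockLibrary, build_block
from .density import DensityParams, hydration_sites
from .fragments import NANT, ClassifierTable, assign_ntc, extract_steps
from .predict import evaluate_prediction, predict_hydration
from .structure_io import (NoSymmetryError, StructureModel, expand_symmetry,
                           extract_waters, read_structure, write_density_map,
                           write_hydration_sites)

logger = logging.getLogger(__name__)

_PARAM_CLASSES = {"association": AssociationParams, "density": DensityParams}


@dataclasses.dataclass
class RunConfig:
    """Effective run parameters: module parameter records plus flags."""

    association: AssociationParams = dataclasses.field(default_factory=AssociationParams)
    density: DensityParams = dataclasses.field(default_factory=DensityParams)
    classifier_mode: str = "lookup"
    allow_unreliable: bool = False
    use_symmetry: bool = True
    model_number: int = 1

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        cfg = cls()
        if path is None:
            return cfg
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if key in _PARAM_CLASSES:
                valid = {f.name for f in dataclasses.fields(_PARAM_CLASSES[key])}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown {key} parameter(s): {sorted(bad)}")
                setattr(cfg, key, _PARAM_CLASSES[key](**value))
            else:
                setattr(cfg, key, value)
        logger.info("effective config: %s", cfg)
        return cfg


def build_library(models: list[StructureModel], classifier: ClassifierTable,
                  config: RunConfig | None = None,
                  references: dict | None = None) -> tuple[BlockLibrary, pd.DataFrame]:
    """Corpus -> hydrated-building-block library plus a combination summary.

    For every structure: extract steps, assign conformer labels,
    associate waters (including symmetry mates when cell data is
    present and symmetry is enabled); then group by (NtC, seq2) and
    build one block per populated combination.  ``references``
    optionally maps (ntc, seq2) to externally supplied class-
    representative coordinates; combinations without one use the
    medoid contributing step.  The summary lists n_steps, n_waters,
    waters per step and the reliability flag per combination.
    """
    config = config or RunConfig()
    grouped: dict[tuple[str, str], list] = {}
    n_steps_total = 0
    for model in models:
        try:
            expansion = (expand_symmetry(model, config.association.d_assoc)
                         if config.use_symmetry else None)
        except NoSymmetryError:
            logger.debug("%s: no crystal symmetry; using ASU waters only",
                         model.structure_id)
            expansion = None
        waters = extract_waters(model, expansion)
        for chain_id, residues in model.chains.items():
            for step in extract_steps(residues, structure_id=model.structure_id):
                step.ntc = assign_ntc(step, classifier, mode=config.classifier_mode)
                n_steps_total += 1
                if step.ntc == NANT:
                    continue
                assoc = blocks_mod.associate_waters(step, waters, config.association)
                grouped.setdefault((step.ntc, step.seq2), []).append((step, assoc))

    library = BlockLibrary(params=config.association,
                           provenance={"n_structures": len(models),
                                       "n_steps_total": n_steps_total})
    rows = []
    references = references or {}
    for (ntc, seq2), hydrated in sorted(grouped.items()):
        block = build_block(ntc, seq2, hydrated,
                            reference=references.get((ntc, seq2)),
                            params=config.association)
        library.add(block)
        rows.append({"ntc": ntc, "seq2": seq2, "n_steps": block.n_steps,
                     "n_waters": block.n_waters,
                     "waters_per_step": (block.n_waters / block.n_steps
                                         if block.n_steps else 0.0),
                     "reliable": block.reliable})
    summary = pd.DataFrame(rows, columns=["ntc", "seq2", "n_steps", "n_waters",
                                          "waters_per_step", "reliable"])
    return library, summary


def run_build_blocks(structure_paths: list[str], out_dir: str | Path,
                     classifier: ClassifierTable,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Read structures, build the block library and write it to disk."""
    config = config or RunConfig()
    if not structure_paths:
        raise ValueError("empty input structure list")
    models = [read_structure(p, model_number=config.model_number)
              for p in structure_paths]
    models = [m for m in models if m.chains]
    if not models:
        raise ValueError("no structure contains DNA residues")
    library, summary = build_library(models, classifier, config)
    out_dir = Path(out_dir)
    library.save(out_dir)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return summary


def run_predict(target_path: str | Path, library_dir: str | Path,
                out_dir: str | Path, classifier: ClassifierTable,
                config: RunConfig | None = None,
                evaluate: bool = False) -> predict_mod.PredictionResult:
    """Predict hydration for one structure and write all artifacts.

    Outputs: base/backbone CCP4 maps, a hydration-site PDB, a site TSV,
    a per-step log and (on request, when the target has waters) an
    evaluation JSON with the 0.5 A distance histogram.
    """
    config = config or RunConfig()
    library = BlockLibrary.load(library_dir)
    target = read_structure(target_path, model_number=config.model_number)
    result = predict_hydration(target, library, classifier,
                               classifier_mode=config.classifier_mode,
                               density_params=config.density,
                               assoc_params=config.association,
                               allow_unreliable=config.allow_unreliable)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.base_grid is not None:
        write_density_map(result.base_grid, out_dir / "base.ccp4")
    if result.backbone_grid is not None:
        write_density_map(result.backbone_grid, out_dir / "backbone.ccp4")
    write_hydration_sites(result.sites, out_dir / "sites.pdb")
    pd.DataFrame([{
        "x": s.position[0], "y": s.position[1], "z": s.position[2],
        "peak_value": s.peak_value, "occupancy": s.occupancy,
        "category": s.category, "n_support": s.n_support,
    } for s in result.sites]).to_csv(out_dir / "sites.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "structure_id": e.source[0], "chain_id": e.source[1],
        "residue_number": e.source[2], "ntc": e.ntc, "seq2": e.seq2,
        "used": e.used, "reason": e.reason,
    } for e in result.per_step_log]).to_csv(out_dir / "steps.tsv", sep="\t", index=False)

    if evaluate:
        if config.use_symmetry and target.cell is not None:
            try:
                expansion = expand_symmetry(target, config.association.d_assoc)
            except NoSymmetryError:
                expansion = None
        else:
            expansion = None
        observed = extract_waters(target, expansion)
        if observed:
            report = evaluate_prediction(result, observed)
            (out_dir / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=1))
            rows = [{"bin_lo": i * report.bin_width,
                     "bin_hi": (i + 1) * report.bin_width,
                     "count": int(c)}
                    for i, c in enumerate(report.histogram["overall"])]
            pd.DataFrame(rows).to_csv(out_dir / "histogram.tsv", sep="\t", index=False)
        else:
            logger.warning("target has no waters: evaluation skipped")
    return result


# ---------------------------------------------------------------------------
# CLI

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="DEBUG-level logging.")
def cli(verbose: bool) -> None:
    """Knowledge-based DNA hydration from dinucleotide building blocks."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


def _load_classifier(ntc_table: str | None, centroids: str | None) -> ClassifierTable:
    if ntc_table:
        return ClassifierTable.read_assignments(ntc_table)
    if centroids:
        return ClassifierTable.read_centroids(centroids)
    raise click.UsageError("provide --ntc-table or --centroids")


@cli.command("build-blocks")
@click.option("--structures", required=True,
              help="Text file listing one structure path per line.")
@click.option("--ntc-table", default=None, help="External NtC assignment TSV.")
@click.option("--centroids", default=None, help="Torsion-centroid TSV (nearest-centroid mode).")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--params", "params_path", default=None, type=click.Path(exists=True))
def cli_build_blocks(structures, ntc_table, centroids, out_dir, params_path):
    """Build the hydrated-building-block library from a structure corpus."""
    config = RunConfig.load(params_path)
    if centroids and not ntc_table:
        config.classifier_mode = "nearest-centroid"
    classifier = _load_classifier(ntc_table, centroids)
    paths = [l.strip() for l in Path(structures).read_text().splitlines() if l.strip()]
    try:
        summary = run_build_blocks(paths, out_dir, classifier, config)
    except ValueError as exc:
        raise click.ClickException(str(exc))
    click.echo(summary.to_string(index=False))
    sys.exit(0 if len(summary) else 2)


@cli.command("predict")
@click.option("--target", required=True, type=click.Path(exists=True))
@click.option("--library", "library_dir", required=True, type=click.Path(exists=True))
@click.option("--ntc-table", default=None)
@click.option("--centroids", default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--evaluate", is_flag=True)
@click.option("--no-symmetry", is_flag=True)
@click.option("--model", "model_number", default=1, type=int)
@click.option("--allow-unreliable", is_flag=True)
@click.option("--params", "params_path", default=None, type=click.Path(exists=True))
def cli_predict(target, library_dir, ntc_table, centroids, out_dir, evaluate,
                no_symmetry, model_number, allow_unreliable, params_path):
    """Predict hydration sites and density maps for a DNA structure."""
    config = RunConfig.load(params_path)
    config.use_symmetry = not no_symmetry
    config.model_number = model_number
    config.allow_unreliable = allow_unreliable
    if centroids and not ntc_table:
        config.classifier_mode = "nearest-centroid"
    classifier = _load_classifier(ntc_table, centroids)
    try:
        result = run_predict(target, library_dir, out_dir, classifier, config,
                             evaluate=evaluate)
    except (ValueError, FileNotFoundError) as exc:
        raise click.ClickException(str(exc))
    click.echo(f"{len(result.base_sites)} base + {len(result.backbone_sites)} "
               f"backbone sites predicted")
    sys.exit(0 if result.sites else 2)


@cli.command("synth")
@click.option("--seq2", default="GC")
@click.option("--form", default="B", type=click.Choice(["B", "A"]))
@click.option("--n-structures", default=100, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--noise", default=0.0, type=float, help="Atom coordinate noise sigma (A).")
@click.option("--out", "out_dir", required=True, type=click.Path())
def cli_synth(seq2, form, n_structures, seed, noise, out_dir):
    """Generate a synthetic corpus with planted hydration sites."""
    spec = synthetic.SyntheticSpec(n_structures=n_structures, seq2=seq2, form=form,
                                   coordinate_noise=noise, seed=seed)
    corpus = synthetic.make_corpus(spec)
    synthetic.write_corpus(corpus, out_dir)
    click.echo(f"wrote {n_structures} structures to {out_dir}")


@cli.command("curate")
@click.option("--table", required=True, type=click.Path(exists=True),
              help="Chain table CSV.")
@click.option("--out", required=True, type=click.Path())
def cli_curate(table, out):
    """Filter, cluster and select representative chains from a CSV table."""
    entries = curation_mod.read_chain_table(table)
    selected = curation_mod.curate(entries)
    curation_mod.write_chain_table(selected, out)
    click.echo(f"{len(selected)} representative chains of {len(entries)} input")
    sys.exit(0 if selected else 2)


if __name__ == "__main__":  # pragma: no cover
    cli()
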