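"""End-to-end orchestration: curate -> classify -> prevalence.

A run is described by a small YAML/dict config naming the inputs (fixture
tables, external TSVs, or a synthetic-table block), the rule system, and
the inclusion models to evaluate.  :func:`run_pipeline` executes the
stages in order, writes the labeled table and per-model JSON results, and
returns a :class:`RunManifest` with input digests and per-stage counts so
a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .acmg import CombinerConfig, concordance_report
from .curation import curate
from .model import BirthPrevalenceModel
from .prevalence import DEFAULT_CONVENTION, AlleleFrequencyConvention
from .records import read_variant_table, write_variant_table
from .simulate import SyntheticConfig, generate_table, make_fixtures

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    version: str
    config: dict
    input_digests: dict
    stage_counts: dict
    engine_system: str
    models: dict  # model id -> result dict
    outputs: dict
    seed: Optional[int] = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: dict, digests: dict, counts: dict, seed_out: dict):
    inputs = config.get("inputs", {})
    published, db = [], []
    if inputs.get("fixtures", False):
        published, unpublished = make_fixtures()
        db = list(unpublished)
        counts["n_published"] = len(published)
        counts["n_db"] = len(db)
        return published, db, True  # already curated
    if "published" in inputs:
        path = Path(inputs["published"])
        published = read_variant_table(path)
        digests[str(path)] = _digest(path)
        counts["n_published"] = len(published)
    if "db" in inputs:
        path = Path(inputs["db"])
        db = read_variant_table(path)
        digests[str(path)] = _digest(path)
        counts["n_db"] = len(db)
        return published, db, False
    if "unpublished" in inputs:
        path = Path(inputs["unpublished"])
        db = read_variant_table(path)
        digests[str(path)] = _digest(path)
        counts["n_db"] = len(db)
        return published, db, True
    if "synthetic" in inputs:
        params = dict(inputs["synthetic"])
        seed_out["seed"] = params.get("seed", 0)
        syn = SyntheticConfig(**params)
        db, _ = generate_table(syn)
        counts["n_db"] = len(db)
        return published, db, True
    return published, db, True


def run_pipeline(config) -> RunManifest:
    """Execute the pipeline described by ``config`` (dict or YAML path)."""
    if not isinstance(config, dict):
        config_path = Path(config)
        if not config_path.exists():
            raise PipelineError("config", f"{config_path} does not exist")
        config = yaml.safe_load(config_path.read_text())

    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    digests: dict = {}
    counts: dict = {}
    seed_out: dict = {}

    try:
        published, db, curated = _load_inputs(config, digests, counts, seed_out)
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc
    if not published and not db:
        raise PipelineError("load", "no inputs configured (fixtures/published/db/synthetic)")

    if not curated and published:
        db, report = curate(db, published)
        counts["n_duplicates_removed"] = report.n_duplicates_removed
        counts["n_overlap_excluded"] = report.n_overlap_excluded
        counts["n_remaining_unpublished"] = report.n_remaining_unpublished

    records = list(published) + list(db)
    system = config.get("engine", "points")
    engine_config = CombinerConfig(system=system)
    outputs: dict = {}

    labeled_any = any(rec.assigned_class is not None for rec in records)
    if labeled_any:
        try:
            report = concordance_report(
                [r for r in records if r.assigned_class is not None], engine_config
            )
            counts["n_engine_agree"] = report.n_agree
            counts["n_engine_labeled"] = report.n_total
            concordance_path = out_dir / "concordance.tsv"
            report.per_record.to_csv(concordance_path, sep="\t", index=False)
            outputs["concordance"] = str(concordance_path)
        except ValueError as exc:
            raise PipelineError("classify", str(exc)) from exc

    labeled_path = out_dir / "labeled.tsv"
    write_variant_table(records, labeled_path)
    outputs["labeled_table"] = str(labeled_path)

    convention = AlleleFrequencyConvention(**config.get("convention", {})) \
        if config.get("convention") else DEFAULT_CONVENTION
    use_engine_labels = bool(config.get("use_engine_labels", False))
    model_results: dict = {}
    for model_id in config.get("models", ["E"]):
        try:
            res = BirthPrevalenceModel(
                records, model=model_id, convention=convention,
                use_engine_labels=engine_config if use_engine_labels else False,
            ).fit()
        except ValueError as exc:
            raise PipelineError(f"prevalence:{model_id}", str(exc)) from exc
        model_results[model_id.upper()] = res.to_dict()
        result_path = out_dir / f"result_{model_id.upper()}.json"
        result_path.write_text(json.dumps(res.to_dict(), indent=2) + "\n")
        outputs[f"result_{model_id.upper()}"] = str(result_path)

    manifest = RunManifest(
        version=__version__,
        config=config,
        input_digests=digests,
        stage_counts=counts,
        engine_system=system,
        models=model_results,
        outputs=outputs,
        seed=seed_out.get("seed"),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
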