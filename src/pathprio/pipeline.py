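"""End-to-end pipeline: config validation, staged execution, run report.

The pipeline is a thin orchestration over the library: network build -> seed
resolution -> all-pairs path mining -> betweenness -> permutation p-values ->
selection -> optional reference-overlap test and functional-profile
similarity. All stage outputs are written as plain TSV/text so each stage can
be inspected like a supplementary file, and identical config + inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import DEFAULT_BACKGROUND
from .model import ShortestPathGeneModel
from .profiles import GOAnnotation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    Defaults follow the study conventions this method is built for:
    2000 permutations, alpha 0.05, a 20000-gene background for the overlap
    test, and no minimum confidence-score filter.
    """

    edges: str = ""
    seeds: str = ""
    mapping: str | None = None
    reference: str | None = None
    annotation: str | None = None
    out: str = "pathprio_out"
    min_score: int = 0
    cost_transform: str = "linear"  # 1000 - score
    n_perm: int = 2000
    alpha: float = 0.05
    rng_seed: int = 0
    background_n: int = DEFAULT_BACKGROUND
    sampling_universe: str = "network"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    if not config.edges:
        problems.append("edges: path is required")
    elif not Path(config.edges).exists():
        problems.append(f"edges: file not found: {config.edges}")
    if not config.seeds:
        problems.append("seeds: path is required")
    elif not Path(config.seeds).exists():
        problems.append(f"seeds: file not found: {config.seeds}")
    for name in ("mapping", "reference", "annotation"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: file not found: {p}")
    if config.min_score < 0 or config.min_score > 999:
        problems.append("min_score: must lie in [0, 999]")
    if config.cost_transform != "linear":
        problems.append(f"cost_transform: unknown transform {config.cost_transform!r}")
    if config.n_perm < 1:
        problems.append("n_perm: must be >= 1")
    if not (0.0 < config.alpha < 1.0):
        problems.append("alpha: must lie in (0, 1)")
    if config.background_n < 1:
        problems.append("background_n: must be positive")
    if config.sampling_universe not in ("network", "mapped"):
        problems.append("sampling_universe: must be 'network' or 'mapped'")
    return problems


@dataclass
class RunReport:
    """Structured record of a pipeline run."""

    config: dict
    config_digest: str
    version: str
    n_nodes: int = 0
    n_edges: int = 0
    n_seed_genes: int = 0
    n_seed_proteins: int = 0
    n_pairs: int = 0
    n_paths: int = 0
    n_skipped_pairs: int = 0
    n_path_genes: int = 0
    n_selected: int = 0
    selected: list[str] = field(default_factory=list)
    overlap: dict | None = None
    profile_similarity: float | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.out``."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("config", ValueError("; ".join(problems)))
    logger.info("run config digest=%s rng_seed=%d", config.digest(), config.rng_seed)

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    try:
        model = ShortestPathGeneModel.from_files(
            config.edges, config.seeds, config.mapping, min_score=config.min_score)
    except Exception as exc:  # noqa: BLE001 - stage labelling
        raise PipelineError("network", exc) from exc

    try:
        results = model.fit(
            n_perm=config.n_perm, alpha=config.alpha, seed=config.rng_seed,
            sampling_universe=config.sampling_universe)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("permutation", exc) from exc

    results.to_files(out)

    report = RunReport(
        config=asdict(config),
        config_digest=config.digest(),
        version=__version__,
        n_nodes=len(model.network),
        n_edges=model.network.n_edges,
        n_seed_genes=len(model.seed_genes),
        n_seed_proteins=len(model.seed_proteins),
        n_pairs=results.path_set.n_pairs,
        n_paths=results.n_paths,
        n_skipped_pairs=len(results.path_set.skipped_pairs),
        n_path_genes=results.n_path_genes,
        n_selected=len(results.selected),
        selected=list(results.selected),
    )

    if config.reference:
        try:
            reference = [
                ln.strip() for ln in Path(config.reference).read_text().splitlines()
                if ln.strip()
            ]
            ov = results.overlap_with_reference(reference, background=config.background_n)
            report.overlap = asdict(ov)
            if config.annotation:
                ann = GOAnnotation.read(config.annotation)
                report.profile_similarity = results.functional_similarity(reference, ann)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("evaluation", exc) from exc

    report.write(out / "report.yaml")
    return report
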