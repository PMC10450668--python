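"""End-to-end pipeline: load terminology, index, map, simulate, report.

The run manifest records the seed, a hash of the configuration, and the
record counts at every stage (cases in, correct diagnoses matched, user
diagnoses matched/unmatched), so a run is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as cio
from .evaluate import SimulationConfig, simulate
from .mapping import DEFAULT_PRIORITY, TagPriority, map_case
from .ontology import OntologyGraph, build_term_index, load_rf2, load_terminology_json
from .records import CaseRecord

__all__ = ["RunConfig", "run_pipeline", "demo_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; serialized into the output directory."""

    terminology: str  # path to a JSON terminology or an RF2 snapshot directory
    cases: str
    responses: str
    output_dir: str
    threshold: float = 1.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    priority: TagPriority = DEFAULT_PRIORITY

    def validate(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        for path in (self.terminology, self.cases, self.responses):
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "terminology": self.terminology,
                "cases": self.cases,
                "responses": self.responses,
                "threshold": self.threshold,
                "simulation": _jsonable(asdict(self.simulation)),
                "priority": list(self.priority.order),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_terminology(path: str | Path) -> OntologyGraph:
    """JSON file or RF2 snapshot directory (sct2_Concept/_Description/_Relationship)."""
    path = Path(path)
    if path.is_dir():
        def find(prefix: str) -> Path:
            hits = sorted(path.glob(f"{prefix}*"))
            if not hits:
                raise FileNotFoundError(f"no {prefix}* file in {path}")
            return hits[0]

        graph = load_rf2(find("sct2_Concept"), find("sct2_Description"),
                         find("sct2_Relationship"))
    else:
        graph = load_terminology_json(path)
    return build_term_index(graph)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute load -> index -> map -> simulate and write the output bundle.

    Writes mapped case/response tables, the accuracy table, and a JSON
    manifest into ``config.output_dir``; returns the accuracy table.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    graph = load_terminology(config.terminology)
    raw_cases = cio.read_case_tables(config.cases, config.responses)
    mapped = [
        map_case(c, graph, priority=config.priority, threshold=config.threshold)
        for c in raw_cases
    ]
    cio.write_mapped_tables(mapped, out / "mapped_cases.csv",
                            out / "mapped_responses.csv")

    results = simulate(mapped, graph, config.simulation)
    results.to_csv(out / "accuracy.csv", index=False)

    n_resp = sum(len(c.responses) for c in mapped)
    n_resp_matched = sum(
        1 for c in mapped for r in c.responses if r.concept_id is not None
    )
    manifest = {
        "seed": config.simulation.seed,
        "config_hash": config.digest(),
        "n_concepts": len(graph),
        "n_cases_in": len(mapped),
        "n_cases_correct_matched": sum(1 for c in mapped if not c.excluded),
        "n_cases_excluded": sum(1 for c in mapped if c.excluded),
        "n_cases_empty": sum(1 for c in mapped if c.empty),
        "n_user_diagnoses": n_resp,
        "n_user_diagnoses_matched": n_resp_matched,
        "n_user_diagnoses_unmatched": n_resp - n_resp_matched,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


def demo_inputs() -> tuple[OntologyGraph, list[CaseRecord]]:
    """The bundled sleep-apnea micro-fixture: terminology + one case.

    Three users give ranked differentials for an obstructive sleep apnea
    case; one diagnosis is unmatchable and two synonyms ("obstructive
    sleep apnea", "OSA—obstructive sleep apnea") must land on the same
    concept.
    """
    data = resources.files("crowddx.data")
    with resources.as_file(data.joinpath("demo_terminology.json")) as p:
        graph = build_term_index(load_terminology_json(p))
    with resources.as_file(data.joinpath("demo_cases.csv")) as cp, \
         resources.as_file(data.joinpath("demo_responses.csv")) as rp:
        cases = cio.read_case_tables(cp, rp)
    return graph, cases
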