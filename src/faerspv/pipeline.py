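"""End-to-end orchestration: load -> dedup -> screen -> statistics -> reports.

``run_analysis`` drives a full run from a config: it loads a quarterly
corpus, screens drug-event cases, computes the four disproportionality
statistics per drug set (plus the pooled class), optionally repeats the
scan after excluding co-medicated cases (the statin sensitivity
analysis), and writes the descriptive tables and a screening-funnel
JSON. The analysis path is deterministic — all randomness lives in the
synthetic-corpus generator.

The co-medication sensitivity scan removes excluded cases from the
exposure arm only: the a and b cells shrink while the comparator cells
c and d keep their main-analysis values, and each table's N is the sum
of its own four cells.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import descriptive
from .dictionary import DrugDictionary, load_ssri_dictionary, load_statin_dictionary
from .disproportionality import (
    ContingencyTable,
    SignalResult,
    contingency_from_counts,
    round_half_up,
    scan,
    signal_from_margins,
    signal_from_table,
)
from .faers_io import Corpus, load_corpus, write_signal_table
from .screening import ScreenedCohort, build_cohort, exclude_comedicated

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_analysis", "run_margins_only", "sensitivity_scan"]

BUILTIN = "builtin"


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    event_term: str = "Rhabdomyolysis"
    target_dict: str | Path = BUILTIN  # "builtin" -> bundled SSRI dictionary
    comed_dict: str | Path | None = None  # "builtin" -> bundled statins; None -> no sensitivity run
    class_label: str = "SSRIs"
    rounding: int = 2
    top_k_countries: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def validate(self) -> None:
        if not str(self.event_term).strip():
            raise ValueError("event_term must be non-empty")
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")
        for label, p in (("target_dict", self.target_dict), ("comed_dict", self.comed_dict)):
            if p is not None and p != BUILTIN and not Path(p).is_file():
                raise FileNotFoundError(f"{label} file not found: {p}")


@dataclass
class RunReport:
    funnel: dict[str, int]
    results: list[SignalResult]
    sensitivity_results: list[SignalResult] | None
    outputs: dict[str, Path] = field(default_factory=dict)


def _load_dict(spec: str | Path) -> DrugDictionary:
    return load_ssri_dictionary() if spec == BUILTIN else DrugDictionary.from_file(spec)


def sensitivity_scan(
    cohort: ScreenedCohort, corpus: Corpus, comed_dict: DrugDictionary, class_label: str
) -> tuple[list[SignalResult], int]:
    """Re-scan after removing co-medicated cases from the exposure arm.

    Returns the results and the number of exposure-arm cases removed.
    """
    event_total = len(cohort.event_case_ids)
    n = cohort.n_total

    def arm_table(ids: set[int], removed: set[int]) -> ContingencyTable:
        kept = ids - removed
        a = len(kept & cohort.event_case_ids)
        b = len(kept) - a
        c = event_total - len(ids & cohort.event_case_ids)
        d = n - len(ids) - c
        return ContingencyTable(a, b, c, d)

    pooled = cohort.pooled_drug_case_ids
    _, removed = exclude_comedicated(pooled, corpus.drug, comed_dict)
    results = [signal_from_table(arm_table(pooled, removed), name=class_label)]
    order = sorted(cohort.drug_case_ids,
                   key=lambda d: (-len(cohort.drug_event_case_ids[d]), d))
    for drug in order:
        results.append(signal_from_table(arm_table(cohort.drug_case_ids[drug], removed), name=drug))
    return results, len(removed & pooled)


def run_analysis(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and write all output tables."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    target_dict = _load_dict(cfg.target_dict)

    corpus = load_corpus(cfg.input_dir)
    cohort = build_cohort(corpus, target_dict, cfg.event_term)
    results = scan(cohort, class_label=cfg.class_label)

    outputs: dict[str, Path] = {}
    outputs["signal_table"] = out / "signal_table.csv"
    write_signal_table(results, outputs["signal_table"], ndigits=cfg.rounding)

    funnel = cohort.funnel()
    funnel["skipped_rows"] = sum(corpus.skipped_rows.values())
    funnel["orphan_rows_dropped"] = sum(corpus.orphans_dropped.values())

    sensitivity = None
    if cfg.comed_dict is not None:
        comed = load_statin_dictionary() if cfg.comed_dict == BUILTIN else DrugDictionary.from_file(cfg.comed_dict)
        sensitivity, n_removed = sensitivity_scan(cohort, corpus, comed, cfg.class_label)
        funnel["comedicated_removed"] = n_removed
        outputs["signal_table_sensitivity"] = out / "signal_table_comed_excluded.csv"
        write_signal_table(sensitivity, outputs["signal_table_sensitivity"], ndigits=cfg.rounding)

    demo = descriptive.demographics_table(cohort, top_k=cfg.top_k_countries)
    outputs["demographics"] = out / "demographics.csv"
    descriptive.demographics_to_frame(demo).to_csv(outputs["demographics"], index=False)

    tto = descriptive.time_to_onset(cohort, corpus, target_dict)
    outputs["time_to_onset"] = out / "time_to_onset.csv"
    tto.to_frame().to_csv(outputs["time_to_onset"], index=False)
    funnel["tto_evaluable"] = tto.overall.n_evaluable

    outc = descriptive.outcome_summary(cohort, corpus.outc)
    outputs["outcomes"] = out / "outcomes.csv"
    outc.to_frame().to_csv(outputs["outcomes"], index=False)

    outputs["funnel"] = out / "funnel.json"
    outputs["funnel"].write_text(json.dumps(funnel, indent=2, sort_keys=True) + "\n")
    logger.info("screening funnel: %s", funnel)
    return RunReport(funnel=funnel, results=results, sensitivity_results=sensitivity, outputs=outputs)


def run_margins_only(a: int, drug_total: int, event_total: int, n: int,
                     rounding: int = 2, name: str = "drug set") -> SignalResult:
    """One signal row straight from four margins — no corpus required."""
    result = signal_from_margins(a, drug_total, event_total, n, name=name)
    return result


def format_margins_row(result: SignalResult, rounding: int = 2) -> str:
    row = result.display_row(rounding)
    return "  ".join(f"{k}: {v}" for k, v in row.items())
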