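"""End-to-end screening pipeline with bit-stable text outputs.

Stages (mirroring routine spontaneous-report practice): obtain a quarterly
extract (synthetic or on disk), read and join the four tables, deduplicate
to the latest case version, normalize drug names, attach SOCs, filter the
cohort to primary-suspect reports of the target drug, then write the stage
log, cohort summary, SOC-level and top-N PT-level signal tables, and the
full signal list. Identical config + seed produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from . import descriptives, ingest, stats, synthetic

MODE_SYNTHETIC = "synthetic"
MODE_FAERS_DIR = "faers-dir"

DEFAULT_DRUG_VOCAB = (
    "MONTELUKAST",
    "ASPIRIN",
    "IBUPROFEN",
    "PARACETAMOL",
    "OMEPRAZOLE",
    "ATORVASTATIN",
    "METFORMIN",
    "SALBUTAMOL",
    "FLUTICASONE",
    "CETIRIZINE",
)


def default_event_vocab() -> tuple[tuple[str, str], ...]:
    """(PT, SOC) pairs of the shipped toy vocabulary."""
    pt_soc = ingest.load_toy_pt_soc_map()
    return tuple((pt, soc) for pt, (_, soc, _) in sorted(pt_soc.entries.items()))


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = MODE_SYNTHETIC
    drug: str = "MONTELUKAST"
    seed: int = 0
    output_dir: str = "pvsignal_out"
    # synthetic-mode generator settings
    n_reports: int = 20000
    planted_signals: tuple[tuple[str, str, float], ...] = (
        ("MONTELUKAST", "Nightmare", 6.0),
    )
    baseline_event_prob: float = 0.02
    drug_exposure_prob: float = 0.15
    duplicate_rate: float = 0.05
    # faers-dir mode
    faers_dir: Optional[str] = None
    # vocabularies (None -> shipped toy files)
    pt_soc_map_path: Optional[str] = None
    drug_dictionary_path: Optional[str] = None
    # screening
    thresholds: stats.SignalThresholds = field(default_factory=stats.SignalThresholds)
    rank_by: str = "ror"
    top_n: int = 50

    def validate(self) -> None:
        if self.mode not in (MODE_SYNTHETIC, MODE_FAERS_DIR):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.mode == MODE_FAERS_DIR and not self.faers_dir:
            raise ValueError("faers-dir mode needs faers_dir")
        if self.mode == MODE_SYNTHETIC and self.faers_dir:
            raise ValueError("exactly one input mode: drop faers_dir in synthetic mode")
        if self.rank_by not in ("ror", "cases"):
            raise ValueError("rank_by must be 'ror' or 'cases'")
        if self.top_n <= 0:
            raise ValueError("top_n must be positive")
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        if "thresholds" in raw:
            raw["thresholds"] = stats.SignalThresholds(**raw["thresholds"])
        if "planted_signals" in raw:
            raw["planted_signals"] = tuple(
                (str(d), str(p), float(m)) for d, p, m in raw["planted_signals"]
            )
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_quarter(config: PipelineConfig, directory) -> dict[str, str]:
    """Generate the configured synthetic report set (duplicates included)
    and write it as a FAERS-style quarter."""
    gen = synthetic.GeneratorConfig(
        n_reports=config.n_reports,
        drug_vocab=DEFAULT_DRUG_VOCAB,
        event_vocab=default_event_vocab(),
        baseline_event_prob=config.baseline_event_prob,
        planted_signals=config.planted_signals,
        drug_exposure_prob=config.drug_exposure_prob,
        duplicate_rate=config.duplicate_rate,
        seed=config.seed,
    )
    reports = synthetic.generate_reports(gen)
    reports = synthetic.inject_duplicates(
        reports, config.duplicate_rate, seed=config.seed + 1
    )
    return synthetic.write_faers_quarter(reports, directory)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage and write the output files; returns name -> path."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == MODE_SYNTHETIC:
        quarter_dir = out_dir / "faers_quarter"
        simulate_quarter(config, quarter_dir)
    else:
        quarter_dir = Path(config.faers_dir)

    log = ingest.CleaningLog()
    raw = ingest.read_faers_quarter(quarter_dir, log)
    n_raw = len(raw)
    dictionary = ingest.load_drug_dictionary(config.drug_dictionary_path)
    pt_soc = (
        ingest.load_toy_pt_soc_map()
        if config.pt_soc_map_path is None
        else ingest.PtSocMap.from_tsv(config.pt_soc_map_path)
    )
    universe = ingest.clean_universe(raw, dictionary, pt_soc, log)
    cohort = ingest.filter_primary_suspect(universe, config.drug)
    if not cohort:
        raise ValueError(f"no primary-suspect reports for {config.drug!r}")

    import pandas as pd

    stage_counts = pd.DataFrame(
        [
            ("raw case versions", n_raw),
            ("deduplicated reports (universe)", len(universe)),
            (f"{config.drug} primary-suspect reports", len(cohort)),
        ],
        columns=["stage", "count"],
    )

    summary = descriptives.summarize_cohort(cohort)
    trend = descriptives.annual_trend(cohort)
    results = stats.screen(
        universe, config.drug, rank_by=config.rank_by, thresholds=config.thresholds
    )
    full = stats.screen_frame(results)
    soc_results = [r for r in results if r.table.level == "SOC"]
    soc_results.sort(key=lambda r: (-r.table.a, r.table.event))
    soc_table = stats.format_signal_table(soc_results)
    pt_table = stats.format_signal_table(results, level="PT", top_n=config.top_n)

    trend_df = pd.DataFrame(
        sorted(trend.counts.items()), columns=["year", "count"]
    )

    outputs = {
        "stage_counts": stage_counts,
        "cleaning_counters": log.to_frame(),
        "cohort_summary": summary.to_frame(),
        "annual_trend": trend_df,
        "signals_soc": soc_table,
        "signals_pt_top": pt_table,
        "signals_all": full,
    }
    paths = {}
    for name, df in outputs.items():
        path = out_dir / f"{name}.tsv"
        _write_tsv(df, path)
        paths[name] = str(path)
    return paths
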