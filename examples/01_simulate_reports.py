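"""Simulate a FAERS-like report stream and write it as a quarterly extract.

Builds a 5,000-report synthetic stream in which montelukast carries a
planted nightmare signal (4x the baseline reporting rate), injects 10%
duplicate case versions, and writes the four "$"-delimited quarterly tables.
"""

import tempfile
from pathlib import Path

import pvsignal as pv
from pvsignal.pipeline import DEFAULT_DRUG_VOCAB, default_event_vocab

config = pv.GeneratorConfig(
    n_reports=5000,
    drug_vocab=DEFAULT_DRUG_VOCAB,
    event_vocab=default_event_vocab(),
    baseline_event_prob=0.02,
    planted_signals=(("MONTELUKAST", "Nightmare", 4.0),),
    drug_exposure_prob=0.15,
    seed=1,
)
reports = pv.generate_reports(config)
reports = pv.inject_duplicates(reports, 0.10, seed=2)

out = Path(tempfile.mkdtemp()) / "quarter"
paths = pv.write_faers_quarter(reports, out)

print(f"case versions written: {len(reports)} "
      f"({sum(not r.is_latest_version for r in reports)} superseded by a duplicate)")
first = reports[0]
print(f"example case {first.case_id}: drugs={first.drug_entries} "
      f"events={first.event_entries} outcomes={first.outcome_codes}")
for name, path in sorted(paths.items()):
    n_rows = len(Path(path).read_text().splitlines()) - 1
    print(f"{name}: {n_rows} rows -> {path}")
# The DEMO row count equals the number of case versions; DRUG/REAC/OUTC
# fan out one row per drug, reaction and outcome code respectively.
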