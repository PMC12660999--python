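"""Shared locations and config for the analysis drivers.

Raw matrices live under scratch/ (regenerated on demand, not tracked);
summary tables land under results/tables/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis_run"
TABLES = ROOT / "results" / "tables"
SEED = 1


def ensure_dirs() -> None:
    RUN.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
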