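"""Shared setup for the analysis drivers: one simulated study, fixed seed.

Each driver calls :func:`get_sc_dataset` (deterministic regeneration, so
drivers can run independently) and writes its tables under ``results/``.
Bulky raw simulation output belongs in ``scratch/``.
"""

from __future__ import annotations

from pathlib import Path

from ntcmetab import ScSimConfig, generate_sc_dataset, log_normalize, qc_filter

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_sc_dataset():
    return generate_sc_dataset(ScSimConfig(seed=SEED))


def qc_and_normalize(matrix, annot):
    filtered, kept_annot, report = qc_filter(matrix, annot)
    return log_normalize(filtered), kept_annot, report
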