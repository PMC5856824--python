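"""Shared configuration for the numbered analysis scripts.

Desk-scale study conditions: 20 subjects per group (healthy, tinnitus,
pain, Parkinson, depression), 60 s records at 128 Hz, default generator
parameters, master seed 7. Every script regenerates the cohort
deterministically from the seed, so they can run independently and in any
order; tables land under results/.
"""

from pathlib import Path

from tcd.synth import GeneratorParams, generate_cohort

MASTER_SEED = 7
PARAMS = GeneratorParams(duration_s=60.0)
COUNTS = {g: 20 for g in ("healthy", "tinnitus", "pain", "parkinson", "depression")}
RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_cohort():
    RESULTS.mkdir(exist_ok=True)
    return generate_cohort(COUNTS, PARAMS, MASTER_SEED)
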