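"""Shared study configuration and output locations for the analysis scripts."""

from pathlib import Path

from epinet.synthetic_data import SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTH_DIR = RESULTS / "synthetic"

#: The study conditions: six cell types in two stages, 35% cell-type-
#: specific enhancers, and a 3x case-variant enrichment planted in C3.
STUDY_CONFIG = SyntheticConfig(seed=7, planted_substructure="C3", planted_odds=3.0)
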