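"""The six-cell-type neural differentiation design.

Three progenitor-stage cell types (embryonic stem cells, neural stem
cells, neural progenitor cells) and three mature neuron types
(GABAergic/inhibitory AD, glutamatergic/excitatory Ngn2, motor neurons).
"""

PROGENITOR = ("ESC", "NSC", "NPC")
MATURE = ("AD", "Ngn2", "Motor")
CELL_TYPES = PROGENITOR + MATURE

STAGE_OF = {ct: "progenitor" for ct in PROGENITOR} | {ct: "mature" for ct in MATURE}


def validate_stage_map(cell_types, stage_map) -> None:
    """Require exactly 3 progenitor and 3 mature cell types."""
    stages = [stage_map[ct] for ct in cell_types]
    if len(cell_types) != 6:
        raise ValueError(f"expected 6 cell types, got {len(cell_types)}")
    if stages.count("progenitor") != 3 or stages.count("mature") != 3:
        raise ValueError("need exactly 3 progenitor and 3 mature cell types")
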