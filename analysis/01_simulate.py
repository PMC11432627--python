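"""Generate the synthetic six-cell-type study and write all input files.

Emulates the study design: six neural cell types (3 progenitor, 3
mature), 35% cell-type-specific enhancers, stage-shared and ubiquitous
sharing, TF binding with planted stage bias, case/control variant sets
with a 3x case enrichment planted in C3 elements, expression tables and
a disease gene list.  Writes everything under results/synthetic/.
"""

from pathlib import Path

from epinet.network_builder import EPINetwork, substructure_elements
from common import STUDY_CONFIG, SYNTH_DIR

from epinet.synthetic_data import (
    generate_epi_tables,
    generate_expression_and_genesets,
    generate_genome,
    generate_tfbs_table,
    generate_variant_sets,
    write_dataset,
)

OUT = SYNTH_DIR


def main() -> None:
    cfg = STUDY_CONFIG
    genome = generate_genome(cfg)
    dataset = generate_epi_tables(cfg, genome)
    fimo = generate_tfbs_table(cfg, dataset)
    bundle = generate_expression_and_genesets(cfg, dataset)
    nets = [EPINetwork(t, ct) for ct, t in dataset.epi_tables.items()]
    elements = substructure_elements(nets)
    case, control = generate_variant_sets(cfg, dataset, elements)
    write_dataset(dataset, OUT, bundle=bundle, fimo=fimo, case=case, control=control)
    n_epis = sum(len(t) for t in dataset.epi_tables.values())
    print(f"genome: {len(genome)} chromosomes x {genome['length'].iloc[0]:,} bp")
    print(f"enhancer archetypes: {len(dataset.enhancers)} "
          f"({dict(dataset.enhancers['sharing_class'].value_counts())})")
    print(f"EPIs: {n_epis} across {len(nets)} cell types")
    print(f"TFBS rows: {len(fimo)}; variants: {len(case)} case / {len(control)} control")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
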