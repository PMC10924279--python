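"""Build founder sequences from a small phased panel.

Generates a 20 kb synthetic reference and a 32-haplotype phased panel,
segments the panel under a founder budget of F=4 (which counts the
reference itself, so at most 3 panel founders) with minimum segment
length L=2 sites, chains segment strings into founders, and prints the
segmentation and recombination summary.
"""

from panproject.fixtures import SimulationConfig, make_panel, make_reference
from panproject.founders import (
    founders_to_msa,
    minimum_segmentation,
    reconstruct_founders,
)

cfg = SimulationConfig(seed=42, ref_length=20_000)
reference = make_reference(cfg)
fixture = make_panel(cfg, reference)
panel = fixture.panel
print(f"panel: {panel.n_haplotypes} haplotypes x {panel.n_sites} variant sites")

seg = minimum_segmentation(panel, F=4, L=2)
print(f"greedy segmentation: {len(seg.segments)} segments "
      f"(capacity {seg.F - 1} strings each, min length {seg.L} sites)")

fs = reconstruct_founders(seg)
print(f"founders: {fs.n_founders}, recombination count: {fs.recombination_count}")
# the recombination count is the number of founder segment junctions never
# observed together in a single panel haplotype -- lower is more realistic

msa = founders_to_msa(fs, panel, reference)
print(f"reference-guided MSA: {len(msa.rows)} rows x {msa.n_columns} columns")
for name in msa.founder_names():
    diffs = sum(
        a != b for a, b in zip(msa.rows[name], msa.rows[msa.reference_name])
    )
    print(f"  {name}: {diffs} columns differ from the reference row")
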