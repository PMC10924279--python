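"""Reference-bias evaluation on a synthetic diploid at truth placements.

Simulates a 100 kb diploid donor held out of a phased panel, draws 40x of
100 bp reads equally from both haplotypes (0.2% substitution errors),
places them at their true reference positions, and measures the per-site
allele balance R/(R+A) at the donor's heterozygous sites together with
the mean absolute error from the unbiased value 0.5.
"""

from panproject.evaluation import (
    group_by_length_diff,
    mean_absolute_error,
    pileup_balance,
)
from panproject.fixtures import (
    SimulationConfig,
    make_panel,
    make_reference,
    oracle_align,
    simulate_reads,
)

cfg = SimulationConfig(seed=1)  # 100 kb, 40x, snp 1e-3, indel 1e-4
reference = make_reference(cfg)
fixture = make_panel(cfg, reference)
read_set = simulate_reads(cfg, fixture)
records = oracle_align(read_set, fixture)
print(f"{len(records)} reads placed at truth over "
      f"{len(fixture.donor_het_sites)} donor het sites")

table = pileup_balance(records, fixture.donor_het_sites, min_coverage=20)
print(f"{len(table)} sites pass the enclosure + coverage filters")
print(f"mean balance {table['balance'].mean():.4f}  "
      f"(0.5 = unbiased; truth placement carries no reference bias)")
print(f"overall MAE  {mean_absolute_error(table['balance']):.4f}")

print("\nby allele length difference (alt - ref):")
print(group_by_length_diff(table).to_string(index=False))
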