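"""Cost ledger aggregation and the deterministic ICER.

Loads the packaged intervention cost ledger, averages it over the 227
intervention children retained through the final assessment, and divides
the per-child incremental cost by the incremental cognitive composite
score (16.11 units) to get the base-case ICER.
"""

import nutricea as nc

items = nc.load_ledger(nc.packaged_ledger_path())
print(f"{len(items)} ledger items across categories: {', '.join(nc.CATEGORIES)}")

# the reported grand total ($60,335) is one dollar below the sum of the
# category subtotals ($60,336, a rounding artefact); pin it explicitly
summary = nc.summarize_costs(items, n_children=227, total_override=60335)
print(f"total intervention cost: ${summary.total:,.0f}")
print(f"incremental cost per child (ΔC): ${summary.per_child_total:.2f}")
for cat, share in summary.category_shares.items():
    per_child = summary.per_child_by_category[cat]
    print(f"  {cat:<18} ${per_child:>7.2f} per child  ({share:.0%})")

result = nc.icer(summary.per_child_total, 16.11)
print(
    f"ICER = ΔC/ΔE = {summary.per_child_total:.2f}/16.11 "
    f"= ${result.icer:.2f} per cognitive composite score unit "
    f"(quadrant {result.quadrant.value})"
)
# Paying less than ~$16.50 per score unit gained would make the
# intervention not worth funding; above it, cost-effective.
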