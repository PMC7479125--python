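"""Hub selection and rich-club / feeder / local edge classification.

Selects the top-16% (7 of 45) highest-degree regions of a hemispheric
network as hubs, classifies every edge by its endpoints, and reports the
per-class connectivity density and strength.
"""

from hemirc import (
    CohortSpec,
    apply_fn_threshold,
    class_density,
    class_strength,
    classify_edges,
    default_node_table,
    generate_base_connectome,
    select_hubs,
    split_hemispheres,
)

fa, fn = generate_base_connectome(CohortSpec(seed=1))
left = split_hemispheres(apply_fn_threshold(fa, fn), default_node_table()).left

hubs = select_hubs(left, fraction=0.16)
cls = classify_edges(left, hubs)

print(f"hubs ({len(hubs.hub_ids)}): {', '.join(hubs.hub_ids)}")
print(f"peripheral regions: {len(hubs.peripheral_ids)}")
print()
print("class       edges  density   strength")
for label in ("rich_club", "feeder", "local"):
    print(
        f"{label:<10s} {cls.counts()[label]:>6d}  {class_density(left, cls, label):.4f}"
        f"    {class_strength(left, cls, label):8.2f}"
    )
# Density is the class's share of all 990 possible hemispheric edges;
# strength is the summed FA over the class's edges. The three classes
# partition the edge set, so both columns add up to whole-network totals.
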