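"""The generic result model: typed attributes on sequence subregions.

One sequence can carry observations from several annotation strategies at
once (taxonomy, protein family, GC content); distributions are precomputed
incrementally, and hierarchical queries roll counts up the tree.
"""

from taxbench.results import CONTINUOUS, DISCRETE, FLAT, HIERARCHICAL, ObservationStore

store = ObservationStore(label="demo metagenome")

store.register_type("taxonomy", HIERARCHICAL, DISCRETE)
store.register_type("COG", FLAT, DISCRETE)
store.register_type("GC_content", FLAT, CONTINUOUS)

root = store.add_attribute("taxonomy", "Bacteria")
psychro = store.add_attribute("taxonomy", "Psychrobacter", parent=root)
cryo = store.add_attribute("taxonomy", "Psychrobacter cryohalolentis", parent=psychro)
bacillus = store.add_attribute("taxonomy", "Bacillus", parent=root)

# one read annotated by three independent methods
store.add_observation("read_0001", 0, 250, cryo)
store.add_observation("read_0001", 40, 190, store.add_attribute("COG", "COG1877"))
store.add_observation("read_0001", 0, 250, store.add_attribute("GC_content", 0.42))
# more taxonomy calls
store.add_observation("read_0002", 0, 180, psychro)
store.add_observation("read_0003", 0, 220, bacillus)
store.add_observation("read_0004", 0, 150, cryo)

print("direct taxonomy counts: ", store.distribution("taxonomy"))
print("rolled-up counts:       ", store.distribution("taxonomy", hierarchical_rollup=True))
print()
print("reads under genus Psychrobacter (includes species-level calls):",
      store.export_subset({"taxonomy": "Psychrobacter"}))
print("reads with that genus AND a trehalose-phosphatase COG hit:     ",
      store.export_subset({"taxonomy": "Psychrobacter", "COG": "COG1877"}))
print()
print("The rollup gives Psychrobacter 3 = its direct call plus two")
print("species-level observations; the conjunction narrows to read_0001.")
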