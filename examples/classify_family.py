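"""Classify a synthetic phytocyanin family and tabulate the census.

Builds the default 62-protein fixture (the rice family cell counts), runs
the sequence-only classifier (domain located by alignment, SP/GAS from
heuristics, glycomodule scan for the AGP-like region) and prints the
subfamily x architecture-type table.
"""

from phytocyanin import classify_family, gen_family_fixture, summarize_types

proteins, truth = gen_family_fixture(seed=1)
assignments = classify_family(proteins)

print(summarize_types(assignments))
print()
chimeric = sum(a.chimeric_agp for a in assignments)
gpi = sum(a.arch_type in ("I", "III") for a in assignments)
print(f"{len(assignments)} phytocyanins: {chimeric} chimeric AGPs (types I+II), "
      f"{gpi} GPI-anchored (types I+III).")
print("Types I/II carry AG glycomodules on a secreted backbone, so they are")
print("predicted substrates for arabinogalactosylation (chimeric AGPs).")
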