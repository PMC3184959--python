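"""qRT-PCR relative quantification via per-gene standard curves.

Fits Ct vs log10(template) on the 3-fold dilution series (amounts
10..2430), converts sample Cts to quantities and normalises by the
geometric mean of four housekeeping reference genes.
"""

from phytocyanin import (
    fit_standard_curves,
    gen_expression_data,
    qpcr_relative_expression,
)
from phytocyanin.simulate import ExprSpec

*_, plate, truth = gen_expression_data(ExprSpec(seed=5))

curves = fit_standard_curves(plate)
c = curves["g001"]
print(f"standard curve for g001: slope {c.slope:.4f}, r^2 {c.r_squared:.4f}")
print("(slope -3.32 per log10 template = 100% amplification efficiency)")

rel = qpcr_relative_expression(plate, ["ref1", "ref2", "ref3", "ref4"], curves)
print(rel.round(3).to_string(index=False))
print("'mean' is the expression level relative to the geometric mean of the")
print("four reference genes, averaged over biological replicates (+/- sd).")
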