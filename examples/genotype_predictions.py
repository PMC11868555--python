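"""Predict ON/OFF phenotypes of the genotype panel in sugar mixtures.

Each genotype maps to a deterministic parameter change (isomaltase
deletions scale u_I,max; MAL11 over-expression raises b_T; gal80
deletion pins K_T at its galactose-elevated value).  "on" means the
regulon reaches p/K_T > 1 from the uninduced state, i.e. the strain uses
palatinose immediately — no diauxie.
"""

from maldiauxie import DEFAULT_PARAMS, predict_scenarios

table = predict_scenarios(DEFAULT_PARAMS)
print(table[["genotype", "galactose", "label", "attained", "on", "runaway"]].to_string(index=False))
print(
    "\nReading: WT shows diauxie (+galactose OFF, -galactose ON); deleting "
    "IMA1 or over-expressing MAL11 abolishes it; gal80 deletion keeps the "
    "regulon OFF until IMA1 is also removed."
)
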