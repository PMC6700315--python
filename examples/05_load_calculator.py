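"""The DNA load calculator: limiting concentrations and multi-construct budgets.

Evaluates the published power law, re-derives it from the model, and budgets
ribosome load across two co-expressed constructs.
"""

import txtlkit as tk

ref = tk.ConstructSpec(P=1.0, U=1.0, Lm=800.0)
print(f"published power law: limiting DNA for the reference construct = "
      f"{tk.limiting_dna(ref):.2f} nM")

fit = tk.derive_power_law(tk.best_fit_parameters())
print(f"re-derived from the model: prefactor {fit.prefactor:.0f}, exponents "
      f"P {fit.exp_P:.3f}, U {fit.exp_U:.3f}, Lm {fit.exp_Lm:.3f}")
print(f"re-derived reference limit = {tk.limiting_dna(ref, fit):.2f} nM")

constructs = [
    tk.ConstructSpec(P=1.0, U=1.0, Lm=800.0, planned_conc=1.0, name="reporter"),
    tk.ConstructSpec(P=0.3, U=1.0, Lm=1500.0, planned_conc=4.0, name="payload"),
]
table = tk.budget_constructs(constructs)
print("\n" + table.to_string(index=False))
print(f"total translation load: {table.attrs['total_load']:.1%}")
# load_fraction is the share of translation capacity each construct consumes;
# remaining_limit_nM is how much of a construct could still be added given
# the load already imposed by the others.
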