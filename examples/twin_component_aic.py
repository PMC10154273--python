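"""A null twin component costs exactly its AIC penalty.

The T effect groups individuals who shared a pregnancy (same family, same
birth date). When the data contain no twin-specific variance the ML
estimate of T lands on the zero boundary, the ACTE and ACE likelihoods
tie, and AIC(ACTE) - AIC(ACE) equals the bare one-parameter penalty 2.0;
a chance T signal can only shrink that difference.
"""

from famvc import FitOptions, SimulationConfig, compare_models, fit_model, simulate_dataset

config = SimulationConfig(
    n_mz=150, n_dz=200, n_sib=150,
    fractions={"A": 0.5, "C": 0.2, "E": 0.3},   # no T in the truth
    age_slope=0.05, sex_effect=0.3, seed=9005,
)
table, _, _ = simulate_dataset(config)

opts = FitOptions(compute_ci=False)
ace = fit_model(table, "pheno", "ACE", options=opts)
acte = fit_model(table, "pheno", "ACTE", options=opts)
cmp = compare_models(ace, acte)

print("ACTE fractions:", {e: round(v, 3) for e, v in acte.fractions.items()})
print("T on boundary:", "T" in acte.boundary_effects)
print(f"delta log-likelihood = {cmp.delta_loglik:.6f}")
print(f"delta AIC (ACTE - ACE) = {cmp.delta_aic:.3f}  (penalty for a null component)")
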