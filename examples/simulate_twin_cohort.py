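"""Simulate a twin/family cohort with known variance fractions.

Builds 300 MZ-pair, 400 DZ-pair, 200 sibling-pair and 100 singleton
families at one visit, with additive-genetic fraction 0.6 and shared
environment 0.2, then prints the realized twin correlations. Under the
generative model r_MZ = f_A + f_C and r_DZ = 0.5 f_A + f_C, so the
printed correlations should sit near 0.8 and 0.5.
"""

from famvc import SimulationConfig, simulate_dataset

config = SimulationConfig(
    n_mz=300, n_dz=400, n_sib=200, n_singleton=100,
    fractions={"A": 0.6, "C": 0.2, "E": 0.2},
    age_slope=0.05, sex_effect=0.3, seed=1,
)
table, grm, truth = simulate_dataset(config)

print(f"observations: {truth.n_obs}, subjects: {truth.n_subjects}, "
      f"families: {truth.n_families}")
print(table.head(4).to_string(index=False))
print(f"realized r_MZ  = {truth.r_mz:.3f}  (model-implied 0.80)")
print(f"realized r_DZ  = {truth.r_dz:.3f}  (model-implied 0.50)")
print(f"realized r_sib = {truth.r_sib:.3f}  (model-implied 0.50)")
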