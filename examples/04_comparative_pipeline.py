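"""Phylogenetically corrected five-group comparison of growth rates.

Simulates a species-level dataset calibrated to the reported group mean
rates (non-probainognathian cynodonts fast-extending, mammaliamorphs slow,
plus diapsids and non-hypsodont/hypsodont crown mammals), then runs the
full chain: PGLS mass correction, Box-Cox, MANOVA, pairwise contrasts with
FDR, univariate ANOVAs and Kruskal-Wallis/Dunn tests.
"""

import enamelgrowth as eg
from enamelgrowth import stats as st

cfg = eg.published_means_comparative_config(seed=1)
table = eg.simulate_species_dataset(cfg)
res = st.run_group_comparison(table, cfg.tree)

m = res.manova
print(f"N = {res.provenance['n_species']} species in "
      f"{len(res.provenance['groups'])} groups")
print(f"MANOVA: Wilks lambda = {m.wilks_lambda:.3f}, "
      f"F({m.df1:.0f},{m.df2:.0f}) = {m.F_stat:.1f}, p = {m.p_value:.2e}, "
      f"multivariate partial eta^2 = {m.partial_eta_sq_mv:.3f}")
for resp, a in res.anova_per_variable.items():
    print(f"ANOVA {resp.upper()}: F({a.df1},{a.df2}) = {a.F_stat:.2f}, "
          f"p = {a.p_value:.2e}, partial eta^2 = {a.partial_eta_sq:.3f}")

np_, mm = "non_probainognathian", "mammaliamorph"
print("pairwise (FDR-adjusted) non-probainognathian vs mammaliamorph:")
print(f"  CER p = {res.pairwise_anova_p['cer'].loc[np_, mm]:.4f}  "
      "(the groups separate on extension rate)")
print(f"  DSR p = {res.pairwise_anova_p['dsr'].loc[np_, mm]:.4f}  "
      "(no difference in secretion rate)")
print(f"Box-Cox lambdas: {res.provenance['boxcox_lambda']}")
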