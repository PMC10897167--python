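"""Two-way ANOVA with Fisher's LSD post hocs under Bonferroni-corrected alphas.

Generates a balanced age x genotype outcome table with a programmed
interaction (the knockout group fails to change with age), decomposes it by
two-way ANOVA, and tests targeted pairwise contrasts with Fisher's LSD at
the alpha corrected for a 4-way comparison family.
"""

import saxstrain as sx

means = {("4mo", "Ctrl"): 12.0, ("15mo", "Ctrl"): 9.0,   # controls decline
         ("4mo", "KO"): 9.0, ("15mo", "KO"): 9.0}        # knockouts start low
data = sx.simulate_group_outcomes(
    ["4mo", "15mo"], ["Ctrl", "KO"], means, sd=1.2, n_per_cell=10, seed=4
)

anova = sx.two_way_anova(data, factors=("age", "genotype"))
print(anova.table.round(4))
p_int = anova.table.loc["age:genotype", "p"]
print(f"\ninteraction p = {p_int:.4f} "
      "(age effect depends on genotype)" if p_int < 0.05 else "")

alpha = sx.bonferroni_alpha(4)
for pair in [(("4mo", "Ctrl"), ("15mo", "Ctrl")),
             (("4mo", "Ctrl"), ("4mo", "KO")),
             (("4mo", "KO"), ("15mo", "KO"))]:
    res = sx.fisher_lsd(anova, *pair)
    mark = "*" if res.p_value < alpha.exact else " "
    print(f"LSD {pair[0]} vs {pair[1]}: t = {res.t_statistic:6.2f}, "
          f"p = {res.p_value:.4f} {mark}")
print(f"(* significant at the 4-way Bonferroni alpha {alpha.exact})")
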