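"""Does low accessibility predict late-stage diagnosis?

Cases are simulated with a known effect (OR 1.3 for low accessibility,
OR 1.2 for high deprivation) and then analyzed with the multilevel
logistic battery: model I adjusts for age, II for age + race, III adds
the deprivation index; the joint form crosses both exposures into a
4-level factor and the stratified form fits within deprivation strata.
"""

import numpy as np

import floatcatch as fc

spec = fc.RegionSpec(n_blockgroups=200, n_facilities=20, seed=7)
bg, fac, net = fc.generate_region(spec)
od = fc.od_matrix(net, bg, fac)
access = fc.compute_all_measures(od, fc.machine_columns(fac), bg["population"])
dep = fc.build_deprivation_index(fc.generate_deprivation_covariates(bg, seed=7))

outcome = fc.OutcomeModelSpec(intercept=-0.3,
                              beta_access=np.log(1.3),
                              beta_deprivation=np.log(1.2),
                              random_intercept_sd=0.3,
                              n_cases=6000, seed=11)
cases = fc.generate_cases(bg, access["SA6Q"], dep["score"], outcome)
print(f"{len(cases)} cases, {cases['late_stage'].mean():.1%} late stage")

tagged = fc.attach_exposures(cases, access, dep["score"], measure="SA6Q")
for form in ("I", "II", "III"):
    res = fc.fit_multilevel_logistic(tagged, form=form)
    t = res.terms.loc["low_access"]
    print(f"model {form:3s} low-access OR = {t['OR']:.2f} "
          f"({t['ci_low']:.2f}, {t['ci_high']:.2f})  "
          f"scaled deviance {res.scaled_deviance:.0f}")

strat = fc.fit_multilevel_logistic(tagged, form="stratified")
for name, sres in strat.strata.items():
    t = sres.terms.loc["low_access"]
    print(f"stratum {name:14s} OR = {t['OR']:.2f} ({t['ci_low']:.2f}, {t['ci_high']:.2f})")

print("\nThe generating low-access OR is 1.30; the fitted CIs should cover "
      "it, and the deprivation-adjusted model III attenuates it only "
      "slightly because the two exposures are nearly independent here.")
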