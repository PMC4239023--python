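"""Fit the size-dependent detection model and read off its thresholds.

Detection is logistic in colony size N: logit(p) = beta0 + beta1 N.
The inverse N*(p) gives the colony size needed to reach a stated
detection probability (the published continental coefficients put 50%
detection near 2.5k pairs and 99% near 13k pairs).
"""

from guanosat import detection
from guanosat.pipeline import RunConfig, run_survey

survey = run_survey(RunConfig(seed=4))
for region in ("continent", "peninsula"):
    recs = [r for r in survey.registry if r.region == region]
    match = survey.matches[region]
    fit = detection.fit_detection_model(
        [(r.n_vhr, int(match.detected[r.colony_id])) for r in recs], region)
    print(f"{region}: beta0 = {fit.beta0:.2f} (SE {fit.se0:.2f}), "
          f"beta1 = {fit.beta1:.2e} (SE {fit.se1:.2e})")
    for p, n_star in detection.thresholds_table(fit).items():
        print(f"   p(detect) = {p:.2f} at {max(0, n_star):,.0f} pairs")
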