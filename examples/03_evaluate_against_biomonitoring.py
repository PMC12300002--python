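"""Generate biomonitoring with known truth and score the model against it.

Synthetic serum/muscle records are drawn around the known-parameter
trajectory with 10 % lognormal measurement noise, then compared to the
stochastic ensemble with the study's agreement statistics.
"""

import datetime as dt

from herdtk import (
    SynthSpec,
    evaluate_scenario,
    generate_biomonitoring,
    generate_farm,
    mape,
    simulate_ensemble,
)

scenario = generate_farm(SynthSpec(seed=1))
lh = scenario.life_history
dates = [dt.date(2021, 4, 30), lh.end_date]  # end of each winter
bio = generate_biomonitoring(scenario, dates, n_animals=5, noise_cv=0.10, seed=1)

ensembles = {a: simulate_ensemble(scenario, a, n=100, seed=1) for a in scenario.analytes}
report = evaluate_scenario(ensembles, bio)
cols = ["date", "analyte", "matrix", "measured_mean", "modeled_mean", "pct_error_display"]
print(report[cols].round(2).to_string(index=False))
print(f"\nMAPE: {mape(report['pct_error']):.0f}%")
print(
    "Percentage errors compare the 100-simulation mean to the measured mean on "
    "the same day; small errors here confirm the pipeline is self-consistent "
    "when the truth is known."
)
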