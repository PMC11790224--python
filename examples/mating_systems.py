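"""Sexual selection on timing differs between mating systems.

One mating season on a toy patch with standing timing variance, no
viability selection.  Under the first-male-precedence baseline, males
return to the market every night while mated females leave, so early-
active males accumulate extra matings; under monogamy both sexes leave in
pairs and the advantage disappears.  The printed "sire shift" is the mean
chronotype of clutch sires minus the male population mean: negative means
sires are earlier than the average male.
"""

import numpy as np

from allochron import ActivityParams, SeasonParams, assign_sire, run_season
from allochron.individual import MALE
from allochron.toys import toy_patch

# a sparse market (eta=1) keeps the season from clearing in one night,
# which is the regime where multi-night male mating matters
activity = ActivityParams(a=50.0, eta=1.0)

for system in ("baseline", "scramble", "monogamy"):
    shifts = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        roster = toy_patch(100, 100, rng)
        males = [i for i in roster if i.sex == MALE]
        records = run_season(roster, SeasonParams(T=100, system=system), activity, rng)
        for r in records:
            assign_sire(r, system, rng)
        sires = [r.sire.tau_adult for r in records]
        shifts.append(np.mean(sires) - np.mean([m.tau_adult for m in males]))
    print(f"{system:9s}: sire shift {np.mean(shifts):+.4f} "
          f"(SE {np.std(shifts) / np.sqrt(len(shifts)):.4f}) over 20 seasons")

print("\nbaseline shows the early-male advantage; monogamy suppresses it.")
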