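"""Rebuild the benchmark life tables from their survivor columns.

The package ships the stage-survivor columns and next-brood egg totals of a
two-generation rearing trial (six diets, 33 eggs per cohort).  Everything
else in a life table — lx, px, qx, dx, the population trend T — is pure
arithmetic on those integers, which this script reruns and prints.

Run:  python examples/reference_tables.py
"""

from cohortdd import generations_per_year, mean_trend, render_life_table
from cohortdd.reference import (
    REFERENCE_CUMULATIVE_ADD,
    reference_life_tables,
)

tables = reference_life_tables()

for diet, by_gen in tables.items():
    print("=" * 72)
    for gen, table in by_gen.items():
        print(render_life_table(table))
        print()
    if len(by_gen) == 2:
        est = mean_trend([by_gen[1].trend, by_gen[2].trend])
        print(f"mean trend T_{diet} = {est.t_mean:.2f}")
    else:
        print(f"{diet}: cohort extinct before adulthood, no second brood")
    print()

print("=" * 72)
print("Generations per year at a constant 25 degC (3650 degree-days/year):")
for diet, by_gen in REFERENCE_CUMULATIVE_ADD.items():
    for gen, (mean_add, sd) in by_gen.items():
        g = generations_per_year(25.0, mean_add)
        print(
            f"  {diet} generation {gen}: {mean_add:7.2f} ADD egg-to-adult"
            f" -> {g.rate:.2f} generations (at most {g.ceiling})"
        )
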