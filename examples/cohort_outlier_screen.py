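"""Personalized-cohort sensitivity analysis with Dixon's Q screening.

Generates a nine-individual synthetic cohort (log-normal inter-individual
variation on concentrations and equilibrium constants), injects one
individual whose PFK ATP- and F6P-binding constants are 3x off, builds a
personalized glycolysis + shunt + hemoglobin + PFK model for each, and
screens every pseudo-elementary rate constant across the cohort with
Dixon's Q test at 99% confidence.
"""

import catpot as cp

spec = cp.CohortSpec(
    n=9, sigma=0.2,
    outlier=cp.OutlierSpec(individual_index=0, enzyme="PFK",
                           fields=("kd_cofactor", "kd_substrate"), fold_change=3.0),
    seed=42,
)
individuals = cp.generate_cohort(spec)
print(f"cohort: {len(individuals)} individuals "
      f"(source-study ids {[i.source_label for i in individuals]})")

table = cp.build_cohort(individuals)
print(f"parameterized models: {len(table.individuals)} "
      f"(excluded: {list(table.excluded) or 'none'})")

critical = cp.dixon_critical_value(9, confidence=0.99, reps=200_000, rng_seed=0)
print(f"Monte-Carlo Dixon Q critical value (n=9, 99%): {critical:.3f}")

results = cp.screen_outlier_percs(table, critical_value=critical)
flagged = [r for r in results if r.outlier]
print(f"\nflagged rate constants ({len(flagged)}):")
for r in flagged:
    print(f"  {r.parameter:18s} Q = {r.q:.3f}  suspect: {r.suspect}")
print("\nThe PFK catalytic-site binding steps are recovered as outliers and "
      "attributed to the perturbed individual.")
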