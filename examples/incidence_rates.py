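"""Directly age-standardized incidence rates and their ratio.

Builds a toy two-stratum example: a small lymphoma cohort with one
incident lung cancer against a large age-matched general population,
standardized to the same weights.
"""

from chlymph import AgeStratum, age_adjusted_rate, rate_ratio, two_proportion_ztest

weights = {"60-69": 0.6, "70-79": 0.4}  # standard-population shares
cohort = [
    AgeStratum("60-69", cases=1, person_base=18, weight=weights["60-69"]),
    AgeStratum("70-79", cases=1, person_base=10, weight=weights["70-79"]),
]
population = [
    AgeStratum("60-69", cases=9_000, person_base=12_000_000, weight=weights["60-69"]),
    AgeStratum("70-79", cases=11_000, person_base=9_000_000, weight=weights["70-79"]),
]

r_cohort = age_adjusted_rate(cohort)
r_pop = age_adjusted_rate(population)
print(f"cohort age-adjusted rate:     {r_cohort.rate_per_100k:,.0f} per 100,000")
print(f"population age-adjusted rate: {r_pop.rate_per_100k:,.1f} per 100,000")
print(f"rate ratio: {rate_ratio(r_cohort.rate_per_100k, r_pop.rate_per_100k):,.1f}")

z = two_proportion_ztest(2, 28, 20_000, 21_000_000)
print(f"two-proportion z test: z = {z['z']:.1f}, p = {z['p_two_sided']:.1e}")
print()
print("Each stratum's rate is cases/person-base x 100,000, combined with the")
print("standard-population weights, so cohorts with different age structures")
print("become comparable; the z test checks the crude proportion difference.")
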