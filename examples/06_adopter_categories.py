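"""Adopter categories and city composition from an adoption table.

Classifies adopters into the four diffusion-of-innovations categories by
standard-deviation bands around the mean adoption week, then profiles each
city by the fraction of its users in each national category.
"""

import numpy as np

from adoptnet import classify_adopters, city_composition
from adoptnet.analysis import category_proportions

rng = np.random.default_rng(10)
# stylised national adoption: most adopters near the mean week, long tails
weeks = np.clip(rng.normal(80, 25, size=20_000), 0, None).round()
cities = rng.integers(0, 12, size=weeks.size)

cats = classify_adopters(weeks)
print("national category shares:")
for name, frac in category_proportions(cats).items():
    print(f"  {name:15s} {frac:6.1%}")

comp = city_composition(cities, cats)
print("\nper-city composition (first 3 cities):")
print(comp.head(3).round(3).to_string())
print("\nrows sum to one; a city's profile is relative to the national")
print("classification, which normalises locations by population size.")
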